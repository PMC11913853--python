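"""Synthetic two-line selective-breeding cross with planted effects.

Generates founder lines with partially segregated biallelic SNPs, an
F1/F2 intercross under Haldane (no-interference) recombination, planted
cis-eQTL effects on negative-binomial counts, planted QTL effects on
correlated continuous behaviors, sex/batch covariate effects, and truth
tables for every planted effect, so each downstream analysis stage can be
validated against known ground truth.

Conventions: the two lines are labelled ``bHR`` (high responder: high
exploratory locomotion) and ``bLR`` (low responder: inhibited, anxious).
Dosages count alternate alleles (0/1/2). Genetic map positions are linear
in physical position (constant cM/Mb per chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AFC_CAP = np.log2(100.0)  # estimator cap on |allelic fold change|, log2 units

#: Multiplier mapping each behavior's raw axis onto "bLR-like = positive".
#: bLR rats show low locomotion, low exploration, high immobility, low %
#: open arms, and low (goal-tracking) PavCA index.
BLR_SIGN = {
    "LocoScore": -1.0,
    "EPM_DistanceTraveled": -1.0,
    "EPM_TimeImmobile": +1.0,
    "EPM_PctTimeOpenArms": -1.0,
    "PavCA_Index": -1.0,
}

#: Juvenile open-field battery used by the replication cohort.
BLR_SIGN_JUVENILE = {
    "OF_DistanceTraveled": -1.0,
    "OF_TimeImmobile": +1.0,
    "OF_PctTimeCenter": -1.0,
}

ADULT_BEHAVIORS = list(BLR_SIGN)
JUVENILE_BEHAVIORS = list(BLR_SIGN_JUVENILE)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Coordinate frame for the synthetic genome.

    SNP and gene TSS positions are drawn uniformly and strictly inside
    chromosome bounds; the genetic map is linear (``chrom_length_cM`` over
    ``chrom_length_bp``).
    """

    n_chrom: int = 3
    chrom_length_bp: int = 100_000_000
    # 3 desk-scale chromosomes stand in for the ~20 rat autosomes; per-
    # chromosome map length is set so the genome-wide recombination budget
    # (~1,500 cM) is conserved, which controls LD decay between unlinked
    # planted effects and hence the resolution of downstream QTL mapping.
    chrom_length_cM: float = 500.0
    n_snps_per_chrom: int = 2000
    n_genes_per_chrom: int = 100

    def validate(self) -> None:
        if min(self.n_chrom, self.n_snps_per_chrom, self.n_genes_per_chrom) < 1:
            raise ValueError("counts must be >= 1")
        if self.chrom_length_bp <= 0 or self.chrom_length_cM < 0:
            raise ValueError("chromosome lengths must be positive")


@dataclass
class FounderLineSpec:
    """Allele-frequency architecture of the two founder lines.

    ``frac_fixed_divergent`` SNPs are fixed for opposite alleles between
    lines; ``frac_partially_segregated`` SNPs have large but incomplete
    divergence (default line frequencies 0.0 vs 0.55); the remainder share
    a common frequency drawn from Beta(``background_beta``). Within-line
    genotypes are drawn under Hardy-Weinberg at the line frequency.
    """

    n_per_line: int = 10
    frac_fixed_divergent: float = 0.05
    frac_partially_segregated: float = 0.10
    partial_freqs: tuple[float, float] = (0.0, 0.55)
    background_beta: tuple[float, float] = (2.0, 2.0)

    def validate(self) -> None:
        f1, f2 = self.frac_fixed_divergent, self.frac_partially_segregated
        if not (0 <= f1 <= 1 and 0 <= f2 <= 1 and f1 + f2 <= 1):
            raise ValueError("category fractions must lie in [0,1] and sum to <= 1")
        if self.n_per_line < 1:
            raise ValueError("need at least one individual per line")


@dataclass
class PlantedEqtl:
    gene_id: str
    evariant_id: str
    true_afc: float  # log2(alternate / reference haplotype expression)
    window_offset_bp: int = 0

    def __post_init__(self) -> None:
        if abs(self.true_afc) > AFC_CAP:
            raise ValueError(f"|aFC| exceeds the log2(100) cap: {self.true_afc}")
        if abs(self.window_offset_bp) > 1_000_000:
            raise ValueError("planted eVariant outside the +/-1 Mb cis window")


@dataclass
class PlantedQtl:
    variant_id: str
    behavior_name: str
    effect_size: float  # behavior units per alternate-allele dose
    pleiotropic_gene: str | None = None


@dataclass
class FounderData:
    """Phased founder genotypes plus the allele-frequency truth table."""

    haplotypes: np.ndarray  # (n_ind, 2, n_snps) int8
    line: np.ndarray  # "bHR"/"bLR" per individual
    sample_ids: list[str]
    snp_table: pd.DataFrame  # variant_id, chrom, pos, cm, ref, alt, category, p_bHR, p_bLR

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)


@dataclass
class CrossData:
    """F1 and F2 phased genotypes with recorded pedigree."""

    f1_haplotypes: np.ndarray  # (n_f1, 2, n_snps); hap 0 from bHR parent, 1 from bLR
    f1_parents: np.ndarray  # (n_f1, 2) founder row indices (bHR, bLR)
    f2_haplotypes: np.ndarray  # (n_f2, 2, n_snps)
    f2_parents: np.ndarray  # (n_f2, 2) F1 row indices
    f2_sample_ids: list[str]

    @property
    def f2_dosages(self) -> np.ndarray:
        return self.f2_haplotypes.sum(axis=1)


# ---------------------------------------------------------------------------
# genome + founders
# ---------------------------------------------------------------------------


def build_genome(config: GenomeConfig, rng: np.random.Generator):
    """Draw SNP and gene-TSS coordinates.

    Returns ``(snp_table, gene_table)``: per-SNP chrom/pos/cM and per-gene
    chrom/TSS/strand, both sorted by position within chromosome.
    """
    config.validate()
    snp_rows, gene_rows = [], []
    for c in range(1, config.n_chrom + 1):
        pos = _draw_unique_positions(rng, config.chrom_length_bp, config.n_snps_per_chrom)
        cm = pos / config.chrom_length_bp * config.chrom_length_cM
        ref, alt = _draw_alleles(rng, config.n_snps_per_chrom)
        for j in range(config.n_snps_per_chrom):
            snp_rows.append((f"chr{c}:{pos[j]}", f"chr{c}", int(pos[j]), cm[j], ref[j], alt[j]))
        tss = _draw_unique_positions(rng, config.chrom_length_bp, config.n_genes_per_chrom)
        strand = rng.choice(["+", "-"], size=config.n_genes_per_chrom)
        for j in range(config.n_genes_per_chrom):
            gene_rows.append((f"gene_{c}_{j:04d}", f"chr{c}", int(tss[j]), strand[j]))
    snp_table = pd.DataFrame(snp_rows, columns=["variant_id", "chrom", "pos", "cm", "ref", "alt"])
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])
    return snp_table, gene_table


def _draw_unique_positions(rng, length_bp, n):
    """n distinct sorted positions strictly inside (0, length_bp)."""
    if n >= length_bp - 1:
        raise ValueError("more positions requested than available base pairs")
    pos = np.unique(rng.integers(1, length_bp, size=2 * n + 16))
    while len(pos) < n:  # collisions: top up (astronomically rare at desk scale)
        pos = np.unique(np.concatenate([pos, rng.integers(1, length_bp, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _draw_alleles(rng, n):
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return bases[ref], bases[alt]


def simulate_founder_lines(
    genome: GenomeConfig, lines: FounderLineSpec, rng: np.random.Generator
) -> FounderData:
    """Simulate phased founder genotypes for the two lines.

    SNP categories (fixed-divergent / partially segregated / background)
    are assigned deterministically by count (``round(frac * n_snps)``) at
    random positions; for divergent categories the line that carries the
    alternate allele is randomized per SNP.
    """
    genome.validate()
    lines.validate()
    snp_table, _ = build_genome(genome, rng)
    n_snps = len(snp_table)
    n_fixed = int(round(lines.frac_fixed_divergent * n_snps))
    n_partial = int(round(lines.frac_partially_segregated * n_snps))
    order = rng.permutation(n_snps)
    category = np.full(n_snps, "background", dtype=object)
    category[order[:n_fixed]] = "fixed_divergent"
    category[order[n_fixed : n_fixed + n_partial]] = "partially_segregated"

    p_bhr = np.empty(n_snps)
    p_blr = np.empty(n_snps)
    bg = category == "background"
    shared = rng.beta(*lines.background_beta, size=int(bg.sum()))
    p_bhr[bg] = shared
    p_blr[bg] = shared
    # randomized orientation: which line is enriched for the alternate allele
    alt_in_blr = rng.random(n_snps) < 0.5
    fx = category == "fixed_divergent"
    p_bhr[fx] = np.where(alt_in_blr[fx], 0.0, 1.0)
    p_blr[fx] = np.where(alt_in_blr[fx], 1.0, 0.0)
    pa = category == "partially_segregated"
    lo, hi = lines.partial_freqs
    p_bhr[pa] = np.where(alt_in_blr[pa], lo, hi)
    p_blr[pa] = np.where(alt_in_blr[pa], hi, lo)

    n = lines.n_per_line
    hap_bhr = (rng.random((n, 2, n_snps)) < p_bhr).astype(np.int8)
    hap_blr = (rng.random((n, 2, n_snps)) < p_blr).astype(np.int8)
    haplotypes = np.concatenate([hap_bhr, hap_blr], axis=0)
    line = np.array(["bHR"] * n + ["bLR"] * n)
    sample_ids = [f"bHR_{i:02d}" for i in range(n)] + [f"bLR_{i:02d}" for i in range(n)]
    snp_table = snp_table.assign(category=category, p_bHR=p_bhr, p_bLR=p_blr)
    return FounderData(haplotypes, line, sample_ids, snp_table)


# ---------------------------------------------------------------------------
# recombination + cross
# ---------------------------------------------------------------------------


def make_gamete(
    hap_pair: np.ndarray, cm_pos: np.ndarray, chrom_length_cM: float, rng: np.random.Generator
) -> np.ndarray:
    """Form one gamete from a phased haplotype pair on a single chromosome.

    Haldane model: the crossover count is Poisson(length in Morgans),
    crossover positions are uniform on the cM map, there is no
    interference. A chromosome of length 0 cM transmits an intact parental
    haplotype.
    """
    if hap_pair.ndim != 2 or hap_pair.shape[0] != 2:
        raise ValueError("expected a phased (2, n_snps) haplotype pair")
    if np.any(np.diff(cm_pos) < 0):
        raise ValueError("map positions must be monotone")
    n_x = rng.poisson(chrom_length_cM / 100.0)
    start = rng.integers(2)
    if n_x == 0:
        return hap_pair[start].copy()
    xpos = np.sort(rng.uniform(0.0, chrom_length_cM, size=n_x))
    which = (start + np.searchsorted(xpos, cm_pos)) % 2
    return hap_pair[which, np.arange(hap_pair.shape[1])]


def _gamete_genomewide(haps, chrom_blocks, cm, chrom_length_cM, rng):
    out = np.empty(haps.shape[1], dtype=np.int8)
    for idx in chrom_blocks:
        out[idx] = make_gamete(haps[:, idx], cm[idx], chrom_length_cM, rng)
    return out


def simulate_cross(
    founders: FounderData,
    n_f1: int,
    n_f2: int,
    chrom_length_cM: float,
    rng: np.random.Generator,
) -> CrossData:
    """Breed F1 (one parent per line) and F2 (random non-sib F1 x F1 pairs).

    Each F1 carries one unrecombined gamete from a bHR founder and one from
    a bLR founder; each F2 genotype is the union of two recombinant F1
    gametes, with the pedigree recorded for Mendelian-consistency checks.
    """
    if n_f1 < 2:
        raise ValueError("need at least two F1 individuals to intercross")
    snp_table = founders.snp_table
    chrom_blocks = list(snp_table.groupby("chrom", sort=False).indices.values())
    cm = snp_table["cm"].values
    bhr_idx = np.flatnonzero(founders.line == "bHR")
    blr_idx = np.flatnonzero(founders.line == "bLR")
    n_snps = founders.haplotypes.shape[2]

    f1_h = np.empty((n_f1, 2, n_snps), dtype=np.int8)
    f1_parents = np.empty((n_f1, 2), dtype=int)
    for i in range(n_f1):
        pa = rng.choice(bhr_idx)
        pb = rng.choice(blr_idx)
        f1_h[i, 0] = _gamete_genomewide(founders.haplotypes[pa], chrom_blocks, cm, chrom_length_cM, rng)
        f1_h[i, 1] = _gamete_genomewide(founders.haplotypes[pb], chrom_blocks, cm, chrom_length_cM, rng)
        f1_parents[i] = (pa, pb)

    f2_h = np.empty((n_f2, 2, n_snps), dtype=np.int8)
    f2_parents = np.empty((n_f2, 2), dtype=int)
    for i in range(n_f2):
        m, f = _pick_nonsib_pair(f1_parents, rng)
        f2_h[i, 0] = _gamete_genomewide(f1_h[m], chrom_blocks, cm, chrom_length_cM, rng)
        f2_h[i, 1] = _gamete_genomewide(f1_h[f], chrom_blocks, cm, chrom_length_cM, rng)
        f2_parents[i] = (m, f)

    ids = [f"F2_{i:04d}" for i in range(n_f2)]
    return CrossData(f1_h, f1_parents, f2_h, f2_parents, ids)


def _pick_nonsib_pair(f1_parents, rng, max_tries=100):
    n = len(f1_parents)
    for _ in range(max_tries):
        m, f = rng.choice(n, size=2, replace=False)
        if not np.array_equal(f1_parents[m], f1_parents[f]):
            return m, f
    return m, f  # all F1 are sibs; accept (degenerate config)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_behavior(
    dosages: np.ndarray,
    variant_ids: pd.Index | list[str],
    planted_qtls: list[PlantedQtl],
    behaviors: list[str],
    sex: np.ndarray,
    rng: np.random.Generator,
    sex_effects: dict[str, float] | None = None,
    polygenic_loading: float = 0.3,
    noise_sd: float = 0.85,
    sign_convention: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate correlated continuous behaviors for one cohort.

    behavior = sum(dosage * effect) + sex term + shared polygenic factor
    + independent noise. The shared factor enters each behavior through
    its bLR-sign multiplier, so all behaviors are mutually correlated
    along the bLR-like/bHR-like axis, mirroring the phenotypic
    correlations that selective breeding produces.
    """
    sign_convention = dict(BLR_SIGN, **BLR_SIGN_JUVENILE) if sign_convention is None else sign_convention
    sex_effects = sex_effects or {}
    vindex = pd.Index(variant_ids)
    for q in planted_qtls:
        if q.behavior_name not in behaviors:
            raise ValueError(f"unknown behavior in planted QTL: {q.behavior_name}")
    n = dosages.shape[0]
    g = rng.normal(size=n)  # shared polygenic bLR-like factor
    is_female = (np.asarray(sex) == "F").astype(float)
    out = {}
    for b in behaviors:
        mult = sign_convention[b]
        y = mult * polygenic_loading * g + sex_effects.get(b, 0.0) * is_female
        y = y + rng.normal(scale=noise_sd, size=n)
        for q in planted_qtls:
            if q.behavior_name == b:
                j = vindex.get_loc(q.variant_id)
                y = y + dosages[:, j] * q.effect_size
        out[b] = y
    return pd.DataFrame(out)


def simulate_expression(
    dosages: np.ndarray,
    variant_ids: pd.Index | list[str],
    gene_table: pd.DataFrame,
    planted_eqtls: list[PlantedEqtl],
    covariates: pd.DataFrame,
    covariate_log2_effects: pd.DataFrame,
    base_mean: np.ndarray,
    dispersion: np.ndarray,
    lib_factor: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial counts under an additive cis-regulatory model.

    Mean for individual i at gene g:
        mu = base_g * ((2 - d_i) + d_i * 2^aFC) / 2 * 2^(covariate terms) * lib_i
    so the log2 ratio of homozygote group means equals the planted aFC
    exactly in expectation. Counts are NB(mu, dispersion_g); dispersion 0
    falls back to Poisson.

    ``covariate_log2_effects`` is genes x covariate-columns (log2 scale per
    unit of the matching ``covariates`` column).
    """
    genes = gene_table["gene_id"].tolist()
    vindex = pd.Index(variant_ids)
    n = dosages.shape[0]
    log2mu = np.tile(np.log2(base_mean)[:, None], (1, n))
    for e in planted_eqtls:
        gi = genes.index(e.gene_id)
        d = dosages[:, vindex.get_loc(e.evariant_id)].astype(float)
        log2mu[gi] += np.log2(((2.0 - d) + d * 2.0**e.true_afc) / 2.0)
    common = [c for c in covariate_log2_effects.columns if c in covariates.columns]
    if common:
        log2mu += covariate_log2_effects[common].values @ covariates[common].values.T
    mu = 2.0**log2mu * lib_factor[None, :]
    counts = _rnbinom(mu, dispersion[:, None], rng)
    return pd.DataFrame(counts, index=genes, columns=list(covariates.index))


def _rnbinom(mu, phi, rng):
    """NB draws parameterized by mean and dispersion (var = mu + phi mu^2)."""
    phi = np.broadcast_to(phi, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi < 1e-8
    out[pois] = rng.poisson(mu[pois])
    if np.any(~pois):
        size = 1.0 / phi[~pois]
        p = size / (size + mu[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


# ---------------------------------------------------------------------------
# Pavlovian conditioned approach index
# ---------------------------------------------------------------------------


def compute_pavca_index(
    prob_lever,
    prob_magazine,
    n_lever_contacts,
    n_magazine_entries,
    latency_lever_s,
    latency_magazine_s,
    cs_duration_s: float = 8.0,
):
    """Pavlovian conditioned approach composite index and ST/IN/GT class.

    index = mean of (1) probability difference (lever - magazine),
    (2) response bias (lever - magazine)/(lever + magazine contacts), and
    (3) latency score (magazine latency - lever latency)/CS duration.
    Class: sign-tracker (ST) if index > 0.5, goal-tracker (GT) if < -0.5,
    intermediate (IN) otherwise. Animals with zero total contacts have an
    undefined response bias and are returned flagged with a NaN index.

    Returns ``(index, cls, flagged)`` as numpy arrays (scalars broadcast).
    """
    pl, pm = np.asarray(prob_lever, float), np.asarray(prob_magazine, float)
    nl, nm = np.asarray(n_lever_contacts, float), np.asarray(n_magazine_entries, float)
    ll, lm = np.asarray(latency_lever_s, float), np.asarray(latency_magazine_s, float)
    pl, pm, nl, nm, ll, lm = np.broadcast_arrays(pl, pm, nl, nm, ll, lm)
    if np.any((pl < 0) | (pl > 1) | (pm < 0) | (pm > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any((ll < 0) | (ll > cs_duration_s) | (lm < 0) | (lm > cs_duration_s)):
        raise ValueError("latencies must lie in [0, cs_duration_s]")
    if np.any(nl < 0) or np.any(nm < 0):
        raise ValueError("contact counts must be >= 0")
    total = nl + nm
    flagged = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(flagged, np.nan, (nl - nm) / np.where(total == 0, 1.0, total))
    latency_score = (lm - ll) / cs_duration_s
    index = (pl - pm + bias + latency_score) / 3.0
    cls = np.full(index.shape, "IN", dtype=object)
    cls[index > 0.5] = "ST"
    cls[index < -0.5] = "GT"
    cls[~np.isfinite(index)] = "NA"
    return index, cls, flagged


# ---------------------------------------------------------------------------
# whole-cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Study conditions for the default synthetic cohort.

    Scale mirrors the study's design: 10+10 sequenced founders, ~250 F2
    animals, a desk-scale genome of 3 chromosomes x 2,000 SNPs x 100 genes.
    Planted architecture: ``n_pleiotropic`` genes whose fixed-divergent
    eVariant drives both expression (|aFC| in ``afc_range``) and behavior
    (``qtl_effect_sd`` per alternate allele, signed so the bLR-enriched
    allele pushes behavior in the bLR-like direction); ``n_eqtl_segregated``
    genes with cis-eQTLs at partially segregated variants but no behavioral
    effect (these exercise the G'st threshold crossing); ``n_eqtl_background``
    genes with cis-eQTLs at non-divergent variants; ``n_line_de`` genes with
    a direct (non-cis) lineage effect on founder expression.
    """

    genome: GenomeConfig = field(default_factory=GenomeConfig)
    lines: FounderLineSpec = field(default_factory=FounderLineSpec)
    n_f1: int = 20
    n_f2: int = 250
    n_pleiotropic: int = 10
    n_eqtl_segregated: int = 6
    n_eqtl_background: int = 10
    n_line_de: int = 30
    afc_range: tuple[float, float] = (1.0, 2.0)
    background_afc_range: tuple[float, float] = (0.75, 1.5)
    qtl_effect_sd: float = 0.5
    line_de_log2fc: float = 1.0
    sex_behavior_effect: float = 0.3
    polygenic_loading: float = 0.3
    behavior_noise_sd: float = 0.85
    base_mean_log2_range: tuple[float, float] = (4.0, 10.0)
    dispersion_log_mean: float = np.log(0.05)
    dispersion_log_sd: float = 0.5
    libsize_cv: float = 0.3
    n_batches: int = 3
    juvenile_cohort: bool = False
    n_f2_juvenile: int = 216


@dataclass
class SimulatedCohort:
    """Everything downstream stages consume, plus planted-effect truth."""

    params: CohortParams
    seed: int
    founders: FounderData
    cross: CrossData
    snp_table: pd.DataFrame
    gene_table: pd.DataFrame
    # expression cohorts: primary founder (F0), replication founder, F2
    f0_counts: pd.DataFrame
    f0_pheno: pd.DataFrame
    f0rep_counts: pd.DataFrame
    f0rep_pheno: pd.DataFrame
    f0rep_founders: FounderData
    f2_counts: pd.DataFrame
    f2_pheno: pd.DataFrame
    planted_eqtls: list[PlantedEqtl]
    planted_qtls: list[PlantedQtl]
    planted_line_de: pd.DataFrame  # gene_id, log2fc (bLR vs bHR)
    juvenile: "SimulatedCohort | None" = None

    @property
    def truth_eqtls(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_id, e.evariant_id, e.true_afc, e.window_offset_bp) for e in self.planted_eqtls],
            columns=["gene_id", "evariant_id", "true_afc", "window_offset_bp"],
        )

    @property
    def truth_qtls(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(q.variant_id, q.behavior_name, q.effect_size, q.pleiotropic_gene) for q in self.planted_qtls],
            columns=["variant_id", "behavior_name", "effect_size", "pleiotropic_gene"],
        )

    @property
    def pleiotropic_genes(self) -> list[str]:
        return sorted({q.pleiotropic_gene for q in self.planted_qtls if q.pleiotropic_gene})


def _pick_evariant(snp_table, gene_row, category, rng, used):
    """Random unused SNP of the given category within +/-1 Mb of the TSS."""
    w = snp_table[
        (snp_table["chrom"] == gene_row["chrom"])
        & (snp_table["pos"] >= gene_row["tss"] - 1_000_000)
        & (snp_table["pos"] <= gene_row["tss"] + 1_000_000)
        & (snp_table["category"] == category)
        & (~snp_table["variant_id"].isin(used))
    ]
    if len(w) == 0:
        return None
    return w.iloc[rng.integers(len(w))]


def _plant_architecture(snp_table, gene_table, params, rng):
    """Assign planted eQTLs/QTLs/line-DE genes to random genes."""
    genes = gene_table.sample(frac=1.0, random_state=int(rng.integers(2**31 - 1))).reset_index(
        drop=True
    )
    eqtls: list[PlantedEqtl] = []
    qtls: list[PlantedQtl] = []
    line_de_rows = []
    used_variants: set[str] = set()
    gi = 0

    def next_gene():
        nonlocal gi
        row = genes.iloc[gi]
        gi += 1
        return row

    secondary = [b for b in ADULT_BEHAVIORS if b != "LocoScore"]
    for k in range(params.n_pleiotropic):
        while True:
            g = next_gene()
            v = _pick_evariant(snp_table, g, "fixed_divergent", rng, used_variants)
            if v is not None:
                break
        used_variants.add(v["variant_id"])
        afc = rng.uniform(*params.afc_range) * rng.choice([-1.0, 1.0])
        eqtls.append(
            PlantedEqtl(g["gene_id"], v["variant_id"], afc, int(v["pos"] - g["tss"]))
        )
        s = 1.0 if v["p_bLR"] > v["p_bHR"] else -1.0  # alt allele bLR-enriched?
        for b in ("LocoScore", secondary[k % len(secondary)]):
            qtls.append(
                PlantedQtl(v["variant_id"], b, BLR_SIGN[b] * params.qtl_effect_sd * s, g["gene_id"])
            )
    for cat, n_cat, rng_range in (
        ("partially_segregated", params.n_eqtl_segregated, params.afc_range),
        ("background", params.n_eqtl_background, params.background_afc_range),
    ):
        for _ in range(n_cat):
            while True:
                g = next_gene()
                v = _pick_evariant(snp_table, g, cat, rng, used_variants)
                if v is not None:
                    break
            used_variants.add(v["variant_id"])
            afc = rng.uniform(*rng_range) * rng.choice([-1.0, 1.0])
            eqtls.append(PlantedEqtl(g["gene_id"], v["variant_id"], afc, int(v["pos"] - g["tss"])))
    for _ in range(params.n_line_de):
        g = next_gene()
        line_de_rows.append((g["gene_id"], params.line_de_log2fc * rng.choice([-1.0, 1.0])))
    line_de = pd.DataFrame(line_de_rows, columns=["gene_id", "log2fc"])
    return eqtls, qtls, line_de


def _gene_covariate_effects(gene_table, columns, rng, frac=0.15, sd=0.2):
    """Sparse per-gene log2 effects for nuisance covariates."""
    eff = pd.DataFrame(0.0, index=gene_table["gene_id"], columns=columns)
    for c in columns:
        hit = rng.random(len(eff)) < frac
        eff.loc[hit, c] = rng.normal(scale=sd, size=int(hit.sum()))
    return eff


def _founder_pheno(founders, rng, prefix):
    n = len(founders.sample_ids)
    sex = np.array(["F", "M"] * (n // 2 + 1))[:n]
    return pd.DataFrame(
        {
            "Lineage": founders.line,
            "Sex": sex,
            "pct_rRNA": rng.normal(size=n),
            "pct_Intergenic": rng.normal(size=n),
        },
        index=pd.Index(founders.sample_ids, name="sample_id"),
    )


def _f2_pheno(cross, behaviors, rng, n_batches):
    n = len(cross.f2_sample_ids)
    sex = np.array(["F", "M"])[rng.integers(2, size=n)]
    pheno = pd.DataFrame(
        {
            "Sex": sex,
            "pct_rRNA": rng.normal(size=n),
            "pct_Intergenic": rng.normal(size=n),
            "Dissector": np.array(["D1", "D2"])[rng.integers(2, size=n)],
            "STGT_Experience": np.where(rng.random(n) < 0.85, "yes", "no"),
            "SequencingBatch": np.array([f"B{i+1}" for i in range(n_batches)])[
                rng.integers(n_batches, size=n)
            ],
        },
        index=pd.Index(cross.f2_sample_ids, name="sample_id"),
    )
    return pd.concat([pheno, behaviors.set_index(pheno.index)], axis=1)


def _expression_for(dosages, variant_ids, gene_table, eqtls, covar_numeric, gene_effects,
                    base_mean, dispersion, rng, libsize_cv, line=None, line_de=None):
    n = covar_numeric.shape[0]
    lib = rng.lognormal(mean=0.0, sigma=np.sqrt(np.log(1 + libsize_cv**2)), size=n)
    eff = gene_effects.copy()
    cov = covar_numeric.copy()
    if line is not None and line_de is not None and len(line_de):
        cov = cov.assign(_lineage=(np.asarray(line) == "bLR").astype(float))
        eff = eff.assign(_lineage=0.0)
        eff.loc[line_de["gene_id"].values, "_lineage"] = line_de["log2fc"].values
    return simulate_expression(
        dosages, variant_ids, gene_table, eqtls, cov, eff, base_mean, dispersion, lib, rng
    )


def simulate_cohort(params: CohortParams | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate the full synthetic study: founders, cross, counts, behaviors, truth.

    All randomness flows from ``seed``; identical seeds give bit-identical
    cohorts. Two founder expression cohorts are produced: the primary F0
    dataset and an independent replication cohort (new individuals drawn
    from the same line frequencies) that fills the second slot of the
    two-dataset DEG rule downstream.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7C55]))
    founders = simulate_founder_lines(params.genome, params.lines, rng)
    snp_table = founders.snp_table
    _, gene_table = build_genome(params.genome, np.random.default_rng(np.random.SeedSequence([seed, 0x6E])))
    cross = simulate_cross(founders, params.n_f1, params.n_f2, params.genome.chrom_length_cM, rng)
    eqtls, qtls, line_de = _plant_architecture(snp_table, gene_table, params, rng)
    vids = pd.Index(snp_table["variant_id"])

    # gene-level expression parameters shared across cohorts
    n_genes = len(gene_table)
    base_mean = 2.0 ** rng.uniform(*params.base_mean_log2_range, size=n_genes)
    dispersion = rng.lognormal(params.dispersion_log_mean, params.dispersion_log_sd, size=n_genes)
    f0_cols = ["pct_rRNA", "pct_Intergenic", "_sexF"]
    f2_cols = f0_cols + ["_batch2", "_batch3", "_dissector2", "_stgt"]
    gene_eff = _gene_covariate_effects(gene_table, f2_cols, rng)

    def numeric_covars(pheno):
        cov = pd.DataFrame(index=pheno.index)
        cov["pct_rRNA"] = pheno["pct_rRNA"]
        cov["pct_Intergenic"] = pheno["pct_Intergenic"]
        cov["_sexF"] = (pheno["Sex"] == "F").astype(float)
        if "SequencingBatch" in pheno:
            cov["_batch2"] = (pheno["SequencingBatch"] == "B2").astype(float)
            cov["_batch3"] = (pheno["SequencingBatch"] == "B3").astype(float)
            cov["_dissector2"] = (pheno["Dissector"] == "D2").astype(float)
            cov["_stgt"] = (pheno["STGT_Experience"] == "yes").astype(float)
        return cov

    # primary F0 expression cohort
    f0_pheno = _founder_pheno(founders, rng, "F0")
    f0_counts = _expression_for(
        founders.dosages, vids, gene_table, eqtls, numeric_covars(f0_pheno), gene_eff,
        base_mean, dispersion, rng, params.libsize_cv, founders.line, line_de,
    )
    f0_counts.columns = founders.sample_ids

    # independent replication founder cohort (second slot of the DEG rule)
    rep_founders = _redraw_founders(founders, params.lines, rng, suffix="r")
    f0rep_pheno = _founder_pheno(rep_founders, rng, "F0rep")
    f0rep_counts = _expression_for(
        rep_founders.dosages, vids, gene_table, eqtls, numeric_covars(f0rep_pheno), gene_eff,
        base_mean, dispersion, rng, params.libsize_cv, rep_founders.line, line_de,
    )
    f0rep_counts.columns = rep_founders.sample_ids

    # F2 cohort: behaviors then counts
    f2_dos = cross.f2_dosages
    sex = np.array(["F", "M"])[rng.integers(2, size=params.n_f2)]
    behaviors = simulate_behavior(
        f2_dos, vids, [q for q in qtls if q.behavior_name in ADULT_BEHAVIORS], ADULT_BEHAVIORS,
        sex, rng,
        sex_effects={b: params.sex_behavior_effect for b in ADULT_BEHAVIORS if b != "LocoScore"},
        polygenic_loading=params.polygenic_loading, noise_sd=params.behavior_noise_sd,
    )
    f2_pheno = _f2_pheno(cross, behaviors, rng, params.n_batches)
    f2_pheno["Sex"] = sex
    f2_counts = _expression_for(
        f2_dos, vids, gene_table, eqtls, numeric_covars(f2_pheno), gene_eff,
        base_mean, dispersion, rng, params.libsize_cv,
    )
    f2_counts.columns = cross.f2_sample_ids
    f2_pheno["lib_size"] = f2_counts.sum(axis=0).values

    cohort = SimulatedCohort(
        params, seed, founders, cross, snp_table, gene_table,
        f0_counts, f0_pheno, f0rep_counts, f0rep_pheno, rep_founders,
        f2_counts, f2_pheno, eqtls, qtls, line_de,
    )
    if params.juvenile_cohort:
        cohort.juvenile = _simulate_juvenile(cohort, rng)
    return cohort


def _redraw_founders(founders, lines, rng, suffix):
    """New founder individuals at the same (true) line allele frequencies."""
    t = founders.snp_table
    n = lines.n_per_line
    hap_bhr = (rng.random((n, 2, len(t))) < t["p_bHR"].values).astype(np.int8)
    hap_blr = (rng.random((n, 2, len(t))) < t["p_bLR"].values).astype(np.int8)
    ids = [f"bHR{suffix}_{i:02d}" for i in range(n)] + [f"bLR{suffix}_{i:02d}" for i in range(n)]
    return FounderData(
        np.concatenate([hap_bhr, hap_blr]), np.array(["bHR"] * n + ["bLR"] * n), ids, t
    )


def _simulate_juvenile(cohort: SimulatedCohort, rng) -> "SimulatedCohort":
    """Disjoint F2 cohort sharing founder genetics, phenotyped on the
    juvenile open-field battery (no expression; used for SMR replication)."""
    p = cohort.params
    cross = simulate_cross(cohort.founders, p.n_f1, p.n_f2_juvenile, p.genome.chrom_length_cM, rng)
    vids = pd.Index(cohort.snp_table["variant_id"])
    juv_map = {  # adult behavior -> analogous juvenile trait
        "LocoScore": "OF_DistanceTraveled",
        "EPM_DistanceTraveled": "OF_DistanceTraveled",
        "EPM_TimeImmobile": "OF_TimeImmobile",
        "EPM_PctTimeOpenArms": "OF_PctTimeCenter",
        "PavCA_Index": "OF_PctTimeCenter",
    }
    sign = dict(BLR_SIGN, **BLR_SIGN_JUVENILE)
    juv_qtls = []
    seen = set()
    for q in cohort.planted_qtls:
        b = juv_map[q.behavior_name]
        key = (q.variant_id, b)
        if key in seen:
            continue
        seen.add(key)
        # same bLR-like push, re-expressed on the juvenile trait's axis
        juv_qtls.append(
            PlantedQtl(q.variant_id, b, sign[b] * sign[q.behavior_name] * q.effect_size,
                       q.pleiotropic_gene)
        )
    sex = np.array(["F", "M"])[rng.integers(2, size=p.n_f2_juvenile)]
    beh = simulate_behavior(
        cross.f2_dosages, vids, juv_qtls, JUVENILE_BEHAVIORS, sex, rng,
        sex_effects={b: p.sex_behavior_effect for b in JUVENILE_BEHAVIORS},
        polygenic_loading=p.polygenic_loading, noise_sd=p.behavior_noise_sd,
    )
    pheno = pd.DataFrame({"Sex": sex}, index=pd.Index(cross.f2_sample_ids, name="sample_id"))
    pheno.index = pd.Index([f"J{s}" for s in cross.f2_sample_ids], name="sample_id")
    cross.f2_sample_ids = list(pheno.index)
    pheno = pd.concat([pheno, beh.set_index(pheno.index)], axis=1)
    return replace(
        cohort, cross=cross, f2_pheno=pheno, f2_counts=pd.DataFrame(),
        planted_qtls=juv_qtls, juvenile=None,
    )
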