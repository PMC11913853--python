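"""Allelic fold change, founder-line segregation, and signed predictions.

The allelic fold change (aFC) of a cis-eQTL is the log2 ratio of
expression driven by the alternate vs the reference haplotype under an
additive cis-regulatory model: expected expression at dosage d is
mu(d) = c_r (2 - d) + c_a d, i.e. log2 mu(d) = log2 c_r +
log2((2 - d) + d 2^aFC). Founder-line allele-frequency differentiation is
scored with Hedrick's standardized G'st (Nei-Chesser small-sample
estimators), and for segregated eVariants (G'st above threshold) the aFC
is signed onto the bLR-vs-bHR axis by which line is enriched for the
alternate allele, yielding a genotype-based prediction of line
differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from tricross.sim import AFC_CAP

GST_THRESHOLD = 0.27


@dataclass
class AfcRecord:
    gene_id: str
    variant_id: str
    afc: float  # log2(c_alt / c_ref)
    c_ref: float  # reference-allele expression level (count scale)
    capped: bool
    flagged: bool = False  # undefined fit (e.g. all-zero counts)


def _dosage_offset(d, afc):
    return np.log2((2.0 - d) + d * 2.0**afc)


def estimate_afc(
    raw_counts_gene, dosage, covariate_design=None, gene_id: str = "", variant_id: str = "",
    cap: float = AFC_CAP,
) -> AfcRecord:
    """Least-squares aFC fit in log2 space on (count + 1).

    For a trial aFC the dosage term enters as a fixed offset and the
    covariates (plus intercept) are profiled out by OLS, leaving a smooth
    one-dimensional residual sum of squares that is minimized over the
    box |aFC| <= log2(100) by a deterministic coarse-grid + bounded-Brent
    search started from the homozygote group-mean ratio.
    """
    y_raw = np.asarray(raw_counts_gene, float)
    d = np.asarray(dosage, float)
    if np.ptp(d) == 0:
        raise ValueError("dosage must be polymorphic")
    if np.any(y_raw < 0):
        raise ValueError("counts must be non-negative")
    if np.all(y_raw == 0):
        return AfcRecord(gene_id, variant_id, 0.0, 0.0, False, flagged=True)
    y = np.log2(y_raw + 1.0)
    n = len(y)
    X = np.ones((n, 1)) if covariate_design is None else np.asarray(covariate_design, float)
    if not np.allclose(X[:, 0], 1.0):
        X = np.hstack([np.ones((n, 1)), X])

    def rss(afc):
        resid = y - _dosage_offset(d, afc)
        beta = np.linalg.lstsq(X, resid, rcond=None)[0]
        e = resid - X @ beta
        return float(e @ e)

    grid = np.linspace(-cap, cap, 27)
    g0 = _group_ratio_start(y, d)
    cand = np.unique(np.clip(np.append(grid, g0), -cap, cap))
    best = cand[np.argmin([rss(a) for a in cand])]
    lo = max(-cap, best - 0.6)
    hi = min(cap, best + 0.6)
    res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-7})
    afc = float(res.x) if res.fun <= rss(best) else float(best)
    capped = bool(abs(afc) >= cap - 1e-6)
    if capped:
        afc = float(np.sign(afc) * cap)
    beta = np.linalg.lstsq(X, y - _dosage_offset(d, afc), rcond=None)[0]
    c_ref = float(2.0 ** beta[0])  # log2 mu(0) = beta0 + offset(0) = beta0 + 1; c_r = mu(0)/2
    return AfcRecord(gene_id, variant_id, afc, c_ref, capped)


def _group_ratio_start(y_log2, d):
    """Initial aFC from homozygote (or extreme-dosage) group means."""
    lo, hi = d.min(), d.max()
    m_lo = y_log2[d == lo].mean()
    m_hi = y_log2[d == hi].mean()
    if hi == lo:
        return 0.0
    slope = (m_hi - m_lo) / (hi - lo) * 2.0  # log2 ratio over the full 0->2 span
    return float(np.clip(slope, -AFC_CAP, AFC_CAP))


# ---------------------------------------------------------------------------
# founder segregation
# ---------------------------------------------------------------------------


def founder_allele_freqs(
    founder_dosages, line_labels, snp_table: pd.DataFrame, variant_ids
) -> pd.DataFrame:
    """Per-line alternate-allele frequencies, sample sizes, observed het.

    Frequencies are alt-allele counts over 2 x non-missing individuals
    (missing encoded as negative or NaN).
    """
    vindex = pd.Index(snp_table["variant_id"])
    missing = [v for v in variant_ids if v not in vindex]
    if missing:
        raise KeyError(f"variants absent from the genotype table: {missing}")
    cols = np.array([vindex.get_loc(v) for v in variant_ids])
    D = np.asarray(founder_dosages, float)[:, cols]
    D = np.where(D < 0, np.nan, D)
    lab = np.asarray(line_labels)
    rows = []
    for i, v in enumerate(variant_ids):
        rec = {"variant_id": v}
        for line in ("bHR", "bLR"):
            d = D[lab == line, i]
            ok = ~np.isnan(d)
            n = int(ok.sum())
            rec[f"p_{line}"] = d[ok].sum() / (2.0 * n) if n else np.nan
            rec[f"n_{line}"] = n
            rec[f"ho_{line}"] = float(np.mean(d[ok] == 1)) if n else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("variant_id")


def gst_prime(p_line1, p_line2, n1, n2, ho1: float = 0.0, ho2: float = 0.0) -> float:
    """Hedrick's standardized G'st for two populations at a biallelic locus.

    Uses the Nei-Chesser small-sample estimators with harmonic-mean sample
    size and the observed-heterozygosity correction:

        Hs_hat = (nt/(nt-1)) (1 - mean_j sum_a p_ja^2 - Ho/(2 nt))
        Ht_hat = 1 - sum_a pbar_a^2 + Hs_hat/(nt k) - Ho/(2 nt k)
        Gst    = (Ht_hat - Hs_hat)/Ht_hat
        G'st   = Gst (k - 1 + Hs_hat) / ((k - 1)(1 - Hs_hat)),  k = 2

    clipped to [0, 1]. ``ho1``/``ho2`` are the observed heterozygote
    proportions per line (0 for fully homozygous lines; pass genotype-based
    values when genotypes are available). Both lines monomorphic for the
    same allele gives 0 by definition.
    """
    p1, p2 = float(p_line1), float(p_line2)
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    if min(n1, n2) < 1:
        raise ValueError("need at least one individual per line")
    if p1 == p2 and p1 in (0.0, 1.0):
        return 0.0
    k = 2
    nt = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic mean
    ho = 0.5 * (ho1 + ho2)
    hom_within = 0.5 * ((p1**2 + (1 - p1) ** 2) + (p2**2 + (1 - p2) ** 2))
    hs = (nt / (nt - 1.0)) * (1.0 - hom_within - ho / (2.0 * nt)) if nt > 1 else 1.0 - hom_within
    pbar = 0.5 * (p1 + p2)
    ht = 1.0 - (pbar**2 + (1 - pbar) ** 2) + hs / (nt * k) - ho / (2.0 * nt * k)
    if ht <= 0:
        return 0.0
    gst = (ht - hs) / ht
    if hs >= 1.0:
        return 0.0
    gprime = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    return float(np.clip(gprime, 0.0, 1.0))


def segregation_records(freqs: pd.DataFrame) -> pd.DataFrame:
    """G'st and bLR-enriched allele for each variant in a frequency table."""
    rows = []
    for v, r in freqs.iterrows():
        g = gst_prime(r["p_bHR"], r["p_bLR"], r["n_bHR"], r["n_bLR"], r["ho_bHR"], r["ho_bLR"])
        if r["p_bLR"] > r["p_bHR"]:
            enriched = "alt"
        elif r["p_bLR"] < r["p_bHR"]:
            enriched = "ref"
        else:
            enriched = "none"
        rows.append({"variant_id": v, "p_bHR": r["p_bHR"], "p_bLR": r["p_bLR"],
                     "n_bHR": r["n_bHR"], "n_bLR": r["n_bLR"], "gst_prime": g,
                     "blr_enriched_allele": enriched})
    return pd.DataFrame(rows).set_index("variant_id")


def segregated_evariants(records: pd.DataFrame, threshold: float = GST_THRESHOLD) -> pd.DataFrame:
    """Subset of variants with G'st strictly above the threshold."""
    return records[records["gst_prime"] > threshold]


def signed_prediction(afc: float, p_bhr: float, p_blr: float) -> float | None:
    """Predicted bLR-vs-bHR Log2FC: aFC signed by the bLR-enriched allele.

    Positive = predicted upregulated in bLR. Returns None when the lines
    have identical frequencies (no direction).
    """
    if p_blr == p_bhr:
        return None
    return float(afc * np.sign(p_blr - p_bhr))


def prediction_concordance(predictions: pd.DataFrame, observed_f0_de: pd.DataFrame):
    """Agreement between genotype-based predictions and observed line DE.

    ``predictions`` is indexed by gene_id with a ``predicted_log2fc``
    column. Returns Pearson/Spearman statistics, the sign-concordance
    fraction, and the congruent gene list (matching signs).
    """
    shared = predictions.index.intersection(observed_f0_de.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    pred = predictions.loc[shared, "predicted_log2fc"].values
    obs = observed_f0_de.loc[shared, "log2fc"].values
    r, r_p = stats.pearsonr(pred, obs)
    rho, rho_p = stats.spearmanr(pred, obs)
    match = np.sign(pred) == np.sign(obs)
    return {
        "r": r, "r_p": r_p, "rho": rho, "rho_p": rho_p,
        "sign_concordance": float(match.mean()),
        "n": len(shared),
        "congruent_genes": list(shared[match]),
    }
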