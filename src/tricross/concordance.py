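"""Cross-dataset agreement of differential-expression results.

Covers the four comparison operations used to relate the F0 line contrast,
the replication dataset, and the F2 behavioral models: effect-size
correlations, the two-sided rank-rank hypergeometric overlap (RRHO) map,
the two-dataset DEG rule, per-gene behavior-concordance flags, and Fisher
exact overlap enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from tricross.sim import BLR_SIGN

#: Default sign convention mapping each analysis onto "bLR-like = positive".
#: Line contrasts (bLR vs bHR) already point that way; behaviors flip
#: according to whether high values are bHR-like.
DEFAULT_SIGN_CONVENTION = dict(
    {"f0_lineage": +1.0, "f0_replication": +1.0, "meta": +1.0}, **BLR_SIGN
)


def log2fc_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame, column: str = "log2fc"):
    """Pearson r and Spearman rho of effect sizes over the shared genes.

    Genes are matched by id, not order. Returns a dict with r, r_p, rho,
    rho_p, n_shared_genes.
    """
    shared = de_a.index.intersection(de_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need >= 10")
    x = de_a.loc[shared, column].values
    y = de_b.loc[shared, column].values
    r, r_p = stats.pearsonr(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    return {"r": r, "r_p": r_p, "rho": rho, "rho_p": rho_p, "n_shared_genes": len(shared)}


def rrho_map(scores_a: pd.Series, scores_b: pd.Series, step: int | None = None) -> pd.DataFrame:
    """Two-sided rank-rank hypergeometric overlap map.

    Both lists are ranked from most-up to most-down by their signed
    scores (t-statistics). At grid point (i, j) the overlap k of the top-i
    genes of A with the top-j genes of B is scored by the hypergeometric
    tail; the signed value is -log10 P(X >= k) when the overlap exceeds
    its expectation (concordance) and +log10 P(X <= k) when it falls below
    (anti-concordance, negative values). Concordant up-up / down-down
    signal therefore falls on the map's diagonal.

    ``step`` defaults to max(1, N // 100).
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("RRHO requires the same gene universe in both lists")
    n = len(scores_a)
    step = max(1, n // 100) if step is None else int(step)
    if step < 1:
        raise ValueError("step must be >= 1")
    # rank 1 = most up
    ra = pd.Series(np.arange(1, n + 1), index=scores_a.sort_values(ascending=False).index)
    rb = pd.Series(np.arange(1, n + 1), index=scores_b.sort_values(ascending=False).index)
    ra, rb = ra.sort_index(), rb.sort_index()
    grid = np.arange(step, n + 1, step)
    # cumulative 2-D count: k[i, j] = #genes with rank_a <= i and rank_b <= j
    edges = np.r_[0, grid] + 0.5
    hist, _, _ = np.histogram2d(ra.values, rb.values, bins=[edges, edges])
    k = hist.cumsum(axis=0).cumsum(axis=1)
    ii = grid[:, None].astype(float)
    jj = grid[None, :].astype(float)
    expected = ii * jj / n
    p_enrich = stats.hypergeom.sf(k - 1, n, ii.astype(int), jj.astype(int))
    p_deplete = stats.hypergeom.cdf(k, n, ii.astype(int), jj.astype(int))
    with np.errstate(divide="ignore"):
        signed = np.where(k >= expected, -np.log10(p_enrich), np.log10(p_deplete))
    return pd.DataFrame(signed, index=pd.Index(grid, name="rank_a"),
                        columns=pd.Index(grid, name="rank_b"))


def define_deg_set(
    de_f0: pd.DataFrame, de_replication: pd.DataFrame, fdr: float = 0.10, nominal: float = 0.05
) -> pd.DataFrame:
    """Two-dataset DEG rule.

    A gene is a differentially expressed gene if it reaches FDR < `fdr`
    in either dataset, or nominal p < `nominal` in both with a consistent
    direction of effect. Returns a frame indexed by gene_id with the
    provenance flag (FDR_F0 | FDR_replication | nominal_both_consistent)
    and the direction (+1 = up in bLR) taken from the F0 result when
    available.
    """
    shared = de_f0.index.union(de_replication.index)
    a = de_f0.reindex(shared)
    b = de_replication.reindex(shared)
    fdr_a = a["q"] < fdr
    fdr_b = b["q"] < fdr
    consistent = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    nom_both = (a["p"] < nominal) & (b["p"] < nominal) & consistent
    member = fdr_a.fillna(False) | fdr_b.fillna(False) | nom_both.fillna(False)
    provenance = np.where(
        fdr_a.fillna(False), "FDR_F0",
        np.where(fdr_b.fillna(False), "FDR_replication", "nominal_both_consistent"),
    )
    direction = np.sign(a["log2fc"].fillna(b["log2fc"]))
    out = pd.DataFrame(
        {"provenance": provenance, "direction": direction}, index=shared
    ).loc[member]
    out.index.name = "gene_id"
    return out


def behavior_concordance_flags(
    deg_set: pd.DataFrame,
    f2_de_per_behavior: dict[str, pd.DataFrame],
    sign_convention: dict[str, float] | None = None,
    nominal: float = 0.05,
    required_behaviors: list[str] | None = None,
) -> pd.Series:
    """Flag DEGs whose F2 behavioral associations match their line direction.

    A bLR-upregulated DEG is flagged ``bLR_like`` iff at least one behavior
    shows a nominal (p < 0.05) association whose coefficient, after sign
    harmonization, points in the bLR-like direction; symmetric for
    ``bHR_like``. All other DEGs are ``none``.
    """
    sign_convention = sign_convention or DEFAULT_SIGN_CONVENTION
    required = required_behaviors if required_behaviors is not None else list(BLR_SIGN)
    missing = [b for b in required if b not in f2_de_per_behavior]
    if missing:
        raise ValueError(f"missing behavior DE results: {missing}")
    flags = pd.Series("none", index=deg_set.index, name="behavior_flag")
    for b, de in f2_de_per_behavior.items():
        mult = sign_convention[b]
        sub = de.reindex(deg_set.index)
        harmonized = mult * np.sign(sub["log2fc"])
        hit = sub["p"] < nominal
        blr_like = hit & (harmonized > 0) & (deg_set["direction"] > 0)
        bhr_like = hit & (harmonized < 0) & (deg_set["direction"] < 0)
        flags[blr_like.fillna(False)] = "bLR_like"
        flags[bhr_like.fillna(False)] = "bHR_like"
    return flags


@dataclass
class OverlapResult:
    odds_ratio: float
    p: float
    ci_low: float
    ci_high: float
    table: np.ndarray
    degenerate: bool = False


def overlap_enrichment(set1, set2, universe) -> OverlapResult:
    """Fisher exact test of the overlap of two gene sets within a universe.

    Reports the sample odds ratio, the exact conditional two-sided p, and
    the 95% CI from conditional maximum-likelihood inversion. A table with
    an empty margin is flagged degenerate (OR undefined, p = 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    s1, s2 = set(set1) & universe, set(set2) & universe
    a = len(s1 & s2)
    b = len(s1) - a
    c = len(s2) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        return OverlapResult(np.nan, 1.0, np.nan, np.nan, table, degenerate=True)
    orr = (a * d) / (b * c) if b * c > 0 else np.inf
    _, p = stats.fisher_exact(table, alternative="two-sided")
    ci = _odds_ratio(table, kind="conditional").confidence_interval(0.95)
    return OverlapResult(orr, p, ci.low, ci.high, table)
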