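"""Combined ranking statistic and preranked gene-set enrichment.

The ranking statistic for a gene is the mean of its sign-harmonized
t-statistics across the included analyses (line contrasts and the F2
behavioral models), so a positive score means "upregulated with the
bLR-like phenotype". A non-directional variant uses the absolute value
of the average. Enrichment is the weighted Kolmogorov-Smirnov running
sum with a gene-permutation null (size-matched random sets).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tricross.concordance import DEFAULT_SIGN_CONVENTION
from tricross.expression import bh_fdr


def combined_statistic(
    de_results: dict[str, pd.DataFrame],
    sign_convention: dict[str, float] | None = None,
    missing_policy: str = "average_available",
    absolute: bool = False,
) -> pd.DataFrame:
    """Average sign-harmonized t-statistics across analyses.

    ``missing_policy``: "average_available" averages each gene over the
    analyses that cover it (the number is recorded); "drop" restricts to
    genes present in every analysis. ``absolute`` returns |score|.
    """
    if not de_results:
        raise ValueError("no DE results supplied")
    sign_convention = sign_convention or DEFAULT_SIGN_CONVENTION
    cols = {}
    for name, de in de_results.items():
        key = de.attrs.get("behavior") or name
        mult = sign_convention.get(key, sign_convention.get(name, 1.0))
        cols[name] = mult * de["mod_t"]
    mat = pd.DataFrame(cols)
    if missing_policy == "drop":
        mat = mat.dropna()
    elif missing_policy != "average_available":
        raise ValueError(f"unknown missing policy: {missing_policy}")
    n_avail = mat.notna().sum(axis=1)
    if (n_avail == 0).all():
        raise ValueError("empty intersection of gene universes")
    mat = mat.loc[n_avail > 0]
    score = mat.mean(axis=1, skipna=True)
    if absolute:
        score = score.abs()
    out = pd.DataFrame({"score": score, "n_analyses": n_avail.loc[score.index]})
    out.index.name = "gene_id"
    return out


def enrichment_score(ranked_scores: pd.Series, gene_set, weight_exponent: float = 1.0):
    """Signed maximal deviation of the weighted KS running sum.

    Genes are ordered by decreasing score; hits increment the running sum
    by |score|^weight normalized over the set, misses decrement by
    1/(N - n_set). Returns ``(es, leading_edge_genes)``.
    """
    s = ranked_scores.sort_values(ascending=False)
    hit = s.index.isin(set(gene_set))
    n, m = len(s), int(hit.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    w = np.abs(s.values) ** weight_exponent
    wh = np.where(hit, w, 0.0)
    total = wh.sum()
    if total == 0:  # all hits have zero score: fall back to unweighted steps
        wh = hit.astype(float)
        total = wh.sum()
    running = np.cumsum(wh / total - np.where(hit, 0.0, 1.0 / (n - m)))
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = s.index[: i_max + 1][hit[: i_max + 1]].tolist()
    else:
        leading = s.index[i_max:][hit[i_max:]].tolist()
    return es, leading


def _es_only(order_weights, hit_mask, n):
    """ES for a permuted hit mask over precomputed |score|^w in rank order."""
    m = hit_mask.sum()
    wh = np.where(hit_mask, order_weights, 0.0)
    total = wh.sum()
    if total == 0:
        wh = hit_mask.astype(float)
        total = float(m)
    running = np.cumsum(wh / total - np.where(hit_mask, 0.0, 1.0 / (n - m)))
    return running[np.argmax(np.abs(running))]


def gsea_test(
    statistic: pd.DataFrame | pd.Series,
    collection: dict[str, list[str]],
    nperm: int = 10_000,
    min_size: int = 10,
    max_size: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    For each set, the null is the ES distribution of ``nperm`` size-matched
    random gene sets; NES = ES / mean(|null ES| of matching sign);
    p = (1 + #{null as extreme}) / (1 + nperm); BH correction across sets.
    Sets outside [min_size, max_size] after intersection with the universe
    are excluded (logged in the result's ``.attrs["excluded"]``).
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    scores = statistic["score"] if isinstance(statistic, pd.DataFrame) else statistic
    if scores.std() == 0:
        raise ValueError("ranking statistic has zero variance")
    s = scores.sort_values(ascending=False)
    n = len(s)
    order_w = np.abs(s.values) ** weight_exponent
    universe = set(s.index)
    rng = np.random.default_rng(seed)

    sizes_needed = {}
    tested, excluded = [], []
    for name, genes in collection.items():
        inset = set(genes) & universe
        m = len(inset)
        if m < min_size or m > max_size:
            excluded.append((name, m))
            continue
        tested.append((name, inset, m))
        sizes_needed[m] = None

    # one null ensemble per distinct set size
    null_es = {}
    for m in sizes_needed:
        es = np.empty(nperm)
        mask = np.zeros(n, dtype=bool)
        for b in range(nperm):
            mask[:] = False
            mask[rng.choice(n, size=m, replace=False)] = True
            es[b] = _es_only(order_w, mask, n)
        null_es[m] = es

    rows = []
    for name, inset, m in tested:
        es, leading = enrichment_score(s, inset, weight_exponent)
        null = null_es[m]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else np.nan
        extreme = (np.abs(null) >= abs(es)).sum()
        p = (1.0 + extreme) / (1.0 + nperm)
        rows.append((name, m, es, nes, p, ";".join(map(str, leading))))
    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "leading_edge"]).set_index(
        "set"
    )
    out["q"] = bh_fdr(out["p"].values)
    out.attrs["excluded"] = excluded
    out.attrs["nperm"] = nperm
    return out
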