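"""SMR colocalization with behavioral QTLs and the convergence gate.

Summary-data-based Mendelian randomization combines the z-scores of the
eQTL and GWAS associations at each eGene's top eVariant:

    T_SMR = z_eQTL^2 z_GWAS^2 / (z_eQTL^2 + z_GWAS^2)

with p-values from the upper tail of chi-squared (df = 1) and BH FDR per
behavior. The "directional" statistic sign(beta_eQTL beta_GWAS) sqrt(T)
encodes the predicted expression-behavior relationship (positive =
expression up with behavior up). The convergence gate then intersects six
lines of evidence to nominate candidate genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from tricross.expression import bh_fdr


def behavior_qtl_scan(behavior_vector, dosages, covariates=None) -> pd.DataFrame:
    """Per-SNP OLS of a behavior on dosage plus covariates (stand-in GWAS).

    ``covariates`` is a (samples x k) matrix, typically an indicator for
    sex; an intercept is always included. Returns beta, se, z per SNP.
    """
    y = np.asarray(behavior_vector, float)
    if np.ptp(y) == 0:
        raise ValueError("behavior is constant")
    D = np.asarray(dosages, float)
    if D.ndim == 1:
        D = D[:, None]
    n = len(y)
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    k = X.shape[1]
    df = n - k - 1
    M = np.column_stack([y, D])
    beta_c = np.linalg.lstsq(X, M, rcond=None)[0]
    resid = M - X @ beta_c
    yr = resid[:, 0]
    Dr = resid[:, 1:]
    dd = (Dr**2).sum(axis=0)
    dd = np.where(dd == 0, np.nan, dd)
    beta = (Dr.T @ yr) / dd
    rss = (yr @ yr) - beta**2 * dd
    se = np.sqrt(np.maximum(rss, 0.0) / df / dd)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    return pd.DataFrame({"beta": beta, "se": se, "z": z})


def smr_statistic(z_eqtl, z_gwas):
    """SMR approximate chi-squared statistic and its df-1 upper-tail p.

    T = z_e^2 z_g^2 / (z_e^2 + z_g^2); T <= min(z_e^2, z_g^2); 0/0 -> 0.
    """
    ze2 = np.asarray(z_eqtl, float) ** 2
    zg2 = np.asarray(z_gwas, float) ** 2
    denom = ze2 + zg2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, ze2 * zg2 / np.where(denom > 0, denom, 1.0), 0.0)
    p = stats.chi2.sf(t, df=1)
    if np.ndim(z_eqtl) == 0 and np.ndim(z_gwas) == 0:
        return float(t), float(p)
    return t, p


def smr_fdr(records: pd.DataFrame, per_behavior: bool = True) -> pd.DataFrame:
    """BH correction of SMR p-values, within each behavior by default."""
    out = records.copy()
    if per_behavior:
        out["q"] = np.nan
        for b, idx in out.groupby("behavior").groups.items():
            out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].values)
    else:
        out["q"] = bh_fdr(out["p"].values)
    return out


def directional_t(beta_eqtl, beta_gwas, t_smr):
    """Signed SMR statistic: sign(beta_eQTL * beta_GWAS) * sqrt(T).

    Positive = expression predicted to rise with the behavior. A zero
    beta gives sign 0 (flag such records upstream).
    """
    t = np.asarray(t_smr, float)
    if np.any(t < 0):
        raise ValueError("T_SMR must be non-negative")
    sgn = np.sign(np.asarray(beta_eqtl, float) * np.asarray(beta_gwas, float))
    out = sgn * np.sqrt(t)
    if np.ndim(beta_eqtl) == 0 and np.ndim(beta_gwas) == 0 and np.ndim(t_smr) == 0:
        return float(out)
    return out


def run_smr(
    eqtl_top: pd.DataFrame,
    gwas: dict[str, pd.DataFrame],
    fdr_per_behavior: bool = True,
) -> pd.DataFrame:
    """SMR for every (top eVariant, behavior) pair.

    ``eqtl_top``: one row per eGene's rank-0 signal with phenotype_id,
    variant_id, slope, t. ``gwas``: behavior -> frame indexed by
    variant_id with beta, z. Returns gene/variant/behavior records with
    T, p, q, signed_T.
    """
    rows = []
    for b, g in gwas.items():
        sub = g.reindex(eqtl_top["variant_id"])
        t, p = smr_statistic(eqtl_top["t"].values, sub["z"].values)
        signed = directional_t(eqtl_top["slope"].values, sub["beta"].values, t)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": eqtl_top["phenotype_id"].values,
                    "variant_id": eqtl_top["variant_id"].values,
                    "behavior": b,
                    "z_eqtl": eqtl_top["t"].values,
                    "z_gwas": sub["z"].values,
                    "beta_eqtl": eqtl_top["slope"].values,
                    "beta_gwas": sub["beta"].values,
                    "T": t,
                    "p": p,
                    "signed_T": signed,
                }
            )
        )
    return smr_fdr(pd.concat(rows, ignore_index=True), per_behavior=fdr_per_behavior)


def directional_concordance(
    smr_records: pd.DataFrame,
    f2_de_for_behavior: pd.DataFrame,
    behavior: str,
    subset_genes=None,
):
    """Correlation of the signed SMR statistic with the behavior's Log2FC.

    ``subset_genes`` restricts to the segregation-validated eGene set when
    given. Returns r, p, n and the merged scatter table.
    """
    sub = smr_records[smr_records["behavior"] == behavior].set_index("gene_id")
    if subset_genes is not None:
        sub = sub.loc[sub.index.intersection(pd.Index(subset_genes))]
    shared = sub.index.intersection(f2_de_for_behavior.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared; need >= 10")
    x = sub.loc[shared, "signed_T"].values
    y = f2_de_for_behavior.loc[shared, "log2fc"].values
    r, p = stats.pearsonr(x, y)
    table = pd.DataFrame({"signed_T": x, "log2fc": y}, index=shared)
    return {"r": r, "p": p, "n": len(shared), "table": table}


# ---------------------------------------------------------------------------
# convergence gate
# ---------------------------------------------------------------------------

GATE_CRITERIA = [
    "c1_deg",
    "c2_behavior_assoc",
    "c3_segregated_egene",
    "c4_afc_sign_match",
    "c5_smr_significant",
    "c6_smr_direction_match",
]


def convergence_gate(
    deg_set: pd.DataFrame,
    behavior_flags: pd.Series,
    eqtl_top: pd.DataFrame,
    segregation: pd.DataFrame,
    predictions: pd.DataFrame,
    f0_de: pd.DataFrame,
    smr_records: pd.DataFrame,
    f2_de_per_behavior: dict[str, pd.DataFrame],
    smr_fdr_threshold: float = 0.10,
    gst_threshold: float = 0.27,
) -> pd.DataFrame:
    """Six-criterion convergence audit per eGene.

    (1) line DEG; (2) >= 1 nominal F2 behavioral association concordant
    with the line direction; (3) eGene whose top eVariant is line
    segregated (G'st > threshold); (4) the allele-signed aFC predicts the
    observed F0 DE sign; (5) SMR q < threshold for >= 1 behavior; (6) the
    SMR-predicted expression-behavior direction matches that behavior's
    F2 DE sign. ``pass`` is the conjunction; rows are sorted by the best
    SMR -log10 p so the strongest colocalizations lead the ledger.
    """
    for name, obj in [("eqtl", eqtl_top), ("segregation", segregation),
                      ("smr", smr_records), ("f0_de", f0_de)]:
        if obj is None or len(obj) == 0:
            raise ValueError(f"missing upstream table: {name}")
    rows = []
    top = eqtl_top[eqtl_top["rank"] == 0].set_index("phenotype_id")
    for gid, erec in top.iterrows():
        v = erec["variant_id"]
        c1 = gid in deg_set.index
        c2 = c1 and behavior_flags.get(gid, "none") != "none"
        seg = segregation.loc[v] if v in segregation.index else None
        c3 = bool(erec.get("is_egene", False)) and seg is not None and seg["gst_prime"] > gst_threshold
        pred = predictions["predicted_log2fc"].get(gid, np.nan)
        obs = f0_de["log2fc"].get(gid, np.nan)
        c4 = bool(np.isfinite(pred) and np.isfinite(obs) and np.sign(pred) == np.sign(obs) and pred != 0)
        g_smr = smr_records[smr_records["gene_id"] == gid]
        sig = g_smr[g_smr["q"] < smr_fdr_threshold]
        c5 = len(sig) > 0
        c6 = False
        for _, srow in sig.iterrows():
            de_b = f2_de_per_behavior.get(srow["behavior"])
            if de_b is None or gid not in de_b.index:
                continue
            if np.sign(srow["signed_T"]) == np.sign(de_b.loc[gid, "log2fc"]) and srow["signed_T"] != 0:
                c6 = True
                break
        best_logp = float(-np.log10(max(g_smr["p"].min(), 1e-300))) if len(g_smr) else 0.0
        rows.append(
            {"gene_id": gid, "variant_id": v, "c1_deg": c1, "c2_behavior_assoc": c2,
             "c3_segregated_egene": c3, "c4_afc_sign_match": c4, "c5_smr_significant": c5,
             "c6_smr_direction_match": c6, "max_neglog10_smr_p": best_logp}
        )
    ledger = pd.DataFrame(rows).set_index("gene_id")
    ledger["pass"] = ledger[GATE_CRITERIA].all(axis=1)
    return ledger.sort_values("max_neglog10_smr_p", ascending=False)


def chance_expectation(
    deg_set: pd.DataFrame,
    behavior_flags: pd.Series,
    eqtl_top: pd.DataFrame,
    segregation: pd.DataFrame,
    predictions: pd.DataFrame,
    f0_de: pd.DataFrame,
    smr_records: pd.DataFrame,
    f2_de_per_behavior: dict[str, pd.DataFrame],
    n_permutations: int = 200,
    seed: int = 0,
    **gate_kwargs,
):
    """Expected chance pass count of the gate under gene-label shuffling.

    The gene-to-DE-result assignment (F0 DE, DEG membership, behavior
    flags, F2 DE) is permuted while the genetic tables stay fixed, and the
    gate is recomputed per permutation. Returns the mean and the 95th
    percentile of the pass count, with the per-permutation counts.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    universe = f0_de.index.to_numpy()
    counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(universe)
        mapping = dict(zip(universe, perm))

        def remap_index(df):
            out = df.copy()
            out.index = pd.Index([mapping.get(g, g) for g in df.index], name=df.index.name)
            return out

        ledger = convergence_gate(
            remap_index(deg_set),
            remap_index(behavior_flags.to_frame()).iloc[:, 0],
            eqtl_top,
            segregation,
            predictions,  # genetic side stays fixed; only DE labels shuffle
            remap_index(f0_de),
            smr_records,
            {b: remap_index(de) for b, de in f2_de_per_behavior.items()},
            **gate_kwargs,
        )
        counts[i] = int(ledger["pass"].sum())
    return {
        "mean_passes": float(counts.mean()),
        "q95_passes": float(np.quantile(counts, 0.95)),
        "counts": counts,
    }
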