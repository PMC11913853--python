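"""cis-eQTL mapping with permutation-based beta-approximated p-values.

Pipeline (per the standard tensorQTL/FastQTL-style workflow): expression
is residualized on the technical covariates, rank-inverse-normal
transformed, and scanned against dosages of SNPs with MAF > 0.01 within
+/-1 Mb of each gene's TSS, with the top five principal components of the
expression matrix and of the LD-pruned genotype matrix as covariates.
Gene-level significance uses the minimum nominal p over permutations of
the (residualized) phenotype, summarized by a fitted Beta(a, b); eGenes
are called by BH FDR over the beta-approximated empirical p-values, and
conditionally independent signals are found by forward stepwise scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

CIS_WINDOW_BP = 1_000_000


# ---------------------------------------------------------------------------
# transforms and covariates
# ---------------------------------------------------------------------------


def residualize(matrix, design) -> np.ndarray:
    """OLS residuals of each row of `matrix` (genes x samples) on `design`
    (samples x covariates). Residuals are orthogonal to the covariates."""
    Y = np.atleast_2d(np.asarray(matrix, float))
    X = np.asarray(design, float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]
    R = Y - (X @ beta).T
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(R, index=matrix.index, columns=matrix.columns)
    return R


def rint(vector) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset 3/8.

    value_i = Phi^-1((rank_i - 3/8) / (n + 1/4)); ties get average ranks.
    """
    v = np.asarray(vector, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("input must be finite")
    if np.ptp(v) == 0:
        raise ValueError("constant vector: ranks undefined")
    r = stats.rankdata(v, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (len(v) + 0.25))


def ld_prune(dosages, window_snps: int = 50, step: int = 5, r2_threshold: float = 0.5):
    """Greedy windowed LD pruning (plink indep-pairwise style).

    Within each sliding window, the later SNP of any retained pair with
    r^2 > threshold is removed; deterministic given input order. Returns
    the retained column indices.
    """
    D = np.asarray(dosages, float)
    m = D.shape[1]
    if m < 2:
        return np.arange(m)
    keep = np.ones(m, dtype=bool)
    Dc = D - D.mean(axis=0)
    sd = Dc.std(axis=0)
    for start in range(0, m, step):
        idx = [j for j in range(start, min(start + window_snps, m)) if keep[j]]
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            if not keep[i]:
                continue
            for j in idx[a_pos + 1 :]:
                if not keep[j]:
                    continue
                if sd[i] == 0 or sd[j] == 0:
                    continue
                r = (Dc[:, i] @ Dc[:, j]) / (len(D) * sd[i] * sd[j])
                if r * r > r2_threshold:
                    keep[j] = False
        if start + window_snps >= m:
            break
    return np.flatnonzero(keep)


def compute_pc_covariates(expression_rint, dosages_pruned, n_pcs: int = 5) -> np.ndarray:
    """Top PCs of the expression matrix and of the pruned dosage matrix.

    Returns a (samples x 2*n_pcs) matrix of orthonormal sample scores
    (left singular vectors of each centered matrix), concatenated.
    """
    E = np.asarray(expression_rint, float).T  # samples x genes
    G = np.asarray(dosages_pruned, float)

    def top_pcs(M):
        if min(M.shape) < n_pcs:
            raise ValueError("fewer dimensions than requested PCs")
        Mc = M - M.mean(axis=0)
        u, s, _ = np.linalg.svd(Mc, full_matrices=False)
        return u[:, :n_pcs]

    return np.hstack([top_pcs(E), top_pcs(G)])


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------


def _residualize_columns(M, covariates):
    X = np.asarray(covariates, float)
    beta = np.linalg.lstsq(X, M, rcond=None)[0]
    return M - X @ beta


def nominal_scan(y_rint, cis_dosages, covariates) -> pd.DataFrame:
    """Per-SNP OLS of expression on dosage plus covariates.

    Equivalent to regressing the covariate-residualized phenotype on the
    covariate-residualized dosage with n - k - 1 residual df. Returns
    beta, se, t, p per SNP.
    """
    y = np.asarray(y_rint, float)
    D = np.asarray(cis_dosages, float)
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValueError("empty cis window")
    X = np.asarray(covariates, float)
    n, k = X.shape
    df = n - k - 1
    yr = _residualize_columns(y[:, None], X)[:, 0]
    Dr = _residualize_columns(D, X)
    dd = (Dr**2).sum(axis=0)
    assert np.all(dd > 0), "monomorphic SNP passed the MAF filter"
    beta = (Dr.T @ yr) / dd
    rss = (yr @ yr) - beta**2 * dd
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / dd)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p})


def _min_p_from_r2(r2, df):
    t2 = r2 * df / np.maximum(1.0 - r2, 1e-300)
    return 2.0 * stats.t.sf(np.sqrt(t2), df)


def fit_beta_to_minima(minima: np.ndarray):
    """Maximum-likelihood Beta(a, b) fit to permutation minimum p-values,
    initialized from moments: a = m(m(1-m)/v - 1), b = a(1-m)/m."""
    x = np.clip(np.asarray(minima, float), 1e-12, 1 - 1e-12)
    m, v = x.mean(), x.var()
    if v <= 0:
        raise ValueError("degenerate minima")
    common = m * (1 - m) / v - 1.0
    a0 = max(m * common, 1e-3)
    b0 = max(a0 * (1 - m) / m, 1e-3)

    def nll(params):
        la, lb = params
        return -np.sum(stats.beta.logpdf(x, np.exp(la), np.exp(lb)))

    res = optimize.minimize(nll, [np.log(a0), np.log(b0)], method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-6})
    a, b = np.exp(res.x)
    return float(a), float(b)


def resolve_perfect_ld(tied_snp_indices, rng) -> int:
    """Uniform seeded choice among SNPs in perfect LD."""
    tied = list(tied_snp_indices)
    if not tied:
        raise ValueError("no tied SNPs supplied")
    return tied[int(rng.integers(len(tied)))]


@dataclass
class PermutationRecord:
    top_idx: int
    beta: float
    se: float
    t: float
    p_nominal: float
    p_empirical: float
    p_perm_direct: float
    beta_a: float
    beta_b: float
    n_tested_snps: int
    degenerate: bool = False


def permutation_pass(
    y_rint, cis_dosages, covariates, n_perm: int = 1000, seed: int = 0
) -> PermutationRecord:
    """Top-SNP association with a beta-approximated empirical p-value.

    The covariate-residualized phenotype is permuted ``n_perm`` times; the
    minimum nominal p over the window is recorded per permutation and a
    Beta(a, b) is fitted to the minima by maximum likelihood; the
    empirical p is BetaCDF(observed min p). A direct rank-based
    permutation p ((1 + #{perm <= obs}) / (1 + n_perm)) is also reported.
    Ties in the observed top association (perfect LD) are broken by a
    seeded uniform choice.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(y_rint, float)
    D = np.asarray(cis_dosages, float)
    X = np.asarray(covariates, float)
    n, k = X.shape
    df = n - k - 1
    yr = _residualize_columns(y[:, None], X)[:, 0]
    Dr = _residualize_columns(D, X)
    dnorm = np.sqrt((Dr**2).sum(axis=0))
    ynorm = np.sqrt(yr @ yr)
    r_obs = (Dr.T @ yr) / (dnorm * ynorm)
    r2_obs = r_obs**2
    best = r2_obs.max()
    tied = np.flatnonzero(r2_obs >= best - 1e-12)
    top = resolve_perfect_ld(tied, rng) if len(tied) > 1 else int(tied[0])

    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = yr[perm_idx].T  # n x n_perm
    R = (Dr.T @ Yp) / (dnorm[:, None] * ynorm)
    min_p = _min_p_from_r2((R**2).max(axis=0), df)
    p_obs = float(_min_p_from_r2(np.array([best]), df)[0])
    p_direct = (1.0 + np.sum(min_p <= p_obs)) / (1.0 + n_perm)

    degenerate = np.ptp(min_p) < 1e-12
    if degenerate:
        a = b = np.nan
        p_emp = p_direct
    else:
        a, b = fit_beta_to_minima(min_p)
        p_emp = float(stats.beta.cdf(p_obs, a, b))

    beta_hat = r_obs[top] * ynorm / dnorm[top]
    rss = ynorm**2 * (1 - r2_obs[top])
    se = np.sqrt(rss / df) / dnorm[top]
    return PermutationRecord(
        top_idx=top, beta=float(beta_hat), se=float(se), t=float(beta_hat / se),
        p_nominal=p_obs, p_empirical=p_emp, p_perm_direct=p_direct,
        beta_a=a, beta_b=b, n_tested_snps=D.shape[1], degenerate=degenerate,
    )


def egene_fdr(per_gene: pd.DataFrame, alpha: float = 0.05, p_col: str = "pval_beta"):
    """BH over the per-gene empirical p-values; eGene iff q < alpha."""
    from tricross.expression import bh_fdr

    out = per_gene.copy()
    out["q"] = bh_fdr(out[p_col].values) if len(out) else []
    out["is_egene"] = out.get("q", pd.Series(dtype=float)) < alpha
    return out


def conditional_scan(
    y_rint, cis_dosages, covariates, primary_idx: int, nominal_threshold: float,
    seed: int = 0, max_signals: int = 5,
) -> list[dict]:
    """Forward stepwise scan for conditionally independent signals.

    The accepted eVariants are added to the covariates and the window is
    rescanned; a new signal is accepted iff its nominal p falls below the
    gene's significance threshold (the nominal p that maps to the
    gene-level alpha through the primary pass's beta null). Collinear
    conditioning dosages are dropped. Ranks follow discovery order.
    """
    rng = np.random.default_rng(seed)
    D = np.asarray(cis_dosages, float)
    X0 = np.asarray(covariates, float)
    accepted = [primary_idx]
    records = []
    for rank in range(1, max_signals + 1):
        cond = D[:, accepted]
        Xc = np.hstack([X0, cond])
        # drop collinear conditioning columns
        q = np.linalg.matrix_rank(Xc)
        while q < Xc.shape[1] and Xc.shape[1] > X0.shape[1]:
            Xc = Xc[:, :-1]
            q = np.linalg.matrix_rank(Xc)
        scan = nominal_scan(y_rint, D, Xc)
        scan.loc[accepted, "p"] = 1.0  # conditioning SNPs are not candidates
        best = scan["p"].idxmin()
        r2_best = scan.loc[best, "t"] ** 2
        tied = scan.index[
            (scan["p"] <= scan.loc[best, "p"] * (1 + 1e-9)) & (scan["p"] < 1.0)
        ].tolist()
        if len(tied) > 1:
            best = resolve_perfect_ld(tied, rng)
        if scan.loc[best, "p"] >= nominal_threshold:
            break
        records.append(
            {"snp_idx": int(best), "rank": rank, "beta": scan.loc[best, "beta"],
             "se": scan.loc[best, "se"], "t": scan.loc[best, "t"], "p": scan.loc[best, "p"]}
        )
        accepted.append(int(best))
    return records


# ---------------------------------------------------------------------------
# full mapping driver
# ---------------------------------------------------------------------------


def maf(dosages) -> np.ndarray:
    """Minor-allele frequency per SNP from non-missing dosages."""
    D = np.asarray(dosages, float)
    f = np.nanmean(D, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def map_cis_eqtls(
    log2cpm: pd.DataFrame,
    tech_design: pd.DataFrame,
    dosages: np.ndarray,
    snp_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    maf_threshold: float = 0.01,
    window_bp: int = CIS_WINDOW_BP,
    n_pcs: int = 5,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    conditional: bool = True,
) -> pd.DataFrame:
    """Whole-transcriptome cis-eQTL scan.

    Residualize -> RINT -> PC covariates -> per-gene permutation pass ->
    gene-level BH FDR -> conditional signals for eGenes. Returns one row
    per signal with tensorQTL-style columns (phenotype_id, variant_id,
    tss_distance, maf, slope, slope_se, pval_nominal, pval_beta, q, rank).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE9]))
    E = residualize(log2cpm, tech_design)
    E_rint = np.vstack([rint(E.iloc[g].values) for g in range(len(E))])
    D = np.asarray(dosages, float)
    snp_maf = maf(D)
    poly = snp_maf > maf_threshold
    pruned = ld_prune(D[:, poly])
    pcs = compute_pc_covariates(E_rint, D[:, poly][:, pruned], n_pcs=n_pcs)
    covs = np.hstack([np.ones((D.shape[0], 1)), pcs])

    pos = snp_table["pos"].values
    chrom = snp_table["chrom"].values
    rows = []
    per_gene_window: dict[str, np.ndarray] = {}
    gene_y: dict[str, np.ndarray] = {}
    for g, grow in gene_table.iterrows():
        gid = grow["gene_id"]
        if gid not in log2cpm.index:
            continue
        in_win = (
            (chrom == grow["chrom"])
            & (np.abs(pos - grow["tss"]) <= window_bp)
            & poly
        )
        widx = np.flatnonzero(in_win)
        if len(widx) == 0:
            continue
        y = E_rint[log2cpm.index.get_loc(gid)]
        rec = permutation_pass(
            y, D[:, widx], covs, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        j = widx[rec.top_idx]
        rows.append(
            {
                "phenotype_id": gid,
                "variant_id": snp_table["variant_id"].iloc[j],
                "tss_distance": int(pos[j] - grow["tss"]),
                "maf": snp_maf[j],
                "slope": rec.beta,
                "slope_se": rec.se,
                "t": rec.t,
                "pval_nominal": rec.p_nominal,
                "pval_beta": rec.p_empirical,
                "pval_perm_direct": rec.p_perm_direct,
                "beta_a": rec.beta_a,
                "beta_b": rec.beta_b,
                "n_tested_snps": rec.n_tested_snps,
                "rank": 0,
            }
        )
        per_gene_window[gid] = widx
        gene_y[gid] = y
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res = egene_fdr(res, alpha=alpha)

    if conditional:
        extra = []
        for _, row in res[res["is_egene"]].iterrows():
            gid = row["phenotype_id"]
            widx = per_gene_window[gid]
            a, b = row["beta_a"], row["beta_b"]
            if not np.isfinite(a):
                continue
            thr = float(stats.beta.ppf(alpha, a, b))
            prim = int(np.flatnonzero(
                snp_table["variant_id"].values[widx] == row["variant_id"]
            )[0])
            for rec in conditional_scan(
                gene_y[gid], np.asarray(dosages, float)[:, widx], covs, prim, thr,
                seed=int(rng.integers(2**31 - 1)),
            ):
                j = widx[rec["snp_idx"]]
                extra.append(
                    {
                        "phenotype_id": gid,
                        "variant_id": snp_table["variant_id"].iloc[j],
                        "tss_distance": int(pos[j] - gene_table.set_index("gene_id").loc[gid, "tss"]),
                        "maf": snp_maf[j],
                        "slope": rec["beta"], "slope_se": rec["se"], "t": rec["t"],
                        "pval_nominal": rec["p"], "pval_beta": np.nan,
                        "pval_perm_direct": np.nan, "beta_a": a, "beta_b": b,
                        "n_tested_snps": len(widx), "rank": rec["rank"],
                        "q": row["q"], "is_egene": True,
                    }
                )
        if extra:
            res = pd.concat([res, pd.DataFrame(extra)], ignore_index=True)
    return res.sort_values(["phenotype_id", "rank"]).reset_index(drop=True)
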