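"""Count normalization and moderated-t differential expression.

Implements the standard bulk RNA-seq linear-model chain: low-expression
filtering, TMM between-sample normalization, log2 CPM, voom-style
mean-variance precision weights, per-gene weighted least squares, empirical
Bayes moderation of the residual variances, and Benjamini-Hochberg FDR.

Two model families are supported, matching the study design:

* F0 line contrast:  y ~ Lineage + Sex + %rRNA + %Intergenic
* F2 behavior:       y ~ Behavior + Sex + %rRNA + %Intergenic + Dissector
                         + STGT_Experience + SequencingBatch

Reference levels are bHR and male, so a positive Log2FC for the Lineage
term means upregulated in bLR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess


# ---------------------------------------------------------------------------
# filtering + normalization
# ---------------------------------------------------------------------------


def filter_low_expression(counts: pd.DataFrame, threshold: float = 1.0, fraction: float = 0.75):
    """Remove genes with low-level expression.

    A gene is removed iff the proportion of samples with count < `threshold`
    is >= `fraction` (boundary inclusive): "<1 read in 75% of subjects".
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    low = (counts.values < threshold).mean(axis=1)
    keep = low < fraction
    return counts.loc[keep]


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors (geometric mean 1).

    Reference sample: library whose 75th-percentile CPM is closest to the
    mean 75th-percentile CPM. For each sample, M (log2 count-fraction
    ratio vs reference) and A (average log2 abundance) are computed over
    genes nonzero in both; the 30% tails of M and 5% tails of A are
    trimmed; the factor is 2**(precision-weighted mean of the retained M),
    weights from the asymptotic binomial variance; factors are rescaled to
    geometric mean 1.
    """
    X = np.asarray(counts, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    q75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        f[j] = _tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref], trim_m, trim_a)
    # rescale so the factors multiply to 1
    f = f / np.exp(np.mean(np.log(f)))
    return f


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a):
    ok = (obs > 0) & (ref > 0)
    if not np.any(ok):
        warnings.warn("sample shares no nonzero genes with the reference; factor set to 1")
        return 1.0
    p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic binomial variance of M
    w = 1.0 / ((n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok]))
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    return 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def log2_cpm(counts, factors=None, prior_count: float = 0.5, lib_sizes=None):
    """log2 counts per million with a prior count.

    value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6).
    """
    X = np.asarray(counts, dtype=float)
    lib = X.sum(axis=0) if lib_sizes is None else np.asarray(lib_sizes, float)
    factors = np.ones(X.shape[1]) if factors is None else np.asarray(factors, float)
    eff = lib * factors
    out = np.log2((X + prior_count) / (eff + 2 * prior_count) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


# ---------------------------------------------------------------------------
# voom weights
# ---------------------------------------------------------------------------


def voom_weights(log2cpm, design, eff_lib_sizes, span: float = 0.5):
    """Gene x sample precision weights from the mean-variance trend.

    Per-gene linear fits give residual standard deviations; the square
    root of the SD is smoothed against mean log2 count by LOWESS
    (``span``); each observation's weight is the inverse fourth power of
    the predicted sqrt-SD at its fitted log2 count. With fewer than 10
    genes the trend is unreliable and unit weights are returned with a
    warning.
    """
    Y = np.asarray(log2cpm, dtype=float)
    X = np.asarray(design, dtype=float)
    G, n = Y.shape
    if G < 10:
        warnings.warn("fewer than 10 genes: mean-variance trend unreliable, using unit weights")
        return np.ones_like(Y)
    if n <= X.shape[1]:
        raise ValueError("design has no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    coef = Y @ pinv.T
    fitted = coef @ X.T
    resid = Y - fitted
    df = n - np.linalg.matrix_rank(X)
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    eff = np.asarray(eff_lib_sizes, float)
    # mean log2 count per gene; 1e6/eff converts cpm back to counts
    sx = Y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    sm = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = sm[:, 0], np.maximum(sm[:, 1], 1e-6)
    fitted_logcount = fitted + (np.log2(eff) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, lx, ly)
    return 1.0 / pred**4


# ---------------------------------------------------------------------------
# per-gene linear models + empirical Bayes
# ---------------------------------------------------------------------------


@dataclass
class GeneFits:
    """Per-gene weighted least-squares summaries."""

    coef: np.ndarray  # (G, p)
    stdev_unscaled: np.ndarray  # (G, p): sqrt(diag (X'WX)^-1)
    sigma2: np.ndarray  # (G,) residual variance
    df_residual: int
    genes: pd.Index
    terms: list[str]

    def t_ordinary(self, term: int | str):
        j = self.terms.index(term) if isinstance(term, str) else term
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef[:, j] / (np.sqrt(self.sigma2) * self.stdev_unscaled[:, j])


def fit_gene_models(y_matrix, design: pd.DataFrame, weights=None) -> GeneFits:
    """Weighted least squares of each gene on a shared design matrix."""
    Y = np.asarray(y_matrix, dtype=float)
    X = np.asarray(design, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    if n <= p:
        raise ValueError("need more samples than parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"design matrix is rank deficient (columns: {list(design.columns)})")
    if weights is None:
        XtX = X.T @ X
        XtXi = np.linalg.inv(XtX)
        coef = Y @ (XtXi @ X.T).T
        resid = Y - coef @ X.T
        rss = (resid**2).sum(axis=1)
        unscaled = np.tile(np.sqrt(np.diag(XtXi)), (G, 1))
    else:
        W = np.asarray(weights, dtype=float)
        XtWX = np.einsum("gs,sp,sq->gpq", W, X, X)
        XtWy = np.einsum("gs,sp,gs->gp", W, X, Y)
        coef = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        resid = Y - coef @ X.T
        rss = (W * resid**2).sum(axis=1)
        unscaled = np.sqrt(np.diagonal(np.linalg.inv(XtWX), axis1=1, axis2=2))
    df = n - p
    sigma2 = rss / df
    genes = y_matrix.index if isinstance(y_matrix, pd.DataFrame) else pd.RangeIndex(G)
    terms = list(design.columns) if isinstance(design, pd.DataFrame) else [f"x{j}" for j in range(p)]
    return GeneFits(coef, unscaled, sigma2, df, pd.Index(genes), terms)


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, cf. Smyth 2004)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float):
    """Moment-match a scaled F distribution to sample variances.

    Models s2_g ~ s0^2 * F(df, d0) and estimates (d0, s0^2) from the
    moments of log s2 (the empirical-Bayes hyperparameter fit of the
    moderated-t procedure). Returns ``(d0, s0_sq)`` with ``d0 = inf`` when
    the variances show no excess spread beyond chi-squared sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


def ebayes_moderate(fits: GeneFits, term: int | str):
    """Empirical-Bayes moderated t-statistics for one coefficient.

    Posterior variance s~2 = (d0 s0^2 + d_g s2_g)/(d0 + d_g); moderated
    t = beta / (s~ * stdev_unscaled), on d0 + d_g degrees of freedom.
    The d0 = inf branch (all genes share variance s0^2) is handled
    explicitly.
    """
    j = fits.terms.index(term) if isinstance(term, str) else term
    d0, s0_sq = fit_f_dist(fits.sigma2, fits.df_residual)
    if np.isinf(d0):
        s2_post = np.full_like(fits.sigma2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + fits.df_residual * fits.sigma2) / (d0 + fits.df_residual)
        df_total = d0 + fits.df_residual
    with np.errstate(divide="ignore", invalid="ignore"):
        mod_t = fits.coef[:, j] / (np.sqrt(s2_post) * fits.stdev_unscaled[:, j])
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(mod_t))
    else:
        p = 2.0 * stats.t.sf(np.abs(mod_t), df_total)
    return mod_t, p, d0, s0_sq


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values. NaN p-values propagate as NaN
    and are excluded from the ranking."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# model composition
# ---------------------------------------------------------------------------

F0_COVARIATES = ["Sex", "pct_rRNA", "pct_Intergenic"]
F2_COVARIATES = F0_COVARIATES + ["Dissector", "STGT_Experience", "SequencingBatch"]


def build_design(pheno: pd.DataFrame, term_of_interest: str | None, covariates: list[str],
                 interaction_sex: bool = False) -> pd.DataFrame:
    """Design matrix with declared reference coding (bHR, male, first level).

    Categorical covariates are dummy-coded against their reference level;
    ``interaction_sex`` adds a Sex x term-of-interest column.
    """
    cols = {"Intercept": np.ones(len(pheno))}
    refs = {"Lineage": "bHR", "Sex": "M"}

    def encode(name):
        v = pheno[name]
        if v.dtype.kind in "fiu" and name not in refs:
            return {name: v.astype(float).values}
        ref = refs.get(name, sorted(v.astype(str).unique())[0])
        levels = [l for l in sorted(v.astype(str).unique()) if l != ref]
        return {f"{name}[{l}]": (v.astype(str) == l).astype(float).values for l in levels}

    missing = [c for c in ([term_of_interest] if term_of_interest else []) + covariates
               if c not in pheno.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    interest_cols = []
    if term_of_interest is not None:
        enc = encode(term_of_interest)
        cols.update(enc)
        interest_cols = list(enc)
    for c in covariates:
        cols.update(encode(c))
    if interaction_sex:
        if "Sex[F]" not in cols or not interest_cols:
            raise ValueError("sex interaction requires a Sex column and a term of interest")
        for ic in interest_cols:
            cols[f"{ic}:Sex[F]"] = cols[ic] * cols["Sex[F]"]
    X = pd.DataFrame(cols, index=pheno.index)
    X.attrs["term_of_interest"] = interest_cols[0] if interest_cols else None
    return X


def run_de(
    counts: pd.DataFrame,
    pheno: pd.DataFrame,
    model: str,
    behavior: str | None = None,
    interaction_sex: bool = False,
    filter_threshold: float = 1.0,
    filter_fraction: float = 0.75,
    use_voom: bool = True,
) -> pd.DataFrame:
    """Full differential-expression run for one model.

    ``model``: ``"f0_lineage"`` (line contrast), ``"f2_behavior"``
    (continuous behavior; pass ``behavior``), or ``"f2_sex"``. Composes
    filter -> TMM -> log2 CPM -> voom -> WLS -> EB moderation -> BH FDR.
    Returns a gene-indexed frame (log2fc, t, mod_t, p, q, ave_expr) with
    the EB hyperparameters and model metadata in ``.attrs``. Positive
    log2fc on the F0 model = upregulated in bLR (bHR/male reference
    coding).
    """
    pheno = pheno.loc[counts.columns]
    if model == "f0_lineage":
        design = build_design(pheno, "Lineage", F0_COVARIATES)
    elif model == "f2_behavior":
        if behavior is None:
            raise ValueError("f2_behavior model requires a behavior name")
        design = build_design(pheno, behavior, F2_COVARIATES, interaction_sex=interaction_sex)
    elif model == "f2_sex":
        design = build_design(pheno, "Sex", [c for c in F2_COVARIATES if c != "Sex"])
    else:
        raise ValueError(f"unknown model: {model}")
    term = design.attrs["term_of_interest"]

    kept = filter_low_expression(counts, filter_threshold, filter_fraction)
    factors = tmm_factors(kept)
    lib = kept.sum(axis=0).values
    eff = lib * factors
    y = log2_cpm(kept, factors)
    weights = voom_weights(y, design, eff) if use_voom else None
    fits = fit_gene_models(y, design, weights)
    t_ord = fits.t_ordinary(term)
    mod_t, p, d0, s0_sq = ebayes_moderate(fits, term)
    j = fits.terms.index(term)
    res = pd.DataFrame(
        {
            "log2fc": fits.coef[:, j],
            "t": t_ord,
            "mod_t": mod_t,
            "p": p,
            "q": bh_fdr(p),
            "ave_expr": np.asarray(y).mean(axis=1),
        },
        index=fits.genes.rename("gene_id"),
    )
    res.attrs.update(
        model=model, behavior=behavior, term=term, d0=d0, s0_sq=s0_sq,
        n_samples=counts.shape[1], n_genes_tested=len(kept), n_genes_input=len(counts),
    )
    return res


def pca_diagnostics(log2cpm: pd.DataFrame, pheno: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    """Correlations of the top expression PCs with each covariate.

    Categorical covariates are dummy-coded; the reported value for a
    covariate is the largest |r| over its dummy columns. Mirrors the
    covariate-selection diagnostic of checking which technical variables
    track the top principal components of variation.
    """
    Y = np.asarray(log2cpm, float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    pcs = vt[:n_pcs].T  # samples x n_pcs
    rows = {}
    for c in pheno.columns:
        v = pheno[c]
        if v.dtype.kind in "fiu":
            mats = [v.astype(float).values]
        else:
            levels = sorted(v.astype(str).unique())[1:]
            mats = [(v.astype(str) == l).astype(float).values for l in levels]
        rs = []
        for k in range(pcs.shape[1]):
            best = 0.0
            for m in mats:
                if np.std(m) > 0:
                    best = max(best, abs(np.corrcoef(m, pcs[:, k])[0, 1]))
            rs.append(best)
        rows[c] = rs
    return pd.DataFrame(rows, index=[f"PC{k+1}" for k in range(pcs.shape[1])]).T
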