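"""Moderated count statistics and auxiliary tests, from first principles.

Implements the normalization/testing chain used for both ChIP peak counts
and RNA counts: trimmed-mean-of-M-values (TMM) factors, precision-weighted
log-CPM modeling (voom-style mean-variance weights), weighted least squares
with empirical-Bayes variance moderation, Benjamini-Hochberg adjustment, and
the differential-calling rules. Auxiliary tests: Wilcoxon rank-sum (exact and
normal paths), pooled two-sample t, and the spectral-count G-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .chipnorm import CountMatrix, NormFactors, fpkm

# ---------------------------------------------------------------------------
# design


@dataclass
class DesignMatrix:
    """Two-group design with intercept; the contrast coefficient is the
    log2 fold change of ``test`` over ``reference``."""

    samples: list[str]
    matrix: np.ndarray  # n_samples x 2
    contrast: np.ndarray  # length 2

    @classmethod
    def two_group(cls, conditions: pd.Series, reference: str, test: str) -> "DesignMatrix":
        samples = [s for s, c in conditions.items() if c in (reference, test)]
        ind = np.array([1.0 if conditions[s] == test else 0.0 for s in samples])
        X = np.column_stack([np.ones(len(samples)), ind])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient (need both conditions)")
        return cls(samples=samples, matrix=X, contrast=np.array([0.0, 1.0]))


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float, trim_m: float, trim_a: float
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference;
    returns the factor on the natural scale."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if len(o) == 0:
        return 1.0
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    # ordinal ranks (stable), double trim by M then A quantile ranks
    rank_m = np.empty(n, dtype=int)
    rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
    rank_a = np.empty(n, dtype=int)
    rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() == 0:
        return 1.0
    log2f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0**log2f)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """TMM normalization factors, centered to geometric mean 1.

    Reference sample: the column whose 75th-percentile count/library ratio is
    closest to the mean of those ratios. Features zero in either member of a
    pair are excluded; M-values are inverse-variance weighted (binomial
    asymptotic) and doubly trimmed (``trim_m`` of M, ``trim_a`` of A, each
    side).
    """
    counts = cm.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = cm.library_sizes.to_numpy(dtype=float)
    q75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(factors=pd.Series(f, index=cm.counts.columns), method="tmm")


# ---------------------------------------------------------------------------
# voom-style weights


def voom_weights(
    cm: CountMatrix, norm: NormFactors | None, design: DesignMatrix, span: float = 0.5
):
    """log2-CPM matrix and precision weights from the mean-variance trend.

    Effective library sizes are library_size x factor. log2-CPM uses a +0.5
    count and +1.0 library offset. The sqrt-residual-SD vs average log-count
    scatter is smoothed by lowess (fraction ``span``); each observation's
    weight is the inverse fourth power of the trend evaluated at its fitted
    log-count.
    """
    sub = cm.subset_samples(design.samples)
    counts = sub.counts.to_numpy(dtype=float)
    lib = sub.library_sizes.to_numpy(dtype=float)
    if norm is not None:
        lib = lib * norm.factors.loc[design.samples].to_numpy()
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer samples than design columns")
    logcpm = np.log2((counts + 0.5) / (lib + 1.0)[None, :] * 1e6)
    # unweighted per-feature OLS for the trend
    pinv = np.linalg.pinv(X)
    beta = logcpm @ pinv.T
    fitted = beta @ X.T
    resid = logcpm - fitted
    df_resid = n - p
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    order = np.argsort(sx, kind="stable")
    smooth = lowess(sy[order], sx[order], frac=span, return_sorted=True)
    tx, ty = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
    fitted_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    trend = np.interp(fitted_count, tx, ty)
    weights = 1.0 / trend**4
    logcpm_df = pd.DataFrame(logcpm, index=sub.counts.index, columns=design.samples)
    return logcpm_df, weights


# ---------------------------------------------------------------------------
# moderated fit


@dataclass
class FitResult:
    table: pd.DataFrame  # log2FC, ave_expr, sigma, df_resid, se_unscaled, t, p, q
    d0: float
    s0_sq: float
    meta: dict = field(default_factory=dict)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, decreasing convex function)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimation of the scaled-F prior (d0, s0^2) on log variances."""
    ok = s_sq > 0
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated(
    logcpm: pd.DataFrame,
    weights: np.ndarray,
    design: DesignMatrix,
    prior_df: float | None = None,
) -> FitResult:
    """Per-feature weighted least squares with empirical-Bayes moderation.

    Posterior variance (d0*s0^2 + d_g*s_g^2)/(d0 + d_g); moderated t =
    coef/(SE_unscaled * s_post) with d0 + d_g degrees of freedom. ``prior_df``
    forces d0 (0 recovers the ordinary t; inf the fully pooled z-like limit).
    """
    y = logcpm.to_numpy(dtype=float)
    X = design.matrix
    c = design.contrast
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    nfeat = y.shape[0]
    coef = np.empty(nfeat)
    s_sq = np.empty(nfeat)
    se_unscaled = np.empty(nfeat)
    for g in range(nfeat):
        w = weights[g]
        xw = X * w[:, None]
        xtx = X.T @ xw
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (xw.T @ y[g])
        resid = y[g] - X @ beta
        s_sq[g] = float((w * resid**2).sum() / df_resid)
        coef[g] = float(c @ beta)
        se_unscaled[g] = float(np.sqrt(c @ xtx_inv @ c))
    if prior_df is None:
        d0, s0_sq = _fit_f_dist(s_sq, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(s_sq, df_resid)
    if np.isinf(d0):
        s_post_sq = np.full(nfeat, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_post_sq = s_sq.copy()
        df_total = float(df_resid)
    else:
        s_post_sq = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
        df_total = d0 + df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / (se_unscaled * np.sqrt(s_post_sq))
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {
            "log2FC": coef,
            "ave_expr": y.mean(axis=1),
            "sigma": np.sqrt(s_sq),
            "df_resid": df_resid,
            "se_unscaled": se_unscaled,
            "t": tstat,
            "p": pvals,
            "q": bh_adjust(pvals),
        },
        index=logcpm.index,
    )
    return FitResult(table=table, d0=d0, s0_sq=s0_sq, meta={"df_total": df_total})


# ---------------------------------------------------------------------------
# multiple testing and calling rules


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_differential(
    table: pd.DataFrame,
    mode: str = "replicated",
    q_max: float = 0.05,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
) -> pd.Series:
    """Up/down/ns calls.

    replicated: q < q_max and |log2FC| > lfc_min (the ChIP rule);
    fc_only:    |log2FC| > lfc_min alone (no-replicate contrasts);
    volcano:    raw p < p_max and |log2FC| > lfc_min (the RNA volcano rule).
    """
    lfc = table["log2FC"]
    if mode == "replicated":
        sig = table["q"] < q_max
    elif mode == "fc_only":
        sig = pd.Series(True, index=table.index)
    elif mode == "volcano":
        sig = table["p"] < p_max
    else:
        raise ValueError(f"unknown mode {mode!r}")
    call = pd.Series("ns", index=table.index, name="call")
    call[sig & (lfc > lfc_min)] = "up"
    call[sig & (lfc < -lfc_min)] = "down"
    return call


def fc_only_log2fc(
    cm: CountMatrix,
    reference: str,
    test: str,
    pseudo_fpkm: float = 0.1,
    norm: NormFactors | None = None,
) -> pd.DataFrame:
    """log2 fold change of mean FPKM for no-replicate contrasts, with a
    pseudo-FPKM floor guarding against division by zero. Normalization
    factors, when given, multiply the library sizes in the FPKM denominator
    (the same contract as the replicated path)."""
    if norm is not None:
        cm = CountMatrix(
            counts=cm.counts,
            lengths=cm.lengths,
            library_sizes=cm.library_sizes * norm.factors.loc[cm.counts.columns],
            conditions=cm.conditions,
        )
    f = fpkm(cm)
    cond = cm.conditions
    a = f[[s for s in f.columns if cond[s] == reference]].mean(axis=1)
    b = f[[s for s in f.columns if cond[s] == test]].mean(axis=1)
    lfc = np.log2((b + pseudo_fpkm) / (a + pseudo_fpkm))
    return pd.DataFrame({"log2FC": lfc, "fpkm_ref": a, "fpkm_test": b}, index=f.index)


# ---------------------------------------------------------------------------
# auxiliary tests


def wilcoxon_rank_sum(x, y, exact_max: int = 8) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank sum of x, p).

    Exact enumeration when min(n, m) <= ``exact_max`` and there are no ties;
    otherwise normal approximation with midranks, tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < n + m
    if min(n, m) <= exact_max and not has_ties:
        total = comb(n + m, n)
        dist: dict[float, int] = {}
        for subset in combinations(range(1, n + m + 1), n):
            s = sum(subset)
            dist[s] = dist.get(s, 0) + 1
        lo = sum(c for s, c in dist.items() if s <= w)
        hi = sum(c for s, c in dist.items() if s >= w)
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return w, p
    mu = n * (n + m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    nn = n + m
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (nn * (nn - 1))
    var = n * m / 12.0 * ((nn + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def unpaired_ttest(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((n - 1) * x.var(ddof=1) + (m - 1) * y.var(ddof=1)) / (n + m - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        return (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    t = diff / np.sqrt(sp2 * (1.0 / n + 1.0 / m))
    p = 2.0 * stats.t.sf(abs(t), n + m - 2)
    return float(t), float(p)


def g_test(observed_a: int, observed_b: int, total_a: int, total_b: int) -> tuple[float, float]:
    """Spectral-count G-test for one feature in two samples.

    Likelihood-ratio statistic over the observed counts with expectations
    from the margins, E_i = total_i * (O_a + O_b) / (total_a + total_b):
    G = 2 * sum O_i ln(O_i / E_i), 0 ln 0 = 0; p from chi-square, 1 df.
    """
    if min(observed_a, observed_b, total_a, total_b) < 0:
        raise ValueError("counts must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    o = np.array([observed_a, observed_b], dtype=float)
    t = np.array([total_a, total_b], dtype=float)
    if o.sum() == 0:
        return 0.0, 1.0
    e = t * o.sum() / t.sum()
    terms = np.where(o > 0, o * np.log(np.where(o > 0, o / e, 1.0)), 0.0)
    g = float(2.0 * terms.sum())
    return g, float(stats.chi2.sf(g, df=1))
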