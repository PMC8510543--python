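"""Statistical toolkit: correlations, two-sample tests, regression with a
slope-equality test, histogram fits, multiple-testing correction, and
box-plot statistics.

Every statistic is computed from its explicit formula here; scipy supplies
only distribution functions (t, F, chi-square, normal CDFs/quantiles) for
the p-values.  The Mann-Whitney test enumerates its exact null distribution
(midranks, so ties are handled) when the product of sample sizes is small,
and otherwise uses the normal approximation with tie and continuity
corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import rankdata

EXACT_MW_LIMIT = 400  # exact enumeration when n_a * n_b <= this


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: float | None
    p_raw: float
    p_adj: float | None = None
    note: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_raw)


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    r_squared: float
    p_F: float | None = None
    n: int = 0
    note: str = ""


def _undefined(name: str, note: str) -> StatResult:
    return StatResult(test_name=name, statistic=float("nan"), df=None, p_raw=float("nan"), note=note)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson(x, y) -> StatResult:
    """Pearson correlation with a two-tailed t-based p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("pearson needs two equal-length samples of n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        return _undefined("pearson", "zero variance")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return StatResult("pearson", r, n - 2, 0.0)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return StatResult("pearson", r, n - 2, float(p))


def spearman(x, y) -> StatResult:
    """Spearman rank correlation: Pearson on midranks."""
    res = pearson(rankdata(x), rankdata(y))
    res.test_name = "spearman"
    return res


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------


def two_sample_t(a, b, variant: str = "pooled") -> StatResult:
    """Two-tailed two-sample t-test (pooled-variance Student by default,
    Welch by ``variant='welch'``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        name = "t_pooled"
    elif variant == "welch":
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
        name = "t_welch"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0:
        if ma == mb:
            return StatResult(name, 0.0, df, 1.0, note="degenerate: zero variance")
        return _undefined(name, "degenerate: zero variance, unequal means")
    t = (ma - mb) / se
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult(name, float(t), float(df), float(p))


def _mw_rank_sum_distribution(scaled_ranks: np.ndarray, na: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the sample-a rank sum over all C(n, na)
    labelings, on integer (doubled-midrank) scale.  Returns (sums, counts)."""
    total = int(scaled_ranks.sum())
    # ways[k, s] = number of size-k subsets with scaled-rank sum s
    ways = np.zeros((na + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in scaled_ranks:
        r = int(r)
        for k in range(min(na, len(scaled_ranks)), 0, -1):
            ways[k, r:] += ways[k - 1, : total + 1 - r]
    counts = ways[na]
    sums = np.nonzero(counts)[0]
    return sums, counts[sums]


def mann_whitney(a, b) -> StatResult:
    """Two-tailed Mann-Whitney U test.

    Exact (enumeration of the rank-sum null, midranks for ties) when
    n_a*n_b <= EXACT_MW_LIMIT; otherwise normal approximation with tie
    correction and a 0.5 continuity correction.  The exact two-sided p is
    2*min(P(R <= r), P(R >= r)) capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("each sample needs n >= 1")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    ra = ranks[:na].sum()
    u = ra - na * (na + 1) / 2  # U for sample a
    if na * nb <= EXACT_MW_LIMIT:
        scaled = np.round(ranks * 2).astype(int)
        r_obs = int(round(ra * 2))
        sums, counts = _mw_rank_sum_distribution(scaled, na)
        total = counts.sum()
        p_le = counts[sums <= r_obs].sum() / total
        p_ge = counts[sums >= r_obs].sum() / total
        p = min(1.0, 2 * min(p_le, p_ge))
        return StatResult("mann_whitney_exact", float(u), None, float(p))
    n = na + nb
    mu = na * nb / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12 * (n + 1 - tie_term)
    if var == 0:
        return StatResult("mann_whitney_normal", float(u), None, 1.0, note="all ties")
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return StatResult("mann_whitney_normal", float(u), None, float(min(1.0, p)))


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares y = b*x + c with slope/intercept standard
    errors, R^2, and the regression F-test p (df 1, n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("linear_fit needs n >= 3")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate x: zero variance")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    mse = sse / (n - 2)
    se_slope = math.sqrt(mse / sxx)
    se_intercept = math.sqrt(mse * (1 / n + x.mean() ** 2 / sxx))
    if mse == 0:
        p_f = 0.0
    else:
        f = (sst - sse) / 1 / mse
        p_f = float(stats.f.sf(f, 1, n - 2))
    return FitResult(
        model="linear",
        params={
            "slope": slope,
            "intercept": intercept,
            "se_slope": se_slope,
            "se_intercept": se_intercept,
        },
        r_squared=r2,
        p_F=p_f,
        n=n,
    )


def slope_equality_test(fit1: FitResult, fit2: FitResult) -> StatResult:
    """t-test of equal slopes: t = (b1-b2)/sqrt(SE1^2+SE2^2) with
    Welch-Satterthwaite degrees of freedom (component df = n_i - 2)."""
    b1, b2 = fit1.params["slope"], fit2.params["slope"]
    s1, s2 = fit1.params["se_slope"], fit2.params["se_slope"]
    v1, v2 = s1 * s1, s2 * s2
    se = math.sqrt(v1 + v2)
    if se == 0:
        if b1 == b2:
            return StatResult("slope_equality", 0.0, None, 1.0, note="zero SEs")
        return _undefined("slope_equality", "zero SEs, unequal slopes")
    df1, df2 = fit1.n - 2, fit2.n - 2
    df = (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)
    t = (b1 - b2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult("slope_equality", float(t), float(df), float(p))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values: p_adj(i) = min_{j>=i} (m/rank_j) p_(j),
    capped at 1; order-preserving in the original input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Histogram fits
# ---------------------------------------------------------------------------


def fit_gaussian_histogram(values, bin_width: float = 1.0) -> FitResult:
    """Nonlinear least-squares fit of binned counts to a*exp(-(x-mu)^2/(2*s^2)).

    Initialization: a = max bin count, mu = count-weighted bin mean,
    s = count-weighted bin SD.  Requires at least 5 nonzero bins.
    """
    values = np.asarray(values, dtype=float)
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    if (counts > 0).sum() < 5:
        raise ValueError("need at least 5 nonzero bins for a Gaussian fit")
    w = counts / counts.sum()
    mu0 = float((centers * w).sum())
    sd0 = float(math.sqrt(((centers - mu0) ** 2 * w).sum())) or bin_width

    def gauss(x, a, mu, sd):
        return a * np.exp(-((x - mu) ** 2) / (2 * sd**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, centers, counts, p0=[counts.max(), mu0, sd0], xtol=1e-10, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Gaussian histogram fit did not converge: {exc}") from exc
    fitted = gauss(centers, *popt)
    sse = float(((counts - fitted) ** 2).sum())
    sst = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return FitResult(
        model="gaussian",
        params={"amplitude": float(popt[0]), "mean": float(popt[1]), "sd": float(abs(popt[2]))},
        r_squared=r2,
        n=len(values),
    )


def poisson_expected_histogram(values) -> tuple[np.ndarray, np.ndarray]:
    """Expected integer-bin counts under a Poisson with the sample mean.

    Returns (k, expected counts) for k = 0..max(values).
    """
    values = np.asarray(values, dtype=float)
    lam = values.mean()
    k = np.arange(0, int(values.max()) + 1)
    return k, len(values) * stats.poisson.pmf(k, lam)


# ---------------------------------------------------------------------------
# Box-plot statistics
# ---------------------------------------------------------------------------


@dataclass
class BoxStats:
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))


def box_stats(values) -> BoxStats:
    """Quartiles (linear-interpolation convention), whiskers at the most
    extreme non-outlier values, and outliers flagged at >= Q3 + 1.5*IQR or
    <= Q1 - 1.5*IQR.  When the IQR is zero the rule degenerates; only
    strictly-outside values are then flagged."""
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("box_stats needs n >= 1")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_cut, hi_cut = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if iqr > 0:
        is_out = (v >= hi_cut) | (v <= lo_cut)
    else:
        is_out = (v > hi_cut) | (v < lo_cut)
    inliers = v[~is_out]
    if len(inliers) == 0:
        w_lo = w_hi = med
    else:
        w_lo, w_hi = inliers.min(), inliers.max()
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=float(w_lo),
        whisker_hi=float(w_hi),
        outliers=np.sort(v[is_out]),
    )


def chi_square_homogeneity(counts) -> StatResult:
    """Chi-square goodness-of-fit of counts against a uniform expectation."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return _undefined("chi_square_homogeneity", "no events")
    expected = counts.mean()
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = len(counts) - 1
    return StatResult("chi_square_homogeneity", stat, df, float(stats.chi2.sf(stat, df)))
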