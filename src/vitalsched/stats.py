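"""Statistical comparisons between charting strategies.

Coverage fractions are compared with two-sample t tests (Welch form by
default) and with Fieller-type confidence intervals for the ratio of group
means under heterogeneous variances.  Capture proportions are compared with
Yates-corrected chi-squared tests and skewness-corrected score (Gart-Nam
family) confidence intervals for the ratio of proportions.  Capture lags are
compared with Wilcoxon signed-rank tests on paired events and with
percentile-bootstrap confidence intervals for the difference in medians.
All tests are two-sided; alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

ALPHA = 0.05


@dataclass
class ComparisonResult:
    """A labelled estimate with 95% CI, two-sided p value and group sizes."""

    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int
    flags: list[str] = field(default_factory=list)


def _as_array(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    return arr


def _welch_se_df(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return math.sqrt(se2), df


def two_sample_t(
    cov_a: Sequence[float],
    cov_b: Sequence[float],
    label: str = "mean difference",
    equal_var: bool = False,
) -> ComparisonResult:
    """Two-sample t test for the difference in means (Welch by default)."""
    a, b = _as_array(cov_a), _as_array(cov_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    flags = []
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            # degenerate: identical constants in both groups
            return ComparisonResult(label, 0.0, 0.0, 0.0, 1.0, len(a), len(b), ["zero_variance"])
        flags.append("zero_variance")
        return ComparisonResult(label, diff, diff, diff, 0.0, len(a), len(b), flags)
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        se = math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        df = float(len(a) + len(b) - 2)
    else:
        se, df = _welch_se_df(a, b)
    tcrit = stats.t.ppf(1 - ALPHA / 2, df)
    return ComparisonResult(
        label, diff, diff - tcrit * se, diff + tcrit * se, float(t_res.pvalue), len(a), len(b), flags
    )


def ratio_of_means_ci(
    cov_a: Sequence[float],
    cov_b: Sequence[float],
    label: str = "ratio of means",
) -> ComparisonResult:
    """Ratio of group means with a Fieller-type CI for heterogeneous variances.

    The CI is the set of ratios R with |mean(a) - R mean(b)| <= t * SE(R),
    SE(R)^2 = va/na + R^2 vb/nb, solved as a quadratic; it is unbounded (and
    flagged) when the denominator mean is not significantly positive.  The
    p value tests ratio = 1, i.e. equality of means (Welch).
    """
    a, b = _as_array(cov_a), _as_array(cov_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    if mb <= 0:
        raise ValueError("denominator group mean must be positive")
    ratio = float(ma / mb)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se, df = _welch_se_df(a, b)
    flags = []
    if se == 0:
        p = 1.0 if ma == mb else 0.0
        return ComparisonResult(label, ratio, ratio, ratio, p, na, nb, ["zero_variance"])
    tcrit = stats.t.ppf(1 - ALPHA / 2, df)
    p = float(2 * stats.t.sf(abs(ma - mb) / se, df))
    # Fieller quadratic: (mb^2 - t^2 vb/nb) R^2 - 2 ma mb R + (ma^2 - t^2 va/na) = 0
    qa = mb**2 - tcrit**2 * vb / nb
    qb = -2 * ma * mb
    qc = ma**2 - tcrit**2 * va / na
    disc = qb**2 - 4 * qa * qc
    if qa <= 0 or disc < 0:
        flags.append("unbounded_ci")
        return ComparisonResult(label, ratio, -np.inf, np.inf, p, na, nb, flags)
    lo = (-qb - math.sqrt(disc)) / (2 * qa)
    hi = (-qb + math.sqrt(disc)) / (2 * qa)
    return ComparisonResult(label, ratio, float(lo), float(hi), p, na, nb, flags)


def prop_test_cc(
    captured_a: int,
    n_a: int,
    captured_b: int,
    n_b: int,
    label: str = "difference in proportions",
) -> ComparisonResult:
    """Yates continuity-corrected chi-squared test on the 2x2 capture table.

    The point estimate is the difference in proportions with a
    continuity-corrected Wald 95% CI (as in R's ``prop.test``).
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be at least 1")
    if not (0 <= captured_a <= n_a and 0 <= captured_b <= n_b):
        raise ValueError("capture counts must lie within group sizes")
    pa, pb = captured_a / n_a, captured_b / n_b
    diff = pa - pb
    flags = []
    table = np.array([[captured_a, n_a - captured_a], [captured_b, n_b - captured_b]])
    if (table.sum(axis=0) == 0).any():
        flags.append("zero_margin")
        p = 1.0
    else:
        p = float(stats.chi2_contingency(table, correction=True).pvalue)
    se = math.sqrt(pa * (1 - pa) / n_a + pb * (1 - pb) / n_b)
    cc = 0.5 * (1 / n_a + 1 / n_b)
    z = stats.norm.ppf(1 - ALPHA / 2)
    half = z * se + cc
    return ComparisonResult(
        label, float(diff), max(diff - half, -1.0), min(diff + half, 1.0), p, n_a, n_b, flags
    )


# ---------------------------------------------------------------------------
# Skewness-corrected score CI for a ratio of proportions (Gart-Nam family)
# ---------------------------------------------------------------------------


def _constrained_mles(phi: float, x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Binomial MLEs of (p1, p2) under the constraint p1 = phi * p2 (Koopman)."""
    a = phi * (n1 + x2) + x1 + n2
    disc = a * a - 4 * phi * (n1 + n2) * (x1 + x2)
    p1 = (a - math.sqrt(max(disc, 0.0))) / (2 * (n1 + n2))
    p1 = min(max(p1, 1e-12), 1 - 1e-12)
    p2 = min(max(p1 / phi, 1e-12), 1 - 1e-12)
    return p1, p2


def _score_u_gamma(phi: float, x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Score statistic u and estimated skewness gamma for H0: p1/p2 = phi."""
    p1h, p2h = x1 / n1, x2 / n2
    p1, p2 = _constrained_mles(phi, x1, n1, x2, n2)
    q1, q2 = 1 - p1, 1 - p2
    var = p1 * q1 / n1 + phi**2 * p2 * q2 / n2
    if var <= 0:
        return 0.0, 0.0
    u = (p1h - phi * p2h) / math.sqrt(var)
    mu3 = p1 * q1 * (q1 - p1) / n1**2 - phi**3 * p2 * q2 * (q2 - p2) / n2**2
    return u, mu3 / var**1.5


def _score_equation(
    phi: float, x1: int, n1: int, x2: int, n2: int, z_target: float, skew_corrected: bool
) -> float:
    """Root function for the CI limits: u(phi) - correction - z_target.

    The skewness correction uses the Cornish-Fisher form evaluated at the
    target quantile, u(phi) = z + gamma(phi) (z^2 - 1) / 6, which keeps the
    equation monotone in phi (the u^2 form blows up far from the estimate).
    """
    u, gamma = _score_u_gamma(phi, x1, n1, x2, n2)
    corr = gamma * (z_target * z_target - 1) / 6 if skew_corrected else 0.0
    return u - corr - z_target


def ratio_of_proportions_ci(
    captured_a: int,
    n_a: int,
    captured_b: int,
    n_b: int,
    label: str = "ratio of proportions",
    skew_corrected: bool = True,
) -> ComparisonResult:
    """Score-based CI for (a/n_a)/(b/n_b), with a skewness correction.

    The limits are the ratios at which the (skewness-corrected) score
    statistic equals the two-sided 95% normal quantile; with
    ``skew_corrected=False`` this is the plain asymptotic score (Koopman)
    interval, which the corrected interval approaches when the estimated
    skewness vanishes.  The p value tests ratio = 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be at least 1")
    z = float(stats.norm.ppf(1 - ALPHA / 2))
    pa, pb = captured_a / n_a, captured_b / n_b
    estimate = pa / pb if pb > 0 else np.inf
    flags = []
    args = (captured_a, n_a, captured_b, n_b)

    tiny, huge = 1e-10, 1e10
    anchor = estimate if (np.isfinite(estimate) and estimate > 0) else 1.0

    def solve(z_target: float) -> Optional[float]:
        """Root of the (monotone decreasing) score equation; None if off-scale."""

        def f(phi: float) -> float:
            return _score_equation(phi, *args, z_target, skew_corrected)

        lo = hi = anchor
        if f(anchor) > 0:
            while f(hi) > 0:
                hi *= 10
                if hi > huge:
                    return None
        else:
            while f(lo) < 0:
                lo /= 10
                if lo < tiny:
                    return 0.0
        return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))

    if captured_a == 0:
        lower = 0.0
        flags.append("zero_numerator")
    else:
        root = solve(z)
        lower = 0.0 if root is None else root
    if captured_b == 0:
        upper = np.inf
        flags.append("zero_denominator")
    else:
        root = solve(-z)
        if root is None:
            upper = np.inf
            flags.append("unbounded_ci")
        else:
            upper = root
    u1, gamma1 = _score_u_gamma(1.0, *args)
    z1 = u1 - gamma1 * (u1 * u1 - 1) / 6 if skew_corrected else u1
    p = float(2 * stats.norm.sf(abs(z1)))
    return ComparisonResult(label, float(estimate), lower, upper, min(p, 1.0), n_a, n_b, flags)


# ---------------------------------------------------------------------------
# Lag comparisons
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    paired_lags_a: Sequence[float],
    paired_lags_b: Sequence[float],
    label: str = "signed-rank",
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired capture lags.

    Pairs with zero difference are dropped; the exact null distribution
    (conditional on the observed ranks, so ties are handled) is used for
    n <= 25, otherwise the normal approximation with tie and continuity
    correction.  The point estimate is the median paired difference; the CI
    is not defined for this test.
    """
    a, b = _as_array(paired_lags_a), _as_array(paired_lags_b)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 1:
        raise ValueError("need at least one pair")
    d = a - b
    estimate = float(np.median(d))
    nz = d[d != 0]
    flags = []
    if len(nz) == 0:
        return ComparisonResult(label, 0.0, np.nan, np.nan, 1.0, len(a), len(b), ["all_zero_diffs"])
    if len(nz) <= 25:
        res = stats.wilcoxon(nz, method="exact")
    else:
        res = stats.wilcoxon(nz, method="approx", correction=True)
        flags.append("normal_approximation")
    return ComparisonResult(
        label, estimate, np.nan, np.nan, float(res.pvalue), len(a), len(b), flags
    )


def bootstrap_median_diff(
    lags_a: Sequence[float],
    lags_b: Sequence[float],
    replicates: int = 10_000,
    seed: int = 0,
    label: str = "median difference",
    paired: bool = False,
) -> ComparisonResult:
    """Percentile bootstrap 95% CI for median(a) - median(b).

    Groups are resampled independently by default (they are event sets, not
    paired observations); ``paired=True`` resamples pairs jointly.  The
    reported p value is the bootstrap achieved significance level for a zero
    median difference (2 * min tail fraction of the bootstrap distribution),
    not an exact test.  Deterministic given the seed.
    """
    a, b = _as_array(lags_a), _as_array(lags_b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be nonempty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    estimate = float(np.median(a) - np.median(b))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired bootstrap requires equal-length samples")
        idx = rng.integers(0, len(a), size=(replicates, len(a)))
        diffs = np.median(a[idx], axis=1) - np.median(b[idx], axis=1)
    else:
        ia = rng.integers(0, len(a), size=(replicates, len(a)))
        ib = rng.integers(0, len(b), size=(replicates, len(b)))
        diffs = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
    lo, hi = np.percentile(diffs, [100 * ALPHA / 2, 100 * (1 - ALPHA / 2)])
    tail = min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    p = float(min(1.0, 2 * tail))
    return ComparisonResult(label, estimate, float(lo), float(hi), p, len(a), len(b))
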