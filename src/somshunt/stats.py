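"""Statistical kernel shared by every pipeline stage.

Kernel smoothing, calibration regression, the seasonal sinusoid fit,
rank tests (Kruskal-Wallis, Dunn's post hoc, an umbrella rhythm test),
Benjamini-Hochberg FDR control, and type-II (major axis) regression with
a permutation null.  Everything here is deterministic given its inputs;
random number generators are explicit arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "LinearFit",
    "SeasonalFit",
    "MajorAxisFit",
    "RhythmResult",
    "PairResult",
    "GroupComparison",
    "nw_smooth",
    "linear_detrend",
    "ols_fit",
    "nls_sinusoid_fit",
    "kruskal_wallis",
    "dunn_posthoc",
    "bh_adjust",
    "major_axis_fit",
    "rank_rhythm_test",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """Ordinary least squares fit y = intercept + slope * x.

    ``standardized_residuals`` are internally studentized residuals,
    residual / (s * sqrt(1 - leverage)) -- the conventional statistic for
    flagging outlying calibration points.
    """

    intercept: float
    slope: float
    adj_r_squared: float
    residuals: np.ndarray
    standardized_residuals: np.ndarray
    n: int
    se_intercept: float = np.nan
    se_slope: float = np.nan


@dataclass
class SeasonalFit:
    """Sinusoidal seasonal model  y = a + b*sin(2*pi*(c + t)),  t in [0, 1).

    The (b, c) pair is only identified up to the equivalence
    (b, c) ~ (-b, c + 0.5 mod 1); output is canonicalized to c in [0.5, 1.0)
    so the reported parameterization is unique.  ``amplitude`` is |b|;
    ``t_min``/``t_max`` locate the extrema of the fitted curve in decimal
    years.  When the amplitude is not significantly positive
    (``phase_identifiable`` False) the phase and extrema are NaN.
    """

    a: float
    b: float
    c: float
    se_a: float
    se_b: float
    se_c: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    ci95_c: tuple[float, float]
    amplitude: float
    t_min: float
    t_max: float
    n: int
    converged: bool
    phase_identifiable: bool


@dataclass
class MajorAxisFit:
    """Type-II (major axis) line; ``perm_p`` from shuffling y against x."""

    slope: float
    intercept: float
    perm_p: float
    n_perm: int
    n: int
    slope_defined: bool = True


@dataclass
class RhythmResult:
    """Umbrella rank test for a periodic signal pooled into phase classes."""

    p_value: float
    period_hours: float
    best_peak_phase: int
    n_phase_classes: int
    statistic: float


@dataclass
class PairResult:
    group_i: int
    group_j: int
    dunn_z: float
    dunn_p_raw: float
    dunn_p_adj: float


@dataclass
class GroupComparison:
    kw_statistic: float
    kw_p: float
    pairs: list[PairResult] = field(default_factory=list)
    group_means: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# smoothing and detrending
# ---------------------------------------------------------------------------


def nw_smooth(x, y, bandwidth, eval_points):
    """Nadaraya-Watson kernel regression with a Gaussian kernel.

    ``bandwidth`` is the Gaussian scale h in exp(-d^2 / (2 h^2)).  Missing
    (NaN) y values are dropped before weighting; because Gaussian weights
    are strictly positive every evaluation point receives an estimate as
    long as one finite observation exists.

    Returns one smoothed value per entry of ``eval_points``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eval_points = np.asarray(eval_points, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be nonempty and of equal length")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    keep = np.isfinite(y) & np.isfinite(x)
    if not keep.any():
        raise ValueError("all y values are missing")
    x, y = x[keep], y[keep]
    d = (eval_points[:, None] - x[None, :]) / bandwidth
    w = np.exp(-0.5 * d * d)
    return (w @ y) / w.sum(axis=1)


def linear_detrend(t, y):
    """Remove the OLS line of y on t; residuals have zero mean and slope."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points to detrend")
    if np.ptp(t) == 0:
        raise ValueError("constant time vector: singular design")
    slope, intercept = np.polyfit(t, y, 1)
    return y - (intercept + slope * t)


# ---------------------------------------------------------------------------
# linear calibration fit
# ---------------------------------------------------------------------------


def ols_fit(x, y) -> LinearFit:
    """OLS of y on x with internally studentized residuals (via statsmodels)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = np.asarray(model.resid)
    if np.allclose(resid, 0):
        # noiseless line: studentized residuals are 0/0; define as zeros
        stud = np.zeros_like(resid)
        adj_r2 = 1.0
    else:
        stud = np.asarray(OLSInfluence(model).resid_studentized_internal)
        adj_r2 = float(model.rsquared_adj)
    return LinearFit(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        adj_r_squared=adj_r2,
        residuals=resid,
        standardized_residuals=stud,
        n=int(x.size),
        se_intercept=float(model.bse[0]),
        se_slope=float(model.bse[1]),
    )


# ---------------------------------------------------------------------------
# seasonal sinusoid
# ---------------------------------------------------------------------------


def _canonicalize_phase(b: float, c: float) -> tuple[float, float]:
    """Map (b, c) to the unique equivalent representation with c in [0.5, 1)."""
    c = c % 1.0
    if c < 0.5:
        b, c = -b, (c + 0.5) % 1.0
    return b, c


def nls_sinusoid_fit(t, y) -> SeasonalFit:
    """Fit y = a + b sin(2 pi (c + t)) by exact linear reparameterization.

    The model is linear in (a, B1, B2) with
    b*sin(2 pi (c+t)) = B1*sin(2 pi t) + B2*cos(2 pi t),
    B1 = b cos(2 pi c), B2 = b sin(2 pi c); the OLS solution is the exact
    nonlinear least squares optimum, so no initialization or convergence
    tolerance is involved.  Standard errors for (b, c) follow by the delta
    method from the OLS covariance of (B1, B2).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need n >= 4 observations")
    n = t.size
    X = np.column_stack([np.ones(n), np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
    model = sm.OLS(y, X).fit()
    a, b1, b2 = (float(v) for v in model.params)
    cov = np.asarray(model.cov_params())
    se_a = float(np.sqrt(cov[0, 0]))

    r = float(np.hypot(b1, b2))
    if r == 0.0:
        # exactly constant fit: amplitude zero, phase undefined
        return SeasonalFit(
            a=a, b=0.0, c=np.nan, se_a=se_a, se_b=0.0, se_c=np.nan,
            ci95_a=(a - 1.96 * se_a, a + 1.96 * se_a),
            ci95_b=(0.0, 0.0), ci95_c=(np.nan, np.nan),
            amplitude=0.0, t_min=np.nan, t_max=np.nan,
            n=n, converged=True, phase_identifiable=False,
        )

    # b sin(2 pi c) = B2, b cos(2 pi c) = B1  ->  take b = +r first, then
    # canonicalize to c in [0.5, 1).
    c_raw = (np.arctan2(b2, b1) / (2 * np.pi)) % 1.0
    b, c = _canonicalize_phase(r, c_raw)

    # delta method: r = sqrt(B1^2+B2^2); c = atan2(B2, B1)/(2 pi).
    # |b| shares se with r; sign flips do not change the se.
    g_r = np.array([b1 / r, b2 / r])
    g_c = np.array([-b2 / r**2, b1 / r**2]) / (2 * np.pi)
    cov_bb = cov[1:, 1:]
    se_b = float(np.sqrt(g_r @ cov_bb @ g_r))
    se_c = float(np.sqrt(g_c @ cov_bb @ g_c))

    # Wald test of amplitude > 0 (two-sided on r)
    wald_p = 2 * sps.norm.sf(r / se_b) if se_b > 0 else 0.0
    identifiable = bool(wald_p <= 0.05)

    if identifiable:
        # extrema of a + b sin(2 pi (c+t)):  peak where sin = sign(b)
        if b > 0:
            t_max = (0.25 - c) % 1.0
            t_min = (0.75 - c) % 1.0
        else:
            t_max = (0.75 - c) % 1.0
            t_min = (0.25 - c) % 1.0
        c_out, ci_c = c, (c - 1.96 * se_c, c + 1.96 * se_c)
    else:
        t_min = t_max = np.nan
        c_out, ci_c = np.nan, (np.nan, np.nan)

    return SeasonalFit(
        a=a, b=b, c=c_out,
        se_a=se_a, se_b=se_b, se_c=se_c,
        ci95_a=(a - 1.96 * se_a, a + 1.96 * se_a),
        ci95_b=(b - 1.96 * se_b, b + 1.96 * se_b),
        ci95_c=ci_c,
        amplitude=abs(b), t_min=t_min, t_max=t_max,
        n=n, converged=True, phase_identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _check_groups(groups):
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.size == 0:
            raise ValueError("empty group")
    return out


def kruskal_wallis(groups):
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    Degenerate case (all observations identical) is defined as H = 0, p = 1.
    """
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups) -> GroupComparison:
    """Dunn's post hoc rank comparison with midranks and tie correction.

    For groups i, j:  z = (Rbar_i - Rbar_j) / sqrt(V * (1/n_i + 1/n_j)) with
    V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)).  Two-sided normal p-values,
    BH-adjusted across the pairs of this comparison.
    """
    groups = _check_groups(groups)
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var = n_tot * (n_tot + 1) / 12.0 - tie_sum / (12.0 * (n_tot - 1))

    kw_h, kw_p = kruskal_wallis(groups)
    pairs = []
    raw_ps = []
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if denom == 0 else float((mean_ranks[i] - mean_ranks[j]) / denom)
            p = float(2 * sps.norm.sf(abs(z)))
            pairs.append(PairResult(i, j, z, p, np.nan))
            raw_ps.append(p)
    adj = bh_adjust(raw_ps)
    for pr, pa in zip(pairs, adj):
        pr.dunn_p_adj = float(pa)
    return GroupComparison(
        kw_statistic=kw_h,
        kw_p=kw_p,
        pairs=pairs,
        group_means=[float(g.mean()) for g in groups],
    )


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (plain BH, no pi0)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# type-II regression
# ---------------------------------------------------------------------------


def _ma_slope(x, y):
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    if sxy == 0:
        return np.nan
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)


def major_axis_fit(x, y, n_perm=10_000, seed=None) -> MajorAxisFit:
    """Major axis (type-II) regression with a permutation significance test.

    The permutation null shuffles y against x.  Exceedance is measured on
    the absolute correlation |r|: the major-axis slope magnitude is
    *minimized*, not maximized, by strong association (for fixed marginal
    variances any permutation that weakens the covariance inflates |slope|),
    so |r| is the statistic whose upper tail corresponds to a significant
    fit -- the same equivalence the standard type-II regression test uses.
    The add-one estimator perm_p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm+1)
    keeps p in [1/(n_perm+1), 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    slope = _ma_slope(x, y)
    if not np.isfinite(slope):
        return MajorAxisFit(np.nan, np.nan, 1.0, int(n_perm), int(x.size), False)
    intercept = float(y.mean() - slope * x.mean())
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    r_obs = abs(float(xc @ yc))  # |r| up to the fixed scale sqrt(sxx*syy)
    count = 0
    yp = yc.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(yp)
        if abs(float(xc @ yp)) >= r_obs:
            count += 1
    perm_p = (1 + count) / (n_perm + 1)
    return MajorAxisFit(float(slope), intercept, float(perm_p), int(n_perm), int(x.size))


# ---------------------------------------------------------------------------
# umbrella rhythm test
# ---------------------------------------------------------------------------


def _mw_counts(a, b):
    """Mann-Whitney count #{(x in a, y in b): x < y}, ties counted 1/2."""
    a = a[:, None]
    b = b[None, :]
    return float(np.sum(a < b) + 0.5 * np.sum(a == b))


def _umbrella_stat(class_data, peak):
    """Mack-Wolfe umbrella statistic with peak at rotated position ``peak``.

    ``class_data`` is the list of per-class samples in the rotated order
    (monotone rise to ``peak``, monotone fall after).  The statistic is the
    sum of Mann-Whitney counts consistent with the umbrella ordering.
    """
    m = len(class_data)
    stat = 0.0
    for i in range(peak + 1):
        for j in range(i + 1, peak + 1):
            stat += _mw_counts(class_data[i], class_data[j])
    for i in range(peak, m):
        for j in range(i + 1, m):
            stat += _mw_counts(class_data[j], class_data[i])
    return stat


def _umbrella_null(sizes, peak, tie_factor):
    """Null mean and variance of the Mack-Wolfe statistic (A_p)."""
    sizes = np.asarray(sizes, dtype=float)
    n1 = sizes[: peak + 1].sum()
    n2 = sizes[peak:].sum()
    n_p = sizes[peak]
    n_tot = sizes.sum()
    mean = (n1**2 + n2**2 - np.sum(sizes**2) - n_p**2) / 4.0
    var = (
        2 * (n1**3 + n2**3)
        + 3 * (n1**2 + n2**2)
        - np.sum(sizes**2 * (2 * sizes + 3))
        - n_p**2 * (2 * n_p + 3)
        + 12 * n_p * n1 * n2
        - 12 * n_p**2 * n_tot
    ) / 72.0
    return mean, var * tie_factor


def rank_rhythm_test(t, y, period_hours=24.0, sampling_interval_hours=4.0) -> RhythmResult:
    """Nonparametric rhythm detection by pooled-phase umbrella rank statistics.

    Observations are pooled into m = period/interval phase classes
    ("independent" mode).  For each candidate peak class an umbrella
    (rise-to-peak / fall-after) statistic -- the sum of Mann-Whitney pair
    counts consistent with that ordering, with the trough fixed half a
    period from the peak -- is compared to its normal null.  The overall
    p-value Bonferroni-corrects the best ordering over the m candidates,
    which is conservative.  The test depends on the data only through
    ranks, so it is invariant to strictly increasing transforms of y.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    m_float = period_hours / sampling_interval_hours
    m = int(round(m_float))
    if abs(m_float - m) > 1e-9 or m < 3:
        raise ValueError("period/interval must be an integer >= 3")
    if np.ptp(t) < 2 * period_hours - sampling_interval_hours:
        raise ValueError("need at least two full cycles of data")

    phase = np.mod(np.round(t / sampling_interval_hours).astype(int), m)
    classes = [y[phase == k] for k in range(m)]
    if any(c.size == 0 for c in classes):
        raise ValueError("every phase class needs at least one observation")
    sizes = [c.size for c in classes]

    pooled = np.concatenate(classes)
    n_tot = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_tot**3 - n_tot)
    if tie_factor <= 0:  # all observations identical
        return RhythmResult(1.0, period_hours, 0, m, 0.0)

    half = m // 2
    best_p, best_peak, best_stat = np.inf, 0, 0.0
    for k in range(m):
        # rotate so the trough (half a period before/after the peak) is
        # first: rise over positions 0..peak_pos, fall after
        start = (k + half) % m if m % 2 == 0 else (k + half + 1) % m
        order = [(start + j) % m for j in range(m)]
        peak_pos = order.index(k)
        rotated = [classes[c] for c in order]
        stat = _umbrella_stat(rotated, peak_pos)
        mean, var = _umbrella_null([sizes[c] for c in order], peak_pos, tie_factor)
        z = (stat - mean) / np.sqrt(var) if var > 0 else 0.0
        p = float(sps.norm.sf(z))
        if p < best_p:
            best_p, best_peak, best_stat = p, k, stat
    return RhythmResult(
        p_value=float(min(best_p * m, 1.0)),
        period_hours=float(period_hours),
        best_peak_phase=int(best_peak),
        n_phase_classes=m,
        statistic=float(best_stat),
    )
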