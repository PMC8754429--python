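"""Rate-compensation statistics.

The central statistic is the per-reaction *rate ratio* k_cold/k_warm: the
aggregated rate constant of the enzyme variant from the organism with the
lowest optimal growth temperature divided by that of the variant from the
warmest organism.  Under the rate-compensation model of cold adaptation the
ratio distribution should sit above 1; under the null it should be
indistinguishable from the *control distribution* built from reactions whose
variants share a single T_Growth (fold change k_max/k_min and its
reciprocal), which captures rate variation arising independently of
temperature.

The module also provides per-reaction slope regressions of log10(rate) on
T_Growth with a Bonferroni screen, bootstrap percentile confidence intervals
for distribution medians, and the two-sided Mann-Whitney U comparison of the
data and control distributions.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .curation import Reaction, ReactionKey

__all__ = [
    "RateRatioResult",
    "ControlFoldChange",
    "MedianSummary",
    "UTestResult",
    "SlopeFit",
    "ComparisonReport",
    "rate_ratio",
    "control_fold_changes",
    "mann_whitney_u",
    "bootstrap_median_ci",
    "fit_reaction_slope",
    "bonferroni_threshold",
    "compare_to_control",
]

#: Largest n1*n2 for which the tie-free Mann-Whitney p-value is computed by
#: exact enumeration; above it (or with ties) the normal approximation with
#: tie and continuity correction is used.  The two regimes agree to ~2
#: decimal places of p near the boundary.
EXACT_MWU_MAX_PRODUCT = 400


@dataclass(frozen=True)
class RateRatioResult:
    """k_cold/k_warm for one reaction.

    ``k_cold`` is the median rate over all variants at the minimum T_Growth
    (the median rule resolves shared extremes); ``k_warm`` likewise at the
    maximum.  Reactions with zero T_Growth spread yield no result.
    """

    reaction_key: ReactionKey
    k_cold: float
    k_warm: float
    ratio: float
    t_cold_C: float
    t_warm_C: float

    def __post_init__(self) -> None:
        if not (self.k_cold > 0 and self.k_warm > 0):
            raise ValueError("rate constants must be positive")
        if self.t_cold_C >= self.t_warm_C:
            raise ValueError("t_cold_C must be below t_warm_C")


@dataclass(frozen=True)
class ControlFoldChange:
    """Fold change between variants sharing one T_Growth: k_max/k_min and
    its reciprocal.  Downstream the control sample is the flattened multiset
    {fold_up, fold_down}, which is closed under reciprocals and therefore
    has median exactly 1 whenever every reaction contributes both."""

    reaction_key: ReactionKey
    t_growth_C: float
    fold_up: float
    fold_down: float

    def __post_init__(self) -> None:
        if self.fold_up < 1:
            raise ValueError("fold_up must be >= 1")


@dataclass(frozen=True)
class MedianSummary:
    median: float
    ci_low: float
    ci_high: float
    n: int
    bootstrap_reps: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("bootstrap CI does not bracket the median")


@dataclass(frozen=True)
class UTestResult:
    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str = "asymptotic"

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of log10(rate) on T_Growth for one reaction (m_rate)."""

    reaction_key: ReactionKey
    m_rate: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ComparisonReport:
    """Data-vs-control comparison: medians with bootstrap CIs, the
    Mann-Whitney U test, and the three-way partition of ratios vs 1."""

    data_summary: MedianSummary
    control_summary: MedianSummary
    utest: UTestResult
    n_above_one: int
    n_below_one: int
    n_equal_one: int


def rate_ratio(reaction: Reaction) -> Optional[RateRatioResult]:
    """Compute k_cold/k_warm for one reaction, or None without T spread.

    When several variants share the extreme T_Growth, their median rate is
    used (the shared-extreme median rule).
    """
    temps = [m.t_growth_C for m in reaction.measurements]
    t_cold, t_warm = min(temps), max(temps)
    if t_cold == t_warm:
        return None
    k_cold = statistics.median(
        m.k for m in reaction.measurements if m.t_growth_C == t_cold
    )
    k_warm = statistics.median(
        m.k for m in reaction.measurements if m.t_growth_C == t_warm
    )
    return RateRatioResult(
        reaction_key=reaction.reaction_key,
        k_cold=float(k_cold),
        k_warm=float(k_warm),
        ratio=float(k_cold) / float(k_warm),
        t_cold_C=t_cold,
        t_warm_C=t_warm,
    )


def control_fold_changes(reactions: Sequence[Reaction]) -> list[ControlFoldChange]:
    """One fold-change pair per reaction with >= 2 variants at one T_Growth.

    When a reaction has several same-temperature groups, the group with the
    most variants is used, ties broken toward the lowest temperature (the
    choice is logged by the caller via the returned record's t_growth_C).
    """
    out: list[ControlFoldChange] = []
    for reaction in reactions:
        groups: dict[float, list[float]] = {}
        for m in reaction.measurements:
            groups.setdefault(m.t_growth_C, []).append(m.k)
        eligible = {t: ks for t, ks in groups.items() if len(ks) >= 2}
        if not eligible:
            continue
        t_sel = min(eligible, key=lambda t: (-len(eligible[t]), t))
        ks = eligible[t_sel]
        fold_up = max(ks) / min(ks)
        out.append(
            ControlFoldChange(
                reaction_key=reaction.reaction_key,
                t_growth_C=t_sel,
                fold_up=fold_up,
                fold_down=1.0 / fold_up,
            )
        )
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``x`` with midrank handling of ties.  The
    p-value is exact (full enumeration of rank arrangements) when
    n1*n2 <= EXACT_MWU_MAX_PRODUCT and the pooled sample is tie-free, and
    otherwise uses the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # Fully tied pooled sample: the rank distribution is degenerate and
        # the normal approximation's variance is zero; by symmetry U sits at
        # its center and there is no evidence against the null.
        return UTestResult(
            u_statistic=x.size * y.size / 2.0,
            p_two_sided=1.0,
            n1=int(x.size),
            n2=int(y.size),
            method="degenerate",
        )
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size * y.size <= EXACT_MWU_MAX_PRODUCT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return UTestResult(
        u_statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
    )


def bootstrap_median_ci(
    values: Sequence[float],
    reps: int = 10_000,
    seed: int = 0,
    log_scale: bool = False,
    _chunk: int = 2_000,
) -> MedianSummary:
    """95% percentile bootstrap CI of the median.

    ``reps`` resamples of size n with replacement; the interval is the
    [2.5, 97.5] percentile of the resample medians.  Deterministic given
    ``seed``.

    With ``log_scale=True`` the median is taken on log(values) and
    back-transformed: for odd n this is the ordinary sample median, for even
    n the *geometric* midpoint of the central pair.  This is the
    scale-appropriate convention for fold-change distributions — it is
    equivariant under taking reciprocals, so a reciprocal-closed sample has
    median exactly 1.  Percentile CIs commute with the monotone transform,
    so coverage is unaffected.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("bootstrap_median_ci requires n >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if log_scale:
        if np.any(values <= 0):
            raise ValueError("log_scale requires strictly positive values")
        values = np.log(values)
    rng = np.random.default_rng(seed)
    medians = np.empty(reps)
    done = 0
    while done < reps:  # chunked to bound memory at large n * reps
        take = min(_chunk, reps - done)
        idx = rng.integers(0, n, size=(take, n))
        medians[done : done + take] = np.median(values[idx], axis=1)
        done += take
    ci_low, ci_high = np.quantile(medians, [0.025, 0.975])
    median, ci_low, ci_high = float(np.median(values)), float(ci_low), float(ci_high)
    if log_scale:
        median, ci_low, ci_high = math.exp(median), math.exp(ci_low), math.exp(ci_high)
    return MedianSummary(
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        n=int(n),
        bootstrap_reps=int(reps),
        seed=int(seed),
    )


def fit_reaction_slope(reaction: Reaction) -> Optional[SlopeFit]:
    """OLS of log10(k) on T_Growth over a reaction's variant measurements.

    Returns None for reactions with fewer than three variants or zero
    temperature variance (the slope is undefined there, not zero).  The
    p-value is the two-sided t-test of zero slope with n-2 degrees of
    freedom.
    """
    if len(reaction.measurements) < 3:
        return None
    t = np.array([m.t_growth_C for m in reaction.measurements])
    if np.ptp(t) == 0:
        return None
    y = np.log10([m.k for m in reaction.measurements])
    if np.ptp(y) == 0:
        # Constant response: the zero-slope line fits with zero residual.
        # R^2 = 1 - SSR/SST is 0/0; residuals vanish, so report a perfect
        # flat fit with no evidence against zero slope.
        return SlopeFit(
            reaction_key=reaction.reaction_key,
            m_rate=0.0,
            intercept=float(y[0]),
            r_squared=1.0,
            p_value=1.0,
            n=len(reaction.measurements),
        )
    fit = sps.linregress(t, y)
    return SlopeFit(
        reaction_key=reaction.reaction_key,
        m_rate=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(reaction.measurements),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def compare_to_control(
    ratios: Sequence[RateRatioResult],
    controls: Sequence[ControlFoldChange],
    reps: int = 10_000,
    seed: int = 0,
) -> ComparisonReport:
    """Compare the rate-ratio distribution against the same-T_Growth control.

    The data sample is one ratio per reaction; the control sample is the
    flattened multiset of (fold_up, fold_down) pairs.  Medians carry 95%
    percentile bootstrap CIs; the distributions are compared with the
    two-sided Mann-Whitney U test.  All randomness derives from ``seed``.
    """
    if not ratios or not controls:
        raise ValueError("both the ratio and control collections must be non-empty")
    data = np.array([r.ratio for r in ratios])
    control = np.array([f for c in controls for f in (c.fold_up, c.fold_down)])
    seed_data, seed_control = np.random.SeedSequence(seed).generate_state(2) >> 1
    return ComparisonReport(
        data_summary=bootstrap_median_ci(
            data, reps=reps, seed=int(seed_data), log_scale=True
        ),
        control_summary=bootstrap_median_ci(
            control, reps=reps, seed=int(seed_control), log_scale=True
        ),
        utest=mann_whitney_u(data, control),
        n_above_one=int(np.sum(data > 1)),
        n_below_one=int(np.sum(data < 1)),
        n_equal_one=int(np.sum(data == 1)),
    )
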