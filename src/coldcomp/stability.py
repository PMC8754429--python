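"""Protein-stability compensation analysis.

Mirrors the kinetic analysis on melting temperatures: wild-type T_m values
are matched to organismal T_Growth, T_m is regressed on T_Growth across all
proteins, and for protein families with variants from more than one organism
the fold change T_m(cold)/T_m(warm) quantifies stability compensation
(fold change < 1 means the warm-adapted variant is more stable).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .curation import TemperatureTable, _temperature_lookup
from .io import StabilityRecord
from .organisms import normalize_organism_name

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityFit",
    "FamilyFoldChange",
    "match_stability_t_growth",
    "fit_tm_vs_tgrowth",
    "family_fold_changes",
]


@dataclass(frozen=True)
class StabilityFit:
    """OLS fit of T_m (degC) on T_Growth (degC), untransformed."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class FamilyFoldChange:
    """T_m(cold)/T_m(warm) for one protein family.

    Computed on Celsius values as plotted in the underlying datasets; both
    temperatures must be positive for the ratio to be defined.
    """

    family: str
    t_m_cold_C: float
    t_m_warm_C: float
    fold_change: float

    def __post_init__(self) -> None:
        if not (self.t_m_cold_C > 0 and self.t_m_warm_C > 0):
            raise ValueError("fold change requires both T_m values > 0 degC")


def match_stability_t_growth(
    records: Sequence[StabilityRecord],
    table: TemperatureTable,
    strip_strain: bool = False,
    deduplicate: bool = True,
) -> tuple[list[StabilityRecord], int]:
    """Fill ``t_growth_C`` on stability records by normalized organism name.

    Unmatched records are dropped and counted.  With ``deduplicate=True``
    (default) repeated T_m measurements of one (protein, organism) collapse
    to their median, consistent with the kinetic-side aggregation rule; set
    it False to keep every measurement.
    """
    if not table:
        raise ValueError("growth-temperature table is empty")
    lookup = _temperature_lookup(table, strip_strain)
    matched: list[StabilityRecord] = []
    unmatched = 0
    for rec in records:
        key = normalize_organism_name(rec.organism, strip_strain=strip_strain)
        if key in lookup:
            matched.append(replace(rec, organism=key, t_growth_C=lookup[key]))
        else:
            unmatched += 1
    if not deduplicate:
        return matched, unmatched

    groups: dict[tuple[str, str], list[StabilityRecord]] = {}
    for rec in matched:
        groups.setdefault((rec.protein_name.strip().casefold(), rec.organism), []).append(rec)
    deduped: list[StabilityRecord] = []
    for key in sorted(groups):
        recs = groups[key]
        if len(recs) > 1:
            logger.info("collapsing %d T_m entries for %r to their median", len(recs), key)
        deduped.append(
            replace(recs[0], t_m_C=float(statistics.median(r.t_m_C for r in recs)))
        )
    return deduped, unmatched


def fit_tm_vs_tgrowth(records: Sequence[StabilityRecord]) -> StabilityFit:
    """OLS of T_m on T_Growth across matched wild-type records."""
    pts = [(r.t_growth_C, r.t_m_C) for r in records if r.t_growth_C is not None]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 matched records to fit, got {len(pts)}")
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(t) == 0:
        raise ValueError("zero T_Growth variance; slope undefined")
    fit = sps.linregress(t, y)
    return StabilityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(pts),
    )


def family_fold_changes(
    records: Sequence[StabilityRecord],
) -> tuple[list[FamilyFoldChange], int]:
    """Per-family T_m(cold)/T_m(warm) ratios.

    A family is a group of matched records sharing a protein label (after
    trim and case-fold) with variants at >= 2 distinct T_Growth values.  The
    cold and warm T_m are the medians over the variants at the minimum and
    maximum T_Growth respectively (the same shared-extreme rule as the
    kinetic rate ratio).  Also returns the number of families with
    fold change < 1, i.e. where the warm-adapted variant is more stable.
    """
    groups: dict[str, list[StabilityRecord]] = {}
    for rec in records:
        if rec.t_growth_C is None:
            continue
        groups.setdefault(rec.protein_name.strip().casefold(), []).append(rec)

    folds: list[FamilyFoldChange] = []
    for family in sorted(groups):
        recs = groups[family]
        temps = [r.t_growth_C for r in recs]
        t_cold, t_warm = min(temps), max(temps)
        if t_cold == t_warm or len(recs) < 2:
            continue
        t_m_cold = statistics.median(r.t_m_C for r in recs if r.t_growth_C == t_cold)
        t_m_warm = statistics.median(r.t_m_C for r in recs if r.t_growth_C == t_warm)
        if t_m_cold <= 0 or t_m_warm <= 0:
            logger.warning("family %r has non-positive T_m; no fold change", family)
            continue
        folds.append(
            FamilyFoldChange(
                family=family,
                t_m_cold_C=float(t_m_cold),
                t_m_warm_C=float(t_m_warm),
                fold_change=float(t_m_cold) / float(t_m_warm),
            )
        )
    n_warm_more_stable = sum(1 for f in folds if f.fold_change < 1)
    return folds, n_warm_more_stable
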