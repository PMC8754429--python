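"""Curation of raw kinetic entries into per-reaction variant measurements.

A *reaction* is an (EC number, substrate) pair.  Curation mirrors the
standard meta-analysis funnel for database-derived kinetic constants:

1. keep wild-type entries only;
2. match each entry's organism to its optimal growth temperature
   (``T_Growth``) by normalized species name;
3. aggregate repeated measurements of the same enzyme variant (same
   reaction, same organism) by their median;
4. keep reactions represented by at least two distinct organisms.

Every input row is accounted for exactly once across the funnel stages, and
the resulting :class:`CurationReport` records the monotone counts.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .io import GrowthTemperatureRecord, KineticEntry, ValueType, VariantStatus
from .organisms import normalize_organism_name

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedEntry",
    "VariantMeasurement",
    "Reaction",
    "CurationReport",
    "normalize_organism_name",
    "filter_wild_type",
    "match_t_growth",
    "build_reactions",
    "subset_reactions",
    "curate",
]

ReactionKey = tuple[str, str]


@dataclass(frozen=True)
class MatchedEntry:
    """A kinetic entry annotated with its organism's growth temperature."""

    entry: KineticEntry
    organism: str  # normalized
    t_growth_C: float


@dataclass(frozen=True)
class VariantMeasurement:
    """The median rate constant of one enzyme variant (one organism) on one
    reaction, with provenance to its source entries."""

    reaction_key: ReactionKey
    organism: str
    t_growth_C: float
    k: float
    n_source_entries: int
    source_entries: tuple[MatchedEntry, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("aggregated rate constant must be positive")
        if self.n_source_entries < 1:
            raise ValueError("n_source_entries must be >= 1")


@dataclass(frozen=True)
class Reaction:
    """An EC-number-substrate pair with measurements from >= 2 organisms."""

    reaction_key: ReactionKey
    value_type: ValueType
    measurements: tuple[VariantMeasurement, ...]

    def __post_init__(self) -> None:
        organisms = {m.organism for m in self.measurements}
        if len(organisms) < 2:
            raise ValueError("a reaction requires measurements from >= 2 organisms")
        if any(m.reaction_key != self.reaction_key for m in self.measurements):
            raise ValueError("measurement reaction_key mismatch")

    @property
    def t_growth_span_C(self) -> float:
        temps = [m.t_growth_C for m in self.measurements]
        return max(temps) - min(temps)


@dataclass
class CurationReport:
    """Counts through the curation funnel.

    Invariant: ``n_input >= n_wild_type >= n_t_growth_matched >=
    n_values_in_reactions``.
    """

    n_input: int = 0
    n_wild_type: int = 0
    n_t_growth_matched: int = 0
    n_values_in_reactions: int = 0
    n_reactions: int = 0
    n_organisms: int = 0
    t_growth_min_C: Optional[float] = None
    t_growth_max_C: Optional[float] = None


def filter_wild_type(entries: Iterable[KineticEntry]) -> list[KineticEntry]:
    """Keep wild-type entries, preserving order.  Idempotent."""
    return [e for e in entries if e.variant_status is VariantStatus.WILD_TYPE]


TemperatureTable = Mapping[str, Union[GrowthTemperatureRecord, float]]


def _temperature_lookup(table: TemperatureTable, strip_strain: bool) -> dict[str, float]:
    lookup: dict[str, float] = {}
    for name, rec in table.items():
        temp = rec.t_growth_C if isinstance(rec, GrowthTemperatureRecord) else float(rec)
        key = normalize_organism_name(str(name), strip_strain=strip_strain)
        if key in lookup and lookup[key] != temp:
            # Distinct raw names collapsing onto one key: keep the median-like
            # midpoint of the colliding values and flag it.
            logger.warning("temperature table collision on %r; averaging", key)
            temp = (lookup[key] + temp) / 2.0
        lookup[key] = temp
    return lookup


def match_t_growth(
    entries: Iterable[KineticEntry],
    table: TemperatureTable,
    strip_strain: bool = False,
) -> tuple[list[MatchedEntry], int]:
    """Attach T_Growth to each entry by normalized organism name.

    Returns the matched entries and the count of entries whose organism is
    absent from the table (those are excluded, never guessed).
    """
    if not table:
        raise ValueError("growth-temperature table is empty")
    lookup = _temperature_lookup(table, strip_strain)
    matched: list[MatchedEntry] = []
    unmatched = 0
    for entry in entries:
        key = normalize_organism_name(entry.organism, strip_strain=strip_strain)
        if key in lookup:
            matched.append(MatchedEntry(entry=entry, organism=key, t_growth_C=lookup[key]))
        else:
            unmatched += 1
    return matched, unmatched


def _reaction_key(entry: KineticEntry) -> ReactionKey:
    return (entry.ec_number.strip(), entry.substrate.strip().casefold())


def build_reactions(
    matched: Sequence[MatchedEntry],
    value_type: ValueType = ValueType.KCAT,
    n_input: Optional[int] = None,
    n_wild_type: Optional[int] = None,
) -> tuple[list[Reaction], CurationReport]:
    """Aggregate matched entries into reactions.

    Per (reaction, organism) the rate constant is the median of the source
    values (midpoint convention for even counts); only reactions with at
    least two distinct organisms are retained.  ``n_input`` / ``n_wild_type``
    let a caller that ran the earlier funnel stages complete the report.
    """
    value_type = ValueType(value_type)
    groups: dict[ReactionKey, dict[str, list[MatchedEntry]]] = {}
    for me in matched:
        if me.entry.value_type is not value_type:
            raise ValueError(
                f"entry {me.entry.entry_id} has value_type {me.entry.value_type}, "
                f"expected {value_type}"
            )
        key = _reaction_key(me.entry)
        groups.setdefault(key, {}).setdefault(me.organism, []).append(me)

    reactions: list[Reaction] = []
    n_values = 0
    organisms: set[str] = set()
    temps: list[float] = []
    # Sort for output determinism regardless of input order.
    for key in sorted(groups):
        by_org = groups[key]
        if len(by_org) < 2:
            continue
        measurements = []
        for org in sorted(by_org):
            sources = by_org[org]
            k = statistics.median(m.entry.value for m in sources)
            measurements.append(
                VariantMeasurement(
                    reaction_key=key,
                    organism=org,
                    t_growth_C=sources[0].t_growth_C,
                    k=float(k),
                    n_source_entries=len(sources),
                    source_entries=tuple(sources),
                )
            )
            n_values += len(sources)
            organisms.add(org)
            temps.append(sources[0].t_growth_C)
        reactions.append(
            Reaction(reaction_key=key, value_type=value_type, measurements=tuple(measurements))
        )

    report = CurationReport(
        n_input=n_input if n_input is not None else len(matched),
        n_wild_type=n_wild_type if n_wild_type is not None else len(matched),
        n_t_growth_matched=len(matched),
        n_values_in_reactions=n_values,
        n_reactions=len(reactions),
        n_organisms=len(organisms),
        t_growth_min_C=min(temps) if temps else None,
        t_growth_max_C=max(temps) if temps else None,
    )
    return reactions, report


def subset_reactions(
    reactions: Sequence[Reaction],
    assay_temperature_C: Optional[float] = None,
    min_t_growth_span_C: Optional[float] = None,
    assay_tolerance_C: float = 0.5,
) -> list[Reaction]:
    """Restrict reactions to one assay temperature and/or a minimum
    T_Growth span.

    The assay filter re-runs aggregation on only the source entries measured
    at ``assay_temperature_C`` (within ``assay_tolerance_C``); reactions that
    fall below two organisms afterwards are dropped.  The span filter keeps
    reactions whose max-min T_Growth strictly exceeds the threshold.
    """
    result = list(reactions)
    if assay_temperature_C is not None:
        sources = [
            me
            for r in result
            for m in r.measurements
            for me in m.source_entries
            if me.entry.assay_temperature_C is not None
            and abs(me.entry.assay_temperature_C - assay_temperature_C) <= assay_tolerance_C
        ]
        value_type = result[0].value_type if result else ValueType.KCAT
        result, _ = build_reactions(sources, value_type=value_type)
    if min_t_growth_span_C is not None:
        result = [r for r in result if r.t_growth_span_C > min_t_growth_span_C]
    return result


def reactions_to_frame(reactions: Sequence[Reaction]):
    """Flatten reactions to one row per variant measurement (for TSV export)."""
    import pandas as pd

    rows = []
    for r in reactions:
        for m in r.measurements:
            rows.append(
                {
                    "ec_number": r.reaction_key[0],
                    "substrate": r.reaction_key[1],
                    "value_type": r.value_type.value,
                    "organism": m.organism,
                    "t_growth_C": m.t_growth_C,
                    "k": m.k,
                    "n_source_entries": m.n_source_entries,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "ec_number", "substrate", "value_type", "organism",
            "t_growth_C", "k", "n_source_entries",
        ],
    )


def reactions_from_frame(frame) -> list[Reaction]:
    """Rebuild reactions from a frame written by :func:`reactions_to_frame`.

    Source-entry provenance is not stored in the flat table, so the rebuilt
    measurements carry empty ``source_entries`` (assay-temperature subsetting
    needs the original entries).
    """
    reactions: list[Reaction] = []
    for (ec, substrate, vt), group in frame.groupby(
        ["ec_number", "substrate", "value_type"], sort=True
    ):
        measurements = tuple(
            VariantMeasurement(
                reaction_key=(str(ec), str(substrate)),
                organism=str(row.organism),
                t_growth_C=float(row.t_growth_C),
                k=float(row.k),
                n_source_entries=int(row.n_source_entries),
            )
            for row in group.itertuples(index=False)
        )
        reactions.append(
            Reaction(
                reaction_key=(str(ec), str(substrate)),
                value_type=ValueType(vt),
                measurements=measurements,
            )
        )
    return reactions


def curate(
    entries: Sequence[KineticEntry],
    table: TemperatureTable,
    value_type: ValueType = ValueType.KCAT,
    strip_strain: bool = False,
) -> tuple[list[Reaction], CurationReport]:
    """Run the full curation funnel: wild-type filter, T_Growth match,
    median aggregation, multi-organism selection."""
    wild_type = filter_wild_type(e for e in entries if e.value_type is ValueType(value_type))
    matched, _unmatched = match_t_growth(wild_type, table, strip_strain=strip_strain)
    return build_reactions(
        matched,
        value_type=value_type,
        n_input=len(entries),
        n_wild_type=len(wild_type),
    )
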