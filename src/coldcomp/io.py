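"""Flat-table input/output for kinetic, growth-temperature and stability data.

Every table the pipeline touches is a delimited text file (TSV/CSV) with a
header row, or a JSON array of flat objects.  Readers validate each row into
a typed record, reject rows that violate the record's invariants (logging a
reason, never aborting the read), and return a :class:`ReadReport` so the
curation funnel is fully accounted for.

Column headers differ between data sources; a small :class:`Dialect` maps
the record fields onto the columns of a particular export so the reading
code is independent of any one source's header conventions.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import re
import typing
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValueType",
    "VariantStatus",
    "KineticEntry",
    "GrowthTemperatureRecord",
    "StabilityRecord",
    "Dialect",
    "ReadReport",
    "SYNTHETIC_KINETIC",
    "BRENDA_KINETIC",
    "SYNTHETIC_STABILITY",
    "PROTHERMDB_STABILITY",
    "read_kinetic_entries",
    "read_growth_temperatures",
    "read_stability_records",
    "read_table",
    "write_table",
]

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_RANGE_RE = re.compile(r"^\s*\d+(\.\d+)?([eE][+-]?\d+)?\s*-\s*\d")


class ValueType(str, enum.Enum):
    """Which kinetic constant a row reports."""

    KCAT = "kcat"                  # turnover number, s^-1
    KCAT_OVER_KM = "kcat_over_km"  # catalytic efficiency, M^-1 s^-1


class VariantStatus(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MUTANT = "mutant"


@dataclass(frozen=True)
class KineticEntry:
    """One measured kinetic constant for one enzyme variant on one substrate.

    ``value`` is in s^-1 for k_cat and M^-1 s^-1 for k_cat/K_M; unit
    conversion happens at read time.  ``assay_temperature_C`` is optional —
    many database entries do not report it.
    """

    entry_id: str
    ec_number: str
    substrate: str
    organism: str
    value: float
    value_type: ValueType
    variant_status: VariantStatus
    assay_temperature_C: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError(f"value must be positive and finite, got {self.value}")
        if not _EC_RE.match(self.ec_number):
            raise ValueError(f"malformed EC number: {self.ec_number!r}")
        object.__setattr__(self, "value_type", ValueType(self.value_type))
        object.__setattr__(self, "variant_status", VariantStatus(self.variant_status))


@dataclass(frozen=True)
class GrowthTemperatureRecord:
    """An organism's optimal growth temperature (median over culture data)."""

    organism: str
    t_growth_C: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_growth_C):
            raise ValueError("t_growth_C must be finite")
        if not (-5.0 <= self.t_growth_C <= 120.0):
            logger.warning(
                "t_growth_C=%s for %r outside plausible range [-5, 120] C",
                self.t_growth_C,
                self.organism,
            )


@dataclass(frozen=True)
class StabilityRecord:
    """A wild-type protein melting temperature with optional assay metadata.

    ``t_growth_C`` is filled later by matching the organism against a
    growth-temperature table; it is None straight off disk.
    """

    protein_name: str
    organism: str
    t_m_C: float
    t_growth_C: Optional[float] = None
    ph: Optional[float] = None
    method: Optional[str] = None
    state: Optional[str] = None
    reversibility: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t_m_C):
            raise ValueError("t_m_C must be finite")


@dataclass(frozen=True)
class Dialect:
    """Maps record field names onto the column headers of one export format.

    ``columns`` is keyed by record field name.  Optional fields may be left
    unmapped.  ``wild_type_tokens`` lists the (case-folded) values of the
    variant/mutation column that denote a wild-type measurement; anything
    else is treated as a mutant.
    """

    columns: Mapping[str, str]
    wild_type_tokens: Sequence[str] = ("wild_type", "wild-type", "wild type", "wt")

    def col(self, field_name: str) -> Optional[str]:
        return self.columns.get(field_name)


#: Column layout emitted by :mod:`coldcomp.simulate` and by ``write_table``.
SYNTHETIC_KINETIC = Dialect(
    columns={
        "entry_id": "entry_id",
        "ec_number": "ec_number",
        "substrate": "substrate",
        "organism": "organism",
        "value": "value",
        "unit": "unit",
        "value_type": "value_type",
        "variant_status": "variant_status",
        "assay_temperature_C": "assay_temperature_C",
    }
)

#: Plausible headers of a flat BRENDA-style kinetic-constant export.
BRENDA_KINETIC = Dialect(
    columns={
        "entry_id": "ENTRY_ID",
        "ec_number": "EC_NUMBER",
        "substrate": "SUBSTRATE",
        "organism": "ORGANISM",
        "value": "VALUE",
        "unit": "UNIT",
        "variant_status": "VARIANT",
        "assay_temperature_C": "ASSAY_TEMPERATURE",
    }
)

SYNTHETIC_STABILITY = Dialect(
    columns={
        "protein_name": "protein_name",
        "organism": "organism",
        "mutation": "mutation",
        "t_m_C": "t_m_C",
        "ph": "ph",
        "method": "method",
        "state": "state",
        "reversibility": "reversibility",
    }
)

#: Headers of a ProThermDB-style stability export.
PROTHERMDB_STABILITY = Dialect(
    columns={
        "protein_name": "PROTEIN",
        "organism": "SOURCE",
        "mutation": "MUTATION",
        "t_m_C": "Tm_(C)",
        "ph": "pH",
        "method": "METHOD",
        "state": "STATE",
        "reversibility": "REVERSIBILITY",
    }
)

# Unit conversion factors onto the canonical units (s^-1 and M^-1 s^-1).
_KCAT_UNIT_FACTORS = {
    "1/s": 1.0,
    "s^-1": 1.0,
    "s-1": 1.0,
    "1/min": 1.0 / 60.0,
    "min^-1": 1.0 / 60.0,
    "1/h": 1.0 / 3600.0,
    "h^-1": 1.0 / 3600.0,
}
_EFFICIENCY_UNIT_FACTORS = {
    "1/m/s": 1.0,
    "m^-1s^-1": 1.0,
    "m^-1*s^-1": 1.0,
    "l/mol/s": 1.0,
    "1/mm/s": 1.0e3,
    "mm^-1s^-1": 1.0e3,
    "1/um/s": 1.0e6,
    "um^-1s^-1": 1.0e6,
    "1/µm/s": 1.0e6,
}


@dataclass
class ReadReport:
    """Row accounting for one reader invocation.

    Invariant: ``n_accepted + n_rejected == n_rows`` (conservation).
    """

    n_rows: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.n_rejected += 1
        self.reasons[reason] += 1


PathOrFrame = Union[str, Path, pd.DataFrame]


def _load_frame(source: PathOrFrame) -> pd.DataFrame:
    """Load a table from TSV/CSV/JSON by extension, or pass a frame through."""
    if isinstance(source, pd.DataFrame):
        return source
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".json":
        return pd.read_json(path, orient="records", dtype=False)
    sep = "," if suffix == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(frame: pd.DataFrame, needed: Iterable[str], context: str) -> None:
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise KeyError(f"{context}: required column(s) missing: {missing}")


def _parse_float(raw: object) -> float:
    """Parse one numeric cell; raises ValueError with a reason string."""
    text = str(raw).strip()
    if text == "" or text.lower() in {"na", "nan", "none", "-", "null"}:
        raise ValueError("non-numeric value")
    if _RANGE_RE.match(text):
        # BRENDA sometimes reports value ranges like "1.2-3.4"; how those were
        # collapsed upstream is unknowable, so they are rejected, not guessed.
        raise ValueError("value range")
    try:
        return float(text)
    except ValueError:
        raise ValueError("non-numeric value") from None


def _parse_optional_float(raw: object) -> Optional[float]:
    try:
        return _parse_float(raw)
    except ValueError:
        return None


def _variant_status(raw: object, dialect: Dialect) -> VariantStatus:
    text = str(raw).strip().casefold()
    if text in {t.casefold() for t in dialect.wild_type_tokens}:
        return VariantStatus.WILD_TYPE
    return VariantStatus.MUTANT


def read_kinetic_entries(
    source: PathOrFrame,
    dialect: Dialect = SYNTHETIC_KINETIC,
    value_type: ValueType = ValueType.KCAT,
) -> tuple[list[KineticEntry], ReadReport]:
    """Read kinetic-constant rows into validated :class:`KineticEntry` records.

    Rows with non-positive, non-numeric or range-valued measurements, with
    malformed EC numbers, or with unconvertible units are rejected and
    counted in the returned :class:`ReadReport`; a missing *required column*
    is a configuration error and raises.

    If the dialect maps a ``value_type`` column it overrides the
    ``value_type`` argument row by row; if it maps a ``unit`` column the
    value is converted onto s^-1 (k_cat) or M^-1 s^-1 (k_cat/K_M), and rows
    whose unit has no known conversion are rejected.
    """
    frame = _load_frame(source)
    required = ["ec_number", "substrate", "organism", "value", "variant_status"]
    _require_columns(
        frame, [dialect.columns[f] for f in required], "kinetic table"
    )
    report = ReadReport(n_rows=len(frame))
    entries: list[KineticEntry] = []
    value_type = ValueType(value_type)

    unit_col = dialect.col("unit")
    vt_col = dialect.col("value_type")
    id_col = dialect.col("entry_id")
    at_col = dialect.col("assay_temperature_C")

    for idx, row in enumerate(frame.itertuples(index=False)):
        row_map = dict(zip(frame.columns, row))
        try:
            value = _parse_float(row_map[dialect.columns["value"]])
        except ValueError as exc:
            report.reject(str(exc))
            continue
        if value <= 0:
            report.reject("non-positive value")
            continue
        row_vt = value_type
        if vt_col and vt_col in row_map and str(row_map[vt_col]).strip():
            try:
                row_vt = ValueType(str(row_map[vt_col]).strip())
            except ValueError:
                report.reject("unknown value type")
                continue
        if unit_col and unit_col in row_map and str(row_map[unit_col]).strip():
            unit = str(row_map[unit_col]).strip().casefold()
            factors = (
                _KCAT_UNIT_FACTORS
                if row_vt is ValueType.KCAT
                else _EFFICIENCY_UNIT_FACTORS
            )
            if unit not in factors:
                report.reject("unconvertible unit")
                continue
            value *= factors[unit]
        try:
            entry = KineticEntry(
                entry_id=str(row_map[id_col]) if id_col else f"row{idx}",
                ec_number=str(row_map[dialect.columns["ec_number"]]).strip(),
                substrate=str(row_map[dialect.columns["substrate"]]).strip(),
                organism=str(row_map[dialect.columns["organism"]]).strip(),
                value=value,
                value_type=row_vt,
                variant_status=_variant_status(
                    row_map[dialect.columns["variant_status"]], dialect
                ),
                assay_temperature_C=(
                    _parse_optional_float(row_map[at_col]) if at_col else None
                ),
            )
        except ValueError:
            report.reject("malformed EC number")
            continue
        entries.append(entry)
        report.n_accepted += 1
    logger.info(
        "read_kinetic_entries: %d accepted, %d rejected (%s)",
        report.n_accepted,
        report.n_rejected,
        dict(report.reasons),
    )
    return entries, report


def read_growth_temperatures(
    source: PathOrFrame,
    organism_column: str = "organism",
    temperature_column: str = "t_growth_C",
    strip_strain: bool = False,
) -> dict[str, GrowthTemperatureRecord]:
    """Read an organism -> optimal growth temperature table.

    The mapping is keyed by the normalized organism name (see
    :func:`coldcomp.organisms.normalize_organism_name`).  Duplicate organism
    names collapse to the median of their temperatures (logged).

    Raises on an empty table or a non-numeric temperature column, because a
    growth-temperature table that cannot be read at all voids every
    downstream match.
    """
    from .organisms import normalize_organism_name

    frame = _load_frame(source)
    _require_columns(frame, [organism_column, temperature_column], "growth-temperature table")
    if len(frame) == 0:
        raise ValueError("growth-temperature table is empty")

    by_name: dict[str, list[float]] = {}
    for raw_name, raw_temp in zip(frame[organism_column], frame[temperature_column]):
        try:
            temp = _parse_float(raw_temp)
        except ValueError:
            raise ValueError(
                f"non-numeric value in temperature column {temperature_column!r}: {raw_temp!r}"
            ) from None
        key = normalize_organism_name(str(raw_name), strip_strain=strip_strain)
        by_name.setdefault(key, []).append(temp)

    import statistics

    mapping: dict[str, GrowthTemperatureRecord] = {}
    for key, temps in by_name.items():
        if len(temps) > 1:
            logger.info(
                "organism %r has %d temperature entries; using median", key, len(temps)
            )
        mapping[key] = GrowthTemperatureRecord(
            organism=key, t_growth_C=float(statistics.median(temps))
        )
    return mapping


def read_stability_records(
    source: PathOrFrame,
    dialect: Dialect = SYNTHETIC_STABILITY,
) -> tuple[list[StabilityRecord], ReadReport]:
    """Read wild-type melting-temperature rows.

    Only rows whose mutation column indicates wild type are admitted; mutant
    rows and rows without a usable T_m are rejected and counted.
    """
    frame = _load_frame(source)
    required = ["protein_name", "organism", "mutation", "t_m_C"]
    _require_columns(frame, [dialect.columns[f] for f in required], "stability table")
    report = ReadReport(n_rows=len(frame))
    records: list[StabilityRecord] = []

    for row in frame.itertuples(index=False):
        row_map = dict(zip(frame.columns, row))
        if _variant_status(row_map[dialect.columns["mutation"]], dialect) is not VariantStatus.WILD_TYPE:
            report.reject("mutant record")
            continue
        try:
            t_m = _parse_float(row_map[dialect.columns["t_m_C"]])
        except ValueError:
            report.reject("missing or non-numeric T_m")
            continue

        def _opt(field_name: str) -> Optional[str]:
            col = dialect.col(field_name)
            if col and col in row_map and str(row_map[col]).strip():
                return str(row_map[col]).strip()
            return None

        ph_col = dialect.col("ph")
        records.append(
            StabilityRecord(
                protein_name=str(row_map[dialect.columns["protein_name"]]).strip(),
                organism=str(row_map[dialect.columns["organism"]]).strip(),
                t_m_C=t_m,
                ph=_parse_optional_float(row_map[ph_col]) if ph_col and ph_col in row_map else None,
                method=_opt("method"),
                state=_opt("state"),
                reversibility=_opt("reversibility"),
            )
        )
        report.n_accepted += 1
    logger.info(
        "read_stability_records: %d accepted, %d rejected (%s)",
        report.n_accepted,
        report.n_rejected,
        dict(report.reasons),
    )
    return records, report


# ---------------------------------------------------------------------------
# Generic result-table round-trip


def _flatten_record(record: object) -> dict:
    out = {}
    for key, value in dataclasses.asdict(record).items():  # type: ignore[arg-type]
        if key == "reaction_key":
            out["ec_number"], out["substrate"] = value
        elif isinstance(value, enum.Enum):
            out[key] = value.value
        else:
            out[key] = value
    return out


def write_table(
    records: Sequence,
    path: Union[str, Path],
    format: str = "tsv",
    record_type: Optional[type] = None,
) -> None:
    """Write a homogeneous collection of result records to TSV/CSV/JSON.

    Numeric fields are written at full precision so that
    ``read_table(write_table(x)) == x`` value-for-value.  An empty
    collection writes a header-only file; pass ``record_type`` so the header
    can be derived.
    """
    path = Path(path)
    if format not in {"tsv", "csv", "json"}:
        raise ValueError(f"unknown format {format!r}")
    if records:
        record_type = type(records[0])
        if any(type(r) is not record_type for r in records):
            raise TypeError("records are not homogeneous")
        rows = [_flatten_record(r) for r in records]
        columns = list(rows[0].keys())
    else:
        if record_type is None:
            raise ValueError("record_type is required to write an empty table")
        columns = []
        for f in dataclasses.fields(record_type):
            if f.name == "reaction_key":
                columns.extend(["ec_number", "substrate"])
            else:
                columns.append(f.name)
        rows = []
    if format == "json":
        path.write_text(json.dumps(rows, indent=1, default=float) + "\n")
        return
    sep = "\t" if format == "tsv" else ","
    frame = pd.DataFrame(rows, columns=columns)
    # str() on a Python float is repr-round-trippable; no float_format needed.
    frame.to_csv(path, sep=sep, index=False)


def _cast_field(value: object, annotation: object):
    if value is None:
        return None
    text = str(value)
    origin = typing.get_origin(annotation)
    if origin is Union:  # Optional[...]
        args = [a for a in typing.get_args(annotation) if a is not type(None)]
        if text == "" or text == "nan":
            return None
        annotation = args[0]
    if annotation is float:
        return float(text)
    if annotation is int:
        return int(float(text))
    if annotation is bool:
        return text in {"True", "true", "1"}
    if isinstance(annotation, type) and issubclass(annotation, enum.Enum):
        return annotation(text)
    return text


def read_table(path: Union[str, Path], record_type: type) -> list:
    """Read back a table written by :func:`write_table` into ``record_type``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        rows = frame.to_dict(orient="records")
    hints = typing.get_type_hints(record_type)
    out = []
    for row in rows:
        kwargs = {}
        for f in dataclasses.fields(record_type):
            if f.name == "reaction_key":
                kwargs["reaction_key"] = (str(row["ec_number"]), str(row["substrate"]))
            else:
                kwargs[f.name] = _cast_field(row.get(f.name), hints[f.name])
        out.append(record_type(**kwargs))
    return out
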