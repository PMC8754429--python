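"""Shared fixtures and builders for the coldcomp test suite."""

from __future__ import annotations

import pandas as pd
import pytest

from coldcomp.curation import MatchedEntry, Reaction, VariantMeasurement
from coldcomp.io import KineticEntry, ValueType, VariantStatus


def make_entry(
    organism: str = "Escherichia coli",
    value: float = 1.0,
    ec: str = "1.1.1.1",
    substrate: str = "substrate_a",
    status: VariantStatus = VariantStatus.WILD_TYPE,
    value_type: ValueType = ValueType.KCAT,
    assay_temperature_C: float | None = None,
    entry_id: str = "e0",
) -> KineticEntry:
    return KineticEntry(
        entry_id=entry_id,
        ec_number=ec,
        substrate=substrate,
        organism=organism,
        value=value,
        value_type=value_type,
        variant_status=status,
        assay_temperature_C=assay_temperature_C,
    )


def make_reaction(
    variants: list[tuple[float, float]],
    key: tuple[str, str] = ("1.1.1.1", "substrate_a"),
    value_type: ValueType = ValueType.KCAT,
) -> Reaction:
    """Build a reaction from (t_growth_C, k) pairs, one synthetic organism each."""
    measurements = tuple(
        VariantMeasurement(
            reaction_key=key,
            organism=f"organismus fictus{i:03d}",
            t_growth_C=t,
            k=k,
            n_source_entries=1,
        )
        for i, (t, k) in enumerate(variants)
    )
    return Reaction(reaction_key=key, value_type=value_type, measurements=measurements)


@pytest.fixture
def kinetic_tsv(tmp_path):
    """A small valid kinetic table on disk in the synthetic dialect."""
    frame = pd.DataFrame(
        [
            {"entry_id": "a", "ec_number": "1.1.1.1", "substrate": "s", "organism": "Org alpha",
             "value": 2.0, "value_type": "kcat", "variant_status": "wild_type",
             "assay_temperature_C": 25.0},
            {"entry_id": "b", "ec_number": "1.1.1.1", "substrate": "s", "organism": "Org beta",
             "value": 4.0, "value_type": "kcat", "variant_status": "wild_type",
             "assay_temperature_C": 25.0},
            {"entry_id": "c", "ec_number": "2.2.2.2", "substrate": "t", "organism": "Org alpha",
             "value": 8.0, "value_type": "kcat", "variant_status": "mutant",
             "assay_temperature_C": ""},
        ]
    )
    path = tmp_path / "entries.tsv"
    frame.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def temperature_tsv(tmp_path):
    frame = pd.DataFrame(
        [
            {"organism": "Org alpha", "t_growth_C": 10.0},
            {"organism": "Org beta", "t_growth_C": 37.0},
        ]
    )
    path = tmp_path / "t_growth.tsv"
    frame.to_csv(path, sep="\t", index=False)
    return path
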