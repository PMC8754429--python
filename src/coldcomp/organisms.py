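"""Organism-name normalization shared by the kinetic and stability tables.

Species names in kinetic databases and in curated growth-temperature tables
rarely agree byte-for-byte ("Escherichia  coli ", "escherichia coli",
"Escherichia coli K-12").  All matching in this package goes through one
deterministic canonical form so that the two sides of a join cannot drift
apart.
"""

from __future__ import annotations

__all__ = ["normalize_organism_name"]


def normalize_organism_name(name: str, strip_strain: bool = False) -> str:
    """Return the canonical form of a species name.

    The canonical form is trimmed, internal whitespace is collapsed to single
    spaces, and every token is lower-cased.  With ``strip_strain=True`` only
    the first two tokens (genus + species epithet) are retained, which folds
    strain designations such as "Pseudomonas putida KT2440" onto their
    species.  Strain stripping is off by default: the granularity at which
    growth-temperature curations annotate strains varies, and collapsing
    strains is a lossy choice the caller must opt into.

    Idempotent: ``normalize_organism_name(normalize_organism_name(x)) ==
    normalize_organism_name(x)`` for either mode.

    Raises
    ------
    ValueError
        If ``name`` is empty or whitespace-only.
    """
    tokens = name.split()
    if not tokens:
        raise ValueError("organism name is empty")
    if strip_strain:
        tokens = tokens[:2]
    return " ".join(t.lower() for t in tokens)
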