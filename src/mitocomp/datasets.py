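"""Bundled reference annotations (coordinates only, no sequence).

The package ships the published annotation tables of three Flatidae
mitogenomes — *Metcalfa pruinosa* haplotypes H1 (MK303326) and H3 (MN417319)
and *Salurnis marginella* (MT628542) — transcribed as feature-table TSVs.
They exercise every coordinate-based analysis without requiring the
deposited sequences.
"""

from __future__ import annotations

from importlib import resources

from .annotation_io import MitogenomeRecord, read_feature_table

_FILES = {
    "H1": "metcalfa_pruinosa_H1.tsv",
    "H3": "metcalfa_pruinosa_H3.tsv",
    "SM": "salurnis_marginella.tsv",
    # accession aliases
    "MK303326": "metcalfa_pruinosa_H1.tsv",
    "MN417319": "metcalfa_pruinosa_H3.tsv",
    "MT628542": "salurnis_marginella.tsv",
}


def available() -> tuple[str, ...]:
    return ("H1", "H3", "SM")


def load_reference(key: str) -> MitogenomeRecord:
    """Load one bundled annotation table by short key or accession."""
    try:
        fname = _FILES[key]
    except KeyError:
        raise KeyError(f"unknown reference {key!r}; available: {available()}")
    ref = resources.files("mitocomp.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return read_feature_table(path)


def load_all() -> dict[str, MitogenomeRecord]:
    return {k: load_reference(k) for k in available()}
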