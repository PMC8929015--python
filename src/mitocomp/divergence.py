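"""Intraspecies per-gene divergence: uncorrected pairwise p-distances.

Within-species divergences are small, so distances are uncorrected
(p-distance) with pairwise deletion of gap/ambiguous columns. The DNA
barcode region is the 5' 658-bp prefix of COI (the standard animal barcode
fragment), configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from statistics import mean, median

from .annotation_io import MitogenomeRecord, extract_gene_sequence

logger = logging.getLogger(__name__)

_GOOD = set("ACGT")

BARCODE_LENGTH = 658


def p_distance(a: str, b: str) -> float:
    """Uncorrected pairwise distance in percent, pairwise-deleting columns
    where either sequence has a gap or an ambiguous base."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    comparable = mismatch = 0
    for x, y in zip(a, b):
        if x in _GOOD and y in _GOOD:
            comparable += 1
            if x != y:
                mismatch += 1
    if comparable == 0:
        raise ValueError("no comparable positions")
    return 100.0 * mismatch / comparable


def barcode_region(rec: MitogenomeRecord, length: int = BARCODE_LENGTH) -> str:
    """The barcode fragment: 5' prefix of COI in reading orientation."""
    if not rec.has_feature("COI"):
        raise KeyError(f"{rec.record_id}: COI not annotated")
    coi = extract_gene_sequence(rec, "COI")
    return coi[:length]


@dataclass(frozen=True)
class DivergenceSummary:
    gene: str
    n_pairs: int
    min: float
    median: float
    mean: float
    max: float


def divergence_table(records: list[MitogenomeRecord],
                     genes: list[str],
                     barcode: bool = True) -> list[DivergenceSummary]:
    """All pairwise p-distances per gene across conspecific records.

    Genes missing from any record (or of unequal extracted length, i.e. not
    pre-aligned) are skipped with a warning. Summaries are sorted by median.
    The pseudo-gene ``barcode`` (COI 5' prefix) is appended when requested.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    targets: list[tuple[str, list[str]]] = []
    for g in genes:
        missing = [r.record_id for r in records if not r.has_feature(g)]
        if missing:
            logger.warning("gene %s missing in %s; skipped", g, missing)
            continue
        seqs = [extract_gene_sequence(r, g) for r in records]
        if len({len(s) for s in seqs}) != 1:
            logger.warning("gene %s has unequal lengths across records "
                           "(not aligned); skipped", g)
            continue
        targets.append((g, seqs))
    if barcode and all(r.has_feature("COI") for r in records):
        seqs = [barcode_region(r) for r in records]
        if len({len(s) for s in seqs}) == 1:
            targets.append(("barcode", seqs))

    out: list[DivergenceSummary] = []
    for g, seqs in targets:
        dists = [p_distance(a, b) for a, b in combinations(seqs, 2)]
        out.append(DivergenceSummary(
            gene=g, n_pairs=len(dists), min=min(dists),
            median=median(dists), mean=mean(dists), max=max(dists)))
    out.sort(key=lambda s: (s.median, s.gene))
    return out
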