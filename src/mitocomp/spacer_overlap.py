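"""Circular adjacency accounting: intergenic spacers (ISS) and overlaps.

Features are taken in genomic start order (both strands interleaved) around
the circle; for each consecutive pair the signed gap is
``start(next) − end(prev) − 1``, so a negative gap is an overlap and zero
means abutting genes. The A+T-rich control region is not an intergenic
spacer: the two junctions flanking it are reported separately and excluded
from the ISS totals, which is the accounting under which the published
totals for the study genomes are reproduced exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotation_io import FeatureType, GeneFeature, MitogenomeRecord
from .composition import at_percent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdjacencyPair:
    upstream: str
    downstream: str
    gap_bp: int  # negative => overlap, 0 => abutting

    @property
    def klass(self) -> str:
        if self.gap_bp > 0:
            return "spacer"
        if self.gap_bp < 0:
            return "overlap"
        return "abut"


@dataclass
class AdjacencyReport:
    record_id: str
    pairs: list[AdjacencyPair]
    control_flanks: list[AdjacencyPair] = field(default_factory=list)

    @property
    def total_spacer_bp(self) -> int:
        return sum(p.gap_bp for p in self.pairs if p.gap_bp > 0)

    @property
    def spacer_region_count(self) -> int:
        return sum(1 for p in self.pairs if p.gap_bp > 0)

    @property
    def total_overlap_bp(self) -> int:
        return sum(-p.gap_bp for p in self.pairs if p.gap_bp < 0)

    @property
    def longest_spacer(self) -> Optional[AdjacencyPair]:
        spacers = [p for p in self.pairs if p.gap_bp > 0]
        if not spacers:
            return None
        # max() keeps the first maximum: ties broken by genome order
        return max(spacers, key=lambda p: p.gap_bp)

    def spacers_ranked(self) -> list[AdjacencyPair]:
        return sorted((p for p in self.pairs if p.gap_bp > 0),
                      key=lambda p: -p.gap_bp)


@dataclass(frozen=True)
class _Span:
    """A feature as one circular span; ``end`` may exceed the genome length
    for origin-spanning features (unrolled coordinates)."""
    feature: GeneFeature
    start: int
    end: int

    @property
    def name(self) -> str:
        return self.feature.name


def _spans(rec: MitogenomeRecord) -> list[_Span]:
    """Start-sorted spans, fusing origin-spanning two-part features.

    Rows without a ``part`` tag are independent spans even when they share a
    name (genuinely duplicated tRNAs); tagged rows are fused into a single
    unrolled span anchored at part 1.
    """
    spans: list[_Span] = []
    parted: dict[str, list[GeneFeature]] = {}
    for f in rec.features:
        if f.part is None:
            spans.append(_Span(feature=f, start=f.start, end=f.end))
        else:
            parted.setdefault(f.name, []).append(f)
    for parts in parted.values():
        parts.sort(key=lambda f: f.part)
        p1, p2 = parts[0], parts[-1]
        # part 1 runs to the end of the sequence, part 2 restarts at 1
        spans.append(_Span(feature=p1, start=p1.start,
                           end=rec.genome_length + p2.end))
    return sorted(spans, key=lambda s: (s.start, s.end))


def adjacency_report(rec: MitogenomeRecord) -> AdjacencyReport:
    """Signed gaps between consecutive features around the circle.

    The control region is treated as a boundary: its two flanking junctions
    appear in ``control_flanks`` only. Nested features trigger a warning but
    are processed in start order.
    """
    spans = _spans(rec)
    if len(spans) < 2:
        raise ValueError(f"{rec.record_id}: need at least 2 features")
    coords = [(s.start, s.end) for s in spans]
    if len(set(coords)) != len(coords):
        raise ValueError(f"{rec.record_id}: duplicate feature coordinates")
    for prev, nxt in zip(spans, spans[1:]):
        if nxt.end <= prev.end:
            logger.warning("%s: %s nested inside %s", rec.record_id,
                           nxt.name, prev.name)

    n = rec.genome_length
    pairs: list[AdjacencyPair] = []
    flanks: list[AdjacencyPair] = []
    for i, s in enumerate(spans):
        t = spans[(i + 1) % len(spans)]
        if i + 1 < len(spans):
            gap = t.start - s.end - 1
        else:  # circular wrap pair (s.end may already be unrolled past n)
            gap = (t.start + n) - s.end - 1
        pair = AdjacencyPair(upstream=s.name, downstream=t.name, gap_bp=gap)
        if FeatureType.CONTROL in (s.feature.ftype, t.feature.ftype):
            flanks.append(pair)
        else:
            pairs.append(pair)
    return AdjacencyReport(record_id=rec.record_id, pairs=pairs,
                           control_flanks=flanks)


@dataclass(frozen=True)
class SpacerSequence:
    upstream: str
    downstream: str
    start: int  # 1-based genome coordinate of first spacer base
    sequence: str
    at_percent: float
    longest_run: tuple[str, int]  # (base, length) of longest mononucleotide run


def _longest_mononucleotide_run(seq: str) -> tuple[str, int]:
    best = ("", 0)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i > best[1]:
            best = (seq[i], j - i)
        i = j
    return best


def _circular_slice(seq: str, start0: int, length: int) -> str:
    """Zero-based circular substring."""
    n = len(seq)
    start0 %= n
    if start0 + length <= n:
        return seq[start0:start0 + length]
    return seq[start0:] + seq[:(start0 + length) % n]


def spacer_sequences(rec: MitogenomeRecord) -> list[SpacerSequence]:
    """Extract each positive-gap spacer with its A+T content and poly-runs."""
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    spans = {s.name: s for s in _spans(rec)}
    report = adjacency_report(rec)
    n = rec.genome_length
    out: list[SpacerSequence] = []
    for pair in report.pairs:
        if pair.gap_bp <= 0:
            continue
        up = spans[pair.upstream]
        seq = _circular_slice(rec.sequence, up.end % n, pair.gap_bp)
        out.append(SpacerSequence(
            upstream=pair.upstream, downstream=pair.downstream,
            start=up.end % n + 1, sequence=seq, at_percent=at_percent(seq),
            longest_run=_longest_mononucleotide_run(seq),
        ))
    return out


def circle_conservation_residual(rec: MitogenomeRecord) -> int:
    """Book-keeping identity on the circle; zero for a consistent record.

    Sum of feature lengths plus all signed gaps (spacers positive, overlaps
    negative, control-region flanks included) must equal the genome length.
    """
    spans = _spans(rec)
    rep = adjacency_report(rec)
    total_len = sum(s.end - s.start + 1 for s in spans)
    signed_gaps = sum(p.gap_bp for p in rep.pairs + rep.control_flanks)
    return total_len + signed_gaps - rec.genome_length
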