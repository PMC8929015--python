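"""Motif scanning around gene junctions (Hamming matching, both strands).

The canonical use is the conserved pentanucleotide ``TAGTA`` found at the
``ND1``–``trnS2`` junction of fulgoroid planthoppers, a candidate binding
site of the mitochondrial transcription-termination factor (mtTERM). The
motif may sit in the intergenic spacer, overlap the 3' end of the upstream
gene, or the 5' end of the downstream gene, so every hit is localized
relative to the two flanking features.

Matching is substitution-only (Hamming distance, no indels), and because the
two flanking genes are typically on opposite strands, both strands are
scanned and each hit carries its strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .annotation_io import MitogenomeRecord, reverse_complement

logger = logging.getLogger(__name__)


class LocationClass(str, Enum):
    WITHIN_UPSTREAM_3PRIME = "within_upstream_3prime"
    WITHIN_SPACER = "within_spacer"
    WITHIN_DOWNSTREAM_5PRIME = "within_downstream_5prime"
    SPANNING = "spanning"


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based genome coordinate of hit start (major strand)
    strand: str  # '+' or '-'
    mismatches: int
    location_class: LocationClass
    matched_seq: str  # genome major-strand letters at the hit


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _classify_span(hit_start: int, hit_end: int, up: tuple[int, int],
                   dn: tuple[int, int]) -> LocationClass:
    """Locate a hit span (1-based inclusive) against the flanking features."""
    def within(span):
        return span[0] <= hit_start and hit_end <= span[1]

    if within(up):
        return LocationClass.WITHIN_UPSTREAM_3PRIME
    if within(dn):
        return LocationClass.WITHIN_DOWNSTREAM_5PRIME
    gap_lo = min(up[1], dn[1]) + 1
    gap_hi = max(up[0], dn[0]) - 1
    if gap_lo <= hit_start and hit_end <= gap_hi:
        return LocationClass.WITHIN_SPACER
    return LocationClass.SPANNING


def scan_junction(rec: MitogenomeRecord, upstream: str, downstream: str,
                  motif: str = "TAGTA", max_mismatch: int = 1,
                  window: int = 30) -> list[MotifHit]:
    """Scan ±``window`` bp around the junction of two named genes.

    The junction point is the midpoint between the facing boundaries of the
    two features (their genomic order does not matter). Every offset within
    the window is scored on both strands by Hamming distance; hits are
    sorted by (mismatches, distance to the junction, position).
    """
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    if window < len(motif):
        raise ValueError("window must be at least the motif length")
    motif = motif.upper()
    up_f = rec.feature(upstream)
    dn_f = rec.feature(downstream)

    # facing boundaries: the gap between the two features in genome order
    if up_f.end < dn_f.start:
        lo, hi = up_f.end, dn_f.start  # gap is (lo, hi) exclusive
    elif dn_f.end < up_f.start:
        lo, hi = dn_f.end, up_f.start
    else:
        lo = min(up_f.end, dn_f.end)
        hi = max(up_f.start, dn_f.start)
    if hi - lo > 2 * window:
        logger.warning("%s: %s and %s are not adjacent (gap %d bp); scanning "
                       "their inter-coordinate interval anyway",
                       rec.record_id, upstream, downstream, hi - lo - 1)
    center = (lo + hi) / 2.0

    n = rec.genome_length
    m = len(motif)
    motif_rc = reverse_complement(motif)
    hits: list[MotifHit] = []
    first = int(center - window)
    last = int(center + window) - m + 1
    up_span = (up_f.start, up_f.end)
    dn_span = (dn_f.start, dn_f.end)
    for start in range(first, last + 1):
        idx = (start - 1) % n
        sub = (rec.sequence[idx:idx + m] if idx + m <= n
               else rec.sequence[idx:] + rec.sequence[:idx + m - n])
        for strand, pat in (("+", motif), ("-", motif_rc)):
            mm = _hamming(sub, pat)
            if mm <= max_mismatch:
                pos = idx + 1
                loc = _classify_span(pos, pos + m - 1, up_span, dn_span)
                hits.append(MotifHit(position=pos, strand=strand,
                                     mismatches=mm, location_class=loc,
                                     matched_seq=sub))
    hits.sort(key=lambda h: (h.mismatches,
                             abs((h.position + m / 2.0 - 0.5) - center),
                             h.position, h.strand))
    return hits
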