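"""Tandem-repeat architecture of the A+T-rich control region.

The control region of Flatidae mitogenomes is organised as two tandem-repeat
arrays — one near each end — flanking a large AT-rich nonrepeat core that
carries poly-A/poly-T/poly-AT runs. This module decomposes a control-region
sequence into that architecture: a small self-contained tandem-repeat finder
(period-wise self-match scan with greedy extension and identity filtering),
segment tiling with per-segment A+T content, poly-run detection, and simple
pairwise comparison of repeat units.

The repeat finder is deliberately conservative and exactly specified so it
can be checked against a brute-force enumeration at test scale; there is no
external repeat-finding dependency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .annotation_io import MitogenomeRecord, Strand, extract_gene_sequence
from .composition import at_percent


@dataclass(frozen=True)
class RepeatArray:
    """One tandem array, in region-local 1-based inclusive coordinates."""

    start: int
    end: int
    unit_length: int
    copies: float  # fractional final copy allowed, one decimal
    consensus: str
    identity: float  # mean per-copy identity to the consensus, full copies
    truncated_final: bool

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _consensus(seq: str, start0: int, unit: int, full_copies: int) -> str:
    cols = []
    for c in range(unit):
        col = Counter(seq[start0 + k * unit + c] for k in range(full_copies))
        # majority, ties broken alphabetically for determinism
        cols.append(min(col.items(), key=lambda kv: (-kv[1], kv[0]))[0])
    return "".join(cols)


def _identity_vs_consensus(seq: str, start0: int, unit: int,
                           full_copies: int, consensus: str) -> float:
    matches = sum(
        seq[start0 + k * unit + c] == consensus[c]
        for k in range(full_copies) for c in range(unit))
    return matches / (unit * full_copies)


def _span_has_shorter_period(seq: str, s0: int, e0: int, u: int,
                             tol: float) -> bool:
    """True when the span itself self-matches at some period d < u at or
    above the identity threshold — i.e. the candidate is a harmonic of a
    shorter unit (or a homopolymer / dinucleotide run when d is tiny)."""
    for d in range(1, u):
        n = e0 - s0 + 1 - d
        if n <= 0:
            continue
        hits = sum(seq[k] == seq[k - d] for k in range(s0 + d, e0 + 1))
        if hits / n >= tol:
            return True
    return False


def _polish_boundaries(seq: str, s0: int, e0: int, u: int,
                       consensus: str) -> tuple[int, int]:
    """Maximal-scoring window trim against the consensus (match +1,
    mismatch -3): cut the prefix up to the leftmost minimum and the suffix
    after the rightmost maximum of the running score, shedding edge noise
    that survives on chance matches."""
    run = 0
    cum = [0]
    for k in range(s0, e0 + 1):
        run += 1 if seq[k] == consensus[(k - s0) % u] else -3
        cum.append(run)
    lo = min(range(len(cum)), key=lambda i: (cum[i], i))
    hi = max(range(len(cum)), key=lambda i: (cum[i], i))
    if hi <= lo:
        return s0, e0
    return s0 + lo, s0 + hi - 1


def _greedy_prefix(seq: str, start0: int, limit: int, consensus: str,
                   tol: float) -> int:
    """Longest prefix length t <= limit whose running identity to the
    consensus (phase-anchored at ``start0``) stays >= tol, ending on a
    match (0 when none)."""
    matches = best = 0
    for k in range(limit):
        if seq[start0 + k] == consensus[k % len(consensus)]:
            matches += 1
            if matches / (k + 1) >= tol:
                best = k + 1
    return best


def _greedy_left(seq: str, s0: int, u: int, consensus: str,
                 tol: float) -> int:
    """Longest leftward extension from ``s0`` with running identity >= tol,
    phase-consistent with the consensus anchored at ``s0``; gives up after a
    full period without improvement."""
    matches = best = 0
    k = 0
    while s0 - 1 - k >= 0 and (k - best) <= u:
        pos = s0 - 1 - k
        if seq[pos] == consensus[(pos - s0) % u]:
            matches += 1
            if matches / (k + 1) >= tol:
                best = k + 1
        k += 1
    return best


def _raw_runs(seq: str, u: int, min_identity: float) -> list[tuple[int, int]]:
    """Greedy raw runs of the period-``u`` self-match profile.

    A run starts at each position that begins a maximal stretch of
    self-matches; it extends while the running identity since the start
    stays at or above the threshold, giving up after a full period without
    improvement. The raw span prepends the template copy:
    ``[start - u, best]`` inclusive, 0-based.
    """
    n = len(seq)
    runs: list[tuple[int, int]] = []
    for i in range(u, n):
        if seq[i] != seq[i - u]:
            continue
        if i > u and seq[i - 1] == seq[i - 1 - u]:
            continue  # not the left edge of a match stretch
        matches = total = 0
        best = i
        j = i
        while j < n and (j - best) <= u:
            total += 1
            if seq[j] == seq[j - u]:
                matches += 1
                if matches / total >= min_identity:
                    best = j
            j += 1
        runs.append((i - u, best))
    return runs


def _copy_identity(seq: str, start0: int, consensus: str, length: int) -> float:
    return sum(seq[start0 + c] == consensus[c]
               for c in range(length)) / length


def _refine(seq: str, s0: int, e0: int, u: int, min_copies: float,
            min_identity: float, min_unit: int) -> Optional[RepeatArray]:
    """Consensus-anchored trimming of a raw span to a clean array.

    Repeatedly: rebuild the consensus from the full copies anchored at the
    current start, shed edge positions that disagree with it, then shed a
    fractional tail, a first copy, or a last copy whose own identity to the
    consensus falls below the threshold (flank sequence absorbed by the raw
    greedy run, especially at harmonic periods). The fixed point qualifies
    if it holds the copy-number and identity thresholds and its consensus is
    not itself periodic below the minimum unit length (which would make it a
    shorter repeat, or a poly-run).
    """
    while True:
        span = e0 - s0 + 1
        full = span // u
        if full < 2:
            return None
        consensus = _consensus(seq, s0, u, full)
        ns = s0
        while ns <= e0 and seq[ns] != consensus[(ns - s0) % u]:
            ns += 1
        ne = e0
        while ne >= ns and seq[ne] != consensus[(ne - s0) % u]:
            ne -= 1
        if (ns, ne) != (s0, e0):
            s0, e0 = ns, ne
            continue
        tail_len = span - full * u
        if tail_len and _copy_identity(seq, s0 + full * u, consensus,
                                       tail_len) < min_identity:
            # keep only the clean left part of the fractional tail
            keep = _greedy_prefix(seq, s0 + full * u, tail_len, consensus,
                                  min_identity)
            new_e0 = s0 + full * u + keep - 1
            if new_e0 < e0:
                e0 = new_e0
                continue
        if _copy_identity(seq, s0 + (full - 1) * u, consensus,
                          u) < min_identity:
            # last full copy is contaminated flank: keep its clean left part
            base = s0 + (full - 1) * u
            keep = _greedy_prefix(seq, base, u + tail_len, consensus,
                                  min_identity)
            new_e0 = base + keep - 1
            if new_e0 < e0:
                e0 = new_e0
                continue
        if _copy_identity(seq, s0, consensus, u) < min_identity:
            # first copy contaminated: drop it, then re-extend leftward
            # through whatever clean array content it did contain
            new_s0 = s0 + u
            new_s0 -= _greedy_left(seq, new_s0, u, consensus, min_identity)
            if new_s0 > s0:
                s0 = new_s0
                continue
        break
    s0, e0 = _polish_boundaries(seq, s0, e0, u, consensus)
    span = e0 - s0 + 1
    full = span // u
    if full < 2:
        return None
    copies = span / u
    if copies < min_copies:
        return None
    consensus = _consensus(seq, s0, u, full)
    ident = _identity_vs_consensus(seq, s0, u, full, consensus)
    if ident < min_identity:
        return None
    if _span_has_shorter_period(seq, s0, e0, u, min_identity):
        return None  # harmonic of a shorter unit, or a poly-run
    frac = round(copies, 1)
    return RepeatArray(start=s0 + 1, end=e0 + 1, unit_length=u, copies=frac,
                       consensus=consensus, identity=ident,
                       truncated_final=abs(frac - round(frac)) > 1e-9)


def find_tandem_repeats(seq: str, min_unit: int = 10, max_unit: int = 200,
                        min_copies: float = 2.0, min_identity: float = 0.85,
                        min_span: int = 0) -> list[RepeatArray]:
    """Maximal non-crossing tandem arrays, reported left to right.

    Candidates are raw greedy runs of each period's self-match profile (see
    :func:`_raw_runs`) refined by consensus-anchored trimming
    (:func:`_refine`); surviving candidates from all periods are resolved
    greedily by longer total span, then higher identity, then smaller unit,
    and never overlap. ``min_span`` optionally drops arrays below a total
    length, for callers interested only in macro-architecture.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_unit:
        return []
    candidates: dict[tuple[int, int, int], RepeatArray] = {}
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        for s0, e0 in _raw_runs(seq, u, min_identity):
            arr = _refine(seq, s0, e0, u, min_copies, min_identity, min_unit)
            if arr is not None and arr.span >= min_span:
                candidates[(arr.start, arr.end, arr.unit_length)] = arr
    ranked = sorted(candidates.values(),
                    key=lambda r: (-r.span, -r.identity, r.unit_length,
                                   r.start))
    chosen: list[RepeatArray] = []
    for cand in ranked:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


# ---------------------------------------------------------------------------
# Region architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    label: str  # 'repeat' | 'nonrepeat'
    start: int  # region-local, 1-based inclusive
    end: int
    at_percent: float


@dataclass(frozen=True)
class PolyRun:
    pattern: str  # 'A', 'T' or 'AT'
    start: int
    length: int


@dataclass
class RegionArchitecture:
    record_id: str
    region_length: int
    segments: list[Segment]
    repeats: list[RepeatArray]
    polyruns: list[PolyRun]


def find_polyruns(seq: str, min_length: int = 8) -> list[PolyRun]:
    """Poly-A, poly-T and alternating poly-AT runs of at least ``min_length``.

    Pure mononucleotide runs take precedence; alternating runs are reported
    only where they do not lie inside a reported pure run.
    """
    seq = seq.upper()
    runs: list[PolyRun] = []
    covered = np.zeros(len(seq), dtype=bool)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] in "AT" and j - i >= min_length:
            runs.append(PolyRun(pattern=seq[i], start=i + 1, length=j - i))
            covered[i:j] = True
        i = j
    # alternating A/T runs
    i = 0
    while i < len(seq) - 1:
        if seq[i] in "AT" and seq[i + 1] in "AT" and seq[i + 1] != seq[i]:
            j = i + 1
            while j + 1 < len(seq) and seq[j + 1] in "AT" \
                    and seq[j + 1] != seq[j]:
                j += 1
            if j - i + 1 >= min_length and not covered[i:j + 1].any():
                runs.append(PolyRun(pattern="AT", start=i + 1,
                                    length=j - i + 1))
            i = j + 1
        else:
            i += 1
    runs.sort(key=lambda r: r.start)
    return runs


def architecture(rec: MitogenomeRecord, min_unit: int = 10,
                 max_unit: int = 200, min_copies: float = 2.3,
                 min_identity: float = 0.85, min_span: int = 60,
                 polyrun_min: int = 8) -> RegionArchitecture:
    """Repeat/nonrepeat segmentation of a record's A+T-rich region.

    The region is read on the major strand, left to right (3' of srRNA
    toward 5' of trnI in the ancestral arrangement); segments exactly tile
    the region. The copy-number floor is slightly above two here: in a
    strongly A+T-biased core, chance period matches routinely sustain two
    near-copies of a short unit, and requiring a bit more than two copies
    plus a modest total span suppresses those without touching the
    multi-copy arrays this region actually carries.
    """
    ctrl = rec.control_feature
    if ctrl is None:
        raise ValueError(f"{rec.record_id}: no control region annotated")
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    seq = extract_gene_sequence(rec, ctrl.name)
    if ctrl.strand is Strand.MINOR:  # architecture is defined on major strand
        from .annotation_io import reverse_complement
        seq = reverse_complement(seq)
    repeats = find_tandem_repeats(seq, min_unit=min_unit, max_unit=max_unit,
                                  min_copies=min_copies,
                                  min_identity=min_identity,
                                  min_span=min_span)
    segments: list[Segment] = []
    cursor = 1
    for r in repeats:
        if r.start > cursor:
            sub = seq[cursor - 1:r.start - 1]
            segments.append(Segment("nonrepeat", cursor, r.start - 1,
                                    at_percent(sub)))
        segments.append(Segment("repeat", r.start, r.end,
                                at_percent(seq[r.start - 1:r.end])))
        cursor = r.end + 1
    if cursor <= len(seq):
        segments.append(Segment("nonrepeat", cursor, len(seq),
                                at_percent(seq[cursor - 1:])))
    return RegionArchitecture(
        record_id=rec.record_id, region_length=len(seq), segments=segments,
        repeats=repeats, polyruns=find_polyruns(seq, min_length=polyrun_min),
    )


# ---------------------------------------------------------------------------
# Repeat-unit comparison
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -2
    return aligner


def compare_repeat_units(units: list[str], threshold: float = 0.6
                         ) -> tuple[np.ndarray, bool]:
    """Pairwise identity matrix of repeat units and an alignability verdict.

    Identity of a pair is aligned matches divided by the shorter unit's
    length (global dynamic-programming alignment, end gaps free); the units
    are judged "alignable" when the mean off-diagonal identity reaches the
    threshold.
    """
    if len(units) < 2:
        raise ValueError("need at least two repeat units to compare")
    aligner = _aligner()
    k = len(units)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            aln = aligner.align(units[i].upper(), units[j].upper())[0]
            ident = aln.counts().identities
            mat[i, j] = mat[j, i] = ident / min(len(units[i]), len(units[j]))
    off = mat[~np.eye(k, dtype=bool)]
    return mat, bool(off.mean() >= threshold)
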