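"""Nucleotide composition, strand skew, codon usage and start/stop codons.

All skew statistics are computed on major-strand letters, even for gene sets
encoded on the minor strand: the asymmetry of interest is the strand
compositional bias of the genome as deposited, so minor-strand gene spans
are *not* reverse-complemented before counting. AT skew = (A−T)/(A+T) and
GC skew = (G−C)/(G+C).

Codon counting follows one fixed convention: every complete in-frame codon
of a protein-coding gene is counted, a complete terminal stop codon is then
excluded, and the 1–2 leftover nucleotides of a truncated stop are dropped.
Translation uses the invertebrate mitochondrial code (NCBI table 5)
throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from .annotation_io import (
    MAJOR_PCGS,
    MINOR_PCGS,
    PCGS,
    FeatureType,
    MitogenomeRecord,
    extract_gene_sequence,
)

TABLE5 = CodonTable.unambiguous_dna_by_id[5]
STOP_CODONS = frozenset(TABLE5.stop_codons)
SENSE_CODONS = tuple(sorted(TABLE5.forward_table))


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under table 5; ``*`` for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return TABLE5.forward_table[codon]


# ---------------------------------------------------------------------------
# Base content and skew
# ---------------------------------------------------------------------------

#: gene sets for per-basis skew; skew is always read off the major strand
SKEW_BASES = {
    "whole_genome": None,
    "all_PCG": PCGS,
    "major_PCG": MAJOR_PCGS,
    "minor_PCG": MINOR_PCGS,
}


@dataclass(frozen=True)
class SkewPair:
    at_skew: Optional[float]
    gc_skew: Optional[float]
    basis: str = "gene"


def base_content(seq: str) -> dict[str, float]:
    """Percentage of each base over non-N positions (sums to 100)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    n = sum(counts[b] for b in "ACGT")
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return {b: 100.0 * counts[b] / n for b in "ACGT"}


def at_percent(seq: str) -> float:
    bc = base_content(seq)
    return bc["A"] + bc["T"]


def skew(seq: str, basis: str = "gene") -> SkewPair:
    """AT and GC skew of a sequence; a zero denominator yields ``None``."""
    seq = seq.upper()
    counts = Counter(seq)
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    at = (a - t) / (a + t) if a + t else None
    gc = (g - c) / (g + c) if g + c else None
    return SkewPair(at_skew=at, gc_skew=gc, basis=basis)


def strand_set_skew(rec: MitogenomeRecord, basis: str) -> SkewPair:
    """Skew of a named gene set, concatenated in genome order.

    Minor-strand genes contribute their major-strand letters unchanged,
    which is what makes the minor-strand protein set read T-rich on an
    A-skewed genome.
    """
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    if basis not in SKEW_BASES:
        raise ValueError(f"unknown basis {basis!r}; one of {sorted(SKEW_BASES)}")
    genes = SKEW_BASES[basis]
    if genes is None:
        return skew(rec.sequence, basis=basis)
    missing = [g for g in genes if not rec.has_feature(g)]
    if missing:
        raise ValueError(f"{rec.record_id}: basis {basis!r} missing genes {missing}")
    parts = []
    for f in rec.features_sorted():
        if f.name in genes:
            parts.append(rec.sequence[f.start - 1:f.end])
    return skew("".join(parts), basis=basis)


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def frequencies(self) -> dict[str, float]:
        if self.total_codons == 0:
            return {c: 0.0 for c in self.counts}
        return {c: 100.0 * n / self.total_codons for c, n in self.counts.items()}

    def top(self, k: int = 4) -> list[tuple[str, float]]:
        freqs = self.frequencies
        return sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def coding_codons(cds: str) -> list[str]:
    """Countable codons of one CDS under the fixed convention.

    Complete in-frame codons, minus a complete terminal stop; truncated
    trailing nucleotides are dropped.
    """
    cds = cds.upper()
    r = len(cds) % 3
    if r:
        cds = cds[:-r]
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return codons


def codon_usage(rec: MitogenomeRecord, genes: Optional[list[str]] = None
                ) -> CodonUsageTable:
    """Aggregate codon usage over the annotated protein-coding genes."""
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    if genes is None:
        # dedupe: origin-split features contribute two part rows, one gene
        genes = list(dict.fromkeys(
            f.name for f in rec.features_sorted()
            if f.ftype is FeatureType.PCG))
    counts: Counter[str] = Counter()
    for g in genes:
        cds = extract_gene_sequence(rec, g)
        counts.update(c for c in coding_codons(cds) if set(c) <= set("ACGT"))
    total = sum(counts.values())
    return CodonUsageTable(counts=dict(counts), total_codons=total)


def expected_codon_count(rec: MitogenomeRecord) -> int:
    """Codon total implied by coordinates alone, under the same convention.

    Genes whose length is a multiple of three are assumed to end in a
    complete stop codon (excluded); otherwise the trailing remainder is a
    truncated stop (dropped).
    """
    total = 0
    for f in rec.features:
        if f.ftype is not FeatureType.PCG or f.part not in (None, 1):
            continue
        length = sum(p.length for p in rec.features if p.name == f.name)
        r = length % 3
        total += length // 3 - (1 if r == 0 else 0)
    return total


# ---------------------------------------------------------------------------
# Start / stop codons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StartStop:
    start_codon: str
    stop_codon: str
    canonical_start: bool


def _is_canonical_start(codon: str) -> bool:
    return (codon.startswith("AT") and len(codon) == 3) or codon == "GTG"


def start_stop_table(rec: MitogenomeRecord) -> dict[str, StartStop]:
    """First and terminal codon of each PCG, from the sequence.

    A gene whose length is not a multiple of three ends in a truncated stop
    ("T" or "TA", completed by post-transcriptional polyadenylation); starts
    other than ATN/GTG are flagged non-canonical.
    """
    if rec.sequence is None:
        raise ValueError(f"{rec.record_id}: record has no sequence")
    out: dict[str, StartStop] = {}
    for f in rec.features_sorted():
        if f.ftype is not FeatureType.PCG or f.part not in (None, 1):
            continue
        cds = extract_gene_sequence(rec, f.name)
        if len(cds) < 6:
            raise ValueError(f"{rec.record_id}: PCG {f.name} shorter than 6 nt")
        start = cds[:3]
        r = len(cds) % 3
        stop = cds[-r:] if r else cds[-3:]
        out[f.name] = StartStop(start_codon=start, stop_codon=stop,
                                canonical_start=_is_canonical_start(start))
    return out
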