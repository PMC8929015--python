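"""Pairwise Ka/Ks estimation by Nei–Gojobori (1986) counting.

Synonymous (S) and nonsynonymous (N) site counts are computed per codon
under the invertebrate mitochondrial code (NCBI table 5), with mutations to
stop codons excluded from the per-position denominator. Differences between
a codon pair are averaged with equal weight over all mutational pathways
that avoid stop codons; codon pairs whose pathways are all blocked are
skipped and counted. Proportions are corrected with the Jukes–Cantor
formula d = −(3/4)·ln(1 − 4p/3).

The ratio Ka/Ks is reported as ``None`` (missing) when Ks is zero or either
correction is undefined (p ≥ 3/4); ratios below one indicate purifying
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from statistics import mean, stdev
from typing import Iterable, Optional

from .annotation_io import MAJOR_PCGS, MINOR_PCGS
from .composition import STOP_CODONS, translate_codon

_BASES = "ACGT"


class StopCodonError(ValueError):
    pass


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(S, N) fractional site counts of one sense codon.

    For each position, the fraction of non-stop single-nucleotide changes
    that are synonymous contributes to S; S + N = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise StopCodonError(f"{codon} is a stop codon under table 5")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if translate_codon(mut) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """(Sd, Nd) for one codon pair, averaged over stop-free pathways.

    Returns ``None`` when every mutational pathway passes through a stop
    codon (the pair is skipped by the caller).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for path in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_valid += 1
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance; ``None`` when the correction is undefined (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: Optional[float]
    pN: Optional[float]
    Ks: Optional[float]
    Ka: Optional[float]
    codons_compared: int
    codons_skipped: int

    @property
    def ratio(self) -> Optional[float]:
        if self.Ka is None or self.Ks is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _codon_iter(cds: str) -> Iterable[str]:
    r = len(cds) % 3
    if r:
        cds = cds[:-r]
    for i in range(0, len(cds), 3):
        yield cds[i:i + 3]


def pairwise_kaks(cds1: str, cds2: str) -> KaKsResult:
    """NG86 Ka/Ks for a pair of pre-aligned coding sequences.

    Sequences must be equal length; a trailing truncated stop (length mod 3)
    is trimmed, terminal complete stops are dropped, and codons containing a
    gap or ambiguity in either sequence are skipped pairwise.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise ValueError(f"length mismatch: {len(cds1)} vs {len(cds2)}")
    cod1 = list(_codon_iter(cds1))
    cod2 = list(_codon_iter(cds2))
    # drop a terminal stop codon present in either sequence
    while cod1 and (cod1[-1] in STOP_CODONS or cod2[-1] in STOP_CODONS):
        cod1.pop()
        cod2.pop()

    S = N = Sd = Nd = 0.0
    compared = skipped = 0
    for a, b in zip(cod1, cod2):
        if not (set(a) <= set(_BASES) and set(b) <= set(_BASES)):
            skipped += 1
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            skipped += 1
            continue
        diffs = _pathway_diffs(a, b)
        if diffs is None:
            skipped += 1
            continue
        sa, na = ng86_sites(a)
        sb, nb = ng86_sites(b)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        compared += 1

    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = jukes_cantor(pS) if pS is not None else None
    Ka = jukes_cantor(pN) if pN is not None else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
                      codons_compared=compared, codons_skipped=skipped)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledKaKs:
    """One pairwise result tagged with the gene and (optionally) family it
    came from, for grouped summaries."""
    gene: str
    result: KaKsResult
    family: str = ""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean_ratio: Optional[float]
    sd_ratio: Optional[float]
    n: int
    n_undefined: int


def _strand_class(gene: str) -> Optional[str]:
    if gene in MAJOR_PCGS:
        return "major_strand"
    if gene in MINOR_PCGS:
        return "minor_strand"
    return None


def group_kaks(pairs: list[LabeledKaKs], grouping: str) -> list[GroupSummary]:
    """Mean and SD of defined Ka/Ks ratios per group.

    ``grouping`` is one of ``whole_PCG``, ``major_strand``, ``minor_strand``,
    ``per_gene``, ``per_family``. Undefined ratios are excluded from the
    statistics and reported in ``n_undefined``.
    """
    if not pairs:
        raise ValueError("no Ka/Ks results to group")
    buckets: dict[str, list[LabeledKaKs]] = {}
    if grouping == "whole_PCG":
        buckets["whole_PCG"] = list(pairs)
    elif grouping in ("major_strand", "minor_strand"):
        buckets[grouping] = [p for p in pairs
                             if _strand_class(p.gene) == grouping]
    elif grouping == "per_gene":
        for p in pairs:
            buckets.setdefault(p.gene, []).append(p)
    elif grouping == "per_family":
        for p in pairs:
            buckets.setdefault(p.family or "?", []).append(p)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    out: list[GroupSummary] = []
    for group in sorted(buckets):
        ratios = [p.result.ratio for p in buckets[group]]
        defined = [r for r in ratios if r is not None]
        out.append(GroupSummary(
            group=group,
            mean_ratio=mean(defined) if defined else None,
            sd_ratio=(stdev(defined) if len(defined) > 1
                      else (0.0 if defined else None)),
            n=len(defined),
            n_undefined=len(ratios) - len(defined),
        ))
    return out
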