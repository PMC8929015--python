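"""Seeded generator of annotated circular mitogenomes and codon populations.

The generator emulates the statistical structure of a flatid planthopper
mitogenome so that every analysis in this package can be exercised against
known truth: 37 genes plus an A+T-rich control region on a circle, biased
A/T composition with controllable AT/GC skew, open reading frames under the
invertebrate mitochondrial code (with configurable start codons and one
truncated-stop gene), a pentanucleotide motif planted at a named junction,
tandem-repeat arrays flanking a nonrepeat core in the control region, the
ancestral (A) or derived (B/B'/C) gene orders, codon-sequence pairs diverged
at a specified dN/dS, and mutated populations for divergence analysis.

Composition targeting is analytic: base probabilities are solved from
(AT%, AT skew, GC skew), and for coding regions the stop-codon exclusion is
inverted by a short fixed-point iteration so that the *conditional* base
composition of sampled codons matches the target in expectation. Every
output is a deterministic function of the config and its mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

from .annotation_io import (
    CONTROL_NAME,
    PCGS,
    RRNAS,
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    Strand,
    reverse_complement,
)
from .composition import STOP_CODONS
from .gene_order import ORDER_TYPES, Signed
from .kaks import translate_codon

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: reference gene lengths (bp), from the M. pruinosa H1 annotation
GENE_LENGTHS: dict[str, int] = {
    "trnI": 65, "trnQ": 69, "trnM": 66, "ND2": 978, "trnW": 68, "trnC": 64,
    "trnY": 64, "COI": 1545, "trnL2": 63, "COII": 678, "trnK": 70,
    "trnD": 69, "ATP8": 156, "ATP6": 652, "COIII": 783, "trnG": 65,
    "ND3": 351, "trnA": 68, "trnR": 64, "trnN": 65, "trnS1": 61, "trnE": 65,
    "trnF": 65, "ND5": 1683, "trnH": 65, "ND4": 1332, "ND4L": 273,
    "trnT": 64, "trnP": 66, "ND6": 501, "CytB": 1125, "trnS2": 63,
    "ND1": 951, "trnL1": 65, "lrRNA": 1226, "trnV": 73, "srRNA": 717,
}

ANTICODONS: dict[str, str] = {
    "trnI": "GAT", "trnQ": "TTG", "trnM": "CAT", "trnW": "TCA", "trnC": "GCA",
    "trnY": "GTA", "trnL2": "TAA", "trnK": "CTT", "trnD": "GTC",
    "trnG": "TCC", "trnA": "TGC", "trnR": "TCG", "trnN": "GTT",
    "trnS1": "GCT", "trnE": "TTC", "trnF": "GAA", "trnH": "GTG",
    "trnT": "TGT", "trnP": "TGG", "trnS2": "TGA", "trnL1": "TAG",
    "trnV": "TAC",
}

#: default start codons (H1 annotation); ND4 retains its TAG stop
START_CODONS: dict[str, str] = {
    "ND2": "ATT", "COI": "ATC", "COII": "ATA", "ATP8": "ATT", "ATP6": "ATG",
    "COIII": "ATG", "ND3": "ATG", "ND5": "ATG", "ND4": "ATG", "ND4L": "ATG",
    "ND6": "ATA", "CytB": "ATG", "ND1": "ATG",
}
STOP_CODON_CHOICE: dict[str, str] = {"ND4": "TAG"}


@dataclass(frozen=True)
class MotifSpec:
    upstream: str = "ND1"
    downstream: str = "trnS2"
    motif: str = "TAGTA"
    mismatches: int = 0
    placement: str = "spacer"  # spacer | upstream | downstream | spanning
    strand: str = "+"


@dataclass(frozen=True)
class RepeatSpec:
    unit_length: int
    copies: float  # fractional final copy allowed
    identity: float = 1.0
    at_content: float = 0.64  # repeat units are less A/T-rich than the core


@dataclass
class SimConfig:
    """All knobs of the mitogenome generator; the seed is mandatory."""

    seed: int
    genome_length: int = 16300
    gene_order_type: str = "A"
    custom_order: Optional[tuple[Signed, ...]] = None
    at_content: float = 0.7662
    at_skew: float = 0.25
    gc_skew: float = -0.26
    spacer_length: int = 2
    motif: Optional[MotifSpec] = MotifSpec()
    repeats: tuple[RepeatSpec, ...] = (
        # composite two-unit repeat, triplicated with the final unit truncated
        RepeatSpec(unit_length=70, copies=2.6),
        # 21-bp unit repeated 20 times near the trnI end
        RepeatSpec(unit_length=21, copies=20.0),
    )
    core_at_content: float = 0.88
    control_tail: int = 40
    start_codons: dict[str, str] = field(default_factory=dict)
    #: optional override for the genome-strand composition of minor-strand
    #: gene spans (at_content, at_skew, gc_skew); None = global targets
    minor_strand_bias: Optional[tuple[float, float, float]] = None


@dataclass
class TruthTable:
    """Machine-readable ground truth of one simulated genome."""

    seed: int
    gene_order_type: str
    features: list[dict]
    control_span: tuple[int, int]
    repeats: list[dict]  # control-region-local coordinates
    motif: Optional[dict]
    targets: dict[str, float]
    start_codons: dict[str, str]
    stop_codons: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Composition machinery
# ---------------------------------------------------------------------------

def base_probs(at_content: float, at_skew: float, gc_skew: float
               ) -> np.ndarray:
    """Per-base probabilities (A, C, G, T) solved from the three targets."""
    if not 0 < at_content < 1:
        raise SimulationError(f"AT content {at_content} out of (0,1)")
    pa = at_content * (1 + at_skew) / 2
    pt = at_content * (1 - at_skew) / 2
    pg = (1 - at_content) * (1 + gc_skew) / 2
    pc = (1 - at_content) * (1 - gc_skew) / 2
    p = np.array([pa, pc, pg, pt])
    if (p < 0.005).any():
        raise SimulationError(
            f"infeasible composition targets (base probabilities {p.round(4)} "
            "include a value below 0.005)")
    return p


_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOP_MASK = np.array([c in STOP_CODONS for c in _ALL_CODONS])
_CODON_BASE_IDX = np.array([[_BASE_INDEX[ch] for ch in c] for c in _ALL_CODONS])


def _codon_distribution(target: np.ndarray, iters: int = 200) -> np.ndarray:
    """Stop-free codon distribution whose marginal base composition equals
    the target (fixed-point inversion of the stop-codon exclusion)."""
    p = target.copy()
    dist = None
    for _ in range(iters):
        dist = (p[_CODON_BASE_IDX[:, 0]] * p[_CODON_BASE_IDX[:, 1]]
                * p[_CODON_BASE_IDX[:, 2]])
        dist[_STOP_MASK] = 0.0
        dist /= dist.sum()
        marginal = np.zeros(4)
        for pos in range(3):
            np.add.at(marginal, _CODON_BASE_IDX[:, pos], dist)
        marginal /= 3.0
        ratio = np.where(marginal > 0, target / marginal, 1.0)
        p = p * ratio
        p /= p.sum()
    return dist


def _quota_counts(n: int, p: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``n`` draws to probabilities."""
    raw = n * p
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _sample_bases(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    """Random sequence whose composition matches ``p`` almost exactly.

    Long stretches use quota sampling (the base counts are the rounded
    expectations, then shuffled), so the realized composition carries no
    multinomial noise; short stretches are i.i.d., where quota rounding
    would be more distorting than the noise it removes.
    """
    if n < 30:
        return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])
    counts = _quota_counts(n, p)
    arr = np.repeat(np.array(list(_BASES)), counts)
    rng.shuffle(arr)
    return "".join(arr)


class _OrfSampler:
    """Samples sense codons whose base marginal matches a target."""

    def __init__(self, target: np.ndarray):
        self.dist = _codon_distribution(target)

    def sample(self, rng: np.random.Generator, n: int) -> list[str]:
        if n < 30:
            idx = rng.choice(64, size=n, p=self.dist)
        else:
            counts = _quota_counts(n, self.dist)
            idx = np.repeat(np.arange(64), counts)
            rng.shuffle(idx)
        return [_ALL_CODONS[i] for i in idx]


def _swap_strand(p: np.ndarray) -> np.ndarray:
    """Base probabilities seen from the complementary strand (A<->T, C<->G)."""
    return p[::-1].copy()


def _orf_sequence(rng: np.random.Generator, sampler: _OrfSampler, length: int,
                  start_codon: str, stop_choice: str) -> str:
    """Reading-orientation CDS of exactly ``length`` nt.

    The trailing remainder (length mod 3) becomes a truncated stop ("T" or
    "TA"); otherwise a complete stop codon ends the gene.
    """
    r = length % 3
    n_sense = length // 3 - (1 if r == 0 else 0)
    if n_sense < 2:
        raise SimulationError(f"PCG length {length} too short")
    codons = sampler.sample(rng, n_sense)
    codons[0] = start_codon
    stop = {0: stop_choice, 1: "T", 2: "TA"}[r]
    return "".join(codons) + stop


# ---------------------------------------------------------------------------
# Mitogenome assembly
# ---------------------------------------------------------------------------

def _expand_order(cfg: SimConfig) -> list[Signed]:
    if cfg.gene_order_type == "custom":
        if not cfg.custom_order:
            raise SimulationError("custom order requested but not supplied")
        return list(cfg.custom_order)
    try:
        order = list(ORDER_TYPES[cfg.gene_order_type])
    except KeyError:
        raise SimulationError(
            f"unknown gene order type {cfg.gene_order_type!r}")
    if cfg.gene_order_type == "B'":
        i = next(k for k, (g, _) in enumerate(order) if g == "trnC")
        order[i:i + 1] = [order[i]] * 3
    return order


def _ftype(gene: str) -> FeatureType:
    if gene in PCGS:
        return FeatureType.PCG
    if gene in RRNAS:
        return FeatureType.RRNA
    return FeatureType.TRNA


def _build_control_region(rng: np.random.Generator, cfg: SimConfig,
                          length: int, probs: np.ndarray
                          ) -> tuple[str, list[dict]]:
    """Control region: leading repeat array, AT-rich core with poly-runs,
    remaining arrays, short tail. Returns (sequence, truth entries)."""
    arrays: list[tuple[str, dict]] = []
    for spec in cfg.repeats:
        if not 0 < spec.identity <= 1:
            raise SimulationError("repeat identity out of (0,1]")
        unit_probs = base_probs(spec.at_content, cfg.at_skew, cfg.gc_skew)
        unit = _sample_bases(rng, spec.unit_length, unit_probs)
        full = int(spec.copies)
        frac_len = int(round((spec.copies - full) * spec.unit_length))
        copies = []
        for k in range(full):
            copy = list(unit)
            if k > 0 and spec.identity < 1.0:
                n_mut = int(round((1 - spec.identity) * spec.unit_length))
                for pos in rng.choice(spec.unit_length, size=n_mut,
                                      replace=False):
                    alts = [b for b in _BASES if b != copy[pos]]
                    copy[pos] = alts[rng.integers(3)]
            copies.append("".join(copy))
        arr = "".join(copies) + unit[:frac_len]
        arrays.append((arr, {
            "unit_length": spec.unit_length,
            "copies": round(len(arr) / spec.unit_length, 1),
            "identity": spec.identity,
            "consensus": unit,
        }))

    tail_len = cfg.control_tail
    used = sum(len(a) for a, _ in arrays) + tail_len
    core_len = length - used
    if core_len < 60:
        raise SimulationError(
            f"control region ({length} bp) too short for the repeat spec "
            f"({used} bp) plus a nonrepeat core")
    core_probs = base_probs(cfg.core_at_content, cfg.at_skew, cfg.gc_skew)
    core = list(_sample_bases(rng, core_len, core_probs))
    # poly-runs scattered through the core: a 23-bp poly-A near the srRNA
    # side, one poly-T and one poly-AT run further in
    def _plant(run: str, lo_frac: float, hi_frac: float) -> None:
        lo = int(core_len * lo_frac)
        hi = max(lo + 1, int(core_len * hi_frac) - len(run))
        at = int(rng.integers(lo, hi))
        core[at:at + len(run)] = list(run)

    if core_len >= 150:
        _plant("A" * 23, 0.02, 0.25)
        _plant("T" * 12, 0.35, 0.6)
        _plant("AT" * 7, 0.65, 0.9)
    tail = list(_sample_bases(rng, tail_len, core_probs))
    if tail_len >= 14:
        tail[2:12] = list("A" * 10)

    pieces = []
    truth: list[dict] = []
    cursor = 1
    if arrays:
        first, *rest = arrays
        pieces.append(first[0])
        truth.append({**first[1], "start": cursor,
                      "end": cursor + len(first[0]) - 1})
        cursor += len(first[0])
        pieces.append("".join(core))
        cursor += core_len
        for arr, info in rest:
            pieces.append(arr)
            truth.append({**info, "start": cursor,
                          "end": cursor + len(arr) - 1})
            cursor += len(arr)
    else:
        pieces.append("".join(core))
        cursor += core_len
    pieces.append("".join(tail))
    return "".join(pieces), truth


def _verify_orf(seq: str, gene: str, start_codon: str) -> bool:
    """Check that a reading-orientation CDS still starts correctly and has
    no internal stop codon."""
    if not seq.startswith(start_codon):
        return False
    r = len(seq) % 3
    body = seq[:-r] if r else seq
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    internal = codons[:-1] if r == 0 else codons
    return all(c not in STOP_CODONS for c in internal)


def simulate_mitogenome(cfg: SimConfig) -> tuple[MitogenomeRecord, TruthTable]:
    """Generate one annotated circular mitogenome with its truth table."""
    rng = np.random.default_rng(cfg.seed)
    probs = base_probs(cfg.at_content, cfg.at_skew, cfg.gc_skew)
    if cfg.minor_strand_bias is not None:
        minor_probs = base_probs(*cfg.minor_strand_bias)
    else:
        minor_probs = probs
    major_sampler = _OrfSampler(probs)
    # minor-strand CDS is sampled in reading orientation from the
    # complementary distribution so its genome-strand letters hit the target
    minor_sampler = _OrfSampler(_swap_strand(minor_probs))
    start_codons = {**START_CODONS, **cfg.start_codons}

    order = _expand_order(cfg)
    spacers = [cfg.spacer_length] * len(order)
    spacers[-1] = 0  # last gene abuts the control region
    motif = cfg.motif
    motif_junction: Optional[int] = None
    if motif is not None:
        names = [g for g, _ in order]
        for idx in range(len(order) - 1):
            if {names[idx], names[idx + 1]} == {motif.upstream,
                                                motif.downstream}:
                motif_junction = idx
                break
        if motif_junction is None:
            raise SimulationError(
                f"motif junction {motif.upstream}/{motif.downstream} is not "
                "an adjacency of this gene order")
        if motif.placement == "spacer":
            spacers[motif_junction] = max(spacers[motif_junction],
                                          len(motif.motif) + 5)

    genic = sum(GENE_LENGTHS[g] for g, _ in order)
    control_len = cfg.genome_length - genic - sum(spacers)
    if control_len < 120:
        raise SimulationError(
            f"genome length {cfg.genome_length} leaves only {control_len} bp "
            "for the control region")

    chunks: list[str] = []
    features: list[GeneFeature] = []
    stop_codons_used: dict[str, str] = {}
    cursor = 0  # 0-based
    for idx, (gene, orient) in enumerate(order):
        length = GENE_LENGTHS[gene]
        ftype = _ftype(gene)
        if ftype is FeatureType.PCG:
            sampler = major_sampler if orient == "+" else minor_sampler
            stop_choice = STOP_CODON_CHOICE.get(gene, "TAA")
            reading = _orf_sequence(rng, sampler, length,
                                    start_codons[gene], stop_choice)
            r = length % 3
            stop_codons_used[gene] = {0: stop_choice, 1: "T", 2: "TA"}[r]
            seq = reading if orient == "+" else reverse_complement(reading)
        elif cfg.minor_strand_bias is not None and orient == "-":
            seq = _sample_bases(rng, length, minor_probs)
        else:
            seq = _sample_bases(rng, length, probs)
        features.append(GeneFeature(
            name=gene, ftype=ftype,
            strand=Strand.MAJOR if orient == "+" else Strand.MINOR,
            start=cursor + 1, end=cursor + length,
            anticodon=ANTICODONS.get(gene),
            start_codon=start_codons.get(gene) if ftype is FeatureType.PCG
            else None,
            stop_codon=stop_codons_used.get(gene),
        ))
        chunks.append(seq)
        cursor += length
        if spacers[idx]:
            chunks.append(_sample_bases(rng, spacers[idx], probs))
            cursor += spacers[idx]

    control_seq, repeat_truth = _build_control_region(rng, cfg, control_len,
                                                      probs)
    control_start = cursor + 1
    features.append(GeneFeature(
        name=CONTROL_NAME, ftype=FeatureType.CONTROL, strand=Strand.MAJOR,
        start=control_start, end=cursor + control_len))
    chunks.append(control_seq)

    genome = list("".join(chunks))
    assert len(genome) == cfg.genome_length

    motif_truth: Optional[dict] = None
    if motif is not None:
        motif_truth = _plant_motif(rng, genome, features, order,
                                   motif_junction, motif, start_codons)

    record = MitogenomeRecord(
        record_id=f"SIM-{cfg.gene_order_type}-{cfg.seed}",
        organism="synthetic flatid mitogenome",
        genome_length=cfg.genome_length,
        sequence="".join(genome),
        features=features,
    )
    record.validate()
    truth = TruthTable(
        seed=cfg.seed,
        gene_order_type=cfg.gene_order_type,
        features=[{"name": f.name, "start": f.start, "end": f.end,
                   "strand": f.strand.value} for f in features],
        control_span=(control_start, control_start + control_len - 1),
        repeats=repeat_truth,
        motif=motif_truth,
        targets={"at_content": cfg.at_content, "at_skew": cfg.at_skew,
                 "gc_skew": cfg.gc_skew},
        start_codons={g: start_codons[g] for g in start_codons
                      if g in {n for n, _ in order}},
        stop_codons=stop_codons_used,
    )
    return record, truth


def _plant_motif(rng: np.random.Generator, genome: list[str],
                 features: list[GeneFeature], order: list[Signed],
                 junction_idx: int, motif: MotifSpec,
                 start_codons: dict[str, str]) -> dict:
    """Write the motif at the configured junction; never break an ORF."""
    pattern = list(motif.motif.upper())
    if motif.mismatches:
        for pos in rng.choice(len(pattern), size=motif.mismatches,
                              replace=False):
            alts = [b for b in _BASES if b != pattern[pos]]
            pattern[pos] = alts[rng.integers(3)]
    planted = "".join(pattern)
    written = planted if motif.strand == "+" else reverse_complement(planted)
    m = len(written)

    by_name = {f.name: f for f in features}
    left = by_name[order[junction_idx][0]]
    right = by_name[order[junction_idx + 1][0]]
    up = by_name[motif.upstream]
    dn = by_name[motif.downstream]
    gap_lo, gap_hi = left.end + 1, right.start - 1  # spacer span, may be empty

    def candidates() -> list[int]:  # 0-based plant starts, best first
        if motif.placement == "spacer":
            mid = (gap_lo + gap_hi) // 2 - m // 2 - 1
            return [mid + d for d in (0, 1, -1, 2, -2)]
        target = up if motif.placement in ("upstream", "spanning") else dn
        # junction side of the target feature
        if target is left:
            boundary = target.end  # motif sits at the feature's right edge
            if motif.placement == "spanning":
                base = boundary - m + 2  # straddles the boundary
            else:
                base = boundary - m - 2  # fully inside, 2 bp from the edge
        else:
            boundary = target.start
            if motif.placement == "spanning":
                base = boundary - 3
            else:
                base = boundary + 1
        return [base - 1 + d for d in (0, 1, -1, 2, -2, 3, -3)]

    pcg_checks = [f for f in (up, dn) if f.ftype is FeatureType.PCG]
    for start0 in candidates():
        saved = genome[start0:start0 + m]
        genome[start0:start0 + m] = list(written)
        ok = True
        for f in pcg_checks:
            reading = "".join(genome[f.start - 1:f.end])
            if f.strand is Strand.MINOR:
                reading = reverse_complement(reading)
            if not _verify_orf(reading, f.name, start_codons[f.name]):
                ok = False
                break
        if ok:
            return {"position": start0 + 1, "strand": motif.strand,
                    "planted_seq": planted, "written_seq": written,
                    "placement": motif.placement,
                    "mismatches": motif.mismatches}
        genome[start0:start0 + m] = saved
    raise SimulationError(
        f"could not plant motif {planted} at {motif.upstream}/"
        f"{motif.downstream} ({motif.placement}) without disrupting an ORF")


# ---------------------------------------------------------------------------
# Codon-pair and population simulation
# ---------------------------------------------------------------------------

def simulate_cds_pair(length_codons: int, omega: float, t: float, seed: int
                      ) -> tuple[str, str, dict[str, int]]:
    """An ancestral CDS and a descendant diverged at dN/dS = ``omega``.

    The ancestor is sampled uniformly from sense codons; the descendant
    accumulates ``Poisson(t * 3L)`` random single-nucleotide proposals, each
    accepted with probability 1 if synonymous and ``omega`` if
    nonsynonymous; proposals creating stop codons are rejected. The realized
    numbers of accepted changes are returned as truth.
    """
    if length_codons < 50:
        raise ValueError("need at least 50 codons")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    sense = [c for c in _ALL_CODONS if c not in STOP_CODONS]
    codons = [sense[i] for i in rng.choice(len(sense), size=length_codons)]
    cds1 = "".join(codons)
    desc = list(codons)
    syn = nonsyn = 0
    n_events = rng.poisson(t * 3 * length_codons)
    for _ in range(n_events):
        site = int(rng.integers(3 * length_codons))
        ci, pos = divmod(site, 3)
        cur = desc[ci]
        alts = [b for b in _BASES if b != cur[pos]]
        nb = alts[rng.integers(3)]
        mut = cur[:pos] + nb + cur[pos + 1:]
        if mut in STOP_CODONS:
            continue
        if translate_codon(mut) == translate_codon(cur):
            desc[ci] = mut
            syn += 1
        elif rng.random() < omega:
            desc[ci] = mut
            nonsyn += 1
    return cds1, "".join(desc), {"synonymous": syn, "nonsynonymous": nonsyn,
                                 "proposals": int(n_events)}


def simulate_population(base: MitogenomeRecord,
                        per_gene_mut_rates: dict[str, float],
                        n: int, seed: int
                        ) -> tuple[list[MitogenomeRecord], dict]:
    """``n`` copies of a genome with independent per-gene substitutions.

    Each copy substitutes every site of each named gene independently with
    the gene's per-site rate; the count of introduced differences per
    individual and gene is returned as truth.
    """
    if base.sequence is None:
        raise ValueError("base record has no sequence")
    if any(r < 0 for r in per_gene_mut_rates.values()):
        raise ValueError("mutation rates must be non-negative")
    rng = np.random.default_rng(seed)
    truth: dict[str, dict[str, int]] = {}
    out: list[MitogenomeRecord] = []
    for k in range(n):
        seq = list(base.sequence)
        counts: dict[str, int] = {}
        for gene, rate in per_gene_mut_rates.items():
            f = base.feature(gene)
            hit = np.nonzero(rng.random(f.length) < rate)[0]
            for off in hit:
                pos = f.start - 1 + int(off)
                alts = [b for b in _BASES if b != seq[pos]]
                seq[pos] = alts[rng.integers(3)]
            counts[gene] = int(len(hit))
        rid = f"{base.record_id}-ind{k + 1}"
        out.append(replace(base, record_id=rid, sequence="".join(seq),
                           features=[replace(f) for f in base.features]))
        truth[rid] = counts
    return out, truth


# ---------------------------------------------------------------------------
# Flat config files
# ---------------------------------------------------------------------------

def config_from_file(path, seed: Optional[int] = None) -> SimConfig:
    """Build a SimConfig from a flat YAML mapping (simple key: value)."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise SimulationError("config must supply a seed")
    if "motif" in raw and raw["motif"] is not None:
        raw["motif"] = MotifSpec(**raw["motif"])
    if "repeats" in raw and raw["repeats"] is not None:
        raw["repeats"] = tuple(RepeatSpec(**r) for r in raw["repeats"])
    return SimConfig(**raw)
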