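"""Evaluation of annotated tRNA cloverleaf structures.

Structures are evaluated, not predicted: the base-pairing of each arm comes
from an annotation (dot-bracket string plus arm spans), and every annotated
pair is classified as Watson–Crick, G-U wobble, or mismatch. Canonical
cloverleaf dimensions — 7 bp aminoacyl (acceptor) stem, 5 bp anticodon stem,
7 nt anticodon loop — are checked, and a DHU arm with no pairs at all marks
the truncated-DHU tRNAs (typically trnS1 in these genomes).

All indices are 1-based positions within the tRNA sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .annotation_io import MitogenomeRecord

ARMS = ("acceptor", "DHU", "anticodon", "TPsiC")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass
class CloverleafAnnotation:
    trna_name: str
    sequence: str
    pairing: dict[str, list[tuple[int, int]]]  # arm -> [(i, j)], i < j
    anticodon_span: Optional[tuple[int, int]] = None  # (start, end), 3 nt

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for arm, pairs in self.pairing.items():
            if arm not in ARMS:
                raise ValueError(f"{self.trna_name}: unknown arm {arm!r}")
            norm = []
            for i, j in pairs:
                if i > j:
                    i, j = j, i  # 5'<->3' normalization
                if not (1 <= i < j <= n):
                    raise ValueError(
                        f"{self.trna_name}: pair ({i},{j}) out of range 1..{n}")
                if i in seen or j in seen:
                    raise ValueError(
                        f"{self.trna_name}: index reused in pair ({i},{j})")
                seen.update((i, j))
                norm.append((i, j))
            self.pairing[arm] = norm


@dataclass
class ArmCounts:
    watson_crick: int = 0
    wobble_GU: int = 0
    mismatch: int = 0

    @property
    def total(self) -> int:
        return self.watson_crick + self.wobble_GU + self.mismatch


@dataclass
class PairCounts:
    trna_name: str
    arms: dict[str, ArmCounts]
    dhu_truncated: bool
    dims_ok: bool
    anticodon_loop_nt: Optional[int]

    @property
    def total_mismatches(self) -> int:
        return sum(a.mismatch for a in self.arms.values())

    @property
    def total_wobble(self) -> int:
        return sum(a.wobble_GU for a in self.arms.values())


def evaluate(annot: CloverleafAnnotation) -> PairCounts:
    """Classify every annotated base pair and check canonical dimensions."""
    seq = annot.sequence.upper().replace("U", "T")
    arms: dict[str, ArmCounts] = {arm: ArmCounts() for arm in ARMS}
    for arm in ARMS:
        for i, j in annot.pairing.get(arm, []):
            duo = (seq[i - 1], seq[j - 1])
            if duo in _WC:
                arms[arm].watson_crick += 1
            elif duo in _WOBBLE:
                arms[arm].wobble_GU += 1
            else:
                arms[arm].mismatch += 1

    ac_pairs = annot.pairing.get("anticodon", [])
    loop_nt: Optional[int] = None
    if ac_pairs:
        inner_i = max(i for i, _ in ac_pairs)
        inner_j = min(j for _, j in ac_pairs)
        loop_nt = inner_j - inner_i - 1
    dims_ok = (arms["acceptor"].total == 7
               and arms["anticodon"].total == 5
               and loop_nt == 7)
    return PairCounts(
        trna_name=annot.trna_name, arms=arms,
        dhu_truncated=len(annot.pairing.get("DHU", [])) == 0,
        dims_ok=dims_ok, anticodon_loop_nt=loop_nt,
    )


# ---------------------------------------------------------------------------
# Dot-bracket input
# ---------------------------------------------------------------------------

def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(structure, 1):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in structure")
    if stack:
        raise ValueError("unbalanced '(' in structure")
    return sorted(pairs)


def _parse_arm_spans(text: str) -> dict[str, tuple[int, int]]:
    """Parse ``acceptor:1-7;DHU:10-25;anticodon:27-43;TPsiC:45-61``."""
    spans: dict[str, tuple[int, int]] = {}
    for tok in text.strip().split(";"):
        if not tok:
            continue
        name, _, rng = tok.partition(":")
        lo, _, hi = rng.partition("-")
        spans[name.strip()] = (int(lo), int(hi))
    return spans


def annotation_from_dotbracket(trna_name: str, sequence: str,
                               structure: str, arm_spans: str
                               ) -> CloverleafAnnotation:
    """Build an annotation from a dot-bracket string plus arm spans.

    A pair belongs to the arm whose span contains its 5' index; pairs whose
    5' index falls in no declared arm are assigned to the acceptor stem
    (its 3' half lies at the far end of the molecule).
    """
    if len(structure) != len(sequence):
        raise ValueError(f"{trna_name}: structure/sequence length mismatch")
    spans = _parse_arm_spans(arm_spans)
    pairing: dict[str, list[tuple[int, int]]] = {arm: [] for arm in ARMS}
    for arm in spans:
        if arm not in ARMS:
            raise ValueError(f"{trna_name}: unknown arm {arm!r}")
    for i, j in pairs_from_dotbracket(structure):
        assigned = None
        for arm, (lo, hi) in spans.items():
            if lo <= i <= hi:
                assigned = arm
                break
        pairing[assigned or "acceptor"].append((i, j))
    return CloverleafAnnotation(trna_name=trna_name, sequence=sequence,
                                pairing=pairing)


def read_cloverleaf_table(path: Union[str, Path]) -> list[CloverleafAnnotation]:
    """Read a TSV of columns trna, sequence, structure, arm_spans."""
    out: list[CloverleafAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("trna\t"):
                continue
            trna, seq, struct, spans = line.split("\t")[:4]
            out.append(annotation_from_dotbracket(trna, seq, struct, spans))
    return out


# ---------------------------------------------------------------------------
# Genome-level report
# ---------------------------------------------------------------------------

def genome_trna_report(recs: list[MitogenomeRecord],
                       annots: dict[str, dict[str, CloverleafAnnotation]]
                       ) -> pd.DataFrame:
    """Per-arm pair classification for every annotated tRNA of each record.

    ``annots`` maps record_id -> tRNA name -> annotation. tRNAs without an
    annotation are flagged; per-genome totals are computed over the
    annotated rows, and the shortest/longest tRNA is identified from the
    record coordinates.
    """
    rows = []
    for rec in recs:
        trnas = [f for f in rec.features_sorted() if f.name.startswith("trn")]
        lengths = {f.name: f.length for f in trnas}
        shortest = min(lengths, key=lambda k: (lengths[k], k)) if lengths else None
        longest = max(lengths, key=lambda k: (lengths[k], k)) if lengths else None
        rec_annots = annots.get(rec.record_id, {})
        for f in trnas:
            ann = rec_annots.get(f.name)
            if ann is None:
                rows.append({"record": rec.record_id, "tRNA": f.name,
                             "arm": None, "length": f.length,
                             "annotated": False})
                continue
            counts = evaluate(ann)
            for arm in ARMS:
                ac = counts.arms[arm]
                rows.append({
                    "record": rec.record_id, "tRNA": f.name, "arm": arm,
                    "length": f.length, "annotated": True,
                    "watson_crick": ac.watson_crick, "wobble_GU": ac.wobble_GU,
                    "mismatch": ac.mismatch,
                    "dhu_truncated": counts.dhu_truncated,
                    "dims_ok": counts.dims_ok,
                    "shortest_trna": shortest, "longest_trna": longest,
                })
    return pd.DataFrame(rows)
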