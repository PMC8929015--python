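"""Mitochondrial gene orders as signed circular permutations.

The ancestral insect arrangement (type A) is the order of the study genomes;
the derived arrangements seen in Delphacinae planthoppers are expressed as
edits of it:

* **B** — (i) ``trnC``/``trnW`` transposed at the ``ND2``–``trnY`` junction
  and (ii) the ``trnT, trnP, ND6`` block between ``ND4L`` and ``CytB``
  replaced by ``ND6`` (inverted), ``trnP``, ``trnT``;
* **B'** — B with ``trnC`` tandemly triplicated;
* **C** — B with ``trnH`` removed from the ``ND5``–``ND4`` junction and
  inserted before ``ND6`` (``trnH, ND6, trnP, trnT``).

Because the published schematic is ambiguous about whether the translocated
``ND6`` is inverted, classification tolerates either ``ND6`` orientation in
the derived block (a note is logged when the non-default one is seen).

Signatures are canonically rotated to start at ``trnI``; the control region
is excluded; tandemly duplicated tRNAs are collapsed into a copy-count map
(they are ignored by breakpoint distance, which is defined on permutations,
but preserved for B' detection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation_io import FeatureType, MitogenomeRecord, Strand

logger = logging.getLogger(__name__)

Signed = tuple[str, str]  # (gene label, '+'/'-')

#: ancestral insect arrangement (type A), control region excluded
ANCESTRAL_ORDER: tuple[Signed, ...] = (
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("ND2", "+"), ("trnW", "+"),
    ("trnC", "-"), ("trnY", "-"), ("COI", "+"), ("trnL2", "+"), ("COII", "+"),
    ("trnK", "+"), ("trnD", "+"), ("ATP8", "+"), ("ATP6", "+"), ("COIII", "+"),
    ("trnG", "+"), ("ND3", "+"), ("trnA", "+"), ("trnR", "+"), ("trnN", "+"),
    ("trnS1", "+"), ("trnE", "+"), ("trnF", "-"), ("ND5", "-"), ("trnH", "-"),
    ("ND4", "-"), ("ND4L", "-"), ("trnT", "+"), ("trnP", "-"), ("ND6", "+"),
    ("CytB", "+"), ("trnS2", "+"), ("ND1", "-"), ("trnL1", "-"),
    ("lrRNA", "-"), ("trnV", "-"), ("srRNA", "-"),
)


def _derive_b(order: tuple[Signed, ...]) -> tuple[Signed, ...]:
    lst = list(order)
    # trnW/trnC transposition at the ND2-trnY junction
    iw = lst.index(("trnW", "+"))
    ic = lst.index(("trnC", "-"))
    lst[iw], lst[ic] = lst[ic], lst[iw]
    # trnT,trnP,ND6 -> ND6(inverted),trnP,trnT between ND4L and CytB
    it = lst.index(("trnT", "+"))
    lst[it:it + 3] = [("ND6", "-"), ("trnP", "-"), ("trnT", "+")]
    return tuple(lst)


def _derive_c(order_b: tuple[Signed, ...]) -> tuple[Signed, ...]:
    lst = [g for g in order_b if g[0] != "trnH"]
    i6 = next(i for i, g in enumerate(lst) if g[0] == "ND6")
    lst.insert(i6, ("trnH", "-"))
    return tuple(lst)


_B_ORDER = _derive_b(ANCESTRAL_ORDER)
_C_ORDER = _derive_c(_B_ORDER)

#: reference orders (B' shares B's permutation; it differs by duplication)
ORDER_TYPES: dict[str, tuple[Signed, ...]] = {
    "A": ANCESTRAL_ORDER,
    "B": _B_ORDER,
    "B'": _B_ORDER,
    "C": _C_ORDER,
}


@dataclass(frozen=True)
class GeneOrderSignature:
    order: tuple[Signed, ...]
    duplications: dict[str, int] = field(default_factory=dict)

    def serialize(self) -> str:
        return ";".join(f"{g},{o}" for g, o in self.order)

    @staticmethod
    def parse(text: str) -> "GeneOrderSignature":
        order = []
        for tok in text.strip().split(";"):
            g, _, o = tok.partition(",")
            order.append((g, o))
        return canonicalize(GeneOrderSignature(order=tuple(order)))


def canonicalize(sig: GeneOrderSignature) -> GeneOrderSignature:
    """Rotate so the signature starts at trnI (or, failing that, the first
    tRNA in the list, with a warning)."""
    order = sig.order
    names = [g for g, _ in order]
    if "trnI" in names:
        i = names.index("trnI")
    else:
        logger.warning("trnI absent; canonical rotation falls back to the "
                       "first tRNA")
        i = next((k for k, n in enumerate(names) if n.startswith("trn")), 0)
    return GeneOrderSignature(order=order[i:] + order[:i],
                              duplications=dict(sig.duplications))


def signature(rec: MitogenomeRecord) -> GeneOrderSignature:
    """Signed circular gene order of a record, canonically rotated.

    Features are taken in start order; consecutive copies of the same gene
    collapse into the duplication map; the control region is dropped.
    """
    feats = [f for f in rec.features_sorted()
             if f.ftype is not FeatureType.CONTROL and f.part in (None, 1)]
    if not feats:
        raise ValueError(f"{rec.record_id}: record has no features")
    order: list[Signed] = []
    dups: dict[str, int] = {}
    for f in feats:
        entry = (f.name, "+" if f.strand is Strand.MAJOR else "-")
        if order and order[-1][0] == f.name:
            dups[f.name] = dups.get(f.name, 1) + 1
            continue
        order.append(entry)
    # a run split across the origin also collapses
    if len(order) > 1 and order[0][0] == order[-1][0]:
        dups[order[0][0]] = dups.get(order[0][0], 1) + 1
        order.pop()
    return canonicalize(GeneOrderSignature(order=tuple(order),
                                           duplications=dups))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _orders_match(a: tuple[Signed, ...], b: tuple[Signed, ...]) -> bool:
    """Equality tolerating either orientation of ND6 (schematic ambiguity)."""
    if len(a) != len(b):
        return False
    for (ga, oa), (gb, ob) in zip(a, b):
        if ga != gb:
            return False
        if oa != ob:
            if ga == "ND6":
                logger.info("ND6 orientation differs from reference; "
                            "tolerated by classification")
                continue
            return False
    return True


def _adjacency_set(order: tuple[Signed, ...]) -> set:
    """Canonical signed adjacencies of a circular signed permutation."""
    inv = {"+": "-", "-": "+"}
    adj = set()
    for i, (g1, o1) in enumerate(order):
        g2, o2 = order[(i + 1) % len(order)]
        fwd = ((g1, o1), (g2, o2))
        rev = ((g2, inv[o2]), (g1, inv[o1]))
        adj.add(min(fwd, rev))
    return adj


def breakpoint_distance(a: GeneOrderSignature, b: GeneOrderSignature) -> int:
    """Number of signed circular adjacencies of one order absent from the
    other (symmetric; duplications are collapsed first)."""
    ua = {g for g, _ in a.order}
    ub = {g for g, _ in b.order}
    if ua != ub:
        raise ValueError(
            f"label universes differ: only in a {sorted(ua - ub)}, "
            f"only in b {sorted(ub - ua)}")
    return len(_adjacency_set(a.order) - _adjacency_set(b.order))


def classify(sig: GeneOrderSignature) -> tuple[str, list[str]]:
    """Arrangement type of a canonical signature, with junction evidence.

    Returns one of ``A``, ``B``, ``B'``, ``C`` or ``novel``; for novel
    orders the evidence lists the nearest type and the adjacencies that
    differ from it.
    """
    sig = canonicalize(sig)
    extra_dups = {g: c for g, c in sig.duplications.items() if c >= 2}
    for label in ("A", "B", "C"):
        ref = ORDER_TYPES[label]
        if _orders_match(sig.order, ref):
            if label == "B" and extra_dups.get("trnC", 1) >= 3:
                return "B'", [f"type B order with trnC x{extra_dups['trnC']}"]
            if extra_dups:
                break  # unexpected duplication on a known order -> novel
            return label, [f"matches type {label} reference order"]
    # novel: report nearest reference and differing adjacencies
    best_label, best_d = None, None
    for label in ("A", "B", "C"):
        ref_sig = GeneOrderSignature(order=ORDER_TYPES[label])
        try:
            d = breakpoint_distance(sig, ref_sig)
        except ValueError:
            continue
        if best_d is None or d < best_d:
            best_label, best_d = label, d
    evidence = []
    if best_label is not None:
        diff = _adjacency_set(sig.order) - _adjacency_set(
            ORDER_TYPES[best_label])
        evidence.append(f"nearest type {best_label} "
                        f"(breakpoint distance {best_d})")
        evidence.extend(
            f"novel adjacency {g1}({o1})-{g2}({o2})"
            for (g1, o1), (g2, o2) in sorted(diff))
    if extra_dups:
        evidence.append(f"duplications: {extra_dups}")
    return "novel", evidence
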