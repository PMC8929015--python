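"""Reading, validating and writing annotated circular mitogenomes.

Coordinates are 1-based inclusive throughout (GenBank convention). The
"major" strand is the strand deposited in GenBank — the one encoding ND2,
COI–COIII, ATP6/8, ND3, ND6 and CytB in the ancestral insect arrangement —
and is written as ``+``; its complement is "minor" (``-``).

Two on-disk representations are supported:

* GenBank flat files (parsed with Biopython);
* a plain feature-table TSV with a ``#genome_length=<N>`` header line and
  columns ``name  ftype  strand  start  end  anticodon  start_codon
  stop_codon``, optionally paired with a FASTA sequence.

Features spanning the replication origin are represented as two rows that
share a name and carry a ``part`` tag, so the ``start <= end`` invariant
always holds for a single row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class Strand(str, Enum):
    MAJOR = "+"
    MINOR = "-"


class FeatureType(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


#: the 13 protein-coding genes encoded on each strand (ancestral arrangement)
MAJOR_PCGS = ("ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3", "ND6", "CytB")
MINOR_PCGS = ("ND1", "ND4", "ND4L", "ND5")
PCGS = MAJOR_PCGS + MINOR_PCGS

TRNAS = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)
RRNAS = ("srRNA", "lrRNA")
CONTROL_NAME = "AT_rich"

#: the canonical 37-gene complement plus the A+T-rich control region
CANONICAL_GENES = frozenset(PCGS) | frozenset(TRNAS) | frozenset(RRNAS) | {CONTROL_NAME}

# GenBank gene labelling is chaotic; map common synonyms onto the controlled
# vocabulary at ingest. Keys are upper-cased, with spaces/underscores removed.
_NAME_ALIASES = {
    "COX1": "COI", "COXI": "COI", "CO1": "COI",
    "COX2": "COII", "COXII": "COII", "CO2": "COII",
    "COX3": "COIII", "COXIII": "COIII", "CO3": "COIII",
    "COB": "CytB", "CYTB": "CytB", "CYB": "CytB",
    "ATP6": "ATP6", "ATP8": "ATP8",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "12S": "srRNA", "12SRRNA": "srRNA", "S-RRNA": "srRNA", "SRRNA": "srRNA",
    "RRNS": "srRNA", "SMALLSUBUNITRIBOSOMALRNA": "srRNA",
    "12SRIBOSOMALRNA": "srRNA",
    "16S": "lrRNA", "16SRRNA": "lrRNA", "L-RRNA": "lrRNA", "LRRNA": "lrRNA",
    "RRNL": "lrRNA", "LARGESUBUNITRIBOSOMALRNA": "lrRNA",
    "16SRIBOSOMALRNA": "lrRNA",
    "TRNL(TAA)": "trnL2", "TRNL(UAA)": "trnL2", "TRNL2": "trnL2",
    "TRNL(TAG)": "trnL1", "TRNL(UAG)": "trnL1", "TRNL1": "trnL1",
    "TRNS(GCT)": "trnS1", "TRNS(GCU)": "trnS1", "TRNS1": "trnS1",
    "TRNS(TGA)": "trnS2", "TRNS(UGA)": "trnS2", "TRNS2": "trnS2",
    "A+T-RICHREGION": CONTROL_NAME, "ATRICH": CONTROL_NAME,
    "AT-RICHREGION": CONTROL_NAME, "CONTROLREGION": CONTROL_NAME,
    "D-LOOP": CONTROL_NAME, "ATRICHREGION": CONTROL_NAME,
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(raw: str) -> str:
    """Map a free-form gene label onto the controlled vocabulary.

    Unknown labels pass through unchanged (validation reports them as
    deviations from the canonical set rather than failing).
    """
    name = raw.strip()
    if name in CANONICAL_GENES:
        return name
    key = name.upper().replace(" ", "").replace("_", "")
    if key in _NAME_ALIASES:
        mapped = _NAME_ALIASES[key]
        logger.debug("normalized gene name %r -> %r", raw, mapped)
        return mapped
    # bare tRNA one-letter forms, e.g. "trnI" / "tRNA-Ile" handled above;
    # try "TRNX" without subscript
    if key.startswith("TRN") and len(key) == 4 and f"trn{key[3]}" in CANONICAL_GENES:
        return f"trn{key[3]}"
    return name


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GeneFeature:
    """One annotated feature on the circular genome (1-based inclusive)."""

    name: str
    ftype: FeatureType
    strand: Strand
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    part: Optional[int] = None  # set for origin-spanning two-row features

    def __post_init__(self) -> None:
        self.ftype = FeatureType(self.ftype)
        self.strand = Strand(self.strand)
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start {self.start} < 1")
        if self.start > self.end:
            raise AnnotationError(
                f"{self.name}: start {self.start} > end {self.end} "
                "(origin-spanning features must use the two-row 'part' convention)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: optional sequence plus ordered annotation."""

    record_id: str
    organism: str = ""
    genome_length: int = 0
    circular: bool = True
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.genome_length == 0:
                self.genome_length = len(self.sequence)

    # -- lookups ---------------------------------------------------------
    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.record_id}: no feature named {name!r}")

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def features_sorted(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    @property
    def control_feature(self) -> Optional[GeneFeature]:
        for f in self.features:
            if f.ftype is FeatureType.CONTROL:
                return f
        return None

    # -- validation ------------------------------------------------------
    def validate(self) -> list[str]:
        """Check hard invariants (raises) and report soft deviations.

        Returns a list of warning strings; each is also logged. The 37+1
        canonical feature complement is a warning, not an error, so partial
        or rearranged genomes remain usable.
        """
        warnings: list[str] = []
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise AnnotationError(
                f"{self.record_id}: sequence length {len(self.sequence)} != "
                f"declared genome length {self.genome_length}"
            )
        for f in self.features:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"{self.record_id}: {f.name} ends at {f.end}, beyond "
                    f"genome length {self.genome_length}"
                )
        n_control = sum(1 for f in self.features
                        if f.ftype is FeatureType.CONTROL and f.part in (None, 1))
        if n_control > 1:
            raise AnnotationError(f"{self.record_id}: {n_control} control regions")
        names = [f.name for f in self.features if f.part is None]
        present = set(names)
        missing = CANONICAL_GENES - present
        extra = present - CANONICAL_GENES
        if missing:
            warnings.append(f"missing canonical features: {sorted(missing)}")
        if extra:
            warnings.append(f"non-canonical features: {sorted(extra)}")
        dup = {n for n in present if names.count(n) > 1}
        if dup:
            warnings.append(f"duplicated features: {sorted(dup)}")
        if not self.features:
            warnings.append("record has no features")
        for w in warnings:
            logger.warning("%s: %s", self.record_id, w)
        return warnings


# ---------------------------------------------------------------------------
# GenBank ingestion
# ---------------------------------------------------------------------------

_GB_TYPE_MAP = {"CDS": FeatureType.PCG, "tRNA": FeatureType.TRNA,
                "rRNA": FeatureType.RRNA}


def read_genbank(path: PathLike) -> MitogenomeRecord:
    """Read one annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA features and the A+T-rich region (``misc_feature`` or
    ``D-loop``) are mapped onto :class:`GeneFeature`; ``complement()``
    locations become minor-strand features.
    """
    try:
        gb = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises plain ValueError
        raise AnnotationError(f"cannot parse GenBank file {path}: {exc}") from exc

    features: list[GeneFeature] = []
    for feat in gb.features:
        if feat.type in _GB_TYPE_MAP:
            ftype = _GB_TYPE_MAP[feat.type]
            raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                   or ["?"])[0]
        elif feat.type in ("misc_feature", "D-loop"):
            note = " ".join(feat.qualifiers.get("note", [])) or feat.type
            if "A+T" not in note and feat.type != "D-loop" \
                    and "control" not in note.lower():
                continue
            ftype = FeatureType.CONTROL
            raw = CONTROL_NAME
        else:
            continue
        name = normalize_gene_name(raw)
        if ftype is FeatureType.CONTROL:
            name = CONTROL_NAME
        loc = feat.location
        features.append(GeneFeature(
            name=name,
            ftype=ftype,
            strand=Strand.MINOR if loc.strand == -1 else Strand.MAJOR,
            start=int(loc.start) + 1,
            end=int(loc.end),
            anticodon=(feat.qualifiers.get("anticodon") or [None])[0],
        ))
    if not features:
        logger.warning("%s: GenBank file contains no usable features", gb.id)
    seq = str(gb.seq).upper() if len(gb.seq) else None
    rec = MitogenomeRecord(
        record_id=gb.id or gb.name,
        organism=gb.annotations.get("organism", ""),
        genome_length=len(gb.seq) if len(gb.seq) else 0,
        sequence=seq,
        features=features,
    )
    if rec.genome_length == 0 and features:
        rec.genome_length = max(f.end for f in features)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Feature-table TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("name", "ftype", "strand", "start", "end",
                "anticodon", "start_codon", "stop_codon")


def read_feature_table(tsv: PathLike, fasta: Optional[PathLike] = None,
                       record_id: Optional[str] = None) -> MitogenomeRecord:
    """Read a record from a feature-table TSV, optionally with its FASTA.

    The header may carry ``#genome_length=<N>``, ``#record_id=`` and
    ``#organism=`` lines; genome length defaults to ``max(end)``.
    """
    genome_length = 0
    rid = record_id or Path(tsv).stem
    organism = ""
    features: list[GeneFeature] = []
    with open(tsv, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip().lower()
                    if key == "genome_length":
                        genome_length = int(val.strip())
                    elif key == "record_id" and record_id is None:
                        rid = val.strip()
                    elif key == "organism":
                        organism = val.strip()
                continue
            cols = line.split("\t")
            if cols[0] == "name":  # column header row
                continue
            if len(cols) < 5:
                raise AnnotationError(f"{tsv}:{lineno}: expected >=5 columns")
            cols += [""] * (len(_TSV_COLUMNS) - len(cols))
            name, ftype, strand, start, end, anticodon, startc, stopc = \
                cols[:len(_TSV_COLUMNS)]
            part = None
            if ":" in name:  # origin-spanning rows: "name:part1"
                name, _, tag = name.partition(":")
                part = int(tag.replace("part", ""))
            try:
                feat = GeneFeature(
                    name=normalize_gene_name(name),
                    ftype=FeatureType(ftype),
                    strand=Strand(strand),
                    start=int(start),
                    end=int(end),
                    anticodon=anticodon or None,
                    start_codon=startc or None,
                    stop_codon=stopc or None,
                    part=part,
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{tsv}:{lineno}: {exc}") from exc
            features.append(feat)

    seen: set[tuple[str, Optional[int]]] = set()
    for f in features:
        key = (f.name, f.part)
        if key in seen:
            raise AnnotationError(f"{tsv}: duplicate feature row for {f.name!r}")
        seen.add(key)

    if genome_length == 0 and features:
        genome_length = max(f.end for f in features)

    sequence = None
    if fasta is not None:
        fa = SeqIO.read(str(fasta), "fasta")
        sequence = str(fa.seq).upper()
        if len(sequence) != genome_length:
            raise AnnotationError(
                f"FASTA length {len(sequence)} != genome length {genome_length}"
            )
    rec = MitogenomeRecord(record_id=rid, organism=organism,
                           genome_length=genome_length, sequence=sequence,
                           features=features)
    rec.validate()
    return rec


def write_feature_table(rec: MitogenomeRecord, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#genome_length={rec.genome_length}\n")
        fh.write(f"#record_id={rec.record_id}\n")
        if rec.organism:
            fh.write(f"#organism={rec.organism}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in rec.features:
            name = f.name if f.part is None else f"{f.name}:part{f.part}"
            fh.write("\t".join([
                name, f.ftype.value, f.strand.value, str(f.start), str(f.end),
                f.anticodon or "", f.start_codon or "", f.stop_codon or "",
            ]) + "\n")


def write_fasta(rec: MitogenomeRecord, path: PathLike) -> None:
    if rec.sequence is None:
        raise AnnotationError(f"{rec.record_id}: no sequence to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{rec.record_id} {rec.organism}\n".rstrip() + "\n")
        for i in range(0, len(rec.sequence), 70):
            fh.write(rec.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_gene_sequence(rec: MitogenomeRecord, name: str) -> str:
    """Return a feature's sequence in reading orientation.

    Minor-strand features are reverse-complemented; origin-spanning two-part
    features are concatenated in part order before orientation.
    """
    if rec.sequence is None:
        raise AnnotationError(f"{rec.record_id}: record has no sequence")
    parts = [f for f in rec.features if f.name == name]
    if not parts:
        raise KeyError(f"{rec.record_id}: no feature named {name!r}")
    parts.sort(key=lambda f: (f.part or 0))
    seq = "".join(rec.sequence[f.start - 1:f.end] for f in parts)
    if parts[0].strand is Strand.MINOR:
        seq = reverse_complement(seq)
    return seq


def rotate_record(rec: MitogenomeRecord, offset: int) -> MitogenomeRecord:
    """Rotate the circular origin by ``offset`` bp (new origin at offset+1).

    Features that would span the new origin are split into two part rows.
    Used by rotation-invariance checks and the generator.
    """
    n = rec.genome_length
    offset %= n
    if offset == 0:
        return rec
    seq = None
    if rec.sequence is not None:
        seq = rec.sequence[offset:] + rec.sequence[:offset]
    feats: list[GeneFeature] = []
    for f in rec.features:
        s = (f.start - 1 - offset) % n + 1
        e = (f.end - 1 - offset) % n + 1
        if s <= e:
            feats.append(replace(f, start=s, end=e))
        else:  # wraps the new origin
            feats.append(replace(f, start=s, end=n, part=1))
            feats.append(replace(f, start=1, end=e, part=2))
    return MitogenomeRecord(record_id=rec.record_id, organism=rec.organism,
                            genome_length=n, circular=rec.circular,
                            sequence=seq, features=feats)
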