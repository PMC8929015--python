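"""Coordinate conventions, format round-trips and GenBank ingestion."""

from __future__ import annotations

import pytest

from mitocomp.annotation_io import (
    AnnotationError,
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    Strand,
    extract_gene_sequence,
    normalize_gene_name,
    read_feature_table,
    read_genbank,
    reverse_complement,
    rotate_record,
    write_feature_table,
)
from mitocomp.synthetic_data import SimConfig, simulate_mitogenome

# printed gene sizes of the two fully-tabulated study genomes, in genome order
H1_SIZES = [65, 69, 66, 978, 68, 64, 64, 1545, 63, 678, 70, 69, 156, 652,
            783, 65, 351, 68, 64, 65, 61, 65, 65, 1683, 65, 1332, 273, 64,
            66, 501, 1125, 63, 951, 65, 1226, 73, 717, 1788]
# the S. marginella lrRNA row prints one size in the per-gene table and
# another in the genome summary; 1204 is what its coordinates give
SM_SIZES = [62, 69, 66, 966, 65, 60, 61, 1536, 62, 681, 69, 63, 153, 652,
            783, 61, 336, 63, 61, 63, 60, 62, 63, 1680, 62, 1324, 273, 61,
            63, 498, 1122, 61, 942, 62, 1204, 70, 724, 1836]


class TestReferenceTables:
    def test_printed_sizes_match_coordinates(self, h1, sm):
        for rec, sizes in ((h1, H1_SIZES), (sm, SM_SIZES)):
            assert [f.length for f in rec.features] == sizes

    def test_h3_differs_from_h1_only_in_control_region(self, h1, h3):
        assert h3.genome_length == 16314
        pairs = zip(h1.features, h3.features)
        diffs = [(a.name, b.name) for a, b in pairs
                 if (a.start, a.end) != (b.start, b.end)]
        assert diffs == [("AT_rich", "AT_rich")]

    def test_genome_lengths_and_feature_count(self, all_refs):
        expected = {"H1": 16312, "H3": 16314, "SM": 16126}
        for key, rec in all_refs.items():
            assert rec.genome_length == expected[key]
            assert len(rec.features) == 38
            assert rec.genome_length == max(f.end for f in rec.features)

    def test_strand_assignment_matches_table(self, h1):
        minor = {f.name for f in h1.features if f.strand is Strand.MINOR}
        assert minor == {"trnQ", "trnC", "trnY", "trnF", "ND5", "trnH",
                         "ND4", "ND4L", "trnP", "ND1", "trnL1", "lrRNA",
                         "trnV", "srRNA"}


class TestFeatureTableIO:
    def test_round_trip_field_for_field(self, h1, tmp_path):
        out = tmp_path / "h1.tsv"
        write_feature_table(h1, out)
        back = read_feature_table(out)
        assert back.genome_length == h1.genome_length
        assert back.record_id == h1.record_id
        assert back.features == h1.features

    def test_single_row_table(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("trnI\ttRNA\t+\t1\t65\tGAT\t\t\n")
        rec = read_feature_table(path)
        assert rec.features[0].length == 65
        assert rec.genome_length == 65

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("trnI\ttRNA\t+\t65\t1\t\t\t\n")
        with pytest.raises(AnnotationError, match="start"):
            read_feature_table(path)

    def test_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("trnI\ttRNA\t+\t1\t65\t\t\t\n"
                        "trnI\ttRNA\t+\t70\t134\t\t\t\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            read_feature_table(path)

    def test_fasta_length_mismatch_rejected(self, tmp_path):
        tsv = tmp_path / "r.tsv"
        tsv.write_text("#genome_length=10\ntrnI\ttRNA\t+\t1\t10\t\t\t\n")
        fa = tmp_path / "r.fasta"
        fa.write_text(">r\nACGT\n")
        with pytest.raises(AnnotationError, match="FASTA length"):
            read_feature_table(tsv, fasta=fa)


_GB = """LOCUS       TEST0001                5000 bp    DNA     circular INV 01-JAN-2021
DEFINITION  synthetic test record.
ACCESSION   TEST0001
FEATURES             Location/Qualifiers
     source          1..5000
                     /organism="test organism"
     CDS             3960..4611
                     /gene="ATP6"
     tRNA            complement(69..137)
                     /gene="trnQ"
     rRNA            complement(1000..1700)
                     /product="12S ribosomal RNA"
     misc_feature    4700..5000
                     /note="A+T-rich region"
ORIGIN
        1 {seq}
//
"""


def _write_genbank(tmp_path, n=5000):
    seq = ("acgt" * ((n // 4) + 1))[:n]
    lines = []
    for i in range(0, n, 60):
        chunk = seq[i:i + 60]
        spaced = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {spaced}")
    body = _GB.replace("        1 {seq}", "\n".join(lines))
    path = tmp_path / "test.gb"
    path.write_text(body)
    return path


class TestGenBank:
    def test_features_mapped_with_strands(self, tmp_path):
        rec = read_genbank(_write_genbank(tmp_path))
        atp6 = rec.feature("ATP6")
        assert (atp6.ftype, atp6.strand, atp6.start, atp6.end) == \
            (FeatureType.PCG, Strand.MAJOR, 3960, 4611)
        trnq = rec.feature("trnQ")
        assert (trnq.strand, trnq.start, trnq.end) == (Strand.MINOR, 69, 137)
        assert rec.feature("srRNA").ftype is FeatureType.RRNA
        assert rec.control_feature is not None
        assert rec.sequence is not None and len(rec.sequence) == 5000

    def test_empty_features_block_warns_not_fails(self, tmp_path):
        text = _write_genbank(tmp_path).read_text()
        head, _, tail = text.partition("FEATURES")
        _, _, origin = tail.partition("ORIGIN")
        stripped = head + ("FEATURES             Location/Qualifiers\n"
                           "ORIGIN") + origin
        path = tmp_path / "empty.gb"
        path.write_text(stripped)
        rec = read_genbank(path)
        assert rec.features == []

    def test_malformed_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "junk.gb"
        path.write_text("this is not a genbank file\n")
        with pytest.raises(AnnotationError, match="cannot parse"):
            read_genbank(path)


class TestNameNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("COX1", "COI"), ("cox3", "COIII"), ("COB", "CytB"),
        ("s-rRNA", "srRNA"), ("16S rRNA", "lrRNA"), ("NAD4L", "ND4L"),
        ("trnL(taa)", "trnL2"), ("trnS(gct)", "trnS1"), ("D-loop", "AT_rich"),
        ("trnI", "trnI"), ("ND2", "ND2"),
    ])
    def test_aliases(self, raw, expected):
        assert normalize_gene_name(raw) == expected


class TestExtraction:
    def _mini(self):
        return MitogenomeRecord(
            record_id="mini", genome_length=5, sequence="ATGCC",
            features=[
                GeneFeature("g+", FeatureType.TRNA, Strand.MAJOR, 1, 3),
                GeneFeature("g-", FeatureType.TRNA, Strand.MINOR, 1, 3),
            ])

    def test_major_and_minor_extraction(self):
        rec = self._mini()
        assert extract_gene_sequence(rec, "g+") == "ATG"
        assert extract_gene_sequence(rec, "g-") == "CAT"

    def test_minor_equals_revcomp_of_major(self, sim_plain):
        rec, _ = sim_plain
        span = rec.feature("ND5")
        major_letters = rec.sequence[span.start - 1:span.end]
        assert extract_gene_sequence(rec, "ND5") == \
            reverse_complement(major_letters)

    def test_missing_sequence_and_unknown_gene(self, h1):
        with pytest.raises(AnnotationError):
            extract_gene_sequence(h1, "COI")  # coordinates-only fixture
        rec, _ = simulate_mitogenome(SimConfig(seed=30, repeats=()))
        with pytest.raises(KeyError):
            extract_gene_sequence(rec, "nonexistent")

    def test_planted_gtg_start_is_extracted(self):
        rec, _ = simulate_mitogenome(
            SimConfig(seed=31, repeats=(), start_codons={"ND5": "GTG"}))
        assert extract_gene_sequence(rec, "ND5").startswith("GTG")

    def test_rotation_preserves_extracted_sequences(self, sim_plain):
        rec, _ = sim_plain
        rot = rotate_record(rec, 4321)
        for gene in ("COI", "ND5", "trnI", "lrRNA"):
            assert extract_gene_sequence(rot, gene) == \
                extract_gene_sequence(rec, gene)


def test_generator_output_passes_validation(sim_default):
    rec, _ = sim_default
    warnings = rec.validate()
    assert not any("missing canonical" in w for w in warnings)
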