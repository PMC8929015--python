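"""Base content, strand skew, codon usage and start/stop codon tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.annotation_io import (
    FeatureType,
    GeneFeature,
    MitogenomeRecord,
    Strand,
    reverse_complement,
    rotate_record,
)
from mitocomp.composition import (
    base_content,
    codon_usage,
    coding_codons,
    expected_codon_count,
    skew,
    start_stop_table,
    strand_set_skew,
)
from mitocomp.synthetic_data import SimConfig, simulate_mitogenome

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestBaseContent:
    def test_simple_compositions(self):
        bc = base_content("ATAT")
        assert bc["A"] == 50.0 and bc["T"] == 50.0
        assert all(v == 25.0 for v in base_content("ACGT").values())

    def test_n_positions_excluded(self):
        bc = base_content("AANN")
        assert bc["A"] == 100.0

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            base_content("NNNN")
        with pytest.raises(ValueError):
            base_content("")

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_percentages_sum_to_100(self, seq):
        assert sum(base_content(seq).values()) == pytest.approx(100.0,
                                                                abs=1e-9)


class TestSkew:
    def test_known_values(self):
        assert skew("AAAT").at_skew == pytest.approx(0.5)
        assert skew("GGC").gc_skew == pytest.approx(1 / 3)

    def test_zero_denominator_flagged_missing(self):
        pair = skew("AAAA")
        assert pair.gc_skew is None and pair.at_skew == 1.0

    def test_antisymmetry_under_reverse_complement(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            n = int(rng.integers(4, 120))
            seq = "".join(bases[rng.integers(0, 4, n)])
            fwd, rev = skew(seq), skew(reverse_complement(seq))
            if fwd.at_skew is not None:
                assert rev.at_skew == pytest.approx(-fwd.at_skew)
            if fwd.gc_skew is not None:
                assert rev.gc_skew == pytest.approx(-fwd.gc_skew)

    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_antisymmetry_property(self, seq):
        fwd, rev = skew(seq), skew(reverse_complement(seq))
        for a, b in ((fwd.at_skew, rev.at_skew), (fwd.gc_skew, rev.gc_skew)):
            if a is None:
                assert b is None
            else:
                assert b == pytest.approx(-a)


class TestStrandSetSkew:
    def test_missing_gene_named_in_error(self, sim_plain):
        rec, _ = sim_plain
        crippled = MitogenomeRecord(
            record_id="x", genome_length=rec.genome_length,
            sequence=rec.sequence,
            features=[f for f in rec.features if f.name != "ND3"])
        with pytest.raises(ValueError, match="ND3"):
            strand_set_skew(crippled, "major_PCG")

    def test_minor_strand_reads_t_rich_on_major_strand(self):
        rec, _ = simulate_mitogenome(
            SimConfig(seed=3, repeats=(),
                      minor_strand_bias=(0.76, -0.45, 0.30)))
        minor = strand_set_skew(rec, "minor_PCG")
        major = strand_set_skew(rec, "major_PCG")
        assert minor.at_skew < -0.35  # profound T-skew, as planted
        assert major.at_skew > 0.15

    def test_unknown_basis_rejected(self, sim_plain):
        rec, _ = sim_plain
        with pytest.raises(ValueError, match="basis"):
            strand_set_skew(rec, "everything")

    def test_generator_hits_whole_genome_targets(self):
        # 15-kb genomes, uniform composition config: targets within +/-0.02
        for seed in (0, 1, 2):
            rec, truth = simulate_mitogenome(
                SimConfig(seed=seed, genome_length=15000, repeats=(),
                          control_tail=20))
            got = skew(rec.sequence)
            t = truth.targets
            assert got.at_skew == pytest.approx(t["at_skew"], abs=0.02)
            assert got.gc_skew == pytest.approx(t["gc_skew"], abs=0.02)
            bc = base_content(rec.sequence)
            assert (bc["A"] + bc["T"]) / 100 == pytest.approx(
                t["at_content"], abs=0.02)


def _single_cds_record(cds: str, name: str = "COI") -> MitogenomeRecord:
    return MitogenomeRecord(
        record_id="cds", genome_length=len(cds), sequence=cds,
        features=[GeneFeature(name, FeatureType.PCG, Strand.MAJOR, 1,
                              len(cds))])


class TestCodonUsage:
    def test_single_cds_with_terminal_stop(self):
        table = codon_usage(_single_cds_record("TTATTATTATAA"))
        assert table.counts == {"TTA": 3}
        assert table.total_codons == 3
        assert table.frequencies["TTA"] == pytest.approx(100.0)

    def test_truncated_trailing_codon_dropped(self):
        # 3 codons + 2 leftover nt: the remainder is not counted
        table = codon_usage(_single_cds_record("ATGAAACCCGG"))
        assert table.total_codons == 3

    def test_top4_share_near_uniform_expectation(self):
        rng = np.random.default_rng(5)
        sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG")]
        cds = "".join(rng.choice(sense, 20000)) + "TAA"
        table = codon_usage(_single_cds_record(cds))
        top4 = sum(f for _, f in table.top(4))
        # uniform codons: expect ~4/62 of the mass on any four codons
        assert top4 == pytest.approx(100 * 4 / 62, abs=1.5)

    def test_total_matches_coordinate_convention(self, sim_default):
        rec, _ = sim_default
        assert codon_usage(rec).total_codons == expected_codon_count(rec)

    def test_frequencies_sum_to_100(self, sim_default):
        rec, _ = sim_default
        assert sum(codon_usage(rec).frequencies.values()) == pytest.approx(
            100.0, abs=1e-9)

    def test_invariant_under_rotation(self, sim_plain):
        rec, _ = sim_plain
        assert codon_usage(rotate_record(rec, 7777)).counts == \
            codon_usage(rec).counts

    def test_coding_codons_convention(self):
        assert coding_codons("ATGAAATAA") == ["ATG", "AAA"]
        assert coding_codons("ATGAAAT") == ["ATG", "AAA"]  # truncated "T"
        assert coding_codons("ATGAAA") == ["ATG", "AAA"]  # no stop at all


class TestStartStop:
    def test_simple_cds(self):
        table = start_stop_table(_single_cds_record("ATGAAATAA"))
        entry = table["COI"]
        assert (entry.start_codon, entry.stop_codon) == ("ATG", "TAA")
        assert entry.canonical_start

    def test_truncated_stop_reported(self, sim_default):
        rec, truth = sim_default
        table = start_stop_table(rec)
        assert table["ATP6"].stop_codon == "T"
        for gene, stop in truth.stop_codons.items():
            assert table[gene].stop_codon == stop

    def test_non_canonical_start_flagged(self):
        table = start_stop_table(_single_cds_record("CTGAAATAA"))
        assert not table["COI"].canonical_start
        assert start_stop_table(
            _single_cds_record("GTGAAATAA"))["COI"].canonical_start

    def test_too_short_pcg_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            start_stop_table(_single_cds_record("ATGAA"))

    def test_generator_start_codons_respected(self):
        rec, truth = simulate_mitogenome(
            SimConfig(seed=31, repeats=(), start_codons={"ND5": "GTG"}))
        assert start_stop_table(rec)["ND5"].start_codon == "GTG"
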