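"""Tandem-repeat detection, control-region architecture, unit comparison."""

from __future__ import annotations

import numpy as np
import pytest

from mitocomp.control_region import (
    architecture,
    compare_repeat_units,
    find_polyruns,
    find_tandem_repeats,
)
from mitocomp.synthetic_data import RepeatSpec, SimConfig, simulate_mitogenome


def _rand(rng, n, at=0.5):
    p = [at * 0.5, (1 - at) * 0.5, (1 - at) * 0.5, at * 0.5]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestFindTandemRepeats:
    def test_21bp_unit_pasted_20_times(self):
        rng = np.random.default_rng(0)
        unit = _rand(rng, 21)
        seq = _rand(rng, 50) + unit * 20 + _rand(rng, 50)
        arrays = find_tandem_repeats(seq)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.unit_length == 21
        assert arr.copies == 20.0
        assert arr.identity == 1.0
        assert not arr.truncated_final
        assert (arr.start, arr.end) == (51, 470)

    def test_fractional_final_copy(self):
        rng = np.random.default_rng(1)
        unit = _rand(rng, 20)
        arrays = find_tandem_repeats(unit * 2 + unit[:10])
        assert len(arrays) == 1
        assert arrays[0].copies == 2.5
        assert arrays[0].truncated_final

    def test_truncated_composite_triplication(self):
        # AB AB A: the third copy lacks unit B
        rng = np.random.default_rng(2)
        a, b = _rand(rng, 40), _rand(rng, 30)
        seq = _rand(rng, 30) + (a + b) * 2 + a + _rand(rng, 30)
        arrays = find_tandem_repeats(seq)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.unit_length == 70
        assert arr.copies == pytest.approx(2.6, abs=0.1)
        assert arr.truncated_final

    def test_reported_arrays_actually_qualify(self):
        # oracle-style verification: every reported array re-checks against
        # the declarative definition, computed directly here
        rng = np.random.default_rng(3)
        unit = _rand(rng, 15)
        seq = _rand(rng, 200) + unit * 4 + _rand(rng, 200)
        for arr in find_tandem_repeats(seq):
            u = arr.unit_length
            span = seq[arr.start - 1:arr.end]
            full = len(span) // u
            assert full >= 2
            assert len(span) / u == pytest.approx(arr.copies, abs=0.05)
            matches = sum(span[k * u + c] == arr.consensus[c]
                          for k in range(full) for c in range(u))
            assert matches / (full * u) == pytest.approx(arr.identity)
            assert arr.identity >= 0.85

    def test_random_sequence_agrees_with_bruteforce_oracle(self):
        # uniform random 1-kb: an exhaustive window enumeration finds no
        # pair of adjacent near-identical copies, and neither does the
        # scanner
        rng = np.random.default_rng(4)
        for _ in range(3):
            seq = _rand(rng, 1000)
            found = find_tandem_repeats(seq, min_unit=10, min_identity=0.85,
                                        min_copies=2.0)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            oracle_hits = []
            for u in range(10, 201):
                if 2 * u > len(seq):
                    break
                m = (arr[:-u] == arr[u:]).astype(int)
                window = np.convolve(m, np.ones(u, dtype=int), "valid")
                hits = np.nonzero(window / u >= 0.85)[0]
                oracle_hits.extend((int(s), u) for s in hits)
            assert [(a.start, a.unit_length) for a in found] == []
            assert oracle_hits == []

    def test_planted_recovery_over_many_random_plantings(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            u = int(rng.integers(10, 60))
            copies = float(rng.uniform(2.2, 8))
            unit = _rand(rng, u)
            full = int(copies)
            arr = unit * full + unit[:int(round((copies - full) * u))]
            seq = _rand(rng, 60) + arr + _rand(rng, 60)
            found = find_tandem_repeats(seq)
            hit = [r for r in found if r.unit_length == u]
            assert hit, f"unit {u} not recovered"
            assert abs(hit[0].copies - len(arr) / u) <= 0.5
            assert abs(hit[0].start - 61) <= u / 2

    def test_mirror_under_reversal(self):
        rng = np.random.default_rng(5)
        unit = _rand(rng, 25)
        seq = _rand(rng, 80) + unit * 5 + _rand(rng, 80)
        fwd = find_tandem_repeats(seq)
        rev = find_tandem_repeats(seq[::-1])
        n = len(seq)
        assert [(n - a.end + 1, n - a.start + 1, a.unit_length)
                for a in reversed(fwd)] == \
            [(a.start, a.end, a.unit_length) for a in rev]

    def test_too_short_sequence_returns_empty(self):
        assert find_tandem_repeats("ACGTACGTACG", min_unit=10) == []


class TestArchitecture:
    def test_four_region_structure_of_default_genome(self, sim_default):
        rec, truth = sim_default
        arch = architecture(rec)
        assert [s.label for s in arch.segments] == \
            ["repeat", "nonrepeat", "repeat", "nonrepeat"]
        for det, tru in zip(arch.repeats, truth.repeats):
            assert det.unit_length == tru["unit_length"]
            assert abs(det.copies - tru["copies"]) <= 0.5
            assert abs(det.start - tru["start"]) <= tru["unit_length"] / 2

    def test_segments_tile_the_region_exactly(self, sim_default):
        rec, _ = sim_default
        arch = architecture(rec)
        assert arch.segments[0].start == 1
        assert arch.segments[-1].end == arch.region_length
        for a, b in zip(arch.segments, arch.segments[1:]):
            assert b.start == a.end + 1
        assert sum(s.end - s.start + 1 for s in arch.segments) == \
            arch.region_length

    def test_per_segment_at_content_near_planted(self):
        # long units so quota rounding keeps segment AT% close to target
        rec, truth = simulate_mitogenome(SimConfig(
            seed=60,
            repeats=(RepeatSpec(unit_length=60, copies=3.0, at_content=0.64),
                     RepeatSpec(unit_length=84, copies=5.0,
                                at_content=0.64)),
            core_at_content=0.88))
        arch = architecture(rec)
        by_label = {}
        for s in arch.segments:
            by_label.setdefault(s.label, []).append(s)
        for s in by_label["repeat"]:
            assert s.at_percent == pytest.approx(64.0, abs=1.0)
        core = max(by_label["nonrepeat"],
                   key=lambda s: s.end - s.start + 1)
        assert core.at_percent == pytest.approx(88.0, abs=1.0)

    def test_random_region_is_single_nonrepeat_segment(self):
        rng = np.random.default_rng(6)
        rec, _ = simulate_mitogenome(SimConfig(seed=61, repeats=()))
        # replace the control region with uniform random sequence
        ctrl = rec.control_feature
        rand = _rand(rng, ctrl.length)
        seq = (rec.sequence[:ctrl.start - 1] + rand
               + rec.sequence[ctrl.end:])
        rec2 = type(rec)(record_id="r", genome_length=rec.genome_length,
                         sequence=seq, features=rec.features)
        arch = architecture(rec2)
        assert [s.label for s in arch.segments] == ["nonrepeat"]

    def test_polyruns_reported(self, sim_default):
        rec, _ = sim_default
        arch = architecture(rec)
        patterns = {p.pattern for p in arch.polyruns}
        assert {"A", "T", "AT"} <= patterns
        assert any(p.pattern == "A" and p.length >= 23 for p in arch.polyruns)

    def test_control_feature_required(self, sim_plain):
        rec, _ = sim_plain
        rec2 = type(rec)(record_id="x", genome_length=rec.genome_length,
                         sequence=rec.sequence,
                         features=[f for f in rec.features
                                   if f.name != "AT_rich"])
        with pytest.raises(ValueError, match="control"):
            architecture(rec2)


class TestPolyruns:
    def test_oracle_comparison(self):
        import re

        seq = "GGAAAAAAAAGGTTTTTTTTTTGGATATATATATGG"
        runs = find_polyruns(seq, min_length=8)
        got = {(r.pattern, r.start, r.length) for r in runs}
        expected = set()
        for pat, rx in (("A", r"A{8,}"), ("T", r"T{8,}"),
                        ("AT", r"(?:AT){4,}A?|(?:TA){4,}T?")):
            for m in re.finditer(rx, seq):
                if len(m.group()) >= 8:
                    expected.add((pat, m.start() + 1, len(m.group())))
        assert got == expected

    def test_pure_runs_take_precedence(self):
        runs = find_polyruns("AAAAAAAAAA", min_length=8)
        assert [(r.pattern, r.length) for r in runs] == [("A", 10)]


class TestCompareRepeatUnits:
    def test_identical_units_fully_alignable(self):
        mat, verdict = compare_repeat_units(["ACGTAACCGGTT" * 4] * 3)
        assert mat.min() == 1.0 and verdict

    def test_random_units_not_alignable(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(10):
            units = [_rand(rng, 60), _rand(rng, 60)]
            mat, verdict = compare_repeat_units(units)
            vals.append(mat[0, 1])
            assert not verdict
        assert np.mean(vals) < 0.55  # near-background identity

    def test_planted_divergence_reflected_in_matrix(self):
        rng = np.random.default_rng(8)
        base = _rand(rng, 60)
        variants = [base]
        for k in (2, 6, 18):  # increasing substitution loads
            v = list(base)
            for pos in rng.choice(60, size=k, replace=False):
                v[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[pos]]
            variants.append("".join(v))
        mat, verdict = compare_repeat_units(variants)
        assert verdict
        assert mat[0, 1] > mat[0, 2] > mat[0, 3]
        assert mat[0, 1] == pytest.approx(58 / 60, abs=0.02)

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="two"):
            compare_repeat_units(["ACGT"])
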