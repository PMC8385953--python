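"""Origin classification, RPM normalization, induction, set comparisons."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cksrna.classify import (ExpressionRecord, ORIGINS, build_expression,
                             classify_origin, compare_sets, compute_log2fc,
                             rpm_normalize, select_induced)
from cksrna.mapper import PresenceFlags


def _flags(seq="A" * 21, plant=False, fungus=False, structural=False):
    return PresenceFlags(seq, plant, fungus, structural, [])


@pytest.mark.parametrize(
    "plant,fungus,structural,expected",
    [
        (True, False, False, "plant"),
        (False, True, False, "fungus"),
        (True, True, False, "ambiguous"),
        (False, False, False, "unmapped"),
        (True, True, True, "structural"),  # structural wins over presence
    ],
)
def test_classify_origin(plant, fungus, structural, expected):
    call = classify_origin(_flags(plant=plant, fungus=fungus,
                                  structural=structural), "Bd-Si")
    assert call.origin == expected and call.origin in ORIGINS


class TestRpm:
    def test_example(self):
        assert rpm_normalize(5, 1000) == 5000.0

    def test_full_library(self):
        assert rpm_normalize(1000, 1000) == 1e6

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(11, 10)


class TestLog2FC:
    def test_basic_ratios(self):
        assert compute_log2fc(40, 10) == 2.0
        assert compute_log2fc(7, 7) == 0.0

    def test_colonized_exclusive_is_na(self):
        assert compute_log2fc(12.5, 0) is None

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_log2fc(0, 0)

    @given(st.floats(0.01, 1e5), st.floats(0.01, 1e5))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert math.isclose(compute_log2fc(a, b), -compute_log2fc(b, a),
                            rel_tol=0, abs_tol=1e-9)


class TestSelectInduced:
    def _rec(self, seq, fc):
        return ExpressionRecord(seq, "plant", 10.0, 5.0, fc)

    def test_downregulated_dropped(self):
        assert select_induced([self._rec("A" * 21, -0.5)]) == []

    def test_exclusive_retained_with_length_filter(self):
        rec = self._rec("C" * 21, None)
        assert select_induced([rec], 21) == [rec]
        assert select_induced([self._rec("C" * 22, None)], 21) == []

    def test_high_flag_is_log2fc_above_one(self):
        recs = select_induced([self._rec("A" * 21, 0.5),
                               self._rec("C" * 21, 1.5),
                               self._rec("G" * 21, None)])
        assert [r.high for r in recs] == [False, True, False]

    def test_no_length_filter(self):
        recs = select_induced([self._rec("A" * 18, 0.1)], length_filter=None)
        assert len(recs) == 1


class TestCompareSets:
    def test_small_example(self):
        cmp = compare_sets({"a", "b", "c"}, {"c", "d"})
        assert (cmp.exclusive_a, cmp.shared, cmp.exclusive_b) == (2, 1, 1)
        assert cmp.pct_shared == 25.0

    def test_identical_sets(self):
        cmp = compare_sets({"a", "b"}, {"a", "b"})
        assert (cmp.exclusive_a, cmp.shared, cmp.exclusive_b) == (0, 2, 0)
        assert cmp.pct_shared == 100.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_sets(set(), set())

    def test_matches_brute_force_on_random_sets(self):
        rng = random.Random(0)
        universe = [f"seq{i}" for i in range(10_000)]
        a = {s for s in universe if rng.random() < 0.3}
        b = {s for s in universe if rng.random() < 0.4}
        cmp = compare_sets(a, b)
        assert cmp.exclusive_a == len(a - b)
        assert cmp.exclusive_b == len(b - a)
        assert cmp.shared == len(a & b)
        assert abs(cmp.pct_exclusive_a + cmp.pct_exclusive_b
                   + cmp.pct_shared - 100.0) < 0.2


class TestBuildExpression:
    def test_control_only_reads_excluded(self):
        origin = {"A" * 21: "plant", "C" * 21: "plant"}
        recs = build_expression({"A" * 21: 10}, {"A" * 21: 5, "C" * 21: 5},
                                origin, "plant")
        assert [r.seq for r in recs] == ["A" * 21]

    def test_rpm_uses_per_organism_totals(self):
        origin = {"A" * 21: "plant", "C" * 21: "fungus"}
        recs = build_expression({"A" * 21: 10, "C" * 21: 90},
                                {"A" * 21: 10}, origin, "plant")
        assert recs[0].rpm_colonized == 1e6  # plant total is 10, not 100


class TestPipelinePartition:
    """Sample-level conservation on the synthetic dataset."""

    def test_origin_classes_partition_all_reads(self, result):
        for sample, part in result.partitions.items():
            total_raw = sum(result.sample_counts[sample].values())
            total_unique = sum(1 for n in result.sample_counts[sample].values()
                               if n > 0)
            assert sum(part["raw"].values()) == total_raw
            assert sum(part["unique"].values()) == total_unique

    def test_per_organism_rpm_sums_to_one_million(self, result):
        for org in ("plant", "fungus"):
            colonized = result.sample_counts["Bd-Si"]
            total = sum(
                rec.rpm_colonized for rec in build_expression(
                    colonized, colonized, result.origin_of, org)
            )
            assert total == pytest.approx(1e6, rel=1e-6)

    def test_noise_free_origins_match_truth(self, result):
        truth_plant = set()
        truth_fungus = set()
        ds = result.dataset
        for ck in ds.truth.planted_ck:
            (truth_plant if ck.origin_organism == "plant"
             else truth_fungus).add(ck.srna_seq)
        for seq in truth_plant:
            assert result.origin_of[seq] == "plant"
        for seq in truth_fungus:
            assert result.origin_of[seq] == "fungus"
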