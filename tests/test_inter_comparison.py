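"""Cross-data-set comparisons: scaled medians, overlap curves, biomarkers."""

import random

import pytest

from mqbench import (
    biomarker_matching,
    full_profile_accessions,
    match_accession,
    overlap_curve,
    read_panel,
    scaled_median_comparison,
)

import oracles
from conftest import make_bundle, make_runs, pg, random_bundle


class TestScaledMedianComparison:
    def test_published_style_medians(self):
        # protein-ID medians of 613 vs 707 on the max=100 scale
        cmp = scaled_median_comparison([613.0], [707.0], "protein_ids")
        assert cmp.scaled_b == 100.0
        assert cmp.scaled_a == pytest.approx(86.7, abs=0.05)
        assert cmp.difference == pytest.approx(13.3, abs=0.05)

    def test_equal_medians_symmetric(self):
        cmp = scaled_median_comparison([5.0, 7.0], [7.0, 5.0])
        assert (cmp.scaled_a, cmp.scaled_b) == (100.0, 100.0)
        assert cmp.difference == 0.0

    def test_hand_computed_decline(self):
        cmp = scaled_median_comparison([10.0], [5.0])
        assert (cmp.scaled_a, cmp.scaled_b) == (100.0, 50.0)
        assert cmp.difference == -50.0

    def test_both_zero_medians_undefined(self):
        cmp = scaled_median_comparison([0.0], [0.0])
        assert cmp.scaled_a is None and cmp.difference is None

    def test_scale_invariance(self):
        rng = random.Random(1)
        for _ in range(30):
            a = [rng.uniform(0, 100) for _ in range(rng.randint(1, 7))]
            b = [rng.uniform(0, 100) for _ in range(rng.randint(1, 7))]
            c = rng.uniform(0.01, 50)
            base = scaled_median_comparison(a, b)
            scaled = scaled_median_comparison([c * x for x in a], [c * x for x in b])
            assert scaled.scaled_a == pytest.approx(base.scaled_a)
            assert scaled.difference == pytest.approx(base.difference)

    def test_empty_or_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            scaled_median_comparison([], [1.0])
        with pytest.raises(ValueError):
            scaled_median_comparison([1.0], [-1.0])


class TestFullProfileAccessions:
    def test_group_accessions_expand(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs, [pg("1", ["P1", "P2"], {r: 1.0 for r in runs})], [], []
        )
        assert full_profile_accessions(bundle) == {"P1", "P2"}

    def test_ceiling_rule_at_80_percent(self):
        runs = make_runs(10)
        lfq = {r: 1.0 for r in runs[:8]}  # present in 8 of 10
        bundle = make_bundle(runs, [pg("1", ["P1"], lfq)], [], [])
        assert full_profile_accessions(bundle, 100) == set()
        assert full_profile_accessions(bundle, 80) == {"P1"}  # ceil(0.8*10)=8
        assert full_profile_accessions(bundle, 75) == {"P1"}

    def test_empty_bundle_empty_set(self):
        assert full_profile_accessions(make_bundle(make_runs(2), [], [], [])) == set()

    def test_threshold_bounds(self):
        bundle = make_bundle(make_runs(2), [], [], [])
        for bad in (0, -1, 101):
            with pytest.raises(ValueError):
                full_profile_accessions(bundle, bad)

    def test_lowering_threshold_is_monotone(self):
        rng = random.Random(8)
        for _ in range(20):
            bundle = random_bundle(rng)
            previous = set()
            for thr in (100, 80, 60, 40, 20):
                current = full_profile_accessions(bundle, thr)
                assert previous <= current
                previous = current

    def test_matches_brute_force(self):
        rng = random.Random(42)
        for _ in range(20):
            bundle = random_bundle(rng)
            for thr in (100, 80, 50):
                assert full_profile_accessions(bundle, thr) == \
                    oracles.naive_full_profile_accessions(bundle, thr)


class TestOverlapCurve:
    def test_hand_computed_curve(self):
        curve = overlap_curve([{"A", "B", "C"}, {"B", "C", "D"}, {"B"}])
        assert curve.intersection_sizes == (3, 2, 1)
        assert curve.union_sizes == (3, 4, 4)
        assert curve.relative_overlap == (100.0, 50.0, 25.0)

    def test_identical_sets_stay_at_100(self):
        s = {"A", "B"}
        curve = overlap_curve([set(s), set(s), set(s)])
        assert all(r == 100.0 for r in curve.relative_overlap)

    def test_disjoint_sets_absorb_to_zero(self):
        curve = overlap_curve([{"A"}, {"B"}, {"A", "B"}])
        assert curve.intersection_sizes == (1, 0, 0)

    def test_invariants_and_brute_force_on_random_sets(self):
        rng = random.Random(77)
        for _ in range(50):
            sets = [
                {f"P{rng.randint(0, 1000)}" for _ in range(rng.randint(0, 200))}
                for _ in range(rng.randint(1, 10))
            ]
            curve = overlap_curve(sets)
            inters, unions = oracles.naive_overlap(sets)
            assert list(curve.intersection_sizes) == inters
            assert list(curve.union_sizes) == unions
            assert list(curve.intersection_sizes) == sorted(
                curve.intersection_sizes, reverse=True
            )
            assert list(curve.union_sizes) == sorted(curve.union_sizes)
            for i, u in zip(curve.intersection_sizes, curve.union_sizes):
                assert i <= u

    def test_permutation_leaves_terminal_values(self):
        rng = random.Random(13)
        sets = [
            {f"P{rng.randint(0, 50)}" for _ in range(30)} for _ in range(6)
        ]
        base = overlap_curve(sets)
        for _ in range(5):
            perm = sets[:]
            rng.shuffle(perm)
            other = overlap_curve(perm)
            assert other.terminal_intersection == base.terminal_intersection
            assert other.terminal_union == base.terminal_union


class TestBiomarkerMatching:
    def test_exact_accession_match(self):
        assert match_accession(["P02768", "A0A024R6I7"], "A0A024R6I7")
        assert not match_accession(["P02768"], "P02768-2")
        assert not match_accession([], "P02768")

    def test_panel_reader_skips_comments(self, tmp_path):
        f = tmp_path / "panel.txt"
        f.write_text("# CSF biomarkers\nP02768\n\nP10451\n")
        assert read_panel(f) == ("P02768", "P10451")

    def _bundle(self, dataset_id, runs, groups):
        return make_bundle(runs, groups, [], [], dataset_id=dataset_id)

    def test_single_match_full_presence(self):
        runs = make_runs(3)
        bundle = self._bundle("d1", runs, [pg("1", ["P1"], {r: 1.0 for r in runs})])
        result = biomarker_matching([bundle], ["P1"])
        assert result.matched_count("d1") == 1
        assert result.presence_overall["P1"] == 100.0

    def test_presence_fraction_and_unmatched_retained(self):
        groups = lambda present: (
            [pg("1", ["P1"], {r: 1.0 for r in make_runs(2)})] if present else []
        )
        bundles = [
            self._bundle(f"d{i}", make_runs(2), groups(i < 2)) for i in range(4)
        ]
        result = biomarker_matching(bundles, ["P1", "P9"])
        assert result.presence_overall["P1"] == 50.0
        assert result.presence_overall["P9"] == 0.0  # reported, not dropped

    def test_presence_per_time_point(self):
        runs_t1 = make_runs(2, time_point="T1")
        runs_t2 = make_runs(2, time_point="T2")
        b1 = self._bundle("t1", runs_t1, [pg("1", ["P1"], {r: 1.0 for r in runs_t1})])
        b2 = self._bundle("t2", runs_t2, [])
        result = biomarker_matching([b1, b2], ["P1"])
        assert result.presence_by_time_point["T1"]["P1"] == 100.0
        assert result.presence_by_time_point["T2"]["P1"] == 0.0
        assert result.presence_overall["P1"] == 50.0

    def test_cv_annotation_and_ambiguity_flag(self):
        runs = make_runs(3)
        full = {r: v for r, v in zip(runs, [90.0, 100.0, 110.0])}
        richer = {r: v for r, v in zip(runs, [200.0, 200.0, 200.0])}
        bundle = self._bundle(
            "d", runs,
            [pg("1", ["P1"], full), pg("2", ["P1", "P2"], richer)],
        )
        result = biomarker_matching([bundle], ["P1"])
        (match,) = result.matches_by_dataset["d"]
        assert match.ambiguous
        # both groups are full profiles; the tie on quantified replicates is
        # broken by the higher median intensity -> CV of the constant group
        assert match.lfq_cv == pytest.approx(0.0)

    def test_only_full_profiles_match(self):
        runs = make_runs(3)
        bundle = self._bundle(
            "d", runs, [pg("1", ["P1"], {runs[0]: 1.0, runs[1]: 1.0})]
        )
        result = biomarker_matching([bundle], ["P1"])
        assert result.matched_count("d") == 0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            biomarker_matching([], [])
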