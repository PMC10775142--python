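"""Per-data-set performance metrics against hand counts and brute force."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mqbench import (
    completeness_profile,
    count_identifications,
    feature_cv,
    missed_cleavage_summary,
    percent_complete_profiles,
    quant_precision,
    rt_precision,
    summarize_dataset,
)
from mqbench.intra_metrics import CompletenessProfile, LEVELS

import oracles
from conftest import ev, make_bundle, make_runs, pep, pg, random_bundle


class TestCountIdentifications:
    def test_hand_counted_protein_groups(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs,
            [
                pg("A", ["A"], {runs[0]: 1.0, runs[1]: 1.0, runs[2]: 1.0}),
                pg("B", ["B"], {runs[0]: 1.0, runs[2]: 1.0}),
            ],
            [], [],
        )
        result = count_identifications(bundle, "protein_group")
        assert [result.per_replicate[r] for r in runs] == [2, 1, 2]
        assert result.median == 2

    def test_empty_bundle_counts_zero(self):
        bundle = make_bundle(make_runs(3), [], [], [])
        result = count_identifications(bundle, "precursor")
        assert all(v == 0 for v in result.per_replicate.values())
        assert result.median == 0

    def test_precursor_is_sequence_times_charge(self):
        runs = make_runs(1)
        bundle = make_bundle(
            runs, [],
            [pep("AAAK", 0, {runs[0]: 1.0})],
            [ev("_AAAK_", 2, runs[0], 1.0), ev("_AAAK_", 3, runs[0], 1.0)],
        )
        assert count_identifications(bundle, "precursor").per_replicate[runs[0]] == 2
        assert count_identifications(bundle, "peptide").per_replicate[runs[0]] == 1

    def test_unknown_level_rejected(self):
        bundle = make_bundle(make_runs(1), [], [], [])
        with pytest.raises(ValueError):
            count_identifications(bundle, "gene")


class TestMissedCleavages:
    def test_hand_computed_percent_zero(self):
        runs = make_runs(1)
        peptides = [
            pep("AK", 0, {runs[0]: 1.0}),
            pep("CK", 0, {runs[0]: 1.0}),
            pep("DK", 1, {runs[0]: 1.0}),
            pep("EK", 2, {runs[0]: 1.0}),
        ]
        summary = missed_cleavage_summary(make_bundle(runs, [], peptides, []))
        assert summary.counts == (2, 1, 1)
        assert summary.percent_zero == 50.0

    def test_all_zero_is_100(self):
        runs = make_runs(1)
        peptides = [pep(f"A{i}K", 0, {runs[0]: 1.0}) for i in range(5)]
        summary = missed_cleavage_summary(make_bundle(runs, [], peptides, []))
        assert summary.percent_zero == 100.0

    def test_no_peptides_reports_missing_not_zero(self):
        summary = missed_cleavage_summary(make_bundle(make_runs(1), [], [], []))
        assert summary.percent_zero is None


class TestCompleteness:
    def test_hand_counted_profile(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs,
            [
                pg("A", ["A"], {r: 1.0 for r in runs}),
                pg("B", ["B"], {runs[0]: 1.0, runs[1]: 1.0}),
                pg("C", ["C"], {runs[2]: 1.0}),
            ],
            [], [],
        )
        profile = completeness_profile(bundle, "protein_group")
        assert dict(profile.count_by_k) == {3: 1, 2: 1, 1: 1}
        assert percent_complete_profiles(profile) == pytest.approx(100.0 / 3.0)

    def test_full_presence_concentrates_at_n(self):
        runs = make_runs(4)
        bundle = make_bundle(
            runs, [pg(str(i), [f"P{i}"], {r: 1.0 for r in runs}) for i in range(7)],
            [], [],
        )
        profile = completeness_profile(bundle, "protein_group")
        assert dict(profile.count_by_k) == {4: 7}
        assert percent_complete_profiles(profile) == 100.0

    def test_empty_profile_percent_is_missing(self):
        profile = completeness_profile(make_bundle(make_runs(2), [], [], []),
                                       "peptide")
        assert percent_complete_profiles(profile) is None

    def test_conservation_against_distinct_feature_count(self):
        rng = random.Random(11)
        for _ in range(20):
            bundle = random_bundle(rng)
            for level in LEVELS:
                profile = completeness_profile(bundle, level)
                assert profile.total_features == len(oracles.naive_presence(bundle, level))

    def test_duplicating_a_replicate_never_lowers_percent_full(self):
        # a cloned replicate observes exactly the features of its template,
        # so every feature's profile either stays or gains the new run
        rng = random.Random(3)
        for _ in range(10):
            bundle = random_bundle(rng)
            profile = completeness_profile(bundle, "protein_group")
            base = percent_complete_profiles(profile)
            if base is None:
                continue
            runs = make_runs(len(bundle.runs) + 1)
            clone_src = bundle.runs[0]
            groups = []
            for row in bundle.protein_groups:
                lfq = {}
                for old_run, v in row.lfq_by_run.items():
                    lfq[runs[old_run.replicate_index - 1]] = v
                if clone_src in row.lfq_by_run:
                    lfq[runs[-1]] = row.lfq_by_run[clone_src]
                groups.append(pg(row.group_id, row.majority_accessions, lfq))
            grown = make_bundle(runs, groups, [], [])
            new = percent_complete_profiles(
                completeness_profile(grown, "protein_group")
            )
            # every old full profile contains the template replicate, so it
            # gains the clone and stays full; no feature is added or removed
            assert new is not None and new >= base - 1e-9


class TestFeatureCV:
    def test_hand_computed(self):
        assert feature_cv([90.0, 100.0, 110.0]) == pytest.approx(10.0)

    def test_constant_values_zero(self):
        assert feature_cv([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_single_value_not_evaluable(self):
        with pytest.raises(ValueError):
            feature_cv([100.0])

    @given(
        values=st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2,
                        max_size=12),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, values, scale):
        assert feature_cv([scale * v for v in values]) == pytest.approx(
            feature_cv(values), rel=1e-9, abs=1e-9
        )


class TestPrecision:
    def test_identical_rts_give_100_percent(self):
        runs = make_runs(3)
        evidence = [ev("_AK_", 2, r, 10.0) for r in runs]
        result = rt_precision(make_bundle(runs, [], [], evidence))
        assert result.percent_below == 100.0

    def test_hand_computed_rt_cv_above_threshold(self):
        runs = make_runs(3)
        evidence = [
            ev("_AK_", 2, runs[0], 10.0),
            ev("_AK_", 2, runs[1], 10.0),
            ev("_AK_", 2, runs[2], 14.0),
        ]
        result = rt_precision(make_bundle(runs, [], [], evidence))
        # CV = 100 * sd([10,10,14]) / mean = 20.38% -> not below 5%
        assert oracles.naive_cv([10.0, 10.0, 14.0]) == pytest.approx(20.38, abs=0.01)
        assert result.n_evaluable == 1 and result.n_below_threshold == 0

    def test_split_peak_rows_collapse_to_median(self):
        runs = make_runs(2)
        evidence = [
            ev("_AK_", 2, runs[0], 10.0),
            ev("_AK_", 2, runs[0], 10.2),
            ev("_AK_", 2, runs[0], 30.0),  # split-peak artifact
            ev("_AK_", 2, runs[1], 10.2),
        ]
        result = rt_precision(make_bundle(runs, [], [], evidence))
        assert result.percent_below == 100.0

    def test_quant_hand_computed_cv_50(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs,
            [pg("1", ["P1"], dict(zip(runs, [100.0, 150.0, 50.0])))],
            [], [],
        )
        result = quant_precision(bundle, "protein_group")
        assert result.n_evaluable == 1 and result.n_below_threshold == 0

    def test_constant_intensities_100_percent(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs, [pg("1", ["P1"], {r: 42.0 for r in runs})], [], []
        )
        assert quant_precision(bundle, "protein_group").percent_below == 100.0

    def test_single_observation_excluded_from_denominator(self):
        runs = make_runs(3)
        bundle = make_bundle(
            runs,
            [pg("1", ["P1"], {runs[0]: 100.0}),
             pg("2", ["P2"], {r: 42.0 for r in runs})],
            [], [],
        )
        result = quant_precision(bundle, "protein_group")
        assert result.n_evaluable == 1

    def test_no_evaluable_feature_percent_missing(self):
        result = rt_precision(make_bundle(make_runs(2), [], [], []))
        assert result.percent_below is None

    def test_lowering_threshold_never_increases_percent_below(self):
        rng = random.Random(23)
        for _ in range(20):
            bundle = random_bundle(rng)
            percents = []
            for thr in (40.0, 20.0, 10.0, 5.0):
                r = quant_precision(bundle, "protein_group", thr)
                if r.percent_below is None:
                    percents = []
                    break
                percents.append(r.percent_below)
            assert percents == sorted(percents, reverse=True)


class TestOracleEquivalence:
    """Every metric equals an independent brute-force recomputation."""

    def test_random_small_bundles(self):
        rng = random.Random(12345)
        for _ in range(60):
            bundle = random_bundle(rng)
            for level in LEVELS:
                ids = count_identifications(bundle, level)
                assert dict(ids.per_replicate) == oracles.naive_id_counts(bundle, level)
                assert ids.median == oracles.naive_median(
                    oracles.naive_id_counts(bundle, level).values()
                )
                profile = completeness_profile(bundle, level)
                assert dict(profile.count_by_k) == oracles.naive_completeness(
                    bundle, level
                )
                expected_pct = oracles.naive_percent_full(bundle, level)
                actual_pct = percent_complete_profiles(profile)
                if expected_pct is None:
                    assert actual_pct is None
                else:
                    assert actual_pct == pytest.approx(expected_pct)
            rt = rt_precision(bundle)
            assert (rt.n_evaluable, rt.n_below_threshold) == oracles.naive_rt_precision(
                bundle
            )
            for level in ("protein_group", "peptide", "precursor"):
                q = quant_precision(bundle, level)
                assert (q.n_evaluable, q.n_below_threshold) == oracles.naive_quant_precision(
                    bundle, level
                )
            mc = missed_cleavage_summary(bundle)
            assert mc.percent_zero == oracles.naive_missed_cleavage_percent_zero(bundle)


class TestSummary:
    def test_summary_matches_individual_metrics(self):
        bundle = random_bundle(random.Random(99))
        summary = summarize_dataset(bundle)
        assert summary.id_counts["peptide"].median == count_identifications(
            bundle, "peptide"
        ).median
        assert summary.rt_precision == rt_precision(bundle)
        assert summary.missed_cleavages == missed_cleavage_summary(bundle)

    def test_determinism(self):
        bundle = random_bundle(random.Random(7))
        assert summarize_dataset(bundle).to_row() == summarize_dataset(bundle).to_row()

    def test_missing_values_propagate(self):
        row = summarize_dataset(make_bundle(make_runs(2), [], [], [])).to_row()
        assert row["percent_zero_missed_cleavages"] is None
        assert row["percent_full_profiles_protein_group"] is None
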