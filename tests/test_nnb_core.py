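import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nnbkit import (
    ItemVector,
    StudyConfig,
    ValidationError,
    centaur1,
    centaur2,
    compute_nnb,
    enumerate_samples,
    item_means,
    nnb_test,
    sampling_analysis,
)
from nnbkit.cost_quality import AGGREGATORS
from conftest import make_trials
from _oracles import brute_force_sampling, one_sample_t


class TestEnumerateSamples:
    def test_full_enumeration_below_cap(self):
        combos = enumerate_samples([f"p{i}" for i in range(10)], 3, cap=500)
        assert len(combos) == 120
        assert len(set(combos)) == 120

    def test_k_equals_n_single_combination(self):
        combos = enumerate_samples(["a", "b", "c"], 3, cap=500)
        assert combos == [("a", "b", "c")]

    def test_cap_branch_distinct_and_reproducible(self):
        pool = [f"p{i}" for i in range(12)]
        combos = enumerate_samples(pool, 6, cap=500, seed=42)
        assert len(combos) == 500
        assert len(set(combos)) == 500
        assert all(len(set(c)) == 6 for c in combos)
        assert combos == enumerate_samples(pool, 6, cap=500, seed=42)
        assert combos != enumerate_samples(pool, 6, cap=500, seed=43)

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValidationError):
            enumerate_samples(["a", "b"], 3)


class TestCentaurs:
    def _vec(self, d, role="sample_mean"):
        return ItemVector(pd.Series(d, dtype=float), role=role)

    def test_centaur1_identity_when_equal(self):
        v = self._vec({"a": 2.0, "b": 4.0})
        out = centaur1(v, self._vec({"a": 2.0, "b": 4.0}, "reference"))
        assert dict(out.values) == {"a": 2.0, "b": 4.0}

    def test_centaur1_arithmetic(self):
        out = centaur1(
            self._vec({"a": 1.0, "b": 3.0}), self._vec({"a": 3.0, "b": 5.0}, "reference")
        )
        assert dict(out.values) == {"a": 2.0, "b": 4.0}

    def test_centaur1_empty_intersection_errors(self):
        with pytest.raises(ValidationError):
            centaur1(self._vec({"a": 1.0}), self._vec({"b": 2.0}, "reference"))

    def test_centaur2_equals_centaur1_at_k1(self):
        t = make_trials([("p1", "A", "a", 2), ("p1", "A", "b", 6)])
        ref = self._vec({"a": 4.0, "b": 2.0}, "reference")
        via2 = centaur2(t, ["p1"], ref)
        via1 = centaur1(item_means(t, ["p1"]), ref)
        pd.testing.assert_series_equal(via2.values, via1.values)

    def test_centaur2_reference_weighted_as_one_participant(self):
        t = make_trials([(f"p{i}", "A", "a", 2) for i in range(3)])
        ref = self._vec({"a": 6.0}, "reference")
        assert centaur2(t, ["p0", "p1", "p2"], ref)["a"] == pytest.approx(3.0)

    def test_centaur2_fixed_point_at_reference_equal_mean(self):
        t = make_trials([("p1", "A", "a", 2), ("p2", "A", "a", 4)])
        ref = self._vec({"a": 3.0}, "reference")
        assert centaur2(t, ["p1", "p2"], ref)["a"] == pytest.approx(3.0)

    def test_centaur2_converges_to_human_mean(self):
        # per-item gap to the human-only mean is bounded by range/(k+1)
        rng = np.random.default_rng(3)
        rows = [
            (f"p{p}", "A", f"i{i}", int(rng.integers(1, 8)))
            for p in range(8)
            for i in range(5)
        ]
        t = make_trials(rows)
        ref = self._vec({f"i{i}": 7.0 for i in range(5)}, "reference")
        for k in (2, 4, 8):
            combo = [f"p{p}" for p in range(k)]
            gap = (centaur2(t, combo, ref).values - item_means(t, combo).values).abs()
            assert (gap <= 6.0 / (k + 1) + 1e-12).all()


class TestSamplingAnalysis:
    def test_full_sample_row_equals_full_mean_correlation(self, two_list_study, config17):
        trials, gold, ref = two_list_study
        table = sampling_analysis(
            trials, gold, ref, ks=[3], aggregators=["human_only"], config=config17
        )
        from nnbkit import correlate

        for list_id in trials.lists:
            sub = table[table["list_id"] == list_id]
            assert len(sub) == 1
            full = item_means(trials, trials.participants_in(list_id))
            v, g = full.aligned_with(gold)
            assert sub["correlation"].iloc[0] == pytest.approx(
                correlate(v, g, "pearson"), abs=1e-12
            )

    def test_row_counts_match_combination_counts(self, two_list_study, config17):
        trials, gold, ref = two_list_study
        table = sampling_analysis(trials, gold, ref, config=config17)
        counts = table.groupby(["list_id", "k", "aggregator"]).size()
        for (list_id, k, agg), n in counts.items():
            assert n == math.comb(3, k)

    def test_matches_brute_force_oracle(self, two_list_study, config17):
        trials, gold, ref = two_list_study
        table = sampling_analysis(trials, gold, ref, config=config17)
        trial_rows = [
            (r.participant_id, r.list_id, r.item_id,
             None if pd.isna(r.response) else float(r.response))
            for r in trials.ratings().itertuples()
        ]
        expected = brute_force_sampling(
            trial_rows, dict(gold.values), dict(ref.values), "pearson", AGGREGATORS
        )
        assert len(table) == len(expected)
        for row in table.itertuples():
            exp_corr, exp_ref = expected[(row.list_id, row.k, row.combination, row.aggregator)]
            assert row.correlation == pytest.approx(exp_corr, abs=1e-12)
            assert row.reference_correlation == pytest.approx(exp_ref, abs=1e-12)

    def test_empty_ks_errors(self, two_list_study, config17):
        trials, gold, ref = two_list_study
        with pytest.raises(ValidationError):
            sampling_analysis(trials, gold, ref, ks=[], config=config17)


def _sampling_frame(ref_corr, corrs, k=2, aggregator="human_only"):
    return pd.DataFrame(
        {
            "list_id": "A",
            "k": k,
            "combination": [("p1", "p2")] * len(corrs),
            "aggregator": aggregator,
            "correlation": corrs,
            "reference_correlation": ref_corr,
        }
    )


class TestNnbTest:
    def test_null_exactly_true_gives_p_half(self):
        table = _sampling_frame(0.8, [0.8, 0.8, 0.8, 0.8 + 1e-9, 0.8 - 1e-9])
        for mode in ("difference", "ratio"):
            res = nnb_test(table, 2, "human_only", mode)
            assert res.p == pytest.approx(0.5, abs=0.01)

    def test_difference_matches_textbook_t_oracle(self):
        diffs = [-0.02, -0.01, -0.03, -0.02, -0.02]
        table = _sampling_frame(0.8, [0.8 - d for d in diffs])
        res = nnb_test(table, 2, "human_only", "difference")
        t_exp, df_exp, p_exp = one_sample_t(diffs, 0.0)
        assert res.t == pytest.approx(t_exp)  # -0.02 / (sd/sqrt(5)) = -6.3246
        assert res.df == df_exp == 4
        assert res.p == pytest.approx(p_exp)

    def test_ratio_wrong_direction_p_near_one(self):
        # human correlations half the reference: ratios all ~2
        corrs = [0.4 + e for e in (-0.01, 0.0, 0.01, 0.02, -0.02)]
        res = nnb_test(_sampling_frame(0.8, corrs), 2, "human_only", "ratio")
        assert res.p > 0.99

    def test_zero_variance_degenerate(self):
        res = nnb_test(_sampling_frame(0.8, [0.9, 0.9, 0.9]), 2, "human_only", "difference")
        assert math.isnan(res.t) and res.p == 0.0
        res = nnb_test(_sampling_frame(0.8, [0.7, 0.7, 0.7]), 2, "human_only", "difference")
        assert res.p == 1.0

    def test_undefined_ratios_dropped(self):
        table = _sampling_frame(0.8, [0.9, 0.85, 0.0, 0.95])
        res = nnb_test(table, 2, "human_only", "ratio")
        assert res.n_dropped == 1 and res.df == 2


class TestComputeNnb:
    @staticmethod
    def _synthetic_table(ref_corr, corr_center, n_per_k=20, ks=(1, 2, 3)):
        rng = np.random.default_rng(0)
        frames = [
            _sampling_frame(
                ref_corr,
                corr_center + rng.normal(0, 0.01, size=n_per_k),
                k=k,
            )
            for k in ks
        ]
        return pd.concat(frames, ignore_index=True)

    def test_worthless_reference_gives_nnb_one(self):
        # reference correlation 0 on every list, humans positively correlated
        table = self._synthetic_table(ref_corr=0.0, corr_center=0.6)
        report = compute_nnb(table, "human_only", alpha=0.05)
        assert report.nnb["difference"] == 1

    def test_unbeatable_reference_not_reached(self):
        table = self._synthetic_table(ref_corr=1.0, corr_center=0.6)
        report = compute_nnb(table, "human_only", alpha=0.05)
        assert report.nnb["difference"] is None
        assert report.nnb["ratio"] is None

    def test_curve_covers_all_ks_and_modes(self, two_list_study, config17):
        trials, gold, ref = two_list_study
        table = sampling_analysis(trials, gold, ref, config=config17)
        report = compute_nnb(table, "centaur2", alpha=0.05)
        assert sorted(report.curve["k"].unique()) == [1, 2, 3]
        assert set(report.curve["mode"]) == {"difference", "ratio"}
        d = report.to_dict()
        assert d["aggregator"] == "centaur2" and "nnb" in d
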