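"""Calibration schemes, rolling no-leakage prediction, the interpolation
baseline, error metrics and the similarity structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_subject_frame
from ppgbp.errors import InvalidArgumentError, TooFewSamplesError
from ppgbp.evaluation import (
    CalibrationScheme,
    SubjectDataset,
    assert_no_leakage,
    compare_models,
    compute_metrics,
    evaluate_cell,
    interpolation_baseline,
    make_model_factory,
    rolling_predict,
    run_experiment,
    scheme1_indices,
    scheme2_indices,
    similarity_histograms,
)


def make_dataset(subject_id="S01", n=115, seed=0, **kw) -> SubjectDataset:
    rng = np.random.default_rng(seed)
    df = make_subject_frame(subject_id, n, rng, **kw)
    return SubjectDataset.from_feature_frame(df, subject_id)


class TestSchemes:
    def test_initial_scheme_takes_first_fifth(self):
        assert scheme1_indices(115).windows == [(1, 23)]
        assert scheme1_indices(118).windows == [(1, 24)]  # round-half-up of 23.6
        assert scheme1_indices(10).windows == [(1, 2)]

    def test_initial_scheme_too_few_samples(self):
        with pytest.raises(TooFewSamplesError):
            scheme1_indices(9)

    def test_intermittent_scheme_windows(self):
        s = scheme2_indices(115)
        assert s.windows == [(1, 5), (15, 18), (35, 38), (55, 58), (75, 78), (95, 98)]
        assert len(s.indices()) == 25
        assert len(s.indices()) / 115 == pytest.approx(0.217, abs=0.001)

    def test_intermittent_scheme_drops_late_windows(self):
        s = scheme2_indices(60)
        assert s.windows == [(1, 3), (15, 18), (35, 38), (55, 58)]

    def test_intermittent_scheme_too_few_samples(self):
        with pytest.raises(TooFewSamplesError):
            scheme2_indices(17)

    @given(n=st.integers(100, 130))
    @settings(max_examples=31, deadline=None)
    def test_calibration_fraction_roughly_one_fifth(self, n):
        for scheme in (scheme1_indices(n), scheme2_indices(n)):
            frac = len(scheme.indices()) / n
            # the ceil rule for the 4% window tops out at 25/101
            assert 0.18 <= frac <= 0.25

    def test_overlapping_windows_rejected(self):
        with pytest.raises(InvalidArgumentError):
            CalibrationScheme("bad", [(1, 5), (4, 8)])


class RecordingFactory:
    """Model factory spy: records each training set, predicts the mean."""

    def __init__(self):
        self.calls = []

    def __call__(self, X, y):
        self.calls.append((X.copy(), y.copy()))
        return lambda Xq: np.full(len(np.atleast_2d(Xq)), float(np.mean(y)))


class TestRollingPredict:
    def test_training_windows_accumulate_without_future_leaks(self):
        ds = make_dataset(n=115)
        scheme = scheme2_indices(115)
        spy = RecordingFactory()
        res = rolling_predict(ds, scheme, spy, ["hr", "ri"], target="sbp_ref")
        assert_no_leakage(res)
        # segment 6..14 trained on [1,5]; segment 19..34 on [1,5]+[15,18]
        assert len(spy.calls[0][1]) == 5
        assert len(spy.calls[1][1]) == 9
        assert res.train_max_index.loc[20] == 18
        # index 99 onward: every window precedes it
        assert res.train_max_index.loc[99] == 98
        assert len(spy.calls[-1][1]) == 25
        assert res.unpredictable == []

    def test_initial_scheme_single_fit(self):
        ds = make_dataset(n=100)
        spy = RecordingFactory()
        res = rolling_predict(ds, scheme1_indices(100), spy, ["hr", "ri"])
        assert len(spy.calls) == 1
        assert (res.train_max_index == 20).all()
        assert list(res.predictions.index) == list(range(21, 101))

    def test_segment_without_prior_window_reported_unpredictable(self):
        ds = make_dataset(n=30)
        scheme = CalibrationScheme("custom", [(5, 8)])
        spy = RecordingFactory()
        res = rolling_predict(ds, scheme, spy, ["hr", "ri"])
        assert res.unpredictable == [1, 2, 3, 4]
        assert list(res.predictions.index) == list(range(9, 31))

    def test_individual_strategy_never_reads_other_subjects(self):
        ds = make_dataset("A", n=60, sbp_base=100.0)
        other = make_dataset("B", n=60, seed=5, sbp_base=160.0)
        spy = RecordingFactory()
        rolling_predict(ds, scheme1_indices(60), spy, ["hr", "ri"],
                        strategy="individual", others=[other])
        for _, y in spy.calls:
            # subject B's references live ~60 mmHg higher; none may appear
            assert y.max() < 140.0

    def test_generalized_strategy_pools_other_subjects(self):
        ds = make_dataset("A", n=60)
        other = make_dataset("B", n=60, seed=5)
        spy = RecordingFactory()
        rolling_predict(ds, scheme1_indices(60), spy, ["hr", "ri"],
                        strategy="generalized", others=[other])
        assert len(spy.calls[0][1]) == 12 + 60

    def test_generalized_requires_others(self):
        ds = make_dataset(n=60)
        with pytest.raises(InvalidArgumentError):
            rolling_predict(ds, scheme1_indices(60), RecordingFactory(),
                            ["hr", "ri"], strategy="generalized")


class TestInterpolationBaseline:
    def _ds_with_bp(self, values):
        n = len(values)
        ds = make_dataset(n=n)
        ds.frame["sbp_ref"] = np.asarray(values, dtype=float)
        return ds

    def test_equal_window_means_give_constant_prediction(self):
        ds = self._ds_with_bp(np.full(115, 100.0))
        res = interpolation_baseline(ds, scheme2_indices(115))
        np.testing.assert_allclose(res.predictions.values, 100.0)

    def test_line_between_window_centers(self):
        vals = np.zeros(60)
        vals[14:18] = 100.0  # window 15-18 (1-based)
        vals[34:38] = 110.0  # window 35-38
        ds = self._ds_with_bp(vals)
        scheme = CalibrationScheme("scheme_2", [(15, 18), (35, 38)])
        res = interpolation_baseline(ds, scheme)
        # anchors at centers 16.5 and 36.5 with means 100 and 110
        for i in range(19, 35):
            expected = 100.0 + 10.0 * (i - 16.5) / 20.0
            assert res.predictions.loc[i] == pytest.approx(expected)
        # after the last window: constant extrapolation of its mean
        assert res.predictions.loc[50] == pytest.approx(110.0)

    def test_segment_before_second_window_uses_flanking_pair(self):
        vals = np.zeros(60)
        vals[:3] = 90.0    # initial window [1,3]
        vals[14:18] = 100.0
        ds = self._ds_with_bp(vals)
        scheme = CalibrationScheme("scheme_2", [(1, 3), (15, 18)])
        res = interpolation_baseline(ds, scheme)
        c0, c1 = 2.0, 16.5
        for i in range(4, 15):
            expected = 90.0 + 10.0 * (i - c0) / (c1 - c0)
            assert res.predictions.loc[i] == pytest.approx(expected)

    def test_single_window_rejected(self):
        ds = self._ds_with_bp(np.zeros(30))
        with pytest.raises(InvalidArgumentError):
            interpolation_baseline(ds, CalibrationScheme("one", [(1, 5)]))


class TestMetrics:
    def test_perfect_prediction_zeroes_everything(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["mae"] == m["me"] == m["sd"] == m["rmse"] == 0.0

    def test_alternating_unit_errors(self):
        ref = np.zeros(4)
        pred = np.array([1.0, -1.0, 1.0, -1.0])
        m = compute_metrics(pred, ref)
        assert m["me"] == 0.0
        assert m["mae"] == 1.0
        assert m["rmse"] == 1.0
        assert m["sd"] == pytest.approx(2.0 / np.sqrt(3.0))

    def test_constant_reference_has_undefined_correlation(self):
        m = compute_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert m["pearson_r"] is None

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_rmse_identity(self, seed):
        rng = np.random.default_rng(seed)
        err = rng.normal(size=20)
        m = compute_metrics(err, np.zeros(20))
        n = 20
        assert m["rmse"] ** 2 == pytest.approx(
            m["me"] ** 2 + m["sd"] ** 2 * (n - 1) / n, rel=1e-10
        )

    def test_bland_altman_limits(self):
        rng = np.random.default_rng(1)
        pred, ref = rng.normal(size=50), rng.normal(size=50)
        m = compute_metrics(pred, ref)
        assert m["ba_high"] - m["ba_low"] == pytest.approx(2 * 1.96 * m["sd"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_metrics([1.0], [1.0, 2.0])


class TestCompareModels:
    def test_identical_lists(self):
        out = compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_offset_is_strongly_significant(self):
        rng = np.random.default_rng(0)
        a = 5.0 + 0.05 * rng.normal(size=11)
        b = a + 5.0 + 0.05 * rng.normal(size=11)
        out = compare_models(a, b)
        assert out["p"] < 0.001
        assert out["lower"] == "A"

    def test_two_subject_comparison_flagged(self):
        out = compare_models([1.0, 2.0], [2.0, 4.0])
        assert out["small_sample"] is True

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_models([1.0], [1.0, 2.0])


class TestSimilarity:
    def test_identical_features_degenerate_at_one(self):
        df = pd.DataFrame(
            {
                "subject_id": ["A"] * 10 + ["B"] * 10,
                "hr": 70.0, "a02": 20.0, "a25": 21.0, "ri": 2.0,
                "rejected": False,
            }
        )
        out = similarity_histograms(df, max_pairs=200, seed=0)
        assert out["median_intra"] == pytest.approx(1.0)
        assert out["median_inter"] == pytest.approx(1.0)

    def test_cohort_intra_exceeds_inter(self, small_cohort_features):
        out = similarity_histograms(small_cohort_features, max_pairs=20000, seed=1)
        assert out["median_intra"] > out["median_inter"]

    def test_label_permutation_destroys_gap(self, small_cohort_features):
        rng = np.random.default_rng(3)
        gaps = []
        for _ in range(20):
            df = small_cohort_features.copy()
            df["subject_id"] = rng.permutation(df["subject_id"].values)
            out = similarity_histograms(df, max_pairs=20000, seed=2)
            gaps.append(out["median_intra"] - out["median_inter"])
        assert abs(np.mean(gaps)) < 0.02

    def test_single_subject_rejected(self):
        df = pd.DataFrame(
            {"subject_id": ["A"] * 5, "hr": np.arange(5.0), "a02": 1.0,
             "a25": 1.0, "ri": 2.0, "rejected": False}
        )
        with pytest.raises(InvalidArgumentError):
            similarity_histograms(df)


@pytest.fixture(scope="module")
def tiny_datasets():
    return [make_dataset(f"S{i}", n=40, seed=i, sbp_base=110 + 10 * i)
            for i in range(3)]


class TestRunExperiment:
    def test_full_factorial_cell_count(self, tiny_datasets):
        grid, cells = run_experiment(
            tiny_datasets, models=("pls",), feature_sets=("set1", "set3"),
            schemes=("scheme_1", "scheme_2"), strategies=("individual",),
            targets=("sbp", "dbp"),
        )
        assert len(cells) == 1 * 2 * 2 * 1 * 2
        # one row per subject per cell plus one pooled row per cell
        assert len(grid) == len(cells) * (len(tiny_datasets) + 1)

    def test_empty_factor_list_rejected(self, tiny_datasets):
        with pytest.raises(InvalidArgumentError):
            run_experiment(tiny_datasets, models=())

    def test_pooled_metrics_match_concatenated_errors(self, tiny_datasets):
        cell = evaluate_cell(
            tiny_datasets, "pls", "set3", "scheme_1", "individual", "sbp"
        )
        assert cell.pooled["rmse"] >= cell.pooled["mae"] >= 0.0
        n_sub = cell.per_subject["n"].sum()
        assert cell.pooled["n"] == n_sub

    def test_all_three_models_run_both_schemes(self, tiny_datasets):
        for model in ("pls", "lwpls", "gpr"):
            cell = evaluate_cell(
                tiny_datasets, model, "set3", "scheme_2", "individual", "sbp",
                gpr_maxiter=10,
            )
            assert np.isfinite(cell.pooled["mae"])
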