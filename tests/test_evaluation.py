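"""Condition construction, cross-validation drivers, transfer and continuous
evaluation, chance bounds, and significance testing."""

import logging

import numpy as np
import pandas as pd
import pytest

from hybridbci.evaluate import (
    CONDITIONS,
    ClassifierConfig,
    ConditionSpec,
    CvPlan,
    FeatureCache,
    WindowFeatureCache,
    _inner_splits,
    build_condition,
    chance_upper_bound,
    compare_accuracies,
    cross_evaluate,
    fit_condition,
    general_activity_accuracy,
    holm_adjust,
    run_continuous_evaluation,
    run_subject_dependent_cv,
    run_subject_independent_cv,
)


class TestConditions:
    def test_binary_subset_counts(self, prepared_small):
        trials = prepared_small[0].trials  # 8 per label
        sub, y = build_condition(trials, CONDITIONS["AUD_vs_VIS"])
        assert len(sub) == 16 and np.bincount(y).tolist() == [8, 8]
        sub, y = build_condition(trials, CONDITIONS["allAUD_vs_nonAUD"])
        assert len(sub) == 32 and np.bincount(y).tolist() == [16, 16]
        # original labels retained for confusion reporting
        assert set(sub.labels) == {"AUD", "VIS", "MIX", "IDLE"}

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ConditionSpec("bad", ("AUD", "MIX"), ("MIX", "IDLE"))

    def test_empty_class_rejected(self, prepared_small):
        trials = prepared_small[0].trials.select(
            prepared_small[0].trials.labels != "IDLE")
        with pytest.raises(ValueError, match="IDLE"):
            build_condition(trials, CONDITIONS["AUD_vs_IDLE"])


class TestInnerSplits:
    def test_59_trials_give_nine_6_and_one_5_fold(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(30, int), np.ones(29, int)]
        splits = _inner_splits(y, 10, rng)
        sizes = sorted(len(ev) for _, ev in splits)
        assert sizes == [5] + [6] * 9
        # a 6-trial evaluation fold leaves 53 training trials
        for tr, ev in splits:
            assert len(tr) + len(ev) == 59
            if len(ev) == 6:
                assert len(tr) == 53

    def test_folds_partition_exactly(self):
        rng = np.random.default_rng(1)
        splits = _inner_splits(np.arange(23) % 2, 10, rng)
        all_eval = np.sort(np.concatenate([ev for _, ev in splits]))
        np.testing.assert_array_equal(all_eval, np.arange(23))

    def test_fewer_trials_than_folds_reduced_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            splits = _inner_splits(np.array([0, 1, 0, 1]), 10,
                                   np.random.default_rng(2))
        assert len(splits) == 4
        assert any("reducing" in r.message for r in caplog.records)


class TestSubjectDependentCv:
    def test_one_outer_fold_per_trial(self, prepared_small):
        res = run_subject_dependent_cv(prepared_small[0].trials,
                                       CONDITIONS["AUD_vs_VIS"],
                                       CvPlan("loto", seed=0))
        assert len(res.fold_params) == 16
        assert set(res.accuracy) == {"HbO", "HbR", "POW", "ERP", "META"}
        assert all(0 <= a <= 1 for a in res.accuracy.values())

    def test_planted_effects_decoded_above_chance(self, prepared_small):
        res = run_subject_dependent_cv(prepared_small[0].trials,
                                       CONDITIONS["AUD_vs_VIS"],
                                       CvPlan("loto", seed=0))
        assert res.accuracy["META"] >= 0.8

    def test_permuted_labels_within_chance_interval(self, prepared_small):
        trials = prepared_small[0].trials
        rng = np.random.default_rng(3)
        shuffled = trials.meta.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        from hybridbci.epochs import TrialSet

        permuted = TrialSet(trials.subject_id, shuffled, trials.blocks)
        res = run_subject_dependent_cv(permuted, CONDITIONS["AUD_vs_VIS"],
                                       CvPlan("loto", seed=0))
        bound = chance_upper_bound(16, alpha=0.01) / 100
        lo = 1 - bound
        assert lo <= res.accuracy["META"] <= bound

    def test_zero_effect_cohort_calibrates_to_chance(self):
        """With every label-dependent effect removed from the generator,
        cross-validated accuracy stays inside the 1 % chance interval."""
        from hybridbci.montage import MontageSpec
        from hybridbci.pipeline import prepare_session
        from hybridbci.simulate import (CohortModels, SimulationConfig,
                                        generate_cohort)

        m = MontageSpec(channels_per_probe=(4, 4, 4))
        cfg = SimulationConfig(n_subjects=1, trials_per_label=8)
        sess = generate_cohort(cfg, CohortModels.null(m), m, seed=5)[0]
        p = prepare_session(sess, seed=0)
        res = run_subject_dependent_cv(p.trials, CONDITIONS["AUD_vs_VIS"],
                                       CvPlan("loto", seed=0))
        bound = chance_upper_bound(16, alpha=0.01) / 100
        for ft, acc in res.accuracy.items():
            assert 1 - bound <= acc <= bound, (ft, acc)

    def test_too_few_trials_per_class_rejected(self, prepared_small):
        trials = prepared_small[0].trials
        keep = np.flatnonzero(np.isin(trials.labels, ["AUD", "VIS"]))[:3]
        with pytest.raises(ValueError):
            run_subject_dependent_cv(trials.select(keep),
                                     CONDITIONS["AUD_vs_VIS"], CvPlan("loto"))


class TestSubjectIndependentCv:
    def test_two_subject_fold_arithmetic(self, prepared_small):
        res = run_subject_independent_cv(
            [p.trials for p in prepared_small], CONDITIONS["AUD_vs_VIS"],
            CvPlan("loso", seed=0))
        # every subject appears in the per-subject breakdown
        assert set(res.per_subject["subject"]) == {p.subject_id
                                                   for p in prepared_small}
        assert res.per_subject.groupby("subject")["n"].first().eq(16).all()

    def test_single_subject_rejected(self, prepared_small):
        with pytest.raises(ValueError, match="2 subjects"):
            run_subject_independent_cv([prepared_small[0].trials],
                                       CONDITIONS["AUD_vs_VIS"],
                                       CvPlan("loso"))


class TestLeakage:
    def test_marker_in_test_trial_never_changes_model(self, prepared_small):
        """No information flows from the held-out trial into fitting."""
        sub, y = build_condition(prepared_small[0].trials,
                                 CONDITIONS["AUD_vs_VIS"])
        cache = FeatureCache(sub, y)
        n = len(cache)
        train_idx = np.arange(1, n)
        splits = _inner_splits(cache.y[train_idx], 5, np.random.default_rng(0))
        model_a = fit_condition(cache, train_idx, splits)
        for key in cache._mats:
            cache._mats[key][0] = 1e9  # poison the held-out trial
        model_b = fit_condition(cache, train_idx, splits)
        for ft in model_a.feature_types:
            np.testing.assert_array_equal(model_a.classifiers[ft].coef_
                                          if hasattr(model_a.classifiers[ft], "coef_")
                                          else 0,
                                          model_b.classifiers[ft].coef_
                                          if hasattr(model_b.classifiers[ft], "coef_")
                                          else 0)
        assert model_a.slope_params == model_b.slope_params
        np.testing.assert_array_equal(model_a.weights.as_array(),
                                      model_b.weights.as_array())


class TestModelSerialization:
    def test_save_load_round_trip_predictions(self, prepared_small, tmp_path):
        from hybridbci.evaluate import FittedCondition

        sub, y = build_condition(prepared_small[0].trials,
                                 CONDITIONS["AUD_vs_VIS"])
        cache = FeatureCache(sub, y)
        train_idx = np.arange(len(cache))
        splits = _inner_splits(cache.y, 5, np.random.default_rng(0))
        model = fit_condition(cache, train_idx, splits)
        path = tmp_path / "model.npz"
        model.save(path)
        again = FittedCondition.load(path)
        idx = np.arange(len(cache))
        a = model.predict_index(cache, idx)
        b = again.predict_index(cache, idx)
        for ft in a:
            np.testing.assert_array_equal(a[ft], b[ft])
        assert again.slope_params == model.slope_params
        np.testing.assert_allclose(again.weights.as_array(),
                                   model.weights.as_array())


class _PerfectStub:
    """Predicts the expected class for every trial."""

    def __init__(self, expected, feature_types=("HbO",)):
        self.expected = expected
        self.feature_types = feature_types

    def predict_index(self, cache, idx):
        want = np.array([self.expected[l] for l in cache.original_labels[idx]])
        return {"META": want}


class TestCrossEvaluate:
    def test_perfect_stub_scores_100(self, prepared_small):
        sub, y = build_condition(prepared_small[0].trials,
                                 CONDITIONS["AUD_vs_VIS"])
        cache = FeatureCache(sub, y, feature_types=("HbO",))
        expected = {"AUD": 0, "VIS": 1}
        rates = cross_evaluate(_PerfectStub(expected), cache, expected)
        assert (rates["rate"] == 1.0).all()

    def test_missing_mapping_rejected(self, prepared_small):
        sub, y = build_condition(prepared_small[0].trials,
                                 CONDITIONS["AUD_vs_VIS"])
        cache = FeatureCache(sub, y, feature_types=("HbO",))
        with pytest.raises(ValueError, match="VIS"):
            cross_evaluate(_PerfectStub({"AUD": 0}), cache, {"AUD": 0})


class TestContinuousEvaluation:
    def test_window_counts_and_erp_guard(self, prepared_small):
        p = prepared_small[0]
        cache = WindowFeatureCache(p.subject_id, p.hemo, p.eeg, p.eeg_fs,
                                   p.segments, CONDITIONS["AUD_vs_VIS"], 1.0)
        # 60 s AUD clip + 60 s VIS clip -> 120 windows per class
        assert len(cache) == 240
        assert np.bincount(cache.y).tolist() == [120, 120]
        with pytest.raises(ValueError, match="ERP"):
            WindowFeatureCache(p.subject_id, p.hemo, p.eeg, p.eeg_fs,
                               p.segments, CONDITIONS["AUD_vs_VIS"], 1.0,
                               feature_types=("HbO", "ERP"))

    def test_loso_run_returns_all_window_sizes(self, prepared_small):
        subjects = [dict(subject_id=p.subject_id, hemo=p.hemo, eeg=p.eeg,
                         eeg_fs=p.eeg_fs, segments=p.segments)
                    for p in prepared_small]
        df = run_continuous_evaluation(subjects, CONDITIONS["AUD_vs_VIS"],
                                       w_lens=(8.0, 16.0),
                                       plan=CvPlan("loso", seed=0))
        assert sorted(df["w_len"].unique()) == [8.0, 16.0]
        assert set(df["feature_type"]) == {"HbO", "HbR", "POW", "META"}
        n_1 = df[df["w_len"] == 8.0]["n_windows"].iloc[0]
        assert n_1 == 2 * 2 * 15  # 2 subjects x 2 classes x 15 windows

    def test_erp_in_feature_types_rejected(self, prepared_small):
        with pytest.raises(ValueError, match="ERP"):
            run_continuous_evaluation([], CONDITIONS["AUD_vs_VIS"],
                                      feature_types=("HbO", "ERP"))

    def test_oversized_window_skipped_with_warning(self, prepared_small, caplog):
        subjects = [dict(subject_id=p.subject_id, hemo=p.hemo, eeg=p.eeg,
                         eeg_fs=p.eeg_fs, segments=p.segments)
                    for p in prepared_small]
        with caplog.at_level(logging.WARNING):
            df = run_continuous_evaluation(subjects, CONDITIONS["AUD_vs_VIS"],
                                           w_lens=(16.0, 200.0),
                                           plan=CvPlan("loso", seed=0))
        assert sorted(df["w_len"].unique()) == [16.0]
        assert any("skipping" in r.message for r in caplog.records)


class TestChanceBound:
    def test_reference_bounds_to_one_decimal(self):
        assert chance_upper_bound(2880) == pytest.approx(52.4, abs=0.05)
        assert chance_upper_bound(1440) == pytest.approx(53.4, abs=0.05)

    def test_asymptotic_limit(self):
        assert chance_upper_bound(10**8) == pytest.approx(50.0, abs=0.02)

    def test_adjusted_wald_variant_is_tighter(self):
        assert chance_upper_bound(100, method="adjusted-wald") < \
            chance_upper_bound(100, method="normal")

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            chance_upper_bound(100, alpha=1.5)


def _holm_oracle(pvals, alpha):
    """Brute-force step-down: reject smallest p while p_(i) <= alpha/(m-i)."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestCompareAccuracies:
    def test_identical_vectors_not_significant(self):
        a = np.full(12, 0.8)
        out = compare_accuracies({"c": (a, a.copy())})
        assert out["p"].iloc[0] == 1.0
        assert not out["significant"].iloc[0]

    def test_constant_improvement_significant(self):
        a = np.full(12, 0.9)
        b = np.full(12, 0.8)
        out = compare_accuracies({"c1": (a, b), "c2": (a, b), "c3": (a, b)})
        assert out["significant"].all()

    def test_holm_decisions_match_enumeration_oracle(self):
        pvals = np.array([0.01, 0.04, 0.03])
        adj = holm_adjust(pvals)
        ours = adj < 0.05
        np.testing.assert_array_equal(ours, _holm_oracle(pvals, 0.05))

    def test_random_pvals_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(0, 0.2, size=rng.integers(2, 6))
            np.testing.assert_array_equal(holm_adjust(p) < 0.05,
                                          _holm_oracle(p, 0.05))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_accuracies({"c": (np.ones(3), np.ones(4))})


class TestGeneralActivityBaseline:
    def test_balanced_detection_condition_is_exactly_75(self):
        labels = np.repeat(["VIS", "MIX", "AUD", "IDLE"], 30)
        acc = general_activity_accuracy(labels, CONDITIONS["allVIS_vs_nonVIS"])
        assert acc == pytest.approx(0.75)

    def test_symmetric_condition(self):
        labels = np.repeat(["VIS", "MIX", "AUD", "IDLE"], 30)
        acc = general_activity_accuracy(labels, CONDITIONS["allAUD_vs_nonAUD"])
        assert acc == pytest.approx(0.75)
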