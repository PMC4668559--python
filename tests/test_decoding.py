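"""Cross-validation harness, balancing, leakage audits and group statistics."""

import numpy as np
import pandas as pd
import pytest

from mazeview import decoding as dec
from mazeview import preprocessing as pp
from mazeview.maze_task import CODE_FAMILIES, CODE_NAMES


def toy_meta(n=24, n_sessions=2, n_maps=3, seed=0):
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({
        "trial_id": np.arange(1, n + 1),
        "session_id": np.sort(np.arange(n) % n_sessions) + 1,
        "map_id": np.tile(np.arange(1, n_maps + 1), n // n_maps + 1)[:n],
    })
    meta["code"] = rng.integers(0, 2, n)
    return meta


class TestBalanceClasses:
    def test_majority_subsampled_to_minority(self, rng):
        labels = np.array([1] * 100 + [0] * 60)
        idx = dec.balance_classes(labels, rng)
        assert (labels[idx] == 1).sum() == 60
        assert (labels[idx] == 0).sum() == 60
        assert len(np.unique(idx)) == len(idx)  # without replacement

    def test_already_balanced_unchanged(self, rng):
        labels = np.array([0, 1] * 10)
        assert np.array_equal(dec.balance_classes(labels, rng), np.arange(20))

    def test_deterministic_given_rng_seed(self):
        labels = np.array([1] * 30 + [0] * 10)
        a = dec.balance_classes(labels, np.random.default_rng(5))
        b = dec.balance_classes(labels, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_empty_class_raises(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            dec.balance_classes(np.ones(10), rng)


class TestFolds:
    def test_loso_one_fold_per_session(self):
        meta = toy_meta(n=30, n_sessions=5)
        folds = dec.make_folds(meta, "LOSO")
        assert len(folds) == 5
        for train, test in folds:
            assert len(test) == 6
            assert meta.session_id.iloc[test].nunique() == 1
            assert set(train) | set(test) == set(range(30))

    def test_loto_singleton_folds(self):
        meta = toy_meta(n=12)
        folds = dec.make_folds(meta, "LOTO")
        assert len(folds) == 12
        assert all(len(test) == 1 for _, test in folds)

    def test_lomo_excludes_all_trials_of_test_map(self):
        meta = toy_meta(n=24)
        for train, test in dec.make_folds(meta, "LOMO"):
            assert not set(meta.map_id.iloc[train]) & set(meta.map_id.iloc[test])

    def test_unknown_scheme_raises(self):
        with pytest.raises(ValueError, match="scheme"):
            dec.make_folds(toy_meta(), "KFOLD")

    def test_audit_catches_crafted_leakage(self):
        meta = toy_meta(n=10)
        with pytest.raises(AssertionError, match="leakage"):
            dec._audit_fold(meta, np.arange(6), np.array([5, 6]), "LOSO")
        meta_same_map = toy_meta(n=9, n_maps=1)
        with pytest.raises(AssertionError, match="LOMO"):
            dec._audit_fold(meta_same_map, np.arange(4), np.arange(5, 9), "LOMO")


class TestRunCV:
    def test_prediction_count_equals_sample_count(self, rng):
        meta = toy_meta(n=24)
        X = rng.standard_normal((24, 8))
        res = dec.run_cv(X, meta, "code", "LOSO", seed=1)
        assert res.n == 24
        assert set(res.trial_ids) == set(meta.trial_id)
        assert np.array_equal(res.pred, (res.proba >= 0.5).astype(int))

    def test_single_class_training_fold_skipped_with_warning(self, rng, caplog):
        meta = toy_meta(n=20, n_sessions=2)
        # session 1 all positive: training for the session-2 fold is fine,
        # but the fold trained on session 2 alone... craft session2 single-class
        labels = np.array([0, 1] * 5 + [1] * 10)
        X = rng.standard_normal((20, 4))
        with caplog.at_level("WARNING"):
            res = dec.run_cv(X, meta, "code", "LOSO", labels=labels, seed=1)
        assert res.skipped_folds == [0]
        assert res.n == 10  # only session-1 predictions remain
        assert "single-class" in caplog.text

    def test_decodes_linearly_separable_signal(self, rng):
        meta = toy_meta(n=40, n_sessions=2)
        y = meta["code"].to_numpy()
        X = rng.standard_normal((40, 10))
        X[:, 0] += (2 * y - 1) * 3.0
        res = dec.run_cv(X, meta, "code", "LOSO", seed=1)
        assert res.accuracy > 0.9

    def test_family_accuracy_is_mean_of_codes(self, tiny_bundle):
        X, meta = pp.extract_samples(tiny_bundle["preprocessed"]["sPC"],
                                     tiny_bundle["trials_df"])
        results = dec.run_battery(X, meta, "LOSO",
                                  codes=CODE_FAMILIES["UPCOMING"], seed=4)
        fam = dec.family_accuracies(results)
        expected = np.mean([results[c].accuracy for c in CODE_FAMILIES["UPCOMING"]])
        assert fam["UPCOMING"] == pytest.approx(expected, abs=1e-12)

    def test_battery_covers_all_twelve_codes(self, tiny_bundle):
        X, meta = pp.extract_samples(tiny_bundle["preprocessed"]["sPC"],
                                     tiny_bundle["trials_df"])
        results = dec.run_battery(X, meta, "LOSO", seed=4)
        assert set(results) == set(CODE_NAMES)


class TestTimecourse:
    def test_output_shape_and_signal_locking(self, tiny_bundle):
        datasets = tiny_bundle["preprocessed"]
        df = tiny_bundle["trials_df"]
        acc, families = dec.timecourse_decoding(
            datasets, df, roi_list=["sPC", "dPFC"], scans=(1, 5),
            codes=CODE_FAMILIES["UPCOMING"], seed=5)
        assert acc.shape == (2, 4, 2)
        assert families == list(CODE_FAMILIES)
        up = families.index("UPCOMING")
        # sPC encodes upcoming codes at scans 5-6 only: scan 5 beats scan 1
        assert acc[1, up, 0] > acc[0, up, 0]
        # families with no samples... all families computed
        assert np.isfinite(acc[:, up, :]).all()


class TestViewpartSplit:
    def test_groups_partition_and_use_own_code(self, tiny_bundle):
        ds = tiny_bundle["preprocessed"]["sPC"]
        df = tiny_bundle["trials_df"]
        res = dec.viewpart_split_decoding(ds, df, seed=2, min_group=4)
        X, meta = pp.extract_samples(ds, df)
        total = sum(r.n for r in res.values())
        assert total == len(meta)
        for part, r in res.items():
            sub = meta[meta.flipped_part == part]
            assert set(r.trial_ids) == set(sub.trial_id)
            expected = sub.set_index("trial_id")[dec.PART_TRUTH_CODE[part]]
            assert np.array_equal(r.label, expected.loc[r.trial_ids].to_numpy())

    def test_small_group_skipped_with_warning(self, tiny_bundle, caplog):
        ds = tiny_bundle["preprocessed"]["sPC"]
        df = tiny_bundle["trials_df"]
        with caplog.at_level("WARNING"):
            res = dec.viewpart_split_decoding(ds, df, seed=2, min_group=1000)
        assert res == {}
        assert "skipped" in caplog.text


class TestIncorrectTrials:
    def test_schemes_agree_on_correct_trials(self, tiny_bundle):
        df = tiny_bundle["trials_df"]
        correct = df[df.outcome == "CORRECT"]
        for part, truth_col in dec.PART_TRUTH_CODE.items():
            choice_col = dec.PART_CHOICE_CODE[part]
            assert (correct[truth_col] == correct[choice_col]).all()

    def test_no_incorrect_trials_yields_none(self, tiny_bundle):
        ds = tiny_bundle["preprocessed"]["sPC"]
        df = tiny_bundle["trials_df"].copy()
        df.loc[df.outcome == "INCORRECT", "outcome"] = "MISS"
        assert dec.incorrect_trial_evaluation(ds, df, seed=1) is None

    def test_invalid_train_labeling_raises(self, tiny_bundle):
        with pytest.raises(ValueError, match="train_labeling"):
            dec.incorrect_trial_evaluation(
                tiny_bundle["preprocessed"]["sPC"], tiny_bundle["trials_df"],
                train_labeling="oracle")


class TestGroupStats:
    def test_zero_effect_not_significant(self):
        acc = np.full((8, 3), 0.5)
        report = dec.group_stats(acc, chance=0.5)
        assert not report.significant.any()
        assert (report.note != "").all()

    def test_extreme_effect_hits_the_exact_test_floor(self):
        # 8 participants all above chance: the exact signed-rank two-sided
        # p-value reaches its floor 2/2^8, so the effect survives Bonferroni
        # correction up to m = 6 comparisons (and no further: an n = 8
        # signed-rank test cannot beat 0.05/m for larger m)
        acc = np.full((8, 1), 0.9)
        report = dec.group_stats(acc, chance=0.5, n_comparisons=1)
        assert report.p.iloc[0] == pytest.approx(2 / 256)
        assert dec.group_stats(acc, chance=0.5, n_comparisons=6).significant.all()
        assert not dec.group_stats(acc, chance=0.5, n_comparisons=7).significant.any()

    def test_bonferroni_scaling(self):
        rng = np.random.default_rng(0)
        acc = 0.6 + 0.05 * rng.standard_normal((8, 2))
        r1 = dec.group_stats(acc, n_comparisons=1)
        r48 = dec.group_stats(acc, n_comparisons=48)
        np.testing.assert_allclose(
            r48.p_bonf, np.minimum(r1.p_bonf * 48, 1.0), atol=1e-12)

    def test_too_few_participants_raises(self):
        with pytest.raises(ValueError, match="5 participants"):
            dec.group_stats(np.full((4, 2), 0.6))

    def test_two_group_and_friedman_helpers(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0.7, 0.05, 10), rng.normal(0.5, 0.05, 10)
        stat, p = dec.compare_two_groups(a, b)
        assert p < 0.01
        m = rng.normal(0.5, 0.01, (10, 3))
        m[:, 1] += 0.2
        stat, p = dec.friedman_test(m)
        assert p < 0.01
        stat, p = dec.friedman_test(np.full((6, 3), 0.5))
        assert np.isnan(p)  # all-tied: undefined, reported not raised

    def test_empirical_chance_is_majority_rate(self):
        assert dec.empirical_chance(np.array([1, 1, 1, 0])) == 0.75
        assert dec.empirical_chance(np.array([0, 0, 1, 1])) == 0.5
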