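import numpy as np
import pytest

import hemilat as hl
from hemilat.classify import (
    FeatureSelectionError,
    _macro_metrics,
    recalibrate_weights,
)

from conftest import small_spec


def make_features(n_per_class=10, n_feat=30, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat(["RLS", "NRLS", "CTRL"], n_per_class)
    x = rng.standard_normal((labels.size, n_feat))
    x[labels == "RLS", 0] += effect
    x[labels == "NRLS", 1] += effect
    prov = tuple(("LFunctionCorrR", i + 1) for i in range(n_feat))
    sids = np.array([f"s{i}" for i in range(labels.size)])
    return hl.FeatureMatrix(x, labels, sids, sids, prov)


class TestSplit:
    def test_ten_per_class_gives_seven_three(self):
        labels = np.repeat(["RLS", "NRLS", "CTRL"], 10)
        train, test = hl.stratified_split(labels, 0.7, np.random.default_rng(0))
        assert train.size == 21 and test.size == 9
        for cls in ("RLS", "NRLS", "CTRL"):
            assert (labels[train] == cls).sum() == 7

    def test_study_sized_groups(self):
        labels = np.repeat(["RLS", "NRLS", "CTRL"], [11, 16, 16])
        train, test = hl.stratified_split(labels, 0.7, np.random.default_rng(1))
        assert [(labels[train] == c).sum() for c in ("RLS", "NRLS", "CTRL")] == [8, 11, 11]

    def test_same_seed_identical(self):
        labels = np.repeat(["RLS", "NRLS", "CTRL"], 10)
        a = hl.stratified_split(labels, 0.7, np.random.default_rng(5))
        b = hl.stratified_split(labels, 0.7, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])

    def test_leakage_guard_keeps_segments_together(self):
        labels = np.repeat(["RLS", "NRLS", "CTRL"], 12)
        origin = np.array([f"subj{i // 2}" for i in range(36)])  # 2 segments each
        for seed in range(5):
            train, test = hl.stratified_split(
                labels, 0.7, np.random.default_rng(seed), origin=origin, leakage_guard=True
            )
            assert not set(origin[train]) & set(origin[test])

    def test_tiny_class_rejected(self):
        labels = np.array(["RLS", "NRLS", "NRLS", "CTRL", "CTRL"])
        with pytest.raises(ValueError, match="fewer than 2"):
            hl.stratified_split(labels, 0.7, np.random.default_rng(0))


class TestSegmentation:
    @pytest.mark.parametrize("t,k,expect", [(150, 2, 75), (118, 2, 59), (151, 2, 75), (225, 5, 45)])
    def test_block_lengths(self, t, k, expect):
        ts = hl.RoiTimeSeries("s", "CTRL", np.random.default_rng(0).standard_normal((t, 8)))
        segs = hl.segment_subjects([ts], k)
        assert len(segs) == k
        assert all(s.n_timepoints == expect for s in segs)
        assert all(s.subject_id.startswith("s__seg") for s in segs)
        assert all(s.group == "CTRL" for s in segs)

    def test_segments_are_contiguous_blocks(self):
        data = np.arange(100 * 4, dtype=float).reshape(100, 4)
        segs = hl.segment_subjects([hl.RoiTimeSeries("s", "RLS", data)], 2)
        np.testing.assert_array_equal(segs[0].data, data[:50])
        np.testing.assert_array_equal(segs[1].data, data[50:])

    def test_short_segments_warn(self):
        ts = hl.RoiTimeSeries("s", "CTRL", np.random.default_rng(1).standard_normal((50, 4)))
        with pytest.warns(UserWarning, match="noisy"):
            hl.segment_subjects([ts], 2)

    def test_invalid_k(self):
        with pytest.raises(ValueError, match=">= 1"):
            hl.segment_subjects([], 0)


class TestFeatureSelection:
    def test_perfect_feature_found_among_noise(self):
        rng = np.random.default_rng(3)
        y = np.repeat(["RLS", "NRLS", "CTRL"], 15)
        x = rng.standard_normal((45, 50))
        x[:, 17] = np.repeat([0.0, 5.0, 10.0], 15) + 0.01 * rng.standard_normal(45)
        sel, imp = hl.select_features_tree(x, y, seed=0)
        assert 17 in sel
        assert np.all((sel >= 0) & (sel < 50))
        assert np.all(imp > 0)

    def test_duplicate_features_share_all_importance(self):
        # the tree spends its two splits on the separating copies only, so
        # the pair absorbs the full importance and no noise feature survives
        rng = np.random.default_rng(4)
        y = np.repeat(["RLS", "NRLS", "CTRL"], 15)
        x = rng.standard_normal((45, 10)) * 1e-6
        sep = np.repeat([0.0, 5.0, 10.0], 15)
        x[:, 2] = sep
        x[:, 7] = sep
        sel, imp = hl.select_features_tree(x, y, seed=0)
        assert set(sel) <= {2, 7}
        assert imp.sum() == pytest.approx(1.0)

    def test_uninformative_features_raise(self):
        y = np.repeat(["RLS", "NRLS", "CTRL"], 5)
        x = np.zeros((15, 8))
        with pytest.raises(FeatureSelectionError):
            hl.select_features_tree(x, y, seed=0)

    def test_cap_limits_feature_count(self):
        rng = np.random.default_rng(5)
        y = np.repeat(["RLS", "NRLS", "CTRL"], 20)
        x = rng.standard_normal((60, 40))
        sel, _ = hl.select_features_tree(x, y, seed=0, max_features=3)
        assert len(sel) <= 3


class TestClassWeights:
    def test_study_sized_counts(self):
        y = np.repeat(["RLS", "NRLS", "CTRL"], [11, 16, 16])
        w = hl.derive_class_weights(y)
        assert w["RLS"] == pytest.approx(43 / 33)
        assert w["NRLS"] == pytest.approx(43 / 48)
        assert w["CTRL"] == pytest.approx(43 / 48)

    def test_equal_counts_give_unit_weights(self):
        y = np.repeat(["RLS", "NRLS", "CTRL"], 10)
        assert set(hl.derive_class_weights(y).values()) == {1.0}

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing class"):
            hl.derive_class_weights(np.repeat(["RLS", "NRLS"], 5))

    def test_logistic_recalibration_positive_and_mean_one(self):
        fm = make_features(effect=1.0, seed=6)
        w0 = hl.derive_class_weights(fm.labels)
        w = recalibrate_weights(fm.x, fm.labels, w0, seed=0)
        vals = np.array(list(w.values()))
        assert np.all(vals > 0)
        assert vals.mean() == pytest.approx(1.0)


class TestGridSearch:
    def test_single_configuration_chosen(self):
        fm = make_features(effect=2.0, seed=7)
        w = hl.derive_class_weights(fm.labels)
        forest, params = hl.grid_search_rf(
            fm.x, fm.labels, w, [{"n_estimators": 30, "max_depth": 4}], seed=0
        )
        assert params == {"n_estimators": 30, "max_depth": 4}

    def test_deterministic_given_seed(self):
        fm = make_features(effect=1.0, seed=8)
        w = hl.derive_class_weights(fm.labels)
        grid = [{"n_estimators": 20, "max_depth": d} for d in (None, 3)]
        _, p1 = hl.grid_search_rf(fm.x, fm.labels, w, grid, seed=11)
        _, p2 = hl.grid_search_rf(fm.x, fm.labels, w, grid, seed=11)
        assert p1 == p2

    def test_separable_data_interpolated(self):
        fm = make_features(effect=8.0, seed=9)
        w = hl.derive_class_weights(fm.labels)
        forest, _ = hl.grid_search_rf(
            fm.x, fm.labels, w, [{"n_estimators": 50, "max_depth": None}], seed=0
        )
        assert (forest.predict(fm.x) == fm.labels).mean() == 1.0


class TestMetrics:
    def test_diagonal_confusion_all_ones(self):
        y = np.repeat(["RLS", "NRLS", "CTRL"], 2)
        proba = np.zeros((6, 3))
        for i, c in enumerate(("RLS", "NRLS", "CTRL")):
            proba[y == c, i] = 1.0
        rec = _macro_metrics(y, y.copy(), proba, ["RLS", "NRLS", "CTRL"])
        for v in rec.as_dict().values():
            assert v == pytest.approx(1.0)
        np.testing.assert_array_equal(rec.confusion, 2 * np.eye(3))

    def test_off_diagonal_hand_arithmetic(self):
        # confusion [[2,1,0],[0,2,0],[0,0,2]] -> ACC 6/7
        y_true = np.array(["RLS"] * 3 + ["NRLS"] * 2 + ["CTRL"] * 2)
        y_pred = np.array(["RLS", "RLS", "NRLS", "NRLS", "NRLS", "CTRL", "CTRL"])
        proba = np.full((7, 3), 1 / 3)
        rec = _macro_metrics(y_true, y_pred, proba, ["RLS", "NRLS", "CTRL"])
        assert rec.acc == pytest.approx(6 / 7)
        np.testing.assert_array_equal(rec.confusion, [[2, 1, 0], [0, 2, 0], [0, 0, 2]])
        # macro sensitivity: mean(2/3, 1, 1)
        assert rec.sen == pytest.approx((2 / 3 + 1 + 1) / 3)

    def test_label_permutation_yields_chance_accuracy(self):
        fm = make_features(n_per_class=12, effect=5.0, seed=10)
        cfg = hl.PipelineConfig(n_repetitions=1, rf_n_estimators=(30,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        bundle = report.bundles[0]
        test = report.test_indices[0]
        rng = np.random.default_rng(0)
        accs = [
            hl.evaluate(bundle, fm.x[test], rng.permutation(fm.labels[test])).acc
            for _ in range(100)
        ]
        assert abs(np.mean(accs) - 1 / 3) < 0.05


class TestHarness:
    def test_single_repetition_aggregate(self):
        fm = make_features(effect=3.0, seed=11)
        cfg = hl.PipelineConfig(n_repetitions=1, rf_n_estimators=(30,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        agg = report.aggregate_frame()
        assert (agg["ci_low"] == agg["mean"]).all() and (agg["ci_high"] == agg["mean"]).all()
        assert agg.set_index("metric")["mean"]["ACC"] == report.records[0].acc

    def test_end_to_end_determinism(self):
        fm = make_features(effect=1.5, seed=12)
        cfg = hl.PipelineConfig(n_repetitions=4, rf_n_estimators=(30,), rf_max_depth=(None, 3),
                                rng_seed=99)
        r1 = hl.repeat_harness(fm, cfg)
        r2 = hl.repeat_harness(fm, cfg)
        assert r1.per_repetition_frame().equals(r2.per_repetition_frame())
        np.testing.assert_array_equal(r1.importances, r2.importances)

    def test_failed_selection_counted_as_skipped(self):
        fm = make_features(effect=0.0, seed=13)
        fm.x[:] = 0.0
        cfg = hl.PipelineConfig(n_repetitions=3, rf_n_estimators=(10,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        assert report.n_skipped == 3 and not report.records

    def test_importances_zero_for_unselected(self):
        fm = make_features(effect=3.0, seed=14)
        cfg = hl.PipelineConfig(n_repetitions=2, rf_n_estimators=(30,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        for row, bundle in zip(report.importances, report.bundles):
            unselected = np.setdiff1d(np.arange(fm.n_features), bundle.selected)
            assert np.all(row[unselected] == 0)


class TestExternalValidation:
    def test_identical_validation_set_reproduces_metrics(self):
        fm = make_features(n_per_class=10, effect=2.0, seed=15)
        cfg = hl.PipelineConfig(n_repetitions=1, rf_n_estimators=(30,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        test = report.test_indices[0]
        ctrl_rows = test[fm.labels[test] == "CTRL"]
        new_controls = fm.rows(ctrl_rows)
        val = hl.external_validation(report, fm, new_controls, cfg, control_fraction=1.0)
        assert val.records[0].acc == pytest.approx(report.records[0].acc)
        assert val.records[0].as_dict() == pytest.approx(report.records[0].as_dict())

    def test_matched_controls_generalize(self):
        fm = make_features(n_per_class=12, effect=3.0, seed=16)
        cfg = hl.PipelineConfig(n_repetitions=5, rf_n_estimators=(30,), rf_max_depth=(None,))
        report = hl.repeat_harness(fm, cfg)
        new_controls = make_features(n_per_class=12, effect=3.0, seed=17)
        ctrl = new_controls.rows(np.nonzero(new_controls.labels == "CTRL")[0])
        val = hl.external_validation(report, fm, ctrl, cfg)
        assert abs(val.mean_metric() - report.mean_metric()) < 0.15

    def test_feature_misalignment_rejected(self):
        fm = make_features(seed=18)
        cfg = hl.PipelineConfig(n_repetitions=1, rf_n_estimators=(10,), rf_max_depth=(None,))
        report = hl.repeat_harness(make_features(effect=2.0, seed=19), cfg)
        bad = fm.family_subset("LFunctionCorrR").rows(np.arange(5))
        bad2 = hl.FeatureMatrix(bad.x[:, :10], bad.labels[:5], bad.subject_ids[:5],
                                bad.origin[:5], bad.provenance[:10])
        with pytest.raises(ValueError, match="misaligned"):
            hl.external_validation(report, fm, bad2, cfg)


class TestLeakage:
    def test_unguarded_segmentation_inflates_accuracy(self):
        """Pseudo-subject segments split across train/test leak identity."""
        spec = small_spec(n_per_group=(8, 8, 8), t_per_group=(120, 120, 120),
                          asymmetry_delta=0.1)
        subs, _ = hl.sample_cohort(spec, seed=55)
        parcels = spec.parcel_table()
        base_cfg = dict(n_repetitions=8, rf_n_estimators=(50,), rf_max_depth=(None,), rng_seed=2)
        segs = hl.segment_subjects(subs, 2)
        cfg = hl.PipelineConfig(**base_cfg)
        profiles = [hl.compute_profile(ts, parcels, cfg) for ts in segs]
        fm = hl.profiles_to_features(profiles)
        guarded = hl.repeat_harness(fm, hl.PipelineConfig(**base_cfg, leakage_guard=True))
        leaky = hl.repeat_harness(fm, hl.PipelineConfig(**base_cfg, leakage_guard=False))
        assert leaky.mean_metric() >= guarded.mean_metric()
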