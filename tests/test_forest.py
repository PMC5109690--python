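"""Tests for information gain, cost weighting, forest training and CV."""

import numpy as np
import pytest

from snvforest.evaluation import EvaluationReport
from snvforest.features import FEATURE_NAMES
from snvforest.forest import (
    TrainingInstance, apply_costs, cross_validate, features_per_node,
    filter_vaf_interval, information_gain, predict, predict_batch,
    rank_features, train_forest,
)
from conftest import feature_instances
from oracles import entropy_oracle, information_gain_oracle


class TestInformationGain:
    def test_feature_equals_class(self):
        assert information_gain([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_feature(self):
        assert information_gain([1, 0, 1, 0], [1, 1, 0, 0]) == pytest.approx(0.0)

    def test_partial_predictor_entropy_arithmetic(self):
        # H(3/4) - 0.5*H(1.0) - 0.5*H(0.5)
        expected = entropy_oracle([1, 1, 1, 0]) - 0.5 * 0.0 - 0.5 * 1.0
        assert information_gain([1, 1, 0, 0], [1, 1, 1, 0]) == pytest.approx(
            expected, abs=1e-12)

    def test_single_class_gives_zero(self):
        assert information_gain([1, 2, 3, 4], [1, 1, 1, 1]) == 0.0

    def test_constant_feature_gives_zero(self):
        assert information_gain([7, 7, 7, 7], [1, 0, 1, 0]) == 0.0

    def test_continuous_threshold_search(self):
        # threshold between 2 and 10 separates perfectly
        assert information_gain([1, 2, 10, 11], [0, 0, 1, 1]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_entropy_oracle_on_random_binary_data(self, seed):
        """Binary features: threshold discretization coincides with direct
        conditioning, so IG must equal the entropy oracle exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)
        expected = information_gain_oracle(x.tolist(), y.tolist()) if len(set(x)) > 1 else 0.0
        if len(set(y.tolist())) == 1:
            expected = 0.0
        assert information_gain(x, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegative_and_bounded_by_class_entropy(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        ig = information_gain(x, y)
        assert 0.0 <= ig <= entropy_oracle(y.tolist()) + 1e-12


class TestRankFeatures:
    def test_perfect_predictor_ranks_first_constant_last(self):
        rng = np.random.default_rng(0)
        instances = []
        for _ in range(40):
            label = "TP" if rng.random() < 0.5 else "FP"
            instances.append(TrainingInstance({
                "perfect": 1.0 if label == "TP" else 0.0,
                "noise": float(rng.normal()),
                "constant": 3.0,
            }, label))
        ranked = rank_features(instances)
        assert ranked[0][0] == "perfect" and ranked[0][1] == pytest.approx(
            entropy_oracle([i.label for i in instances]), abs=1e-12)
        assert ranked[-1][0] == "constant" and ranked[-1][1] == 0.0

    def test_deterministic_tiebreak_by_name(self):
        instances = [TrainingInstance({"b": v, "a": v, "c": v}, l)
                     for v, l in [(1.0, "TP"), (1.0, "TP"), (0.0, "FP"), (0.0, "FP")]]
        assert [n for n, _ in rank_features(instances)] == ["a", "b", "c"]

    def test_single_class_raises(self):
        instances = [TrainingInstance({"x": float(i)}, "TP") for i in range(5)]
        with pytest.raises(ValueError, match="both classes"):
            rank_features(instances)


class TestCostsAndVaf:
    @staticmethod
    def _balanced(n=250):
        return ([TrainingInstance({"tumor_vaf": 0.4}, "TP") for _ in range(n)]
                + [TrainingInstance({"tumor_vaf": 0.1}, "FP") for _ in range(n)])

    def test_unit_costs_identity(self):
        inst = self._balanced()
        out = apply_costs(inst, 1.0, 1.0)
        assert [i.weight for i in out] == [1.0] * len(inst)

    def test_fp_cost_scales_fp_weights(self):
        out = apply_costs(self._balanced(250), 10.0, 1.0)
        fp_total = sum(i.weight for i in out if i.label == "FP")
        tp_total = sum(i.weight for i in out if i.label == "TP")
        assert fp_total == pytest.approx(2500.0)
        assert tp_total == pytest.approx(250.0)
        assert len(out) == 500

    def test_nonpositive_cost_raises(self):
        with pytest.raises(ValueError):
            apply_costs(self._balanced(5), 0.0, 1.0)

    def test_vaf_interval_identity_and_subset(self):
        inst = [TrainingInstance({"tumor_vaf": v}, "TP") for v in (0.1, 0.5, 0.9)]
        assert filter_vaf_interval(inst, 0.0, 1.0) == inst
        kept = filter_vaf_interval(inst, 0.4, 0.6)
        assert [i.features["tumor_vaf"] for i in kept] == [0.5]

    def test_degenerate_interval_raises(self):
        inst = [TrainingInstance({"tumor_vaf": 0.5}, "TP")]
        with pytest.raises(ValueError):
            filter_vaf_interval(inst, 0.5, 0.5)

    def test_empty_result_advises_wider_interval(self):
        inst = [TrainingInstance({"tumor_vaf": 0.9}, "TP")]
        with pytest.raises(ValueError, match="widen"):
            filter_vaf_interval(inst, 0.1, 0.2)


class TestFeaturesPerNode:
    def test_fifteen_features_give_four(self):
        assert features_per_node(15) == 4

    def test_exact_power_of_two(self):
        assert features_per_node(16) == 5

    @pytest.mark.parametrize("m,k", [(1, 1), (2, 2), (3, 2), (8, 4)])
    def test_floor_convention(self, m, k):
        assert features_per_node(m) == k


class TestTrainPredict:
    def test_model_records_hyperparameters(self):
        inst = feature_instances(30, 30, seed=1)
        model = train_forest(inst, n_trees=20, seed=5, costs=(2.0, 1.0))
        assert model.n_trees == 20 and len(model.trees) == 20
        assert model.features_per_node == 4  # 15 features
        assert model.seed == 5 and model.class_costs == (2.0, 1.0)
        assert set(model.selected_features) == set(FEATURE_NAMES)

    def test_separable_data_zero_oob(self):
        inst = feature_instances(100, 100, seed=2, shift=8.0)
        model = train_forest(inst, n_trees=50, seed=0)
        assert model.oob_error == 0.0

    def test_single_class_raises(self):
        inst = feature_instances(20, 0, seed=0)
        with pytest.raises(ValueError, match="both"):
            train_forest(inst, n_trees=5, seed=0)

    def test_reproducible_given_seed(self, tmp_path):
        inst = feature_instances(40, 60, seed=3, shift=1.0)
        m1 = train_forest(inst, n_trees=30, seed=7)
        m2 = train_forest(inst, n_trees=30, seed=7)
        m1.save(tmp_path / "a.json")
        m2.save(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        m3 = train_forest(inst, n_trees=30, seed=8)
        _, f2 = predict_batch(m2, [i.features for i in inst])
        _, f3 = predict_batch(m3, [i.features for i in inst])
        assert not np.allclose(f2, f3)  # different seed, different forest

    def test_probability_range_and_tie_rule(self):
        inst = feature_instances(50, 50, seed=4, shift=0.3)  # heavy overlap
        model = train_forest(inst, n_trees=40, seed=1)
        labels, frac = predict_batch(model, [i.features for i in inst])
        for lab, f in zip(labels, frac):
            p = f if lab == "TP" else 1.0 - f
            assert 0.5 <= p <= 1.0
            if f == 0.5:
                assert lab == "FP"  # conservative tie

    def test_predict_missing_feature_named(self):
        inst = feature_instances(20, 20, seed=5)
        model = train_forest(inst, n_trees=5, seed=0)
        fv = dict(inst[0].features)
        fv.pop("tumor_vaf")
        with pytest.raises(KeyError, match="tumor_vaf"):
            predict(model, fv)

    def test_saved_and_loaded_model_predicts_identically(self, tmp_path):
        inst = feature_instances(40, 40, seed=6)
        model = train_forest(inst, n_trees=25, seed=3)
        model.save(tmp_path / "m.json")
        from snvforest.forest import ForestModel
        loaded = ForestModel.load(tmp_path / "m.json")
        fvs = [i.features for i in inst]
        assert np.array_equal(predict_batch(model, fvs)[1],
                              predict_batch(loaded, fvs)[1])
        assert loaded.oob_error == model.oob_error

    def test_forest_beats_single_tree_on_train_votes(self):
        inst = feature_instances(80, 80, seed=7, shift=4.0)
        model = train_forest(inst, n_trees=40, seed=2)
        labels, _ = predict_batch(model, [i.features for i in inst])
        acc = np.mean([l == i.label for l, i in zip(labels, inst)])
        assert acc >= 1.0 - model.oob_error - 1e-9


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        inst = feature_instances(10, 10, seed=8, shift=8.0)
        report = cross_validate(inst, k=5, seed=0, n_trees=15)
        assert isinstance(report, EvaluationReport)
        assert report.accuracy == 1.0 and report.roc_auc == 1.0

    def test_same_seed_identical_scores(self):
        inst = feature_instances(30, 40, seed=9, shift=1.0)
        r1 = cross_validate(inst, k=5, seed=4, n_trees=10)
        r2 = cross_validate(inst, k=5, seed=4, n_trees=10)
        assert r1.roc_auc == r2.roc_auc and r1.threshold_table == r2.threshold_table

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            cross_validate(feature_instances(10, 10), k=1)

    def test_k_above_minority_count_rejected(self):
        inst = feature_instances(3, 50, seed=10)
        with pytest.raises(ValueError, match="minority"):
            cross_validate(inst, k=10)
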