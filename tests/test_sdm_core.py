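import numpy as np
import pytest

from symbiosdm.grid_io import ClimateLayerSet, Grid, OccurrenceMap
from symbiosdm.sdm_core import (
    EnsembleModel,
    FittedLearner,
    LearnerSpec,
    SurfaceRangeEnvelope,
    fit_ensemble,
    fit_learner,
    make_learner,
    predict_prob,
    rank_variables,
    split_data,
    variable_importance,
)
from symbiosdm.evaluation import auc

from conftest import make_occurrence


def _layers_1d(x, name="x", period="current"):
    n = len(x)
    grid = Grid.regular(1, n)
    return ClimateLayerSet(grid, period, {name: np.asarray(x, float)})


class TestSplitData:
    def test_seventy_thirty_arithmetic(self):
        occ = make_occurrence([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], n_cols=5)
        split = split_data(occ, 0.7, seed=0)
        assert len(split.training) == 7 and len(split.test) == 3

    def test_same_seed_identical(self):
        occ = make_occurrence([1, 0] * 10, n_cols=10)
        a, b = split_data(occ, seed=3), split_data(occ, seed=3)
        np.testing.assert_array_equal(a.training, b.training)
        np.testing.assert_array_equal(a.test, b.test)

    def test_partition_properties(self):
        occ = make_occurrence([1, 0, -1, 1, 0, 1, 0, 0, 1, 0], n_cols=5)
        split = split_data(occ, 0.7, seed=1)
        surveyed = set(np.flatnonzero(occ.surveyed))
        assert set(split.training) | set(split.test) == surveyed
        assert not set(split.training) & set(split.test)

    def test_fraction_one_flags_empty_test(self):
        occ = make_occurrence([1, 0, 1, 0], n_cols=2)
        with pytest.warns(UserWarning, match="empty test"):
            split = split_data(occ, 1.0, seed=0)
        assert split.empty_test and len(split.test) == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            split_data(make_occurrence([1, 1, 1, 1], n_cols=2), seed=0)


class TestSurfaceRangeEnvelope:
    def test_q_zero_envelope_is_presence_range(self):
        X = np.arange(1.0, 101.0)[:, None]
        sre = SurfaceRangeEnvelope(q=0.0).fit(X, np.ones(100))
        probe = np.array([[0.99], [1.0], [50.0], [100.0], [100.01]])
        np.testing.assert_array_equal(sre.predict_proba(probe), [0, 1, 1, 1, 0])

    def test_predictions_are_binary(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 2))
        sre = SurfaceRangeEnvelope().fit(X, np.ones(50))
        assert set(np.unique(sre.predict_proba(rng.random((200, 2))))) <= {0.0, 1.0}

    def test_needs_two_presences(self):
        with pytest.raises(ValueError, match="2 presences"):
            SurfaceRangeEnvelope().fit(np.ones((3, 1)), [1, 0, 0])


class TestGlmPoly2:
    def test_separable_data_has_training_auc_one(self):
        x = np.concatenate([np.linspace(-5, -1, 25), np.linspace(1, 5, 25)])
        y = (x > 0).astype(int)
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", y.astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(50))
        scores = predict_prob(fl, layers).probability
        assert auc(scores, y) == 1.0

    def test_null_labels_give_chance_auc(self):
        rng = np.random.default_rng(11)
        n = 500
        x = rng.normal(size=n)
        y = rng.random(n) < 0.5  # labels independent of x
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", y.astype(np.int8))
        split = split_data(occ, 0.7, seed=11)
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, split.training)
        scores = predict_prob(fl, layers).probability[split.test]
        assert 0.35 <= auc(scores, y[split.test]) <= 0.65

    def test_constant_predictor_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        grid = Grid.regular(1, 40)
        layers = ClimateLayerSet(
            grid, "current", {"x": rng.normal(size=40), "c": np.full(40, 3.0)}
        )
        occ = OccurrenceMap(grid, "sp", (rng.random(40) < 0.5).astype(np.int8))
        with caplog.at_level("WARNING"):
            fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(40))
        assert fl.dropped == ["c"] and fl.predictor_names == ["x"]

    def test_unknown_learner_name(self):
        with pytest.raises(KeyError, match="unknown learner"):
            make_learner(LearnerSpec("gbm"))


def _const_member(value, names=("x",)):
    class Const:
        def predict_proba(self, X):
            return np.full(len(X), value)

    return FittedLearner(
        spec=LearnerSpec(f"const{value}"),
        predictor_names=list(names),
        learner=Const(),
        species="sp",
        n_presences=1,
        n_absences=1,
    )


class TestEnsemble:
    def test_mean_of_members(self):
        layers = _layers_1d(np.linspace(0, 1, 10))
        ens = EnsembleModel(members=[_const_member(0.2), _const_member(0.4)])
        np.testing.assert_allclose(predict_prob(ens, layers).probability, 0.3)

    def test_single_member_identity(self):
        x = np.linspace(-2, 2, 30)
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", (x > 0).astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(30))
        ens = EnsembleModel(members=[fl])
        np.testing.assert_array_equal(
            predict_prob(ens, layers).probability, predict_prob(fl, layers).probability
        )

    def test_bounded_by_member_min_max(self):
        x = np.linspace(-2, 2, 60)
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", (np.abs(x) < 1).astype(np.int8))
        ens = fit_ensemble(
            [LearnerSpec("glm_poly2"), LearnerSpec("sre")], layers, occ, np.arange(60)
        )
        member_probs = np.vstack(
            [predict_prob(m, layers).probability for m in ens.members]
        )
        combined = predict_prob(ens, layers).probability
        assert (combined >= member_probs.min(axis=0) - 1e-12).all()
        assert (combined <= member_probs.max(axis=0) + 1e-12).all()

    def test_missing_cells_propagate(self):
        x = np.linspace(-2, 2, 20)
        x[3] = np.nan
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", (np.nan_to_num(x) > 0).astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(20))
        assert np.isnan(predict_prob(fl, layers).probability[3])


class TestVariableImportance:
    def test_absent_predictor_importance_exactly_zero(self):
        rng = np.random.default_rng(0)
        n = 100
        grid = Grid.regular(1, n)
        layers_one = ClimateLayerSet(grid, "current", {"a": rng.normal(size=n)})
        occ = OccurrenceMap(grid, "sp", (layers_one.variables["a"] > 0).astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers_one, occ, np.arange(n))
        layers_two = ClimateLayerSet(
            grid,
            "current",
            {"a": layers_one.variables["a"], "b": rng.normal(size=n)},
        )
        imp = variable_importance(fl, layers_two, n_perm=3, seed=0)
        assert imp["b"] == 0.0
        assert imp["a"] > 0.1

    def test_matches_hand_rolled_permutation_loop(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", (x + 0.3 * rng.normal(size=n) > 0).astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(n))
        n_perm, seed = 4, 9
        imp = variable_importance(fl, layers, n_perm=n_perm, seed=seed)

        # independent transcription of the randomisation scheme: same
        # seeded stream, one permutation per round, 1 - Pearson r
        ref = predict_prob(fl, layers).probability
        rng2 = np.random.default_rng(seed)
        scores = []
        for _ in range(n_perm):
            perm = rng2.permutation(n)
            permuted_layers = ClimateLayerSet(layers.grid, "current", {"x": x[perm]})
            pred = predict_prob(fl, permuted_layers).probability
            scores.append(1.0 - np.corrcoef(ref, pred)[0, 1])
        np.testing.assert_allclose(imp["x"], np.mean(scores), rtol=1e-12)

    def test_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        layers = _layers_1d(x)
        occ = OccurrenceMap(layers.grid, "sp", (x > 0).astype(np.int8))
        fl = fit_learner(LearnerSpec("glm_poly2"), layers, occ, np.arange(80))
        a = variable_importance(fl, layers, n_perm=2, seed=4)
        b = variable_importance(fl, layers, n_perm=2, seed=4)
        assert a == b

    def test_invalid_n_perm(self):
        fl = _const_member(0.5)
        with pytest.raises(ValueError):
            variable_importance(fl, _layers_1d([1.0, 2.0]), n_perm=0, seed=0)


class TestRankVariables:
    @pytest.mark.parametrize(
        "imp, expected",
        [
            ({"a": 0.1, "b": 0.9}, ["b", "a"]),
            ({"a": 0.5, "b": 0.5}, ["a", "b"]),  # tie -> lexicographic
            ({"only": 0.2}, ["only"]),
        ],
    )
    def test_ordering(self, imp, expected):
        assert rank_variables(imp) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_variables({})
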