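import numpy as np
import pandas as pd
import pytest

from virtualsdm import (
    ALGORITHMS,
    CVPlan,
    EnvStack,
    GridSpec,
    ModelSpec,
    Raster,
    auc,
    cross_validate,
    fit_model,
    independent_evaluation,
    make_background,
    predict_surface,
    sample_presences,
)
from virtualsdm.errors import DegenerateDataError, GridError, ParameterError
from virtualsdm.predictor_prep import extract_features

FAST_PARAMS = {"GBM": {"n_estimators": 150}}  # keep the boosted model quick


def spec_for(alg, seed=0):
    return ModelSpec(alg, FAST_PARAMS.get(alg, {}), seed=seed)


def toy_table(n_pos=20, n_neg=20, seed=0, separation=2.0):
    rng = np.random.default_rng(seed)
    x_pos = separation / 2 + 0.3 * rng.random(n_pos)
    x_neg = -separation / 2 - 0.3 * rng.random(n_neg)
    return pd.DataFrame(
        {
            "x": np.concatenate([x_pos, x_neg]),
            "label": np.array([1] * n_pos + [0] * n_neg),
        }
    )


class TestModelSpec:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec("GARP")

    def test_defaults_filled_and_overridable(self):
        spec = ModelSpec("RF", {"n_estimators": 50})
        assert spec.resolved()["n_estimators"] == 50
        assert ModelSpec("RF").resolved()["n_estimators"] == 500


class TestMakeBackground:
    def test_seeded_repeatability(self, small_stack):
        a = make_background(small_stack, 500, seed=7)
        b = make_background(small_stack, 500, seed=7)
        c = make_background(small_stack, 500, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_points_fall_in_valid_cells(self):
        spec = GridSpec(10, 10)
        values = np.ones((10, 10))
        values[:5, :] = np.nan
        stack = EnvStack([("a", Raster(spec, values))])
        pts = make_background(stack, 300, seed=1)
        rows, cols = spec.cell_of(pts[:, 0], pts[:, 1])
        assert np.all(rows >= 5)


class TestFitModel:
    def test_single_class_rejected(self):
        table = pd.DataFrame({"x": [0.1, 0.2, 0.3], "label": [1, 1, 1]})
        with pytest.raises(DegenerateDataError):
            fit_model(ModelSpec("GLM"), table)

    def test_too_few_presences_rejected(self):
        table = pd.DataFrame({"x": [0.1, 0.2, 0.3], "label": [1, 0, 0]})
        with pytest.raises(DegenerateDataError):
            fit_model(ModelSpec("GLM"), table)

    def test_rf_separable_data_gives_perfect_training_auc(self):
        table = toy_table(seed=1)
        model = fit_model(spec_for("RF", seed=2), table)
        scores = model.predict(table[["x"]].to_numpy())
        assert auc(scores, table["label"].to_numpy()) == 1.0

    def test_glm_prediction_monotone_in_informative_predictor(self):
        table = toy_table(n_pos=40, n_neg=40, seed=3)
        model = fit_model(ModelSpec("GLM", seed=4), table)
        grid = np.sort(table["x"].to_numpy()).reshape(-1, 1)
        preds = model.predict(grid)
        assert np.all(np.diff(preds) >= -1e-9)

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_all_algorithms_share_the_contract(self, alg):
        table = toy_table(n_pos=30, n_neg=60, seed=5)
        model = fit_model(spec_for(alg, seed=6), table)
        scores = model.predict(table[["x"]].to_numpy())
        assert scores.shape == (90,)
        assert np.all((scores >= 0.0) & (scores <= 1.0))
        # separable data: every algorithm must rank presences on top
        assert auc(scores, table["label"].to_numpy()) > 0.95

    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_seeded_fits_are_deterministic(self, alg):
        table = toy_table(seed=7)
        X = table[["x"]].to_numpy()
        a = fit_model(spec_for(alg, seed=8), table).predict(X)
        b = fit_model(spec_for(alg, seed=8), table).predict(X)
        assert np.array_equal(a, b)


class TestPredictSurface:
    @pytest.fixture()
    def fitted(self, small_stack, generalist):
        occ = sample_presences(generalist, 60, seed=1)
        bg = make_background(small_stack, 300, seed=2)
        pts = np.vstack([occ.points, bg])
        labels = np.array([1] * 60 + [0] * 300)
        feats = extract_features(small_stack, pts, labels=labels)
        return fit_model(ModelSpec("GLM", seed=3), feats)

    def test_surface_in_unit_interval_and_deterministic(self, fitted, small_stack):
        a = predict_surface(fitted, small_stack)
        b = predict_surface(fitted, small_stack)
        assert np.nanmin(a.values) >= 0.0 and np.nanmax(a.values) <= 1.0
        assert np.array_equal(a.values, b.values)

    def test_constant_stack_gives_constant_surface(self, fitted, small_stack):
        spec = small_stack.spec
        flat = EnvStack(
            [(n, Raster(spec, np.full(spec.shape, 1.5))) for n in small_stack.names]
        )
        out = predict_surface(fitted, flat)
        assert np.allclose(out.values, out.values.flat[0])

    def test_missing_layer_rejected(self, fitted, small_stack):
        partial = small_stack.subset(small_stack.names[:-1])
        with pytest.raises(GridError):
            predict_surface(fitted, partial)

    def test_nodata_cells_propagate(self, fitted, small_stack):
        spec = small_stack.spec
        layers = []
        for i, name in enumerate(small_stack.names):
            values = small_stack[name].values.copy()
            if i == 0:
                values[0, 0] = np.nan
            layers.append((name, Raster(spec, values)))
        out = predict_surface(fitted, EnvStack(layers))
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:, :]).all()


@pytest.fixture(scope="module")
def runs(small_stack, generalist):
    occ = sample_presences(generalist, 30, seed=4)
    plan = CVPlan(background_size=200, seed=5)
    return cross_validate(ModelSpec("GLM", seed=6), occ.points, small_stack, plan)


class TestCrossValidate:
    def test_exactly_25_runs(self, runs):
        assert len(runs) == 25
        assert {(r.replicate, r.fold) for r in runs} == {
            (rep, fold) for rep in range(5) for fold in range(5)
        }

    def test_folds_partition_each_replicate(self, runs):
        for rep in range(5):
            rep_runs = [r for r in runs if r.replicate == rep]
            all_test = np.concatenate([r.test_index for r in rep_runs])
            assert len(all_test) == len(set(all_test)) == 230
            for r in rep_runs:
                assert not set(r.test_index) & set(r.train_index)
                assert set(r.test_index) | set(r.train_index) == set(all_test)

    def test_each_fold_holds_both_classes(self, runs):
        for r in runs:
            assert set(np.unique(r.test_labels)) == {0, 1}

    def test_replicates_use_distinct_backgrounds(self, small_stack, generalist):
        occ = sample_presences(generalist, 10, seed=7)
        plan = CVPlan(background_size=100, seed=8)
        runs = cross_validate(ModelSpec("GLM", seed=9), occ.points, small_stack, plan)
        sizes = {len(r.test_index) for r in runs}
        assert all(s == 22 for s in sizes)  # 2 presences + 20 background
        rep_scores = {
            rep: np.sort(
                np.concatenate(
                    [r.test_scores for r in runs if r.replicate == rep]
                )
            )
            for rep in range(5)
        }
        assert not np.allclose(rep_scores[0], rep_scores[1])

    def test_too_few_presences_rejected(self, small_stack, generalist):
        occ = sample_presences(generalist, 4, seed=10)
        with pytest.raises(DegenerateDataError):
            cross_validate(ModelSpec("GLM"), occ.points, small_stack, CVPlan())


class TestHighSampleSizeRecovery:
    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_every_algorithm_recovers_the_generalist_at_n200(
        self, alg, small_stack, generalist
    ):
        """At 200 precise presences each algorithm crosses the 0.7 AUC bar."""
        occ = sample_presences(generalist, 200, seed=11)
        bg = make_background(small_stack, 500, seed=12)
        pts = np.vstack([occ.points, bg])
        labels = np.array([1] * 200 + [0] * 500)
        feats = extract_features(small_stack, pts, labels=labels)
        model = fit_model(spec_for(alg, seed=13), feats)
        rec = independent_evaluation(
            model, generalist, small_stack, n_eval=400, seed=14
        )
        assert rec.auc > 0.7
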