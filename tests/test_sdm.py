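"""Pseudoabsence generation, skill metrics, the ensemble classifier, and
map prediction/binarization."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from sklearn.metrics import cohen_kappa_score

from benthoshift.sdm import (
    EnsembleHabitatClassifier,
    PerformanceReport,
    binarize,
    evaluate_predictions,
    features_at_points,
    generate_pseudoabsences,
    variable_importance,
)
from benthoshift.synth import TrueHabitatModel, sample_occurrences


def _presences(small_grid, bathy, n=40, seed=0):
    rng = np.random.default_rng(seed)
    ocean = np.argwhere(np.isfinite(bathy.values))
    pick = ocean[rng.choice(len(ocean), size=n, replace=False)]
    return pd.DataFrame(
        {
            "lon": bathy["lon"].values[pick[:, 0]],
            "lat": bathy["lat"].values[pick[:, 1]],
            "depth": bathy.values[pick[:, 0], pick[:, 1]],
            "species": "t",
            "label": 1,
            "set_id": 0,
        }
    )


class TestPseudoabsences:
    def test_each_set_matches_presence_count(self, small_grid, bathy):
        pres = _presences(small_grid, bathy, n=37)
        table = generate_pseudoabsences(pres, small_grid, bathy, n_sets=3, seed=1)
        for s in (1, 2, 3):
            assert (table["set_id"] == s).sum() == 37
        assert (table["label"] == 1).sum() == 37

    def test_no_shared_cells_with_presences(self, small_grid, bathy):
        pres = _presences(small_grid, bathy, n=50)
        table = generate_pseudoabsences(pres, small_grid, bathy, n_sets=3, seed=2)
        pres_cells = set(zip(pres["lon"].round(6), pres["lat"].round(6)))
        absn = table[table["label"] == 0]
        abs_cells = set(zip(absn["lon"].round(6), absn["lat"].round(6)))
        assert not pres_cells & abs_cells

    def test_depths_read_from_bathymetry(self, small_grid, bathy):
        pres = _presences(small_grid, bathy, n=20)
        table = generate_pseudoabsences(pres, small_grid, bathy, n_sets=1, seed=3)
        absn = table[table["label"] == 0]
        assert np.isfinite(absn["depth"]).all()
        assert (absn["depth"] >= 0).all()

    def test_seeded_reproducibility(self, small_grid, bathy):
        pres = _presences(small_grid, bathy, n=25)
        a = generate_pseudoabsences(pres, small_grid, bathy, seed=9)
        b = generate_pseudoabsences(pres, small_grid, bathy, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_eligible_cells_raise(self, small_grid, bathy):
        n_ocean = int(np.isfinite(bathy.values).sum())
        pres = _presences(small_grid, bathy, n=100)
        pres_big = pd.concat([pres] * ((n_ocean // 100) + 1), ignore_index=True)
        with pytest.raises(ValueError, match="eligible"):
            generate_pseudoabsences(pres_big, small_grid, bathy, seed=0)


class TestMetrics:
    def test_hand_computed_confusion_table(self):
        r = PerformanceReport.from_counts(tp=9, fp=2, tn=8, fn=1)
        assert r.sensitivity == pytest.approx(0.90)
        assert r.specificity == pytest.approx(0.80)
        assert r.tss == pytest.approx(0.70)
        assert r.accuracy == pytest.approx(0.85)
        assert r.kappa == pytest.approx(0.70)

    def test_kappa_matches_sklearn_oracle(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_prob = np.clip(y_true * 0.6 + rng.normal(0.2, 0.3, 200), 0, 1)
        r = evaluate_predictions(y_true, y_prob, 0.5)
        y_pred = (y_prob >= 0.5).astype(int)
        assert r.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))
        assert r.accuracy == pytest.approx(np.mean(y_true == y_pred))

    def test_perfect_predictions(self):
        y = np.array([0, 1] * 10)
        r = evaluate_predictions(y, y.astype(float))
        assert r.tss == r.kappa == r.accuracy == 1.0

    def test_degenerate_all_presence_classifier(self):
        y = np.array([0, 1] * 10)
        r = evaluate_predictions(y, np.ones_like(y, dtype=float))
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0
        assert r.tss == pytest.approx(0.0)

    def test_tss_identity_holds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            if y.min() == y.max():
                continue
            p = rng.random(60)
            r = evaluate_predictions(y, p)
            assert r.tss == pytest.approx(r.sensitivity + r.specificity - 1)

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError):
            evaluate_predictions(np.array([]), np.array([]))


class TestEnsembleClassifier:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 3))
        X[:, 0] += y * 4.0
        return X, y

    def test_separable_data_high_accuracy(self):
        X, y = self._separable()
        model = EnsembleHabitatClassifier(
            n_estimators=100, max_features=2, n_repeats=2, random_state=0
        )
        model.fit(X, y)
        assert model.performance_["accuracy"].mean() >= 0.95

    def test_noise_labels_give_near_zero_skill(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(240, 3))
        y = np.repeat([0, 1], 120)
        model = EnsembleHabitatClassifier(
            n_estimators=100, max_features=2, n_repeats=10, random_state=1
        )
        model.fit(X, y)
        assert abs(model.performance_["tss"].mean()) < 0.2

    def test_max_features_clamped_with_warning(self):
        X, y = self._separable()
        model = EnsembleHabitatClassifier(
            n_estimators=20, max_features=8, n_repeats=1, random_state=0
        )
        with pytest.warns(UserWarning, match="clamp"):
            model.fit(X, y)
        assert len(model.members_) == 1

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError):
            EnsembleHabitatClassifier(n_estimators=10).fit(X, np.ones(30, dtype=int))

    def test_groups_yield_one_member_per_set_and_repeat(self):
        X, y = self._separable(n=120)
        groups = np.zeros_like(y)
        groups[y == 0] = np.tile([1, 2, 3], 20)
        model = EnsembleHabitatClassifier(
            n_estimators=20, max_features=2, n_repeats=4, random_state=0
        )
        model.fit(X, y, groups=groups)
        assert len(model.members_) == 3 * 4
        assert sorted(model.performance_["set_id"].unique()) == [1, 2, 3]

    def test_ensemble_probability_within_member_range(self):
        X, y = self._separable(n=160, seed=3)
        model = EnsembleHabitatClassifier(
            n_estimators=50, max_features=2, n_repeats=3, random_state=4
        )
        model.fit(X, y)
        probs = np.stack(
            [m.predict_proba(X)[:, list(m.classes_).index(1)] for m in model.members_]
        )
        ens = model.predict_proba(X)[:, 1]
        assert np.all(ens >= probs.min(axis=0) - 1e-12)
        assert np.all(ens <= probs.max(axis=0) + 1e-12)

    def test_identical_members_average_to_themselves(self):
        X, y = self._separable(n=100, seed=5)
        model = EnsembleHabitatClassifier(
            n_estimators=30, max_features=2, n_repeats=1, random_state=6
        )
        model.fit(X, y)
        single = model.members_[0].predict_proba(X)[:, 1]
        assert np.allclose(model.predict_proba(X)[:, 1], single)

    def test_importance_shares_sum_to_one(self):
        X, y = self._separable()
        model = EnsembleHabitatClassifier(
            n_estimators=50, max_features=2, n_repeats=2, random_state=0
        )
        model.fit(X, y)
        imp = variable_importance(model, ["a", "b", "c"])
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        assert imp.idxmax() == "a"  # the planted informative predictor

    def test_performance_summary_reports_two_sd(self):
        X, y = self._separable()
        model = EnsembleHabitatClassifier(
            n_estimators=30, max_features=2, n_repeats=5, random_state=0
        )
        model.fit(X, y)
        summary = model.performance_summary()
        assert set(summary.index) >= {"tss", "kappa", "accuracy"}
        assert (summary["two_sd"] >= 0).all()


class TestBinarize:
    def _map(self, small_grid, values):
        return xr.DataArray(
            values,
            dims=("lon", "lat"),
            coords={"lon": small_grid.lons, "lat": small_grid.lats},
        )

    def test_boundary_value_is_presence(self, small_grid):
        vals = np.full((small_grid.n_lon, small_grid.n_lat), 0.5)
        vals[0, 0] = 0.75
        out = binarize(self._map(small_grid, vals), 0.75)
        assert out.values[0, 0] == 1.0
        assert out.values[1, 1] == 0.0

    def test_all_below_threshold_gives_empty_map(self, small_grid):
        vals = np.full((small_grid.n_lon, small_grid.n_lat), 0.4)
        out = binarize(self._map(small_grid, vals), 0.75)
        assert (out.values == 0).all()

    def test_idempotent(self, small_grid):
        rng = np.random.default_rng(0)
        vals = rng.random((small_grid.n_lon, small_grid.n_lat))
        once = binarize(self._map(small_grid, vals), 0.75)
        twice = binarize(once, 0.75)
        assert np.array_equal(once.values, twice.values, equal_nan=True)

    def test_missing_propagates(self, small_grid):
        vals = np.full((small_grid.n_lon, small_grid.n_lat), 0.9)
        vals[2, 3] = np.nan
        out = binarize(self._map(small_grid, vals), 0.75)
        assert np.isnan(out.values[2, 3])

    def test_threshold_out_of_range_raises(self, small_grid):
        vals = np.zeros((small_grid.n_lon, small_grid.n_lat))
        with pytest.raises(ValueError):
            binarize(self._map(small_grid, vals), 1.5)


def test_features_at_points_nearest_cell(small_grid, bathy):
    stack = xr.Dataset({"BAT": bathy})
    lon = bathy["lon"].values[[2, 5]]
    lat = bathy["lat"].values[[3, 7]]
    X = features_at_points(stack, lon, lat)
    assert X[0, 0] == bathy.values[2, 3]
    assert X[1, 0] == bathy.values[5, 7]
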