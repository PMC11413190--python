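"""Pseudoabsence ensemble species distribution modeling.

True absences are unobserved, so the classifier is trained against
background "pseudoabsence" points: three sets, each matching the presence
count, drawn uniformly from ocean cells not holding a presence, with depths
filled from the bathymetry layer. Each (pseudoabsence set x repeat) pair
contributes one random-forest member trained on a stratified 75/25 split of
its presences + absences and evaluated on the held-out 25% with sensitivity,
specificity, TSS, Cohen's kappa and accuracy. The default 10 repeats x 3
sets = 30 members; the cell-wise mean of member probabilities is the
ensemble's continuous probability of occurrence CP(o) in [0, 1], thresholded
at 0.75 into the binary map BP(o).

Training uses the annual-mean predictor stack; prediction runs per month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data

from .grids import DomainGrid
from .synth import TrueHabitatModel


def generate_pseudoabsences(
    presences: pd.DataFrame,
    grid: DomainGrid,
    bathymetry: xr.DataArray,
    n_sets: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Append ``n_sets`` pseudoabsence sets to a presence table.

    Each set holds exactly as many points as there are presences, sampled
    uniformly (without replacement within a set) from ocean cells that do not
    contain a presence; depths come from the bathymetry raster. Presences
    keep ``set_id`` 0, pseudoabsence sets are numbered 1..n_sets.
    """
    if len(presences) < 1:
        raise ValueError("need at least one presence")
    rng = np.random.default_rng(seed)
    bat = bathymetry.values
    lons, lats = bathymetry["lon"].values, bathymetry["lat"].values
    res_lon = lons[1] - lons[0] if len(lons) > 1 else grid.resolution
    res_lat = lats[1] - lats[0] if len(lats) > 1 else grid.resolution
    pi = np.clip(np.round((presences["lon"].values - lons[0]) / res_lon).astype(int), 0, len(lons) - 1)
    pj = np.clip(np.round((presences["lat"].values - lats[0]) / res_lat).astype(int), 0, len(lats) - 1)
    occupied = np.zeros_like(bat, dtype=bool)
    occupied[pi, pj] = True
    eligible = np.isfinite(bat) & ~occupied
    flat = np.flatnonzero(eligible.ravel())
    n = len(presences)
    if flat.size < n:
        raise ValueError(f"only {flat.size} eligible ocean cells for {n} pseudoabsences per set")
    frames = [presences.assign(label=1, set_id=0)]
    species = presences["species"].iloc[0] if "species" in presences else "unknown"
    for s in range(1, n_sets + 1):
        pick = rng.choice(flat, size=n, replace=False)
        ii, jj = np.unravel_index(pick, bat.shape)
        frames.append(
            pd.DataFrame(
                {
                    "lon": lons[ii],
                    "lat": lats[jj],
                    "depth": bat[ii, jj],
                    "species": species,
                    "label": 0,
                    "set_id": s,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class PerformanceReport:
    """Confusion counts and the derived skill scores for one model run."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    accuracy: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "PerformanceReport":
        total = tp + fp + tn + fn
        if total == 0:
            raise ValueError("empty confusion matrix")
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        acc = (tp + tn) / total
        p_yes = ((tp + fn) / total) * ((tp + fp) / total)
        p_no = ((tn + fp) / total) * ((tn + fn) / total)
        pe = p_yes + p_no
        kappa = (acc - pe) / (1 - pe) if pe != 1 else np.nan
        return cls(tp, fp, tn, fn, sens, spec, sens + spec - 1, kappa, acc)


def evaluate_predictions(
    y_true: np.ndarray, y_prob: np.ndarray, prob_threshold: float = 0.5
) -> PerformanceReport:
    """Score probabilistic predictions against 0/1 labels at a probability
    cut (default 0.5; distinct from the 0.75 mapping threshold)."""
    y_true = np.asarray(y_true).astype(int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    y_pred = (np.asarray(y_prob, dtype=float) >= prob_threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return PerformanceReport.from_counts(tp, fp, tn, fn)


class EnsembleHabitatClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest pseudoabsence ensemble with per-member evaluation.

    ``fit(X, y, groups=...)`` expects presence/pseudoabsence labels in
    ``y`` (1/0) and, in ``groups``, the pseudoabsence set id per row (0 for
    presences, 1..k for the k sets). Every (set, repeat) pair trains one
    random forest on presences + that set's absences, split 75/25 stratified
    by label; the held-out 25% yields one PerformanceReport. Without
    ``groups`` the whole table forms a single set.

    Parameters follow the reference configuration: 1000 trees, 8 candidate
    predictors per split (clamped, with a warning, when fewer predictors
    exist), minimum node size 5, 10 repeats.

    Attributes
    ----------
    members_ : list of fitted RandomForestClassifier (n_sets * n_repeats)
    performance_ : DataFrame, one row per member (set_id, repeat, tp..kappa)
    feature_importances_ : impurity importances, mean over members, sum 1
    """

    def __init__(
        self,
        n_estimators: int = 1000,
        max_features: int = 8,
        min_samples_leaf: int = 5,
        n_repeats: int = 10,
        test_size: float = 0.25,
        eval_threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_repeats = n_repeats
        self.test_size = test_size
        self.eval_threshold = eval_threshold
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if groups is None:
            groups = np.where(y == 1, 0, 1)
        groups = np.asarray(groups)
        set_ids = sorted(int(g) for g in np.unique(groups[y == 0]))
        if not set_ids:
            raise ValueError("no pseudoabsence rows (label 0) found")
        mtry = self.max_features
        if mtry > X.shape[1]:
            warnings.warn(
                f"max_features={mtry} exceeds the {X.shape[1]} available predictors; clamping",
                stacklevel=2,
            )
            mtry = X.shape[1]
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(len(set_ids) * self.n_repeats * 2)
        self.members_ = []
        rows = []
        importances = []
        k = 0
        pres_mask = y == 1
        for set_id in set_ids:
            mask = pres_mask | (groups == set_id)
            Xs, ys = X[mask], y[mask]
            for rep in range(self.n_repeats):
                split_seed = int(seeds[k] % (2**31 - 1))
                rf_seed = int(seeds[k + 1] % (2**31 - 1))
                k += 2
                X_tr, X_te, y_tr, y_te = train_test_split(
                    Xs,
                    ys,
                    test_size=self.test_size,
                    stratify=ys,
                    random_state=split_seed,
                )
                if len(np.unique(y_tr)) < 2:
                    raise ValueError("single-class training partition")
                rf = RandomForestClassifier(
                    n_estimators=self.n_estimators,
                    max_features=mtry,
                    min_samples_leaf=self.min_samples_leaf,
                    random_state=rf_seed,
                    n_jobs=1,
                )
                rf.fit(X_tr, y_tr)
                prob = rf.predict_proba(X_te)[:, list(rf.classes_).index(1)]
                rep_report = evaluate_predictions(y_te, prob, self.eval_threshold)
                rows.append({"set_id": set_id, "repeat": rep, **rep_report.__dict__})
                self.members_.append(rf)
                importances.append(rf.feature_importances_)
        self.performance_ = pd.DataFrame(rows)
        imp = np.mean(importances, axis=0)
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def predict_proba(self, X):
        """Cell-wise ensemble mean of member presence probabilities."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        p1 = np.zeros(X.shape[0])
        for rf in self.members_:
            p1 += rf.predict_proba(X)[:, list(rf.classes_).index(1)]
        p1 /= len(self.members_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.eval_threshold).astype(int)

    def performance_summary(self) -> pd.DataFrame:
        """Mean and 2-standard-deviation spread of each skill score over the
        ensemble's member runs."""
        check_is_fitted(self)
        cols = ["sensitivity", "specificity", "tss", "kappa", "accuracy"]
        stats = self.performance_[cols].agg(["mean", "std"]).T
        stats["two_sd"] = 2 * stats["std"]
        return stats[["mean", "two_sd"]]


def stack_feature_names(stack: xr.Dataset) -> list[str]:
    """Predictor order used for design matrices (dataset variable order)."""
    return list(stack.data_vars)


def features_at_points(stack: xr.Dataset, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Sample the annual-mean stack at the nearest grid cell of each point."""
    annual = stack.mean("month", skipna=True) if "month" in stack.dims else stack
    cols = []
    for name in stack.data_vars:
        da = annual[name]
        vals = da.sel(lon=xr.DataArray(lon, dims="pt"), lat=xr.DataArray(lat, dims="pt"), method="nearest")
        cols.append(vals.values)
    return np.column_stack(cols)


def fit_sdm(
    occurrences: pd.DataFrame,
    stack: xr.Dataset,
    **params,
) -> EnsembleHabitatClassifier:
    """Train the ensemble on occurrence/pseudoabsence points against the
    annual-mean predictor stack."""
    X = features_at_points(stack, occurrences["lon"].values, occurrences["lat"].values)
    y = occurrences["label"].values.astype(int)
    groups = occurrences["set_id"].values.astype(int)
    ok = np.isfinite(X).all(axis=1)
    model = EnsembleHabitatClassifier(**params)
    model.fit(X[ok], y[ok], groups=groups[ok])
    return model


def predict_suitability(
    model: EnsembleHabitatClassifier, stack: xr.Dataset, month: int | None = None
) -> xr.DataArray:
    """Ensemble CP(o) map on the stack's grid for one month (or the
    annual-mean stack when ``month`` is None); missing on land."""
    if month is not None:
        layers = {
            name: (stack[name].sel(month=month) if "month" in stack[name].dims else stack[name])
            for name in stack.data_vars
        }
        ds = xr.Dataset(layers)
    else:
        ds = stack.mean("month", skipna=True) if "month" in stack.dims else stack
    shape = (ds.sizes["lon"], ds.sizes["lat"])
    cols = [np.asarray(ds[name].transpose("lon", "lat").values, dtype=float).ravel() for name in stack.data_vars]
    X = np.column_stack(cols)
    valid = np.isfinite(X).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = model.predict_proba(X[valid])[:, 1]
    da = xr.DataArray(
        out.reshape(shape),
        dims=("lon", "lat"),
        coords={"lon": ds["lon"], "lat": ds["lat"]},
        name="suitability",
    )
    da.attrs["long_name"] = "ensemble continuous probability of occurrence CP(o)"
    return da


def binarize(suitability: xr.DataArray, threshold: float = 0.75) -> xr.DataArray:
    """BP(o): presence where CP(o) >= threshold, absence below, missing
    propagated. A map can come out empty when CP(o) sits below the threshold
    everywhere — that is a legitimate result, not an error."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = suitability.values
    out = np.where(np.isnan(vals), np.nan, (vals >= threshold).astype(float))
    da = suitability.copy(data=out)
    da.name = "presence"
    da.attrs = {"threshold": threshold, "long_name": "binary probability of occurrence BP(o)"}
    return da


def variable_importance(model: EnsembleHabitatClassifier, names: list[str]) -> pd.Series:
    """Per-predictor importance shares (nonnegative, summing to 1),
    averaged over ensemble members."""
    check_is_fitted(model)
    return pd.Series(model.feature_importances_, index=names, name="importance")


def range_jaccard(binary: xr.DataArray, truth: TrueHabitatModel, stack: xr.Dataset) -> float:
    """Jaccard overlap between the ensemble's binary range and the true
    range of the generating habitat model."""
    annual = stack.mean("month", skipna=True) if "month" in stack.dims else stack
    features = {n: annual[n].transpose("lon", "lat").values for n in truth.coefficients}
    true_mask = truth.true_range(features)
    pred = binary.transpose("lon", "lat").values == 1.0
    both = np.isfinite(binary.transpose("lon", "lat").values)
    inter = np.sum(pred & true_mask & both)
    union = np.sum((pred | true_mask) & both)
    return float(inter / union) if union else np.nan
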