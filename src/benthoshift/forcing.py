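"""Delta-method bias correction, GCM ensemble averaging, and statistical /
ML downscaling with RMSE-based method selection.

The delta method anchors a model's future field to observed climatology:
with observed climatology O, historical-model climatology H and future-model
field F (all on the coarse model grid), the corrected field is

    F' = F + (O - H)

which satisfies the anchoring identity (a perfect model, F = H, returns the
observation exactly) and preserves the climate signal cell-wise
(F' - O = F - H). A literal "subtract the bias from the future projection"
convention (F - (O - H)) is available behind ``convention="literal"`` for
comparison; it breaks the anchoring identity.

Downscaling regresses fine-grid values on (bilinearly interpolated coarse
value, lon, lat, bathymetry). Candidate regressors: robust linear regression
(rr), a piecewise-linear spline regressor with MARS-like inductive shape
(mars), random forest (rf), a smooth additive spline regressor with GAM-like
shape (gam), and a multilayer perceptron (ann). The method with minimal
held-out RMSE wins; ties fall to configuration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import HuberRegressor, LinearRegression, Ridge
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

from .grids import DomainGrid
from .preprocess import resample_bilinear

DOWNSCALER_METHODS = ("rr", "mars", "rf", "gam", "ann")


def delta_bias_correct(
    obs_clim: xr.DataArray,
    hist_model: xr.DataArray,
    future_model: xr.DataArray,
    convention: str = "anchored",
) -> xr.DataArray:
    """Delta-method correction of a coarse future field.

    All three fields must share the coarse grid. ``convention="anchored"``
    (default) computes F + (O - H); ``"literal"`` computes F - (O - H).
    """
    for other, label in ((hist_model, "hist_model"), (future_model, "future_model")):
        if obs_clim.sizes != other.sizes or not all(
            np.array_equal(obs_clim[d].values, other[d].values) for d in ("lon", "lat")
        ):
            raise ValueError(f"{label} is not on the same grid as obs_clim")
    bias = obs_clim - hist_model
    if convention == "anchored":
        out = future_model + bias
    elif convention == "literal":
        out = future_model - bias
    else:
        raise ValueError("convention must be 'anchored' or 'literal'")
    out.attrs = dict(future_model.attrs)
    return out


def ensemble_mean(fields: list[xr.DataArray]) -> xr.DataArray:
    """Cell-wise missing-aware mean across bias-corrected GCM fields."""
    if not fields:
        raise ValueError("need at least one field")
    first = fields[0]
    for f in fields[1:]:
        if f.sizes != first.sizes:
            raise ValueError("fields are not co-registered")
    stacked = xr.concat(fields, dim="member")
    out = stacked.mean("member", skipna=True)
    out.attrs = dict(first.attrs)
    return out


def make_downscaler(method: str, random_state: int | None = None):
    """A fresh regressor for one downscaling method name."""
    if method == "rr":
        return make_pipeline(StandardScaler(), HuberRegressor(max_iter=500))
    # future inputs can sit outside the training range (a shifted climate),
    # so spline bases must extrapolate linearly, not clamp
    if method == "mars":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=1, n_knots=6, extrapolation="linear"),
            LinearRegression(),
        )
    if method == "gam":
        return make_pipeline(
            StandardScaler(),
            SplineTransformer(degree=3, n_knots=8, extrapolation="linear"),
            Ridge(alpha=1e-3),
        )
    if method == "rf":
        return RandomForestRegressor(n_estimators=200, random_state=random_state, n_jobs=1)
    if method == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(32, 32),
                max_iter=3000,
                random_state=random_state,
                early_stopping=False,
            ),
        )
    raise ValueError(f"unknown downscaling method {method!r}; choose from {DOWNSCALER_METHODS}")


@dataclass
class DownscalerReport:
    """Held-out performance of one candidate downscaling method."""

    method: str
    rmse: float
    selected: bool


class RmseDownscalerSelector(RegressorMixin, BaseEstimator):
    """Fit several downscaling regressors and keep the one with minimal
    held-out RMSE.

    The first column of ``X`` is the bilinearly interpolated coarse value;
    the remaining columns are the local covariates (lon, lat, bathymetry).
    With ``anchor=True`` (default) the prediction is anchored to the
    interpolated coarse field and the regressor learns only the fine-scale
    residual from the covariates — so an additive signal imposed on the
    coarse field passes through the downscaling step exactly. With
    ``anchor=False`` the regressor predicts the fine value freely from all
    columns (a free fit can damp imposed climate shifts).

    Parameters
    ----------
    methods : sequence of str
        Candidate methods among ``("rr", "mars", "rf", "gam", "ann")``; at
        least two. Ties in RMSE fall to the first method in this order.
    test_size : float
        Fraction of samples held out for the RMSE comparison.
    anchor : bool
        Anchored-residual (True) versus free regression (False).
    random_state : int or None
        Seeds both the held-out split and any stochastic regressor.

    Attributes
    ----------
    reports_ : list of DownscalerReport
    best_method_ : str
    best_estimator_ : fitted regressor (refit on all samples)
    """

    def __init__(
        self, methods=("rr", "mars", "rf"), test_size=0.25, anchor=True, random_state=None
    ):
        self.methods = methods
        self.test_size = test_size
        self.anchor = anchor
        self.random_state = random_state

    def _split(self, X, y):
        if self.anchor:
            return X[:, 1:], y - X[:, 0]
        return X, y

    def _raw_predict(self, est, X):
        if self.anchor:
            return X[:, 0] + est.predict(X[:, 1:])
        return est.predict(X)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if X.shape[1] < 2:
            raise ValueError("X needs the interpolated coarse column plus covariates")
        if len(self.methods) < 2:
            raise ValueError("need at least two candidate methods")
        if X.shape[0] < 10:
            raise ValueError("fewer than 10 jointly valid samples")
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_size, random_state=self.random_state
        )
        self.reports_ = []
        for method in self.methods:
            est = make_downscaler(method, random_state=self.random_state)
            est.fit(*self._split(X_tr, y_tr))
            pred = self._raw_predict(est, X_te)
            rmse = float(np.sqrt(mean_squared_error(y_te, pred)))
            self.reports_.append(DownscalerReport(method=method, rmse=rmse, selected=False))
        best = min(self.reports_, key=lambda r: r.rmse)  # stable min: config order wins ties
        best.selected = True
        self.best_method_ = best.method
        # refit the winner on everything it can see
        self.best_estimator_ = clone(make_downscaler(best.method, random_state=self.random_state))
        self.best_estimator_.fit(*self._split(X, y))
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self._raw_predict(self.best_estimator_, X)


def _feature_matrix(
    coarse: xr.DataArray, covariates: dict[str, xr.DataArray], grid: DomainGrid
) -> tuple[np.ndarray, np.ndarray]:
    """(n_cells, n_features) design matrix on the fine grid: interpolated
    coarse value, lon, lat, then covariates in name order; plus validity mask."""
    interp = resample_bilinear(coarse, grid)
    lon2d, lat2d = np.meshgrid(grid.lons, grid.lats, indexing="ij")
    cols = [interp.values.ravel(), lon2d.ravel(), lat2d.ravel()]
    for name in sorted(covariates):
        cols.append(np.asarray(covariates[name].values, dtype=float).ravel())
    X = np.column_stack(cols)
    valid = np.isfinite(X).all(axis=1)
    return X, valid


def fit_downscalers(
    coarse: xr.DataArray,
    fine_truth: xr.DataArray,
    covariates: dict[str, xr.DataArray],
    grid: DomainGrid,
    methods=("rr", "mars", "rf"),
    split_seed: int | None = 0,
) -> RmseDownscalerSelector:
    """Train candidate downscalers to predict fine-grid truth from the
    interpolated coarse field plus (lon, lat, covariate) features, and select
    by held-out RMSE. Returns the fitted selector (see ``reports_``)."""
    X, valid = _feature_matrix(coarse, covariates, grid)
    y = np.asarray(fine_truth.values, dtype=float).ravel()
    valid &= np.isfinite(y)
    if valid.sum() < 10:
        raise ValueError("fewer than 10 jointly valid cells for downscaler training")
    sel = RmseDownscalerSelector(methods=methods, random_state=split_seed)
    sel.fit(X[valid], y[valid])
    return sel


def apply_downscaler(
    selector: RmseDownscalerSelector,
    future_coarse: xr.DataArray,
    covariates: dict[str, xr.DataArray],
    grid: DomainGrid,
) -> xr.DataArray:
    """Predict a fine-grid field from a coarse future field; missing where
    any covariate (or the interpolated coarse value) is missing."""
    check_is_fitted(selector)
    X, valid = _feature_matrix(future_coarse, covariates, grid)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = selector.predict(X[valid])
    da = xr.DataArray(
        out.reshape(grid.n_lon, grid.n_lat),
        dims=("lon", "lat"),
        coords={"lon": grid.lons, "lat": grid.lats},
        name=future_coarse.name,
    )
    da.attrs = dict(future_coarse.attrs)
    return da
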