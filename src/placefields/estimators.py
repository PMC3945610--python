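"""Scikit-learn style estimators for the regression-shaped fits.

:class:`WeberSizeRegressor` fits the single Weber factor gamma to observed
field sizes given an environment's geometry; :class:`ObjectSubsetRegressor`
selects, by exhaustive enumeration, the subset of track observations that
best explains a field-size profile.  Both follow the sklearn contract
(``fit``/``predict``/``get_params``/``set_params``, fitted attributes with a
trailing underscore) and compose with sklearn model selection; the
module-level functions in :mod:`placefields.fitting` are thin wrappers.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cue_model import SIGMA_FLOOR_CM, CueParams, SubsetMask
from .geometry import CircularTrack, RectEnvironment, track_distances

__all__ = ["WeberSizeRegressor", "ObjectSubsetRegressor", "golden_section_minimize"]


def golden_section_minimize(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Deterministic golden-section search for the minimum of a unimodal f on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


class WeberSizeRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of the Weber factor gamma to place-field sizes.

    Given an environment, each field's predicted size follows from the
    distances of its centroid to the boundaries/objects:

    * rectangular environment, ``size_dialect="area"``: the product of the
      per-axis uncertainties, each fused from the two opposing walls
      (area-like, matches field area measured in bins);
    * circular track, ``size_dialect="std"``: the 1D posterior std from the
      object and barrier distances along the track.

    The single parameter gamma is adjusted by a golden-section line search
    (the scalar degenerate case of coordinate descent) minimizing the sum of
    squared size errors over ``bounds``.

    Parameters
    ----------
    env : RectEnvironment or CircularTrack
    size_dialect : {"area", "std"}
    alpha : float, prior precision (cm^-2), default 0 (sensory-driven cells)
    bounds : (float, float), search bracket for gamma
    tol : float, bracket width at which the search stops
    trajectory_offset_cm : float
        For rectangular environments, the wall offset of the near-wall
        trajectory used for the bound-curve coverage statistic.

    Attributes
    ----------
    gamma_ : fitted Weber factor
    result_ : :class:`placefields.fitting.FitResult` with the fit statistics
    """

    def __init__(self, env=None, size_dialect: str = "std", alpha: float = 0.0,
                 bounds: tuple[float, float] = (1e-4, 10.0), tol: float = 1e-8,
                 trajectory_offset_cm: float = 1.0):
        self.env = env
        self.size_dialect = size_dialect
        self.alpha = alpha
        self.bounds = bounds
        self.tol = tol
        self.trajectory_offset_cm = trajectory_offset_cm

    # -- geometry precomputation ------------------------------------------

    def _inverse_square_sums(self, X: np.ndarray):
        """Per-point sums of 1/d^2 over the relevant observations."""
        env = self.env
        if isinstance(env, RectEnvironment):
            if X.shape[1] != 2:
                raise ValueError("rect environment expects X of shape (n, 2)")
            x, y = X[:, 0], X[:, 1]
            if np.any((x < 0) | (x > env.length_cm) | (y < 0) | (y > env.width_cm)):
                raise ValueError("some centroids fall outside the environment")
            with np.errstate(divide="ignore"):
                ix = x**-2 + (env.length_cm - x) ** -2
                iy = y**-2 + (env.width_cm - y) ** -2
            return ix, iy
        if isinstance(env, CircularTrack):
            if X.shape[1] != 1:
                raise ValueError("circular track expects X of shape (n, 1)")
            inv = np.empty(X.shape[0])
            for i, s in enumerate(X[:, 0]):
                d = np.array([o.distance_cm for o in track_distances(float(s), env)])
                with np.errstate(divide="ignore"):
                    inv[i] = np.sum(d**-2.0)
            return (inv,)
        raise TypeError(f"unsupported environment type {type(env).__name__}")

    def _predict_from_inv(self, inv_sums, gamma: float) -> np.ndarray:
        beta = 1.0 / gamma**2
        sigmas = []
        with np.errstate(divide="ignore"):
            for inv in inv_sums:
                precision = self.alpha + beta * inv
                sigmas.append(np.where(np.isinf(precision), 0.0, precision**-0.5))
        if self.size_dialect == "area":
            if len(sigmas) != 2:
                raise ValueError('size_dialect "area" requires a rectangular environment')
            return sigmas[0] * sigmas[1]
        if len(sigmas) == 2:
            raise ValueError('size_dialect "std" on a rect environment is ambiguous; '
                             'use "area" or fit each axis separately')
        return sigmas[0]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if self.env is None:
            raise ValueError("env must be set before fitting")
        if self.size_dialect not in ("area", "std"):
            raise ValueError(f"unknown size dialect {self.size_dialect!r}")
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if np.any(y < 0) or not np.any(y > 0):
            raise ValueError("sizes must be >= 0 with at least one positive")
        inv_sums = self._inverse_square_sums(X)

        def sse(gamma):
            resid = self._predict_from_inv(inv_sums, gamma) - y
            return float(resid @ resid)

        lo, hi = self.bounds
        gamma = golden_section_minimize(sse, lo, hi, self.tol)
        if not np.isfinite(sse(gamma)):
            raise ValueError("non-finite objective at fitted gamma")
        self.gamma_ = float(gamma)
        self.n_features_in_ = X.shape[1]
        self._fit_result(X, y, inv_sums)
        return self

    def _fit_result(self, X, y, inv_sums):
        from . import fitting

        pred = self._predict_from_inv(inv_sums, self.gamma_)
        r2 = fitting.r_squared(pred, y) if np.std(y) > 0 else float("nan")
        n = y.size
        r2_adj = (fitting.adjusted_r_squared(r2, n, 1)
                  if n > 2 and np.isfinite(r2) else float("nan"))
        if np.std(pred) > 0 and np.std(y) > 0:
            pearson = float(np.corrcoef(pred, y)[0, 1])
        else:
            pearson = float("nan")
        n_obs = 4 if isinstance(self.env, RectEnvironment) else len(self.env.object_arcs_cm) + 1
        extras = {"data_series": y.copy()}
        if isinstance(self.env, RectEnvironment) and self.size_dialect == "area":
            extras.update(self._bound_curves(X, y))
        self.result_ = fitting.FitResult(
            params=CueParams(gamma=self.gamma_, alpha=self.alpha),
            mask=SubsetMask.ones(n_obs),
            r2=float(r2), r2_adj=float(r2_adj), pearson_r=pearson,
            residuals=y - pred, n_params_used=1, extras=extras,
        )

    def _bound_curves(self, X, y, n_grid: int = 200):
        """Bound curves: predicted size along a near-wall and a
        midline trajectory, plus the fraction of fields between them."""
        env = self.env
        off = min(self.trajectory_offset_cm, env.width_cm / 2)
        xs = np.linspace(0.0, env.length_cm, n_grid + 2)[1:-1]
        lower = self._predict_from_inv(
            self._inverse_square_sums(np.column_stack([xs, np.full_like(xs, off)])),
            self.gamma_)
        upper = self._predict_from_inv(
            self._inverse_square_sums(np.column_stack([xs, np.full_like(xs, env.width_cm / 2)])),
            self.gamma_)
        lo_at = np.interp(X[:, 0], xs, lower)
        hi_at = np.interp(X[:, 0], xs, upper)
        frac = float(np.mean((y >= lo_at) & (y <= hi_at)))
        return {"bound_x_cm": xs, "bound_lower": lower, "bound_upper": upper,
                "coverage_fraction": frac}

    def predict(self, X):
        check_is_fitted(self, "gamma_")
        X = check_array(X)
        return self._predict_from_inv(self._inverse_square_sums(X), self.gamma_)


class ObjectSubsetRegressor(RegressorMixin, BaseEstimator):
    """Exhaustive subset selection over track observations.

    Scores every non-empty binary mask over the N = objects + barrier
    observations of a circular track: the z-scored predicted uncertainty
    profile under that mask is compared (R-squared) to the z-scored observed
    size series.  With alpha = 0 the Weber factor only scales the profile's
    amplitude, so it drops out after z-scoring and the enumeration is exact
    in the mask.

    Attributes
    ----------
    mask_ : :class:`placefields.cue_model.SubsetMask`, the winning subset
    r2_, r2_adj_ : scores of the winning subset (adjusted with p = N + 1)
    scores_ : R-squared of every mask, indexed by the mask's bit pattern - 1
    result_ : :class:`placefields.fitting.FitResult`
    """

    def __init__(self, track=None, gamma: float = 1.0, max_observations: int = 20,
                 sigma_floor_cm: float = SIGMA_FLOOR_CM):
        self.track = track
        self.gamma = gamma
        self.max_observations = max_observations
        self.sigma_floor_cm = sigma_floor_cm

    def _distance_matrix(self, arcs: np.ndarray) -> np.ndarray:
        return np.array(
            [[o.distance_cm for o in track_distances(float(s), self.track)] for s in arcs]
        )

    def fit(self, X, y):
        if self.track is None:
            raise ValueError("track must be set before fitting")
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("X must be arc positions of shape (n, 1)")
        from . import fitting

        n_obs = len(self.track.object_arcs_cm) + 1
        if n_obs > self.max_observations:
            raise ValueError(
                f"{n_obs} observations exceed the enumeration guard "
                f"({self.max_observations}); use the base single-parameter model"
            )
        arcs = X[:, 0]
        D = self._distance_matrix(arcs)
        with np.errstate(divide="ignore"):
            inv_sq = D**-2.0  # (n_points, n_obs)
        # a point exactly on an object has infinite precision; cap it so the
        # masked matmul stays finite and the sigma lands on the floor
        inv_sq = np.minimum(inv_sq, self.sigma_floor_cm**-2.0)
        n_masks = 2**n_obs - 1
        bits = np.arange(1, n_masks + 1)
        masks = ((bits[:, None] >> np.arange(n_obs)) & 1).astype(float)  # (M, N)
        precision = inv_sq @ masks.T  # (n_points, M)
        sigma = np.maximum(precision**-0.5, self.sigma_floor_cm)
        z_obs = fitting.zscore(y)
        mu = sigma.mean(axis=0)
        sd = sigma.std(axis=0, ddof=0)
        valid = sd > 0
        z_pred = np.full_like(sigma, np.nan)
        z_pred[:, valid] = (sigma[:, valid] - mu[valid]) / sd[valid]
        ss_err = np.nansum((z_pred - z_obs[:, None]) ** 2, axis=0)
        scores = np.where(valid, 1.0 - ss_err / y.size, -np.inf)
        best = int(np.argmax(scores))
        self.scores_ = scores
        self.mask_ = SubsetMask.from_index(int(bits[best]), n_obs)
        self.r2_ = float(scores[best])
        p = n_obs + 1
        self.r2_adj_ = (fitting.adjusted_r_squared(self.r2_, y.size, p)
                        if y.size > p + 1 else float("nan"))
        self.n_features_in_ = 1
        z_best = z_pred[:, best]
        self.result_ = fitting.FitResult(
            params=CueParams(gamma=self.gamma),
            mask=self.mask_,
            r2=self.r2_, r2_adj=self.r2_adj_,
            pearson_r=float(np.corrcoef(z_best, z_obs)[0, 1]),
            residuals=z_obs - z_best,
            n_params_used=p,
            extras={"data_series": z_obs},
        )
        return self

    def predict(self, X):
        """Z-scored predicted profile at the given arc positions under the
        fitted mask (z-scoring constants from these positions)."""
        check_is_fitted(self, "mask_")
        X = check_array(X)
        from . import fitting

        D = self._distance_matrix(X[:, 0])
        delta = np.asarray(self.mask_.delta, dtype=bool)
        with np.errstate(divide="ignore"):
            precision = (D[:, delta] ** -2.0).sum(axis=1)
            sigma = np.where(np.isinf(precision), self.sigma_floor_cm,
                             np.maximum(precision**-0.5, self.sigma_floor_cm))
        return fitting.zscore(sigma)
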