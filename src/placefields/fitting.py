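"""Fitting the cue-integration model to place-field data, plus the statistics
reported alongside (R-squared, adjusted R-squared, Pearson r, chi-square
goodness of fit, paired t-tests).

Field "size" comes in two dialects that are never mixed:

``"std"``
    standard deviation of the spike positions of a field (cm); used on the
    circular track where uncertainty is one-dimensional (arc coordinate).
``"area"``
    field area in bins; used on rectangular tracks, where the model's
    area-like prediction is the product of the per-axis uncertainties.

The single free parameter gamma (Weber factor) is fitted by least squares on
the sizes via a deterministic golden-section line search (the 1-parameter
degenerate case of coordinate descent).  The subset extension scores all
2**N - 1 non-empty observation masks by exhaustive enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .cue_model import CueParams, SubsetMask
from .geometry import CircularTrack, Point2D, RectEnvironment

__all__ = [
    "PlaceField",
    "RateMap",
    "FitResult",
    "GaussianFit",
    "CrossEnvResult",
    "field_from_spikes",
    "moving_average",
    "zscore",
    "r_squared",
    "adjusted_r_squared",
    "residual_tests",
    "chi2_gof_normal",
    "fit_gamma",
    "fit_subset",
    "fit_gaussian_ratemap",
    "cross_env_predict",
    "flag_asymmetric",
]


# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class PlaceField:
    """One firing field of a place cell (a cell may own several)."""

    cell_id: str
    field_id: int
    centroid: object  # Point2D (2D) or float arc coordinate (1D), cm
    size: object  # float, or per-axis tuple for 2D std dialect
    size_dialect: str = "std"  # "std" (cm) or "area" (bins)
    spike_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.size_dialect not in ("std", "area"):
            raise ValueError(f"unknown size dialect {self.size_dialect!r}")
        sizes = np.atleast_1d(np.asarray(self.size, dtype=float))
        if np.any(sizes < 0):
            raise ValueError("field size must be >= 0")


@dataclass(frozen=True)
class RateMap:
    """Binned firing-rate grid.  ``rates[iy, ix]`` is the mean rate (Hz) in the
    bin whose centre is ``origin + ((ix + 0.5) * bin, (iy + 0.5) * bin)``."""

    bin_size_cm: float
    origin: Point2D
    rates: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.ndim != 2:
            raise ValueError("rates must be a 2D grid")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "rates", r)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.rates.shape
        xs = self.origin.x_cm + (np.arange(nx) + 0.5) * self.bin_size_cm
        ys = self.origin.y_cm + (np.arange(ny) + 0.5) * self.bin_size_cm
        return xs, ys


@dataclass
class FitResult:
    """Outcome of a model fit and the statistics the analyses report."""

    params: CueParams
    mask: SubsetMask
    r2: float
    r2_adj: float
    pearson_r: float
    residuals: np.ndarray
    n_params_used: int
    extras: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gamma": self.params.gamma,
            "beta": self.params.beta,
            "alpha": self.params.alpha,
            "mask": list(self.mask.delta),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "pearson_r": self.pearson_r,
            "n_params_used": self.n_params_used,
            "residuals": np.asarray(self.residuals).tolist(),
            **{k: v for k, v in self.extras.items() if np.isscalar(v)},
        }


# ---------------------------------------------------------------------------
# Elementary statistics


def field_from_spikes(spike_positions, cell_id: str = "", field_id: int = 0,
                      size_dialect: str = "std") -> PlaceField:
    """Summarize a spike cloud into a field: centroid = mean, size = std.

    Accepts a 1D array of arc coordinates or an (n, 2) array of x/y
    positions.  The std is the population (divide-by-n) estimator, applied
    per axis in 2D.
    """
    pos = np.asarray(spike_positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 spikes to define a field")
    centroid = pos.mean(axis=0)
    size = pos.std(axis=0, ddof=0)
    if pos.shape[1] == 1:
        return PlaceField(cell_id, field_id, float(centroid[0]), float(size[0]),
                          size_dialect, pos[:, 0].copy())
    return PlaceField(cell_id, field_id, Point2D(*centroid), tuple(size),
                      size_dialect, pos.copy())


def moving_average(series, window: int = 10, circular: bool = False) -> np.ndarray:
    """Moving average with windows centred at each index.

    The window spans offsets ``-floor((window-1)/2) .. +floor(window/2)``
    (for even windows the extra sample is taken forward).  Circular series
    wrap around; linear series truncate the window at the edges.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if not circular and window > x.size:
        raise ValueError(f"window {window} larger than series of length {x.size}")
    lo, hi = -((window - 1) // 2), window // 2
    n = x.size
    out = np.empty(n)
    for i in range(n):
        idx = np.arange(i + lo, i + hi + 1)
        if circular:
            out[i] = x[idx % n].mean()
        else:
            out[i] = x[idx[(idx >= 0) & (idx < n)]].mean()
    return out


def zscore(series) -> np.ndarray:
    """Normalize to mean 0 and variance 1 (population variance)."""
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance series")
    return (x - x.mean()) / sd


def r_squared(pred, obs) -> float:
    """Proportion of variance explained: 1 - SS_err / SS_tot (can be < 0)."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or o.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance: R^2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """R-squared penalized for the number of parameters p at sample size n."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def chi2_gof_normal(x) -> tuple[float, float]:
    """Chi-square goodness of fit of ``x`` against a normal distribution.

    The normal's parameters are estimated from the data (MLE), the support is
    split into k = max(8, n // 5) equal-probability bins, and the statistic is
    referred to a chi-square with k - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points for the binned chi-square test")
    mu, sd = x.mean(), x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance data: normal fit degenerate")
    k = max(8, n // 5)
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, k + 1), loc=mu, scale=sd)
    counts, _ = np.histogram(x, bins=edges)
    expected = n / k
    statistic = float(np.sum((counts - expected) ** 2) / expected)
    pvalue = float(stats.chi2.sf(statistic, df=k - 3))
    return statistic, pvalue


def residual_tests(data, model) -> dict:
    """The statistics reported for a model/data comparison.

    Returns Pearson's r (with p-value) between model and data, a chi-square
    normality test of the data itself (is there non-random structure?), and
    the same test on the residuals data - model (is what remains random?).
    """
    d = np.asarray(data, dtype=float)
    m = np.asarray(model, dtype=float)
    if d.shape != m.shape or d.size < 8:
        raise ValueError("data and model must have equal length >= 8")
    r, p = stats.pearsonr(m, d)
    chi2_data = chi2_gof_normal(d)
    chi2_resid = chi2_gof_normal(d - m)
    return {
        "pearson_r": float(r),
        "pearson_p": float(p),
        "chi2_data": chi2_data[0],
        "chi2_data_p": chi2_data[1],
        "chi2_resid": chi2_resid[0],
        "chi2_resid_p": chi2_resid[1],
    }


def flag_asymmetric(spike_positions, skew_threshold: float = 1.0) -> bool:
    """True if the spike cloud is too skewed on any axis for a Gaussian fit."""
    pos = np.asarray(spike_positions, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    skews = stats.skew(pos, axis=0, bias=True)
    return bool(np.any(np.abs(np.atleast_1d(skews)) > skew_threshold))


# ---------------------------------------------------------------------------
# Gamma and subset fits (thin wrappers over the estimator layer)


def fit_gamma(fields, env, mode: str | None = None, alpha: float = 0.0,
              bounds: tuple[float, float] = (1e-4, 10.0), tol: float = 1e-8,
              trajectory_offset_cm: float = 1.0) -> FitResult:
    """Least-squares fit of the Weber factor gamma to observed field sizes.

    ``mode`` is the size dialect ("std" or "area"); by default it is taken
    from the fields.  On a rectangular environment the result's ``extras``
    also carry the two bound curves (a near-wall and a midline
    trajectory) and the fraction of fields falling between them.
    """
    from .estimators import WeberSizeRegressor

    fields = list(fields)
    if mode is None:
        if not fields:
            raise ValueError("no fields supplied")
        mode = fields[0].size_dialect
    X, y = _fields_to_xy(fields, env, mode)
    est = WeberSizeRegressor(env=env, size_dialect=mode, alpha=alpha,
                             bounds=bounds, tol=tol,
                             trajectory_offset_cm=trajectory_offset_cm)
    est.fit(X, y)
    return est.result_


def _fields_to_xy(fields, env, mode):
    sizes = []
    coords = []
    for f in fields:
        if f.size_dialect != mode:
            raise ValueError(
                f"size dialect mismatch: field {f.cell_id}/{f.field_id} is "
                f"{f.size_dialect!r}, fit requested {mode!r}"
            )
        if isinstance(env, RectEnvironment):
            c = f.centroid
            coords.append([c.x_cm, c.y_cm])
        else:
            coords.append([float(f.centroid)])
        sizes.append(float(np.atleast_1d(np.asarray(f.size, dtype=float))[0])
                     if np.ndim(f.size) else float(f.size))
    return np.asarray(coords, dtype=float), np.asarray(sizes, dtype=float)


def fit_subset(sizes, track: CircularTrack, params: CueParams | None = None,
               arcs=None, max_observations: int = 20) -> FitResult:
    """Exhaustively score every non-empty observation subset against a size series.

    ``sizes`` is a series of (smoothed) field sizes sampled on a regular arc
    grid over the track (pass ``arcs`` to override the inferred grid).  For
    each of the 2**N - 1 non-empty masks over the N = objects + barrier
    observations, the z-scored predicted profile (alpha = 0, so gamma only
    scales amplitude and drops out) is compared to the z-scored sizes; the
    mask maximizing R-squared wins.  Adjusted R-squared uses p = N + 1
    parameters (N binary indicators plus gamma).
    """
    from .estimators import ObjectSubsetRegressor

    sizes = np.asarray(sizes, dtype=float)
    if arcs is None:
        arcs = np.linspace(0.0, track.circumference_cm, sizes.size, endpoint=False)
    est = ObjectSubsetRegressor(track=track, max_observations=max_observations,
                                gamma=(params.gamma if params is not None else 1.0))
    est.fit(np.asarray(arcs, dtype=float)[:, None], sizes)
    return est.result_


# ---------------------------------------------------------------------------
# Rate-map Gaussian fits and cross-environment prediction


@dataclass(frozen=True)
class GaussianFit:
    """Separable 2D Gaussian fitted to a rate map (least squares)."""

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    baseline: float
    r2: float

    def evaluate(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        gx = np.exp(-0.5 * ((xs - self.mu_x) / self.sigma_x) ** 2)
        gy = np.exp(-0.5 * ((ys - self.mu_y) / self.sigma_y) ** 2)
        return self.baseline + self.amplitude * np.outer(gy, gx)


def fit_gaussian_ratemap(rate_map: RateMap, with_baseline: bool = True) -> GaussianFit:
    """Least-squares fit of a separable 2D Gaussian (plus optional uniform
    baseline) to a rate map; returns per-axis means and stds in cm.

    The baseline convention: the fitted ``amplitude`` is the peak rate above
    the uniform ``baseline`` term, so adding a constant to the map moves the
    baseline and leaves the stds (and amplitude) unchanged.
    """
    r = rate_map.rates
    peak = r.max()
    if not peak > 0:
        raise ValueError("rate map has no positive peak")
    xs, ys = rate_map.bin_centers()
    X, Y = np.meshgrid(xs, ys)
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    # moment-based initialization around the peak
    w = np.clip(r - r.mean(), 0, None) + 1e-12
    mx0 = float((w * X).sum() / w.sum())
    my0 = float((w * Y).sum() / w.sum())
    sx0 = max(float(np.sqrt((w * (X - mx0) ** 2).sum() / w.sum())), rate_map.bin_size_cm / 2)
    sy0 = max(float(np.sqrt((w * (Y - my0) ** 2).sum() / w.sum())), rate_map.bin_size_cm / 2)

    def model(p):
        mx, my, lsx, lsy, amp, base = p
        sx, sy = math.exp(lsx), math.exp(lsy)
        return base + amp * np.exp(
            -0.5 * (((X - mx) / sx) ** 2 + ((Y - my) / sy) ** 2)
        )

    def resid(p):
        return (model(p) - r).ravel()

    p0 = [float(xs[ix]), float(ys[iy]), math.log(sx0), math.log(sy0), float(peak), 0.0]
    if not with_baseline:
        p0 = p0[:5]

        def model(p):  # noqa: F811 - narrowed parameter vector
            mx, my, lsx, lsy, amp = p
            return amp * np.exp(
                -0.5 * (((X - mx) / math.exp(lsx)) ** 2 + ((Y - my) / math.exp(lsy)) ** 2)
            )

        def resid(p):  # noqa: F811
            return (model(p) - r).ravel()

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"Gaussian rate-map fit did not converge: {sol.message}")
    p = sol.x
    fitted = model(p)
    r2 = r_squared(fitted.ravel(), r.ravel())
    base = float(p[5]) if with_baseline else 0.0
    return GaussianFit(float(p[0]), float(p[1]), math.exp(p[2]), math.exp(p[3]),
                       float(p[4]), base, float(r2))


def _axis_gamma(sigma: float, d1: float, d2: float) -> float:
    """Invert sigma = gamma / sqrt(1/d1^2 + 1/d2^2) for gamma (alpha = 0)."""
    return sigma * math.sqrt(1.0 / d1**2 + 1.0 / d2**2)


@dataclass
class CrossEnvResult:
    per_field: list
    mean_r2_model: float
    mean_r2_optimal: float
    t_stat: float
    p_value: float


def cross_env_predict(fits_cd: dict, observed_maps: dict,
                      env_c: RectEnvironment, env_d: RectEnvironment,
                      target_env: RectEnvironment) -> CrossEnvResult:
    """Predict each field's rate map in a new environment from fits in two others.

    ``fits_cd`` maps cell id -> (GaussianFit in env C, GaussianFit in env D);
    ``observed_maps`` maps cell id -> observed RateMap in the target
    environment.  Per field: a Weber factor gamma is computed from the fitted
    stds and the wall distances in C and D (mean of the four per-axis
    estimates); the centroid is relocated to the same relative position
    (x/L, y/W preserved); the predicted stds in the target environment follow
    from its wall distances; the predicted Gaussian (amplitude and baseline
    fitted linearly, since rate amplitude is not a spatial quantity) is
    compared to the observed map by R-squared, against the best achievable
    Gaussian fit, with a paired t-test over the per-field R-squared pairs.
    """
    records = []
    for cell_id, (fc, fd) in fits_cd.items():
        obs = observed_maps.get(cell_id)
        if obs is None:
            continue
        rel_x = 0.5 * (fc.mu_x / env_c.length_cm + fd.mu_x / env_d.length_cm)
        rel_y = 0.5 * (fc.mu_y / env_c.width_cm + fd.mu_y / env_d.width_cm)
        if not (0.0 < rel_x < 1.0 and 0.0 < rel_y < 1.0):
            continue  # centroid outside the target environment after rescaling
        gammas = []
        for fit, env in ((fc, env_c), (fd, env_d)):
            gammas.append(_axis_gamma(fit.sigma_x, fit.mu_x, env.length_cm - fit.mu_x))
            gammas.append(_axis_gamma(fit.sigma_y, fit.mu_y, env.width_cm - fit.mu_y))
        gamma = float(np.mean(gammas))
        cx, cy = rel_x * target_env.length_cm, rel_y * target_env.width_cm
        sx = gamma / math.sqrt(1.0 / cx**2 + 1.0 / (target_env.length_cm - cx) ** 2)
        sy = gamma / math.sqrt(1.0 / cy**2 + 1.0 / (target_env.width_cm - cy) ** 2)

        xs, ys = obs.bin_centers()
        gx = np.exp(-0.5 * ((xs - cx) / sx) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sy) ** 2)
        shape = np.outer(gy, gx)
        # linear LSQ for amplitude and baseline given the predicted shape
        A = np.column_stack([shape.ravel(), np.ones(shape.size)])
        coef, *_ = np.linalg.lstsq(A, obs.rates.ravel(), rcond=None)
        predicted = (A @ coef).reshape(obs.rates.shape)
        r2_model = r_squared(predicted.ravel(), obs.rates.ravel())
        opt = fit_gaussian_ratemap(obs)
        predicted_map = RateMap(obs.bin_size_cm, obs.origin, np.clip(predicted, 0, None))
        records.append({
            "cell_id": cell_id,
            "gamma": gamma,
            "centroid": (cx, cy),
            "sigma": (sx, sy),
            "r2_model": r2_model,
            "r2_optimal": opt.r2,
            "predicted_map": predicted_map,
        })
    if not records:
        raise ValueError("no usable fields for cross-environment prediction")
    r2m = np.array([rec["r2_model"] for rec in records])
    r2o = np.array([rec["r2_optimal"] for rec in records])
    if np.allclose(r2m, r2o):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(r2m, r2o)
    return CrossEnvResult(records, float(r2m.mean()), float(r2o.mean()),
                          float(t), float(p))
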