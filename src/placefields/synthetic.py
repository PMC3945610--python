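"""Seeded synthetic datasets with the statistical structure the analyses assume.

Three generators emulate the three in-vivo experiment styles the model is
evaluated against:

* a narrow rectangular track where field area grows toward the track centre
  (dimensions are package defaults, 200 x 30 cm);
* the annular track (106.7 cm midline diameter, 15 cm wide) carrying eight
  objects and a barrier, where field sizes are minimal near objects — the
  default object arcs are fixed pseudo-random positions published here so
  that runs are deterministic;
* four open boxes (61x61, 122x122, 61x122, 122x61 cm) with Gaussian-like
  rate maps whose widths follow the wall distances.

Sizes carry multiplicative lognormal noise (mean-one, coefficient of
variation ``noise_cv``): sizes are positive and their spread grows with their
magnitude.  At ``noise_cv = 0`` every generator is an exact closure of the
corresponding fit, which is what the recovery tests exercise.  All outputs
are reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cue_model import CueParams, SubsetMask, posterior_sigma, rect_track_size
from .fitting import PlaceField, RateMap
from .geometry import CircularTrack, Point2D, RectEnvironment, track_distances
from .spiking import Trajectory

__all__ = [
    "DEFAULT_OBJECT_ARCS_CM",
    "default_circular_track",
    "default_linear_track",
    "OPEN_BOXES",
    "SyntheticSpec",
    "gen_linear_track",
    "gen_circular_track",
    "gen_openfield",
    "gen_trajectory",
    "fields_from_table",
]

#: Fixed pseudo-random object arc positions (cm) for the default synthetic
#: track; spread over the ~335.2 cm circumference, none on the barrier.
DEFAULT_OBJECT_ARCS_CM: tuple[float, ...] = (
    22.0, 58.5, 97.0, 131.5, 168.0, 205.5, 247.0, 291.5,
)


def default_circular_track() -> CircularTrack:
    """The annular-track geometry: 106.7 cm midline diameter, 15 cm width,
    eight objects plus the barrier at arc 0."""
    return CircularTrack(
        diameter_cm=106.7,
        track_width_cm=15.0,
        barrier_arc_cm=0.0,
        object_arcs_cm=DEFAULT_OBJECT_ARCS_CM,
    )


def default_linear_track() -> RectEnvironment:
    """Default narrow rectangular track (package default dimensions)."""
    return RectEnvironment(length_cm=200.0, width_cm=30.0)


#: The four open boxes of the environment-resizing experiment.
OPEN_BOXES: dict[str, RectEnvironment] = {
    "A": RectEnvironment(61.0, 61.0),
    "B": RectEnvironment(122.0, 122.0),
    "C": RectEnvironment(61.0, 122.0),
    "D": RectEnvironment(122.0, 61.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth container for a synthetic dataset.

    ``gamma_true`` is the generating Weber factor; ``mask_true`` the
    generating observation subset (circular track; None = all observations);
    ``multi_field_prob`` the probability that a cell owns two fields;
    ``noise_cv`` the coefficient of variation of the multiplicative lognormal
    size noise.
    """

    environment: object = None
    gamma_true: float = 0.2
    mask_true: SubsetMask | None = None
    n_cells: int = 100
    multi_field_prob: float = 0.2
    noise_cv: float = 0.1
    seed: int = 0
    n_spikes_per_field: int = 150
    peak_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if not self.gamma_true > 0:
            raise ValueError("gamma_true must be > 0")
        if not 0.0 <= self.multi_field_prob <= 1.0:
            raise ValueError("multi_field_prob must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def params(self) -> CueParams:
        return CueParams(gamma=self.gamma_true)


def _size_noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    s = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * s**2, sigma=s, size=n)


def gen_linear_track(spec: SyntheticSpec) -> pd.DataFrame:
    """Field table on a rectangular track: uniform centroids, area-dialect sizes.

    Sizes are the model's sigma_x * sigma_y product at each centroid times
    lognormal noise.  Columns: cell_id, field_id, x_cm, y_cm, size_value,
    size_dialect.
    """
    env = spec.environment or default_linear_track()
    if not isinstance(env, RectEnvironment):
        raise TypeError("gen_linear_track requires a RectEnvironment")
    rng = np.random.default_rng(spec.seed)
    params = spec.params()
    rows = []
    for c in range(spec.n_cells):
        n_fields = 2 if rng.random() < spec.multi_field_prob else 1
        for f in range(n_fields):
            x = rng.uniform(0.0, env.length_cm)
            y = rng.uniform(0.0, env.width_cm)
            size = rect_track_size(Point2D(x, y), env, params)
            rows.append((f"cell{c:03d}", f, x, y, size))
    df = pd.DataFrame(rows, columns=["cell_id", "field_id", "x_cm", "y_cm", "size_value"])
    df["size_value"] *= _size_noise(rng, len(df), spec.noise_cv)
    df["size_dialect"] = "area"
    return df


def gen_circular_track(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Field table + spike table on the circular track (std dialect).

    Per field: centroid uniform on the arc, generating sigma from the
    posterior under ``mask_true``, spike positions Gaussian(centroid, sigma).
    ``size_value`` is sigma times lognormal noise.  Returns ``(fields,
    spikes)`` DataFrames; spikes carry cell_id, field_id, arc_cm.
    """
    track = spec.environment or default_circular_track()
    if not isinstance(track, CircularTrack):
        raise TypeError("gen_circular_track requires a CircularTrack")
    rng = np.random.default_rng(spec.seed)
    params = spec.params()
    n_obs = len(track.object_arcs_cm) + 1
    mask = spec.mask_true or SubsetMask.ones(n_obs)
    circ = track.circumference_cm
    frows, srows = [], []
    for c in range(spec.n_cells):
        n_fields = 2 if rng.random() < spec.multi_field_prob else 1
        for f in range(n_fields):
            arc = rng.uniform(0.0, circ)
            d = [o.distance_cm for o in track_distances(arc, track)]
            sigma = posterior_sigma(d, params, mask)
            spikes = rng.normal(arc, sigma, size=spec.n_spikes_per_field)
            frows.append((f"cell{c:03d}", f, arc, sigma))
            srows.extend((f"cell{c:03d}", f, s) for s in spikes)
    fields = pd.DataFrame(frows, columns=["cell_id", "field_id", "arc_cm", "size_value"])
    fields["size_value"] *= _size_noise(rng, len(fields), spec.noise_cv)
    fields["size_dialect"] = "std"
    spikes = pd.DataFrame(srows, columns=["cell_id", "field_id", "arc_cm"])
    return fields, spikes


def gen_openfield(
    spec: SyntheticSpec,
    environments: dict[str, RectEnvironment] | None = None,
    bin_size_cm: float = 1.9,
    occupancy_s_per_bin: float | None = None,
    gamma_spread: float = 0.2,
) -> tuple[dict[str, dict[str, RateMap]], pd.DataFrame]:
    """Rate maps per cell per open-box environment.

    Each cell gets a Weber factor drawn from a lognormal with median
    ``gamma_true`` and log-std ``gamma_spread``, and a relative centroid
    (x/L, y/W) shared across environments.  In each environment the per-axis
    sigmas follow from the wall distances, and the map is the Gaussian
    surface sampled on ``bin_size_cm`` bins.  With ``occupancy_s_per_bin``
    set, Poisson count noise for that uniform occupancy is applied (rate =
    Poisson(rate * T) / T); None means noiseless maps.

    Returns ``(maps, truth)``: maps[env_name][cell_id] and a truth table of
    the generating parameters.
    """
    envs = environments or OPEN_BOXES
    rng = np.random.default_rng(spec.seed)
    maps: dict[str, dict[str, RateMap]] = {name: {} for name in envs}
    rows = []
    for c in range(spec.n_cells):
        cell = f"cell{c:03d}"
        gamma = spec.gamma_true * rng.lognormal(0.0, gamma_spread)
        rel_x, rel_y = rng.uniform(0.15, 0.85, size=2)
        rows.append((cell, gamma, rel_x, rel_y))
        for name, env in envs.items():
            cx, cy = rel_x * env.length_cm, rel_y * env.width_cm
            sx = gamma / math.sqrt(cx**-2 + (env.length_cm - cx) ** -2)
            sy = gamma / math.sqrt(cy**-2 + (env.width_cm - cy) ** -2)
            nx = int(round(env.length_cm / bin_size_cm))
            ny = int(round(env.width_cm / bin_size_cm))
            xs = (np.arange(nx) + 0.5) * bin_size_cm
            ys = (np.arange(ny) + 0.5) * bin_size_cm
            rates = spec.peak_rate_hz * np.outer(
                np.exp(-0.5 * ((ys - cy) / sy) ** 2),
                np.exp(-0.5 * ((xs - cx) / sx) ** 2),
            )
            if occupancy_s_per_bin is not None:
                rates = rng.poisson(rates * occupancy_s_per_bin) / occupancy_s_per_bin
            maps[name][cell] = RateMap(bin_size_cm, Point2D(0.0, 0.0), rates)
    truth = pd.DataFrame(rows, columns=["cell_id", "gamma", "rel_x", "rel_y"])
    return maps, truth


def gen_trajectory(env, speed_cm_s: float, duration_s: float, seed: int = 0,
                   dt_s: float = 0.02) -> Trajectory:
    """Constant-speed 1D trajectory through an environment.

    Rect environments give back-and-forth runs along the track length;
    circular tracks give barrier-bounded lap alternation in the arc
    coordinate (clockwise / counter-clockwise, never crossing the barrier).
    Both are triangle waves in the 1D coordinate; ``seed`` is accepted for
    interface uniformity (the default path is deterministic).
    """
    if not speed_cm_s > 0 or not duration_s > 0:
        raise ValueError("speed and duration must be > 0")
    if isinstance(env, RectEnvironment):
        extent = env.length_cm
    elif isinstance(env, CircularTrack):
        extent = env.circumference_cm
    else:
        raise TypeError(f"unsupported environment type {type(env).__name__}")
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    path = speed_cm_s * t
    # reflect off both ends of [0, extent]
    cycle = np.mod(path, 2.0 * extent)
    pos = np.where(cycle <= extent, cycle, 2.0 * extent - cycle)
    return Trajectory(t, pos)


def fields_from_table(df: pd.DataFrame) -> list[PlaceField]:
    """Convert a field-table DataFrame into PlaceField records."""
    out = []
    for _, row in df.iterrows():
        if "arc_cm" in df.columns:
            centroid = float(row["arc_cm"])
        else:
            centroid = Point2D(float(row["x_cm"]), float(row["y_cm"]))
        out.append(PlaceField(str(row["cell_id"]), int(row["field_id"]), centroid,
                              float(row["size_value"]), str(row["size_dialect"])))
    return out
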