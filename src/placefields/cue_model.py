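"""Precision-weighted Gaussian cue fusion: location uncertainty from geometry.

The model treats the animal's location belief as Gaussian.  Each boundary or
object observation contributes a Gaussian likelihood whose standard deviation
grows linearly with the observation distance, sigma_o = gamma * d (Weber-law
scaling with Weber factor gamma).  Bayesian fusion of Gaussians adds
precisions (inverse variances) and precision-weights means, so the posterior
standard deviation at a location with observation distances d_j is

    sigma(x) = (alpha + beta * sum_j delta_j / d_j**2) ** -0.5,

where alpha is the precision of the path-integration prior (default 0:
negligible), beta = 1/gamma**2, and delta_j in {0, 1} masks observations in
or out (subset extension).  Under the hypothesis that place-field size tracks
location uncertainty, sigma(x) profiles predict field-size profiles.

In 2D the same accumulation happens on the precision matrix,

    P = alpha * I + sum_j n_j n_j^T / (gamma * d_j)**2,

with n_j the unit direction along which observation j constrains position;
the posterior covariance is P^{-1}.  For axis-aligned normals this reduces to
independent per-axis 1D fusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    CircularTrack,
    ObservationGeometry,
    Point2D,
    RectEnvironment,
    rect_boundary_distances,
    track_distances,
)

__all__ = [
    "Gaussian1D",
    "Gaussian2D",
    "CueParams",
    "SubsetMask",
    "observation_sigma",
    "fuse_1d",
    "posterior_sigma",
    "posterior_covariance_2d",
    "rect_track_size",
    "size_profile",
    "spike_density_curve",
    "SIGMA_FLOOR_CM",
]

#: Floor applied to degenerate (d = 0) sigmas when sampling profiles, so that
#: z-scoring and plotting remain finite.  Exact queries still return 0.
SIGMA_FLOOR_CM = 1e-6


@dataclass(frozen=True)
class Gaussian1D:
    """1D Gaussian location belief (mean and std in cm)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class Gaussian2D:
    """2D Gaussian location belief: mean 2-vector (cm), 2x2 covariance (cm^2)."""

    mu: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValueError("cov must be positive definite")
        object.__setattr__(self, "mu", tuple(float(v) for v in self.mu))
        object.__setattr__(self, "cov", tuple(tuple(float(v) for v in row) for row in c))

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.asarray(self.cov, dtype=float)


class CueParams:
    """Model parameters: Weber factor gamma, prior precision alpha.

    beta = 1/gamma**2 (the observation precision factor) is kept consistent
    with gamma; construct with either ``CueParams(gamma=...)`` or
    ``CueParams(beta=...)``.

    Parameters
    ----------
    gamma : float, optional
        Weber factor — observation std per cm of distance (dimensionless).
    alpha : float, default 0
        Precision of the path-integration prior, cm^-2.  The default is 0:
        for the datasets modelled here the prior is negligible because the
        recorded cells are mainly sensory-driven.
    beta : float, optional
        1/gamma**2; alternative parameterization.
    """

    __slots__ = ("gamma", "alpha")

    def __init__(self, gamma: float | None = None, alpha: float = 0.0, *, beta: float | None = None):
        if (gamma is None) == (beta is None):
            raise ValueError("specify exactly one of gamma or beta")
        if beta is not None:
            if not beta > 0:
                raise ValueError(f"beta must be > 0, got {beta}")
            gamma = 1.0 / math.sqrt(beta)
        if not gamma > 0:
            raise ValueError(f"gamma must be > 0, got {gamma}")
        if alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {alpha}")
        self.gamma = float(gamma)
        self.alpha = float(alpha)

    @property
    def beta(self) -> float:
        return 1.0 / self.gamma**2

    def __repr__(self) -> str:
        return f"CueParams(gamma={self.gamma!r}, alpha={self.alpha!r})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CueParams)
            and self.gamma == other.gamma
            and self.alpha == other.alpha
        )


@dataclass(frozen=True)
class SubsetMask:
    """Binary indicators selecting which observations enter the fusion."""

    delta: tuple[int, ...]

    def __post_init__(self) -> None:
        d = tuple(int(v) for v in self.delta)
        if any(v not in (0, 1) for v in d):
            raise ValueError("mask entries must be 0 or 1")
        object.__setattr__(self, "delta", d)

    def __len__(self) -> int:
        return len(self.delta)

    @classmethod
    def ones(cls, n: int) -> "SubsetMask":
        return cls((1,) * n)

    @classmethod
    def from_index(cls, bits: int, n: int) -> "SubsetMask":
        """Mask from the binary representation of ``bits`` (bit j = delta_j)."""
        return cls(tuple((bits >> j) & 1 for j in range(n)))


def observation_sigma(d: float, params: CueParams) -> float:
    """Observation noise for a distance ``d``: sigma_o = gamma * d (Weber-law)."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return params.gamma * d


def fuse_1d(prior: Gaussian1D | None, observations: list[Gaussian1D]) -> Gaussian1D:
    """Fuse a prior and observations by the 1D Gaussian product.

    Posterior precision is the sum of input precisions; the posterior mean is
    the precision-weighted mean of input means.  ``prior`` may be None
    (negligible path-integration prior) as long as at least one observation is
    supplied.
    """
    inputs = ([] if prior is None else [prior]) + list(observations)
    if not inputs:
        raise ValueError("cannot fuse an empty set of beliefs")
    precisions = np.array([1.0 / g.sigma**2 for g in inputs])
    means = np.array([g.mu for g in inputs])
    total = precisions.sum()
    return Gaussian1D(mu=float((precisions * means).sum() / total), sigma=float(total**-0.5))


def posterior_sigma(
    distances,
    params: CueParams,
    mask: SubsetMask | None = None,
) -> float:
    """Posterior location uncertainty from observation distances.

    sigma = (alpha + beta * sum_j delta_j / d_j**2) ** -0.5.  A masked-in
    distance of exactly 0 is a degenerate (perfectly informative) observation:
    the function returns 0.0.  Use :data:`SIGMA_FLOOR_CM` downstream where a
    strictly positive value is required.
    """
    d = np.asarray(list(distances), dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if mask is None:
        mask = SubsetMask.ones(len(d))
    if len(mask) != len(d):
        raise ValueError(f"mask length {len(mask)} != {len(d)} observations")
    delta = np.asarray(mask.delta, dtype=bool)
    used = d[delta]
    if np.any(used == 0.0):
        return 0.0
    precision = params.alpha + params.beta * np.sum(1.0 / used**2)
    if precision <= 0:
        raise ValueError("all observations masked out and alpha = 0: belief undefined")
    return float(precision**-0.5)


def posterior_covariance_2d(
    observations: list[ObservationGeometry],
    params: CueParams,
) -> np.ndarray:
    """Posterior covariance from directional distance observations.

    Accumulates the precision matrix alpha*I + sum_j n_j n_j^T/(gamma d_j)^2
    and inverts it.  Observations without a direction or with d = 0 are
    rejected (a d = 0 wall observation pins one axis exactly; handle it
    upstream before asking for a full covariance).
    """
    P = params.alpha * np.eye(2)
    for obs in observations:
        if obs.normal is None:
            raise ValueError("2D fusion requires each observation's normal direction")
        if obs.distance_cm == 0.0:
            raise ValueError(f"degenerate d=0 observation {obs.label!r}: covariance singular")
        n = np.asarray(obs.normal, dtype=float)
        P += np.outer(n, n) / (params.gamma * obs.distance_cm) ** 2
    eigvals = np.linalg.eigvalsh(P)
    if eigvals[0] <= max(1e-300, 1e-12 * eigvals[1]):
        raise ValueError(
            "precision matrix is rank-deficient: some direction is unconstrained "
            "(all normals parallel with alpha = 0?)"
        )
    return np.linalg.inv(P)


def _axis_sigma(d_near: float, d_far: float, params: CueParams) -> float:
    return posterior_sigma([d_near, d_far], params)


def rect_track_size(p: Point2D, env: RectEnvironment, params: CueParams) -> float:
    """Predicted field size at ``p``: product of the per-axis uncertainties.

    Each axis is fused from its two opposing walls; the product sigma_x *
    sigma_y is an area-like quantity matching field-size-in-bins measures.
    Maximal at the arena centre, symmetric about both midlines.
    """
    w, e, s, n = rect_boundary_distances(p, env)
    sx = _axis_sigma(w.distance_cm, e.distance_cm, params)
    sy = _axis_sigma(s.distance_cm, n.distance_cm, params)
    return sx * sy


def rect_axis_sigmas(p: Point2D, env: RectEnvironment, params: CueParams) -> tuple[float, float]:
    """Per-axis posterior stds (sigma_x, sigma_y) at ``p`` from the four walls."""
    w, e, s, n = rect_boundary_distances(p, env)
    return (
        _axis_sigma(w.distance_cm, e.distance_cm, params),
        _axis_sigma(s.distance_cm, n.distance_cm, params),
    )


def size_profile(
    track: CircularTrack,
    params: CueParams,
    mask: SubsetMask | None = None,
    resolution_cm: float = 1.0,
    sigma_floor_cm: float = SIGMA_FLOOR_CM,
):
    """Predicted uncertainty profile along a circular track.

    Returns ``(arcs, sigmas)``: a regular arc grid of spacing
    ``resolution_cm`` over [0, circumference) and the posterior sigma at each
    position, using the object + barrier distances and the subset mask.
    Degenerate positions (exactly at a masked-in object) are clipped to
    ``sigma_floor_cm``.  Local minima of the profile sit at masked-in object
    and barrier positions.
    """
    if not resolution_cm > 0:
        raise ValueError(f"resolution_cm must be > 0, got {resolution_cm}")
    circ = track.circumference_cm
    arcs = np.arange(0.0, circ, resolution_cm)
    n_obs = len(track.object_arcs_cm) + 1  # + barrier
    if mask is None:
        mask = SubsetMask.ones(n_obs)
    if len(mask) != n_obs:
        raise ValueError(f"mask length {len(mask)} != {n_obs} observations (objects + barrier)")
    sigmas = np.empty_like(arcs)
    for i, s in enumerate(arcs):
        dists = [o.distance_cm for o in track_distances(float(s), track)]
        sigmas[i] = max(posterior_sigma(dists, params, mask), sigma_floor_cm)
    return arcs, sigmas


def spike_density_curve(fields, grid) -> np.ndarray:
    """Summed Gaussian spike density over ``grid`` from (centroid, sigma, weight) triples.

    One Gaussian per place field, centred at the field centroid with std equal
    to its predicted uncertainty; the pointwise sum models the aggregate spike
    density across cells.  Z-score before comparing shapes to recorded
    densities (amplitudes depend on non-spatial factors).
    """
    fields = list(fields)
    if not fields:
        raise ValueError("spike_density_curve requires at least one field")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for centroid, sigma, weight in fields:
        if not sigma > 0:
            raise ValueError(f"field sigma must be > 0, got {sigma}")
        out += weight * np.exp(-0.5 * ((grid - centroid) / sigma) ** 2) / (
            sigma * math.sqrt(2.0 * math.pi)
        )
    return out
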