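"""Bayesian inference by coincidence detection in a spiking place cell.

A current-based leaky integrate-and-fire (LIF) place cell receives Poisson
spike trains from Gaussian-tuned inputs (a grid-cell prior field and a
border-cell observation field).  If the spike threshold is high enough that
only near-coincident input spikes can discharge the cell, its output rate
approximates the *product* of the input rate profiles — the multiplication
Bayesian fusion requires — so the output firing field approximates the
Gaussian-product posterior: located between the input field centres, closer
to the narrower (more precise) one, and narrower than either input.

The temporal window within which inputs count as coincident is tied to the
membrane dynamics: a PSP of amplitude A decays with the membrane time
constant tau_m, and a second spike still finds a useful depolarization while
the decay is within the membrane-noise amplitude sigma_V of the peak, giving

    delta_t = tau_m * ln(A / (A - sigma_V)).

With the defaults (tau_m 20 ms, A 12 mV, sigma_V 1.5 mV) this is ~2.7 ms,
the order of magnitude of the 5-10 ms coincidence window measured in vitro
in CA1.  The same delta_t discretizes the binary-window coincidence rule and
the spikes-as-posterior-samples read-outs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LIFParams",
    "SpikeTrain",
    "GaussianRateField",
    "Trajectory",
    "temporal_resolution",
    "poisson_train",
    "coincidence_train",
    "simulate_place_cell",
    "posterior_from_spikes",
    "gaussian_product_mean",
    "multiplication_error",
    "error_surface",
    "path_probability",
    "peak_output_rate",
]


@dataclass(frozen=True)
class LIFParams:
    """Current-based leaky integrate-and-fire parameters.

    The default voltages and time constants are package defaults in the range
    reported for CA1 pyramidal cells in vivo (effective membrane constants
    under synaptic bombardment are short); ``psp_amp_mV`` is the peak
    depolarization caused by a single input spike, set just under the
    rest-to-threshold gap so that a single input alone cannot fire the cell
    but two coincident inputs can — the fluctuation-driven coincidence
    regime the place-cell model needs.
    """

    tau_m_ms: float = 10.0
    tau_s_ms: float = 3.0
    V_rest_mV: float = -70.0
    V_thresh_mV: float = -54.0
    V_reset_mV: float = -70.0
    psp_amp_mV: float = 10.0
    sigma_V_mV: float = 1.5
    dt_ms: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tau_m_ms", "tau_s_ms", "dt_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.V_thresh_mV > self.V_rest_mV:
            raise ValueError("V_thresh must exceed V_rest")
        if not self.psp_amp_mV > 0:
            raise ValueError("psp_amp_mV must be > 0")
        if self.sigma_V_mV < 0:
            raise ValueError("sigma_V_mV must be >= 0")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) within [0, duration_s]."""

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1:
            raise ValueError("times_s must be 1D")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.duration_s):
            raise ValueError("spike times must be strictly increasing within [0, duration]")
        object.__setattr__(self, "times_s", t)

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class GaussianRateField:
    """Gaussian spatial tuning: rate(x) = peak_rate * exp(-(x-center)^2 / 2 sigma^2)."""

    center_cm: float
    sigma_cm: float
    peak_rate_hz: float

    def __post_init__(self) -> None:
        if not self.sigma_cm > 0:
            raise ValueError("sigma_cm must be > 0")
        if self.peak_rate_hz < 0:
            raise ValueError("peak_rate_hz must be >= 0")

    def rate_at(self, x_cm) -> np.ndarray:
        x = np.asarray(x_cm, dtype=float)
        return self.peak_rate_hz * np.exp(-0.5 * ((x - self.center_cm) / self.sigma_cm) ** 2)


@dataclass(frozen=True)
class Trajectory:
    """Sampled 1D position over time (animal path driving the input rates)."""

    times_s: np.ndarray
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.positions_cm, dtype=float)
        if t.ndim != 1 or t.shape != x.shape:
            raise ValueError("times and positions must be 1D with equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "positions_cm", x)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])

    def position_at(self, t_s) -> np.ndarray:
        return np.interp(np.asarray(t_s, dtype=float), self.times_s, self.positions_cm)


def temporal_resolution(params: LIFParams) -> float:
    """Coincidence-detection window (ms) from the membrane parameters.

    delta_t = tau_m * ln(A / (A - sigma_V)): the time for a PSP of amplitude
    A to decay by more than the membrane-noise amplitude sigma_V, i.e. the
    window during which a second input still finds the first one's
    depolarization effectively at peak.  Requires sigma_V < A; widens with
    noise (noise blurs what counts as simultaneous) and tightens with larger
    PSPs or faster membranes.
    """
    if not params.sigma_V_mV > 0:
        raise ValueError("temporal resolution undefined for sigma_V = 0")
    if not params.psp_amp_mV > params.sigma_V_mV:
        raise ValueError("requires psp_amp > sigma_V (PSPs resolvable above noise)")
    return params.tau_m_ms * math.log(params.psp_amp_mV / (params.psp_amp_mV - params.sigma_V_mV))


def poisson_train(rate_fn, duration_s: float, dt_ms: float, seed,
                  refractory_ms: float = 0.0) -> SpikeTrain:
    """Non-homogeneous Poisson spike train by per-bin Bernoulli sampling.

    ``rate_fn`` maps an array of times (s) to instantaneous rates (Hz);
    ``seed`` may be an int or a numpy Generator.  ``refractory_ms`` imposes a
    dead time after each spike (spiking neurons do not fire arbitrarily short
    interspike intervals).  Reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    dt_s = dt_ms / 1000.0
    t = np.arange(0.0, duration_s, dt_s)
    rates = np.asarray(rate_fn(t), dtype=float)
    if np.any(rates < 0):
        raise ValueError("rate_fn returned a negative rate")
    p = np.clip(rates * dt_s, 0.0, 1.0)
    fired = rng.random(t.size) < p
    # spike at the bin centre keeps times strictly inside the bin grid
    times = t[fired] + dt_s / 2.0
    if refractory_ms > 0 and times.size:
        dead = refractory_ms / 1000.0
        kept = [times[0]]
        for ts in times[1:]:
            if ts - kept[-1] >= dead:
                kept.append(ts)
        times = np.asarray(kept)
    return SpikeTrain(times, duration_s)


def _window_counts(trains: list[SpikeTrain], delta_t_ms: float, duration_s: float):
    """For each delta_t window, how many distinct inputs spiked in it."""
    dt_s = delta_t_ms / 1000.0
    n_win = max(1, int(math.ceil(duration_s / dt_s)))
    counts = np.zeros(n_win, dtype=int)
    for train in trains:
        idx = np.minimum((train.times_s / dt_s).astype(int), n_win - 1)
        counts[np.unique(idx)] += 1
    return counts, dt_s


def coincidence_train(inputs: list[SpikeTrain], theta: float, delta_t_ms: float) -> SpikeTrain:
    """Binary-window coincidence rule (Heaviside form).

    Time is cut into windows of width delta_t; an output spike is emitted at
    a window's centre when at least ceil(theta * n) distinct inputs each
    spiked within that window.  theta = 1 is conjunction of all inputs;
    theta <= 1/n degenerates to disjunction.
    """
    if not inputs:
        raise ValueError("need at least one input train")
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    if not delta_t_ms > 0:
        raise ValueError("delta_t_ms must be > 0")
    duration = max(tr.duration_s for tr in inputs)
    counts, dt_s = _window_counts(inputs, delta_t_ms, duration)
    need = math.ceil(theta * len(inputs))
    win = np.nonzero(counts >= need)[0]
    return SpikeTrain((win + 0.5) * dt_s, duration)


def simulate_place_cell(
    lif: LIFParams,
    input_fields: list[GaussianRateField],
    traj: Trajectory,
    seed,
    return_trace: bool = False,
    input_refractory_ms: float = 15.0,
):
    """Euler-integrated LIF place cell driven by Poisson Gaussian-tuned inputs.

    Each input field generates a Poisson spike train with rate given by the
    field evaluated along the trajectory.  Synapses are exponential
    current-based (time constant tau_s), scaled so a single spike causes a
    peak depolarization of ``psp_amp_mV``, and *saturating*: a spike resets
    its synapse's trace to the unit level instead of summing, so repeated
    spikes from one input can never impersonate a coincidence of distinct
    inputs — threshold crossings require genuinely coincident inputs, which
    is what makes the cell multiply rather than add its input rate profiles.
    Membrane noise is an Ornstein-Uhlenbeck term with stationary std
    ``sigma_V_mV``.  Input trains carry a dead time ``input_refractory_ms``
    (spatially tuned afferents do not fire arbitrarily short interspike
    intervals), which prevents one input's successive spikes from summing
    across the membrane window into a spurious "coincidence".  After each
    output spike the potential resets and the cell is refractory for one
    coincidence window.

    Returns a dict with ``output`` (SpikeTrain), ``inputs`` (list of
    SpikeTrain) and, if requested, ``t_s`` / ``V_mV`` traces.
    """
    if lif.dt_ms > lif.tau_s_ms / 2.0:
        raise ValueError(f"dt={lif.dt_ms} ms too coarse for tau_s={lif.tau_s_ms} ms "
                         "(need dt <= tau_s / 2)")
    rng = np.random.default_rng(seed)
    duration = traj.duration_s
    dt_s = lif.dt_ms / 1000.0
    t = np.arange(0.0, duration, dt_s)
    pos = traj.position_at(t)

    inputs = [
        poisson_train(lambda _t, f=f: f.rate_at(traj.position_at(_t)), duration,
                      lif.dt_ms, rng, refractory_ms=input_refractory_ms)
        for f in input_fields
    ]
    # saturating exponential trace per input: value exp(-(t - last spike)/tau_s)
    syn = np.zeros(t.size)
    for train in inputs:
        last = np.searchsorted(train.times_s, t, side="right") - 1
        has = last >= 0
        trace = np.zeros(t.size)
        trace[has] = np.exp(-(t[has] - train.times_s[last[has]]) * 1000.0 / lif.tau_s_ms)
        syn += trace
    unit_peak = _unit_psp_peak(lif)
    w = lif.psp_amp_mV / unit_peak

    leak = lif.dt_ms / lif.tau_m_ms
    noise = (lif.sigma_V_mV * math.sqrt(2.0 * leak)) * rng.standard_normal(t.size)
    drive = leak * w * syn

    refractory_steps = max(1, int(round(temporal_resolution_safe(lif) / lif.dt_ms)))
    v = lif.V_rest_mV
    spikes = []
    trace = np.empty(t.size) if return_trace else None
    i = 0
    v_rest, v_th, v_reset = lif.V_rest_mV, lif.V_thresh_mV, lif.V_reset_mV
    n = t.size
    while i < n:
        v = v + leak * (v_rest - v) + drive[i] + noise[i]
        if trace is not None:
            trace[i] = v
        if v >= v_th:
            spikes.append(t[i])
            v = v_reset
            if trace is not None:
                trace[i : i + refractory_steps] = v_reset
            i += refractory_steps
            continue
        i += 1
    out = {
        "output": SpikeTrain(np.asarray(spikes), duration),
        "inputs": inputs,
        "positions_cm": pos,
    }
    if return_trace:
        out["t_s"] = t
        out["V_mV"] = trace
    return out


def temporal_resolution_safe(lif: LIFParams) -> float:
    """temporal_resolution with a fallback window for noiseless parameter sets."""
    try:
        return temporal_resolution(lif)
    except ValueError:
        return lif.tau_s_ms


def _unit_psp_peak(lif: LIFParams) -> float:
    """Peak depolarization for w = 1, computed on the discrete update itself."""
    n = int(10 * max(lif.tau_m_ms, lif.tau_s_ms) / lif.dt_ms)
    decay_s = math.exp(-lif.dt_ms / lif.tau_s_ms)
    syn = decay_s ** np.arange(n)
    leak = lif.dt_ms / lif.tau_m_ms
    v = 0.0
    peak = 0.0
    for s in syn:
        v = v + leak * (-v) + leak * s
        if v > peak:
            peak = v
    return peak


def posterior_from_spikes(output: SpikeTrain, traj: Trajectory,
                          n_sigma: float = 3.0, max_passes: int = 5):
    """Read the posterior belief out of the output spikes.

    Spike times map to positions through the trajectory; positions beyond
    ``n_sigma`` running stds of the running mean are trimmed iteratively
    (noise filtering, at most ``max_passes`` passes).  Returns ``(mean_cm,
    std_cm, kept_positions)``.  A zero-spread result signals a degenerate
    read-out and raises.
    """
    if len(output) < 5:
        raise ValueError(f"need at least 5 output spikes, got {len(output)}")
    x = traj.position_at(output.times_s)
    for _ in range(max_passes):
        mu, sd = x.mean(), x.std(ddof=0)
        if sd == 0:
            raise ValueError("degenerate read-out: all spike positions identical")
        keep = np.abs(x - mu) <= n_sigma * sd
        if keep.all():
            break
        x = x[keep]
        if x.size < 2:
            raise ValueError("trimming removed nearly all spikes")
    return float(x.mean()), float(x.std(ddof=0)), x


def gaussian_product_mean(prior: GaussianRateField, obs: GaussianRateField) -> float:
    """Mean of the exact Gaussian-product posterior of the two tuning curves."""
    w1, w2 = prior.sigma_cm**-2, obs.sigma_cm**-2
    return (w1 * prior.center_cm + w2 * obs.center_cm) / (w1 + w2)


def multiplication_error(
    lif: LIFParams,
    prior_field: GaussianRateField,
    obs_field: GaussianRateField,
    traj: Trajectory,
    seed,
    reps: int = 10,
) -> float:
    """Absolute error of the neuronal posterior mean vs. the exact product mean.

    Runs ``reps`` independent simulations (per-rep seeds derived from
    ``seed``), reads out the posterior mean from the output spikes, and
    averages |model mean - exact mean| in cm.  Reps with too few output
    spikes are discarded with a warning; if all are empty, raises.
    """
    exact = gaussian_product_mean(prior_field, obs_field)
    root = np.random.SeedSequence(seed)
    errors = []
    for child in root.spawn(reps):
        sim = simulate_place_cell(lif, [prior_field, obs_field], traj, child)
        try:
            mean, _, _ = posterior_from_spikes(sim["output"], traj)
        except ValueError:
            warnings.warn("repetition discarded: too few output spikes", stacklevel=2)
            continue
        errors.append(abs(mean - exact))
    if not errors:
        raise ValueError("no repetition produced enough output spikes")
    return float(np.mean(errors))


def error_surface(
    tau_m_grid,
    v_thresh_grid,
    lif: LIFParams,
    prior_field: GaussianRateField,
    obs_field: GaussianRateField,
    traj: Trajectory,
    seed,
    reps: int = 5,
) -> np.ndarray:
    """Multiplication error over a (tau_m, V_thresh) grid; NaN where no spikes.

    Output shape is ``(len(tau_m_grid), len(v_thresh_grid))``.
    """
    tau_m_grid = np.atleast_1d(np.asarray(tau_m_grid, dtype=float))
    v_thresh_grid = np.atleast_1d(np.asarray(v_thresh_grid, dtype=float))
    if tau_m_grid.size == 0 or v_thresh_grid.size == 0:
        raise ValueError("grids must be non-empty")
    out = np.full((tau_m_grid.size, v_thresh_grid.size), np.nan)
    root = np.random.SeedSequence(seed)
    for i, tau in enumerate(tau_m_grid):
        for j, vth in enumerate(v_thresh_grid):
            p = replace(lif, tau_m_ms=float(tau), V_thresh_mV=float(vth))
            cell = int(np.random.SeedSequence((seed, i, j)).generate_state(1)[0] % 2**31)
            try:
                out[i, j] = multiplication_error(p, prior_field, obs_field, traj,
                                                cell, reps=reps)
            except ValueError:
                pass  # NaN marks grid points with no usable output
    return out


def path_probability(output: SpikeTrain, interval, traj: Trajectory,
                     delta_t_ms: float) -> float:
    """Probability the animal's represented location lies in ``interval``.

    Output spikes are read as posterior samples: the estimate is the fraction
    of delta_t windows containing at least one output spike whose (window
    centre) position falls inside the half-open interval [x_a, x_b) — the
    upper end is included when it reaches the top of the trajectory's range,
    so disjoint intervals are exactly additive and a partition of the domain
    sums to 1.
    """
    x_a, x_b = interval
    if len(output) == 0:
        raise ValueError("no output spikes: probability undefined")
    counts, dt_s = _window_counts([output], delta_t_ms, output.duration_s)
    win = np.nonzero(counts > 0)[0]
    pos = traj.position_at((win + 0.5) * dt_s)
    if x_b < x_a:
        return 0.0
    upper = pos <= x_b if x_b >= traj.positions_cm.max() else pos < x_b
    return float(np.mean((pos >= x_a) & upper))


def peak_output_rate(output: SpikeTrain, traj: Trajectory, bin_cm: float = 5.0) -> float:
    """Peak spatial firing rate (Hz): max over position bins of spikes / occupancy."""
    t = traj.times_s
    occupancy_dt = np.diff(t, append=t[-1] + (t[-1] - t[-2]))
    pos = traj.positions_cm
    lo, hi = pos.min(), pos.max()
    edges = np.arange(lo, hi + bin_cm, bin_cm)
    occ, _ = np.histogram(pos, bins=edges, weights=occupancy_dt)
    spk, _ = np.histogram(traj.position_at(output.times_s), bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spk / occ, 0.0)
    return float(rate.max())
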