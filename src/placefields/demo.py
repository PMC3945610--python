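"""Canonical two-input place-cell demonstration setup.

One wide "grid cell" prior field and one narrow "border cell" observation
field drive the coincidence-detecting LIF place cell along a back-and-forth
run on a 100 cm segment.  The exact Gaussian-product posterior of the two
tuning curves has its mean between the field centres, closer to the narrow
(more precise) field, and a smaller std than either input; the simulated
cell's output field approximates it.  Used by the README worked example and
the reproduction script so every quoted number comes from one configuration.
"""

from __future__ import annotations

import numpy as np

from .geometry import RectEnvironment
from .spiking import (
    GaussianRateField,
    LIFParams,
    Trajectory,
    gaussian_product_mean,
    peak_output_rate,
    posterior_from_spikes,
    simulate_place_cell,
)
from .synthetic import gen_trajectory

__all__ = ["demo_fields", "demo_trajectory", "run_demo"]

#: segment length (cm) of the demonstration track
TRACK_LENGTH_CM = 100.0


def demo_fields() -> tuple[GaussianRateField, GaussianRateField]:
    """(prior, observation) tuning: wide grid field at 40 cm (sigma 12 cm),
    narrow border field at 58 cm (sigma 6 cm), both peaking at 20 Hz — the
    top of the typical grid-cell firing-rate band."""
    prior = GaussianRateField(center_cm=40.0, sigma_cm=12.0, peak_rate_hz=20.0)
    obs = GaussianRateField(center_cm=58.0, sigma_cm=6.0, peak_rate_hz=20.0)
    return prior, obs


def demo_trajectory(duration_s: float = 80.0, speed_cm_s: float = 10.0) -> Trajectory:
    """Constant-speed back-and-forth run over the demonstration segment."""
    return gen_trajectory(RectEnvironment(TRACK_LENGTH_CM, 1.0), speed_cm_s,
                          duration_s, seed=0)


def run_demo(seed, reps: int = 30, duration_s: float = 80.0,
             lif: LIFParams | None = None) -> dict:
    """Run the two-input simulation ``reps`` times and summarize the read-out.

    Returns posterior mean/std (mean over reps), the exact Gaussian-product
    mean, and the peak output firing rate at the field centre (Hz, mean over
    reps).  Per-rep seeds derive from ``seed``.
    """
    lif = lif or LIFParams()
    prior, obs = demo_fields()
    traj = demo_trajectory(duration_s)
    means, stds, peaks = [], [], []
    for child in np.random.SeedSequence(seed).spawn(reps):
        sim = simulate_place_cell(lif, [prior, obs], traj, child)
        m, sd, _ = posterior_from_spikes(sim["output"], traj)
        means.append(m)
        stds.append(sd)
        peaks.append(peak_output_rate(sim["output"], traj))
    return {
        "posterior_mean_cm": float(np.mean(means)),
        "posterior_mean_sem_cm": float(np.std(means) / np.sqrt(reps)),
        "posterior_std_cm": float(np.mean(stds)),
        "posterior_std_sem_cm": float(np.std(stds) / np.sqrt(reps)),
        "exact_mean_cm": gaussian_product_mean(prior, obs),
        "peak_rate_hz": float(np.mean(peaks)),
        "reps": reps,
    }
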