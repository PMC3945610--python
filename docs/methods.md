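# Methods

## Model

The package treats a place cell's firing field as a read-out of the
animal's Gaussian location belief. Observations are distances to walls,
objects and obstacles; each contributes a Gaussian likelihood centred on
the true location with standard deviation proportional to the distance,
`sigma_o = gamma * d` (Weber-law scaling — distance judgements degrade
linearly with range). Bayesian fusion of Gaussians adds precisions and
precision-weights means, so with a path-integration prior of precision
`alpha` (cm^-2) and observation subset indicators `delta_j`,

    sigma(x) = (alpha + beta * sum_j delta_j / d_j(x)^2) ** -0.5,
    beta = 1 / gamma^2.

In 2D the precision matrix `alpha*I + sum_j n_j n_j^T / (gamma d_j)^2`
accumulates the same information directionally (`n_j` the unit direction
along which observation j constrains position) and its inverse is the
posterior covariance; for axis-aligned walls this reduces exactly to two
independent 1D fusions, which the tests verify.

Assumptions worth keeping in mind: beliefs and likelihoods are Gaussian
(no skewed or multimodal fields); observations are conditionally
independent given location; each field of a multi-field cell is treated
independently; `alpha` defaults to 0 because the modelled recordings come
from distal CA1, which is mainly sensory-driven, so the path-integration
prior is taken as negligible — pass a positive `alpha` to restore it.

## Environments and conventions

Coordinates are Cartesian cm with the origin at the south-west corner.
The circular track's 1D coordinate is arc length along the track midline,
counter-clockwise from the barrier; the printed 106.7 cm diameter is
treated as the midline diameter of the 15 cm-wide annulus. The barrier
blocks passage, so object distances are arc differences that never cross
it, and the barrier itself is approachable from both sides. The default
eight object arcs (22.0, 58.5, 97.0, 131.5, 168.0, 205.5, 247.0, 291.5 cm)
are fixed pseudo-random positions published in the package so all runs are
deterministic; the original experiment's positions are not recoverable and
are config inputs. The linear-track default of 200 x 30 cm is likewise a
package default, not a measured arena.

## Field size dialects

Two size measures are supported and never mixed: the standard deviation of
a field's spike positions (cm; circular track, 1D), and field area in bins
(rectangular track), which the model matches with the product
`sigma_x * sigma_y` of the per-axis uncertainties. Stds are population
(divide-by-n) estimators throughout. Field segmentation for rate maps uses
contiguous bins above 20% of the field peak (configurable), and fields
whose spike clouds have |skewness| > 1 on any axis are flagged as
asymmetric and excluded from Gaussian fitting.

## Fitting

`gamma` is fitted by least squares on the observed sizes. Because the
model has a single scalar parameter, the coordinate-descent fit degenerates
to a golden-section line search on the bracket [1e-4, 10] with bracket
tolerance 1e-8 — deterministic and derivative-free. The
"fraction of fields between the bound curves" statistic (near-wall trajectory at a
configurable 1 cm offset vs. the midline trajectory) is reported as a
separate statistic, not the objective.

The subset extension scores every non-empty mask over the N = objects +
barrier observations (guard: N <= 20). With `alpha = 0`, `gamma` only
scales the profile amplitude, so both profile and data are z-scored before
comparison and the enumeration is exact in the mask; adjusted R^2 uses
p = N + 1 parameters. Positions that coincide with a used object have zero
predicted uncertainty; sampled profiles clip such degenerate values at a
1e-6 cm floor so z-scoring stays finite.

Rate-map Gaussian fits use `scipy.optimize.least_squares` on a separable
2D Gaussian with a uniform baseline term (amplitude is peak rate above
baseline, so adding a constant moves only the baseline). Cross-environment
prediction computes a per-field `gamma` as the mean of the four per-axis
inversions of the fused-wall formula in the two source environments,
relocates the centroid by preserving its relative position (x/L, y/W), and
predicts the target-environment stds from its wall distances; amplitude
and baseline of the predicted map are fitted linearly because firing-rate
amplitude is not a spatial quantity. Chi-square goodness-of-fit tests use
equal-probability bins, k = max(8, n // 5), normal parameters estimated
from the data, k - 3 degrees of freedom.

## Spiking model

The neuronal demonstration is a current-based leaky integrate-and-fire
place cell with exponential synapses, Euler-integrated at 0.1 ms, driven
by Poisson spike trains whose rates follow Gaussian spatial tuning curves
along a simulated trajectory. Multiplication of the input rate profiles —
what Bayesian fusion requires — is achieved by coincidence detection: the
rest-to-threshold gap (16 mV) exceeds a single PSP (10 mV), so only
near-coincident spikes from *distinct* inputs fire the cell.

Two mechanisms protect that "distinct inputs" requirement, and both were
necessary: synapses are saturating (a spike resets its synapse's trace to
the unit level instead of summing), and input trains carry a 15 ms dead
time (spatially tuned afferents at these rates do not fire arbitrarily
short interspike intervals). Without them, successive spikes from one
input sum across the membrane window, threshold crossings track the sum of
squared input rates, and the output field collapses onto the addition
regime (we measured the read-out mean landing at the rate-sum mean instead
of the product mean). Default membrane parameters are tau_m = 10 ms,
tau_s = 3 ms, V_rest = V_reset = -70 mV, V_thresh = -54 mV, PSP amplitude
10 mV, membrane-noise std 1.5 mV — effective in-vivo membrane constants
are short under synaptic bombardment, and these values put the cell in the
fluctuation-driven coincidence regime (single-input leak is ~0 spikes per
80 s run).

The coincidence window is tied to the membrane: a PSP of amplitude A
stays within the noise amplitude sigma_V of its peak for

    delta_t = tau_m * ln(A / (A - sigma_V)),

about 2.7 ms at the defaults — the order of magnitude of the 5-10 ms
coincidence windows measured in CA1 in vitro. This operational form is the
package's own derivation (the window widens with noise and tightens with
larger PSPs or faster membranes); it discretizes the binary-window
coincidence rule, the spikes-as-posterior-samples read-outs, and the
output refractory period. The posterior read-out maps output spike times
to positions and iteratively trims beyond 3 running stds (at most 5
passes) before taking mean and std; 3-sigma trimming is the package's
substitute for an unspecified noise filter. The multiplication error is
the absolute difference between that mean and the exact Gaussian-product
mean, averaged over seeded repetitions; the error surface sweeps it over
(tau_m, V_thresh) grids, with NaN marking silent settings. All randomness
descends from one master seed via `numpy.random.SeedSequence` spawning.

## Synthetic data

The generators produce the statistical structure the analyses assume —
nothing more. Sizes carry mean-one multiplicative lognormal noise
(log-std `sqrt(log(1 + cv^2))`), chosen because sizes are positive and
their spread grows with magnitude; the default coefficient of variation is
0.1 with 100 cells per dataset, the regime in which the recovery tests
require the Weber factor back within 10% in at least 95% of 100
replicates (at zero noise, recovery is exact to 1e-6 and the generating
mask is recovered exactly). Default `gamma_true` is 0.2, a plausible
Weber fraction for rodent distance judgements. Open-field rate maps are
sampled on 1.9 cm bins with optional Poisson count noise under uniform
occupancy. Trajectories are constant-speed triangle waves (back-and-forth
runs, or barrier-bounded lap alternation on the circular track).

What the generators do *not* emulate: theta modulation, speed-dependent
firing, realistic foraging paths, non-uniform occupancy, skewed fields, or
cross-cell correlations. Passing recovery tests therefore shows the
pipeline is self-consistent and well-calibrated under the model's own
assumptions, not that real recordings satisfy those assumptions.

## Problem sizes

Test and reproduction runs use desk-scale sizes chosen as good
signal-to-noise points for each check: 100 replicates x 100 fields for
recovery, 0.25 cm profile grids, 30 repetitions x 80 s simulations for the
spiking read-outs, and 60 s runs for the regime comparison.

## Known limitations

The subset enumeration is exponential and guarded at 20 observations.
The 2D covariance path rejects exactly-zero distances rather than
returning a rank-one degenerate posterior. The spiking demonstration uses
two pooled inputs, not a population, and its input dead time slightly
thins high-rate stretches of the Poisson trains (a bias of order
rate x dead time that compresses the effective tuning curves). Printed
per-animal fit statistics from the original recordings are not
reproducible here because those recordings are not deposited; all
quantitative checks run against the synthetic generators instead.
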