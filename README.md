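# placefields

Bayesian cue-integration models of hippocampal place-field size.

Hippocampal place cells fire at specific locations; the size of a cell's
firing field can be read as the animal's location *uncertainty* at that
spot. This package implements a model in which that uncertainty is the
result of statistically optimal (Bayesian) fusion of distance observations
to boundaries, objects and obstacles, where the noise of each distance
observation grows linearly with the distance itself (Weber-law scaling).
It is aimed at computational neuroscientists who want to predict and fit
place-field size profiles from environment geometry, and to explore how a
spiking neuron could carry out the same inference by coincidence detection.

## The model

The location belief is Gaussian. An observation of a boundary or object at
distance $d_j$ contributes a Gaussian likelihood with standard deviation
$\sigma_o = \gamma d_j$ ($\gamma$: the Weber factor, the single free
parameter). Fusing a path-integration prior of precision $\alpha$ with the
observations multiplies Gaussians — precisions add — so the posterior
uncertainty at a location is

$$\sigma = \Big(\alpha + \beta \sum_j \delta_j / d_j^2\Big)^{-1/2},
\qquad \beta = 1/\gamma^2 ,$$

with binary indicators $\delta_j$ selecting which observations a cell
actually uses (subset extension). In 2D the same accumulation runs on the
precision matrix $\alpha I + \sum_j n_j n_j^\top/(\gamma d_j)^2$ with $n_j$
the observation's direction. Under the hypothesis that field size tracks
uncertainty, $\sigma$ evaluated over an environment predicts the field-size
profile; $\gamma$ is fitted by least squares (golden-section line search),
subsets by exhaustive enumeration of all $2^N - 1$ masks, and fits are
scored with $R^2$, adjusted $R^2$, Pearson's $r$ and chi-square
goodness-of-fit tests.

The spiking module demonstrates the same computation neuronally: a leaky
integrate-and-fire place cell receives Poisson spike trains from a wide
"grid cell" prior field and a narrow "border cell" observation field; with
a spike threshold that only coincident inputs can cross, the output firing
field approximates the *product* of the input tuning curves — the Bayesian
posterior — rather than their sum.

## Worked example

```python
from placefields import fit_gamma, fit_subset
from placefields.synthetic import (SyntheticSpec, default_circular_track,
                                   fields_from_table, gen_circular_track)

track = default_circular_track()   # 106.7 cm diameter, 15 cm wide, 8 objects + barrier
spec = SyntheticSpec(gamma_true=0.2, noise_cv=0.1, n_cells=100, seed=1)
fields, spikes = gen_circular_track(spec)

res = fit_gamma(fields_from_table(fields), track)
print(f"gamma = {res.params.gamma:.4f}, R^2 = {res.r2:.3f}")
```

prints

```
gamma = 0.1981, R^2 = 0.954
```

i.e. the Weber factor is recovered within 1% from 100 noisy synthetic
fields, and the single-parameter model explains 95% of the size variance.
The spiking demonstration:

```python
from placefields.demo import run_demo
out = run_demo(seed=1, reps=30)
print(f"posterior mean {out['posterior_mean_cm']:.1f} cm "
      f"(exact product mean {out['exact_mean_cm']:.1f} cm), "
      f"std {out['posterior_std_cm']:.1f} cm, peak rate {out['peak_rate_hz']:.1f} Hz")
```

prints

```
posterior mean 54.1 cm (exact product mean 54.4 cm), std 5.6 cm, peak rate 2.5 Hz
```

— the simulated cell's field sits between the prior field (40 cm, sigma
12 cm) and the observation field (58 cm, sigma 6 cm), closer to the
narrower, more reliable input, with a spread below the narrower input's,
and fires at CA1-typical rates.

## Command line

Reproducible runs are driven by JSON/YAML configs through the
`placefields` console script, one seed per run:

```bash
placefields generate --config gen.json --seed 11 --out data/
placefields fit-gamma --config fit.json --seed 11 --out fit/ --verbose
```

Subcommands: `generate`, `fit-gamma`, `fit-subset`, `predict-crossenv`,
`simulate-spiking`, `sweep-error`, `report`. Environment configs use cm
throughout, e.g. `{"type": "circular_track", "diameter_cm": 106.7,
"track_width_cm": 15, "barrier": 0, "objects": [22.0, 58.5, ...]}`.

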