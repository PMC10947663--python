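# bdmix

**Deconvolution of tumor subpopulation structure from bulk drug-screen cell
counts, using linear birth–death process mixtures.**

High-throughput drug screens report total cell counts of a tumor sample
over time, dose and replicate wells. Real tumors are mixtures: a mostly
drug-sensitive population can hide a small resistant clone that drives
relapse, and the bulk dose-response curve reflects neither clone
faithfully. bdmix infers, from bulk counts alone, how many subpopulations
are present, their initial proportions, their birth and death rates, and
each clone's dose–response — in particular its GR50, the dose producing
half the drug's maximal effect on the death rate. It is aimed at
quantitative biologists and biostatisticians analyzing viability screens
(e.g. Ba/F3 or patient-derived cells under a kinase inhibitor titration).

## Model

Each of S subpopulations is an independent linear birth–death process:
clone *i* divides at rate β_i and dies at rate

    ν_i(d) = ν_i − log H(d; b_i, E_i, m_i),
    H(d; b, E, m) = b + (1 − b)/(1 + (d/E)^m),

so the net growth rate is λ_i(d) = β_i − ν_i + log H_i(d) and
GR50_i = E_i · b_i^{−1/(2m_i)}. Observed counts are the summed clones plus
Gaussian read noise N(0, c²). Two likelihoods match the two ways screens
count cells:

* **endpoint** — destructive assays: every (time, dose) observation is an
  independent culture; each count is Gaussian with mean μ(t, d) and
  variance n σ²(t, d) + c², both in closed form from the branching
  process.
* **livecell** — repeated imaging of the same well: the per-well count
  vector is multivariate Gaussian N(μ(d), nΣ(d) + c²I) with an explicit
  inter-time covariance Σ, so the time correlation becomes information
  rather than nuisance.

The predecessor deterministic-growth model with two fixed noise levels
(**phenopop**) is included for comparison. Fitting is multi-start maximum
likelihood; uncertainty comes from a case bootstrap over replicate wells;
the number of clones is chosen by AIC. An exact simulator (validated
against an event-by-event oracle) generates synthetic screens, and an
energy-distance diagnostic quantifies how good the Gaussian approximation
is at a given seeding density. See `docs/methods.md` for the full account.

## Worked example

Deconvolve a simulated two-clone screen (11 doses × 13 time points × 14
replicate wells, live-cell mode) and bootstrap the confidence intervals —
this is `examples/fit_mixture.py`:

```python
import numpy as np
import bdmix as bm

rng = np.random.default_rng(7)
model = bm.sample_parameters(2, rng)            # hidden truth
design = bm.ExperimentDesign(times=bm.LONG_TIME_GRID,
                             doses=bm.default_dose_grid(),
                             n_replicates=14, mode="livecell")
data = bm.simulate_dataset(model, design, rng)

boot = bm.bootstrap_ci(data, S=2, method="livecell", B=30,
                       config=bm.FitConfig(n_starts=8), rng=1)
```

which prints

```
target      truth  estimate              95% CI
p_0        0.4250    0.4225 [  0.4115,   0.4344]
gr50_0     0.0664    0.0658 [  0.0642,   0.0672]
gr50_1     1.4723    1.4691 [  1.4235,   1.5075]
```

`p_0` is the initial fraction of the drug-sensitive clone (clones are
always reported sensitive-first, i.e. by ascending E); `gr50_0` and
`gr50_1` are the two clones' half-maximal-effect doses in the units of the
dose grid. All three estimates land within a percent or two of the
generating truth, with the resistant GR50 — backed by the larger clone —
the tightest on the log scale.

The other `examples/` scripts each exercise one capability: dose-response
primitives, screen simulation to CSV, AIC model selection, and the
Gaussian-approximation diagnostic.

## Command line

A thin CLI wraps the library for shell use:

```bash
bdmix simulate  --config screen.yaml --out screen.csv --seed 1
bdmix fit       --data screen.csv --method livecell -S 2 --out fit.csv
bdmix bootstrap --data screen.csv --method livecell -S 2 -B 100 --out ci.csv
bdmix select    --data screen.csv -S 1 -S 2 -S 3 --out aic.csv
bdmix diagnose  --config screen.yaml --n-list 10,100,1000 --out scan.csv
```

Datasets are tidy CSV (`time,dose,replicate,count`); every run writes a
`.log` with the seed, config hash and version, so results are reproducible
from the log alone.

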