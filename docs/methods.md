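# Methods

## The model

bdmix treats a bulk tumor cell population as a mixture of `S` independent
subpopulations ("clones"), each a linear birth–death process: a cell of
clone *i* divides at rate β_i ≥ 0 and dies at rate ν_i(d) ≥ 0 per unit
time under drug concentration *d*. Drug action is cytotoxic: the dose
raises the death rate through a three-parameter Hill curve,

    H(d; b, E, m) = b + (1 − b) / (1 + (d/E)^m),
    ν_i(d) = ν_i − log H_i(d),        λ_i(d) = β_i − ν_i(d),

so λ_i(d), the net growth rate, falls from β_i − ν_i at d = 0 toward
β_i − ν_i + log b_i at saturating dose. The quantity −log b_i is the
maximal drug effect on the death rate, and the **GR50** dose — at which
half that maximal effect is realized — has the closed form
GR50 = E · b^{−1/(2m)} (the solution of −log H(d) = −log(b)/2, i.e.
H = √b; the root-finding definition is what the tests treat as
authoritative, the closed form is checked against it). GR50 is always
above E and is reported in whatever units the input doses use; the package
is unit-agnostic.

A screen supplies total counts x_{t,d,r} on a time grid (starting at the
known seeding time t = 0 with count n), a dose grid, and N_R replicate
wells. Only the total across clones is observed — deconvolving the clone
structure from that bulk signal is the point of the method.

### Moments and the Gaussian approximation

For one clone started from n_p cells,

    E X(t)   = n_p e^{λt},
    Var X(t) = n_p (β + ν(d))/λ · (e^{2λt} − e^{λt}),

with the critical-case limit n_p (β + ν) t taken when |λt| < 1e−8 (a
second-order series switch; moments are continuous across the branch to
< 1e−6 relative error, which is tested). Clones are independent, so
mixture moments add.

For live-cell imaging the same well is observed repeatedly and counts are
correlated in time. The centered, 1/√n-scaled total count on a grid
0 < t_1 < … < t_N converges, as n → ∞, to a zero-mean Gaussian vector
with covariance

    Σ_{ij} = Σ_{ℓ ≤ min(i,j)} Σ_k p_k e^{λ_k(t_i − t_ℓ)} e^{λ_k(t_j − t_ℓ)}
             e^{λ_k t_{ℓ−1}} σ_k²(t_ℓ − t_{ℓ−1}),

where σ_k²(τ) is the per-cell variance factor above. The diagonal of Σ
telescopes exactly back to the marginal variances — an algebraic identity
the test suite enforces at 1e−10 on a thousand random models, and the
reason the third exponential factor must carry t_{ℓ−1} rather than t_ℓ.
The t = 0 observation is deterministic (known n), carries zero variance,
and is excluded from every covariance matrix and likelihood.

### Likelihoods

Observation noise is i.i.d. additive Gaussian N(0, c²) per positive time
point. Doses and replicates are independent throughout. Three likelihoods
are implemented, all as log-densities to avoid underflow at large counts:

* **endpoint** — destructive counting: each (t, d) observation is an
  independent culture, Gaussian with mean μ(t, d) and variance
  n σ²(t, d) + c² (variance floored at 1e−12).
* **livecell** — repeated imaging of the same well: the per-well time
  vector is multivariate Gaussian with mean μ(d) and covariance
  n Σ(d) + c² I, evaluated by (batched) Cholesky factorization. On the
  rare ill-conditioned parameter points met during optimization, the
  factorization escalates a diagonal jitter from 1e−10 × mean diagonal by
  factors of ten, at most three times, before raising.
* **phenopop** — the deterministic-growth predecessor: exponential clone
  growth at rate α_i + log H_i(d) plus Gaussian noise with two fixed
  variance levels, σ_H² at late times and low doses (t ≥ T_L, d ≤ D_L)
  and σ_L² otherwise. T_L and D_L are treated as known and default to the
  medians of the time and dose grids; their exact values have little
  influence, which is why they are not estimated.

The endpoint likelihood is exactly the live-cell likelihood with the
off-diagonal covariance entries removed (tested to 1e−9), which is the
cleanest statement of what the live-cell model adds: the information in
the time correlation.

The exact path likelihood of the total count (a non-Markovian sum of
Markov clones) is computationally infeasible at screen scale; a truncated
forward-summation version exists in the test suite as an oracle for tiny
instances. One empirical caveat found while testing it: the Gaussian
log-density converges to the exact one as n grows only when the read
noise c is at least about one cell — for much smaller c the exact smoothed
density keeps a local lattice factor (counts are integers) that no
continuous Gaussian can track, so the oracle comparison is run at c = 1.

## Simulation

The simulator is exact, not Euler-style. Over an interval dt a single
ancestor's descendant count follows the classical linear birth–death
transition law: extinct with probability α = ν(g−1)/(βg−ν) (g = e^{λdt}),
else geometric with ratio γ = β(g−1)/(βg−ν); for many ancestors this
becomes Binomial survivors plus a negative-binomial excess, drawn in one
vectorized step. The critical case β = ν uses α = γ = βdt/(1+βdt), and
pure death reduces to binomial thinning. The sampler is validated against
an event-by-event (Gillespie) oracle by a KS battery across supercritical,
subcritical, critical and pure-death regimes.

End-point mode re-simulates each observation time independently from t = 0
(matching the independence the endpoint likelihood assumes); live-cell
mode steps one population through the grid increments. Initial clone
counts are round(n·p_i) with largest-remainder correction so they sum to
n exactly. No noise is added at t = 0.

### Synthetic study conditions

`sample_parameters` draws generating models uniformly from the default
ranges: sensitive fraction p_s ∈ [0.3, 0.5] (resistant = complement),
β ∈ [0, 1], ν ∈ [max(0, β − 0.1), β], b ∈ [0.8, 0.9], m ∈ [1.5, 5],
E_s ∈ [0.05, 0.1], E_r ∈ [0.5, 2.5], c ∈ [0, 10], n = 1000. The
three-clone variant uses p_s, p_m ∈ [0.167, 0.333] and
E ∈ [0.0313, 0.0625] / [0.25, 0.375] / [1.25, 2.5]. The canonical designs
are a long grid t = 0, 3, …, 36 and a short-horizon grid t = 0, 1/3, …, 4;
the default dose grid is 11 log-spaced doses spanning E_s/10 to 10·E_r
(0.005 to 25), with 14 replicates — the dimensions of a typical imatinib
Ba/F3 screen. These are the conditions under which the stochastic
acceptance checks run; they model well-mixed, non-interacting clones with
dose-independent birth rates, no carrying capacity, no phenotype
switching, and exponential division times — passing tests therefore say
nothing about screens where cell–cell interactions or confluence effects
matter.

## Inference

Maximum likelihood by multi-start bounded L-BFGS-B on transformed scales:
log for β, ν, E, m and the noise SDs, logit for b, stick-breaking logits
for the fractions. Default box bounds are wide (β ∈ [1e−3, 1],
ν ∈ [1e−6, 1], b ∈ (0.002, 0.998), E within a factor 10 of the dose-grid
span, m ∈ [0.3, 10], c ∈ [0.01, 0.3n]) and overridable. Starts are Latin
hypercube in a practical sub-box, with the E starts of the S clones
staggered across the dose range on the log scale so the
sensitive-to-resistant ordering is seeded rather than left to chance;
20 starts by default (the studies in the test suite use 6–8, which the
recovery results show is ample for S ≤ 2 on standard screens). The best
final log-likelihood wins, ties broken by smaller parameter norm. After
fitting, clones are relabeled by ascending E, so index 0 is always the
most drug-sensitive; this resolves label switching.

Free-parameter counts for information criteria: the birth–death mixture
has 6S (five shape parameters per clone, S − 1 free fractions, one noise
SD); the two-level-noise growth model has 5S + 1. AIC = −2 log L + 2|θ|,
lower preferred; BIC is reported alongside. This counting is a
documented convention, configurable in the sense that the raw
log-likelihoods are always exposed.

Uncertainty: nonparametric **case bootstrap** — whole replicate
trajectories resampled with replacement within each dose, preserving the
within-well time correlation. Each resample is refit from the point
estimate (warm start) plus a few fresh Latin-hypercube starts (default 3,
capped at 150 iterations each): resampled likelihood surfaces are
multimodal often enough that warm-only refits visibly understate the
bootstrap spread, so the extra starts are not optional polish but part of
mimicking the multi-start estimator on each resample. Percentile
intervals at the requested level; the run fails if more than 20% of
refits error. A single-resample bootstrap degenerates to a point, as it
should.

The optimizer's inner loop evaluates the likelihoods through numba-
compiled kernels operating on plain parameter arrays (`bdmix._fast`);
these are asserted equal to the reference numpy implementations at 1e-9
in the test suite, and the package falls back to the numpy path when
numba is absent. Reported log-likelihoods, AIC values and per-dose
decompositions always come from the reference path.

Error metrics for recovery studies: the absolute log ratio
|log(x/x̂)| — symmetric on the log scale, natural for dose-like
quantities — and the relative error |x − x̂|/|x|.

## Diagnostics

The empirical energy distance between samples {X_i} and {Y_j},

    D_E = (2/km) ΣΣ ‖X_i − Y_j‖ − (1/k²) ΣΣ ‖X_i − X_j‖ − (1/m²) ΣΣ ‖Y_i − Y_j‖,

is computed with chunked pairwise-distance accumulation; samples larger
than 2·10⁴ are subsampled (the computation is O((k+m)²)).
`gaussian_approx_scan` simulates ensembles of live-cell count vectors at a
list of initial counts and measures D_E to matched draws from
N(μ, nΣ + c²I), repeated over several datasets for spread; the median
distance decreasing in n is the practical certificate that the Gaussian
likelihood is safe at a given seeding density. By default the scan adds no
read noise (c = 0 isolates the branching-process error from the trivially
Gaussian noise term); c is taken from the model if nonzero.

## Numerical conventions

* Hill at d = 0 returns exactly 1 (no 0^m evaluation).
* λ → 0 handled by series branches with switch at |λt| < 1e−8.
* Dataset CSVs are tidy (time, dose, replicate, count) and round-trip
  bitwise; reading uses correctly-rounded float parsing.
* Counts are stored as floats — Gaussian read noise makes observations
  non-integer; t = 0 rows must all equal the integer seeding count.
* All randomness flows through `numpy.random.Generator` objects; a seed
  plus a config reproduces any simulation bit-for-bit.

## Problem sizes used in the shipped studies

The test suite's stochastic studies are scaled to desk size as the
package's own defaults: 10 synthetic screens with B = 50 bootstrap
resamples for the coverage study, 5 screens for the recovery / CI-width /
short-horizon comparisons, 10⁴ replicates per energy-distance sample with
3 dataset repeats, and 10⁴ draws per side in the simulator KS battery.
Larger versions (e.g. 30 screens × B = 100, 10⁵ replicates) run with the
same code by raising the corresponding arguments.

## Known limitations

* Cytostatic action (dose-dependent birth rate) is not modeled; the Hill
  effect enters the death rate only.
* The live-cell covariance assumes the time grid and clone fractions do
  not depend on n, and clone independence rules out competition or
  switching; screens near confluence violate this.
* The m (steepness) parameter is weakly identified and contributes most
  of the optimization's non-convexity; its estimates are the least
  reliable part of a fit.
* Percentile bootstrap CIs inherit the usual small-B roughness; B = 100
  is a sensible floor for reported intervals. They also cannot absorb
  dataset-level bias of the maximum-likelihood point estimate: when the
  global optimum for a particular dataset sits further from the
  generating truth than the bootstrap spread (which the coverage study in
  the test suite shows does happen, particularly for the sensitive
  clone's GR50), the interval misses even though the fit is correct as an
  MLE. Joint coverage of several targets at once is correspondingly lower
  than per-target coverage.
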