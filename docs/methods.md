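# Methods

`contextddm` models two-interval duration discrimination — "which of two
successively presented stimuli lasted longer?" — with a family of diffusion
decision models in which the stimulus-comparison stage of classical
psychophysical models (internal-reference updating, sensation weighting)
drives the trial-level drift rate and starting point of the decision
process.

## The model family

On trial *n* a standard (fixed, default 500 ms) and a comparison duration
are presented in one of two orders (`sc` = standard first, `cs` =
comparison first).  Stimulus magnitudes enter all equations as physical
durations centered on the standard, X := dur − standard, in ms.

The decision is a Wiener diffusion between absorbing boundaries 0 and *a*
with diffusion coefficient fixed at 1, relative starting point z_n, drift
v_n (evidence/s) and non-decision time τ (s).  The upper boundary is the
"first stimulus longer" response.  All variants share the drift rule

    v_n = v0 + v1·ref_n + v2·X2_n,        ref_n ∈ {X1_n, I_n},

where the internal reference I_n is a geometrically weighted average of
first-interval magnitudes, updated every trial,

    I_n = g·I_{n−1} + (1−g)·X1_n,          0 ≤ g ≤ 1,

and three structural switches generate the seven variants: (1) replace
X1 by I (reference updating), (2) free v2 instead of the tied difference
weight v2 ≡ −v1 (separate sensation weights), and (3) let the starting
point track the first interval, z_n = z0 + z1·ref_n.  The canonical
numbering and free individual-level parameter counts are

| # | reference | separate weights | z regression | free params |
|---|-----------|------------------|--------------|-------------|
| 1 | –         | –                | –            | 5 |
| 2 | yes       | –                | –            | 6 |
| 3 | –         | yes              | –            | 6 |
| 4 | yes       | yes              | –            | 7 |
| 5 | yes       | –                | yes          | 7 |
| 6 | –         | yes              | yes          | 7 |
| 7 | yes       | yes              | yes          | 8 |

Setting g = 0 collapses the reference to the current first stimulus, so
variant 2 reduces to variant 1, 4 to 3, and 7 (with z1 = 0) to 4; these
reduction identities are enforced exactly in the test suite.

Because durations enter in ms and time in the diffusion runs in seconds,
v1, v2 and z1 are per-ms slopes.  Under the unit diffusion coefficient a
drift slope v1 ≈ 0.01/ms means a 100 ms duration difference produces a
drift of ≈ 1 evidence unit per second.  The 0.1 diffusion-coefficient
convention that also circulates in this literature rescales a, v and z1 by
10; parameter values are not portable across conventions.

**Reference initialization.** The reference starts at the first trial's
own first stimulus (I_1 = X1_1).  This makes trial 1 identical across
reference and non-reference variants and adds no free parameter.
Alternatives (start at the standard, or estimate the start) differ only in
a vanishing early-session transient.  Reference state is never carried
across participants or sessions.

**Sensation-weighting absorption.** The sensation-weighting comparison
D = [w1·X1 + (1−w1)R1] − [w2·X2 + (1−w2)R2] + b enters through its drift-
regression form: the constant reference levels R1, R2 and the bias b are
absorbed into the drift intercept v0, and the weights map as w1 ≙ v1,
w2 ≙ −v2 (the second stimulus is subtracted, so fitted v2 is negative when
both weights are positive).  R1 and R2 are therefore not separate free
quantities.

**Starting-point violations.** z_n is never clipped; a trial whose
computed starting point leaves (0, 1) contributes −∞ log-likelihood (the
sampler simply avoids that region).  Clipping would silently distort the
posterior.

## Wiener first-passage machinery

The defective first-passage-time density is evaluated by the classic dual
series: a small-time (image method) and a large-time (spectral) expansion
of the standardized density, switching to whichever needs fewer terms for
the requested truncation error (default 1e−7 in density units; the
standardized tolerance is rescaled by the drift/boundary factor so the
bound holds on the final density).  Reflection (v, z) → (−v, 1−z) gives
the other boundary.  Upper-boundary absorption probabilities use the
closed form (1 − e^{−2vaz})/(1 − e^{−2va}), computed via `expm1` with the
z limit taken below |2va| < 1e−9.

Simulation uses Euler–Maruyama with dt = 1e−4 s (configurable) and a
30 s time cap; non-absorbed paths are censored, dropped with a warning and
counted in dataset provenance.  Because a discretely observed path misses
boundary crossings between grid points, the naive scheme behaves like a
diffusion with boundaries widened by ≈ 0.5826·σ√dt on each side — enough
to shift choice probabilities by several Monte-Carlo standard errors at
n = 10^5.  The simulator therefore applies the standard continuity
correction (absorption tested against boundaries shifted inward by that
amount), which removes the O(√dt) bias; the test suite verifies both that
simulated (choice, RT) pairs match the integrated density (defective-CDF
Kolmogorov–Smirnov distance < 0.01 over a 27-point parameter grid at
n = 5·10^4 per setting) and that halving dt leaves the outcome unchanged.
Path state is float32: its rounding (~1e−7 of the boundary scale) is far
below the discretization error at any sensible dt.

## Synthetic experiments

The generator emulates the classical auditory paradigm: standard 500 ms,
nine comparison levels equally spaced over 400–600 ms (the exact level set
of the original experiments is not published; the list is a configuration
field), both orders randomly intermixed with exact per-cell balance, ISI
1000 ms (metadata only).  Cohorts are drawn around group-level values with
Gaussian spread on the unconstrained scales (log for a and τ, logit for z0
and g), matching the hierarchical model's generative assumptions.  Unless
a test states otherwise, group means are set to the published group-level
posterior modes of the auditory experiment (a = 1.4736, τ = 0.1456,
z0 = 0.4411, z1 = 0.0007, v0 = 0.0437, v1 = 0.0096, v2 = −0.0198) with
modest spreads (0.15–0.2 on log/logit scales; 0.002–0.004 on the per-ms
slopes).

What the generator does *not* emulate: fast-guess contamination (added
explicitly where screening is tested), attention lapses, session/block
effects, RT-measurement artifacts of responding before second-stimulus
offset, and any perceptual clock nonlinearity — simulated "durations" are
the physical values.  Passing recovery and calibration tests therefore
shows the estimation machinery is correct under the model's own
assumptions, not that the model is true of real data.

## Contaminant screening

Fast guesses are located per participant with an EWMA control chart:
trials sorted by ascending RT, an exponentially weighted moving average of
response correctness (chosen-the-longer-stimulus; equal-duration trials
are skipped) initialized at 0.5, compared against the upper control limit
0.5 + L·σ_t with the standard EWMA chart σ_t under Bernoulli(0.5)
variance.  The cutoff is the RT from which the chart stays above the limit
for the rest of the sequence (0 if it holds from the first trial, ∞ if
never).  Defaults λ = 0.01, L = 1.5 — the conventional RT-screening
values; both are configuration keys recorded in every report.  With L > 1
the chart cannot clear the limit on the very first trials, so even a
perfect session nominally flags its 2–3 fastest responses; this startup
artifact is far below any exclusion threshold.  Participants whose fast
guesses exceed 10% of **all** their responses (strictly greater;
equal-duration trials count in the denominator) are excluded entirely;
remaining responses faster than 100 ms are removed.

## Hierarchical estimation

Each individual-level parameter is sampled on an unconstrained scale with
a Gaussian hyper-distribution (mean and sd estimated); hyper-means get
weakly-informative normal priors — N(0,1) on log a, N(−1.5,1) on log τ,
N(0,1) on logit z0 and logit g, N(0,2) on v0, N(0,0.1) on the per-ms
slopes — and hyper-sds half-normal(0.5) priors.  These defaults are
configuration (`PriorSpec`), not constants, and every fit records the
priors it used.  The original study's prior table is not available in the
text this package was built from; the defaults above are the package's own
choice of weakly-informative priors on these scales.

Sampling is blocked Metropolis-within-Gibbs, exploiting the conditional
independence of participants given the hyper-parameters:

* each participant's block is updated by directional slice sampling, with
  directions drawn from a per-block proposal covariance adapted during
  warm-up (slice sampling needs no step-size acceptance tuning);
* hyper-means are updated by their exact conjugate Gaussian conditional,
  hyper-sds by univariate slice sampling on the log scale;
* because the centered parametrization mixes slowly along the direction
  where a group mean and all its individual values shift together,
  interweaved (ancillarity–sufficiency) group moves re-update each
  hyper-mean and hyper-sd holding the individual deviations fixed —
  cheap Metropolis versions every sweep, self-tuning slice versions every
  third sweep.

Any sampler meeting the convergence contract would be acceptable; this
design was chosen because its per-sweep cost is linear in participants and
trials and it needs no gradients of the Wiener density.  Defaults mirror
common practice for this model class: 4 chains × 2000 iterations, first
50% discarded as warm-up, and a fit is `converged` only when every
parameter's split R-hat (classic between/within comparison on half-
chains; 1.0 by convention for zero-variance chains) is below 1.01.
Initialization draws from priors shrunk toward their means, with the
non-decision time capped below half the fastest RT and progressively
stronger shrinkage on retries until the density is finite.  With a single
participant the hierarchy is disabled (hyper-mean priors act directly as
individual priors) with a warning.

Summaries: the 95% HDI is the shortest contiguous interval containing
⌈0.95·n⌉ sorted draws; the posterior mode is the argmax of a Gaussian KDE
(normal-reference bandwidth, 512-point grid, ties toward the lower value).
Group-level point values reported on the natural scale are transforms of
the hyper-mean (e.g. exp(μ) for log-scale parameters — the group median of
the implied individual distribution).

## Model comparison

Out-of-sample fit is estimated by Pareto-smoothed importance-sampling
leave-one-out cross-validation on the per-draw, per-trial log-likelihood
matrix (reference state recomputed per draw).  Raw importance ratios
1/p(y_i|θ_s) are stabilized by a generalized-Pareto fit to the largest
min(0.2·S, 3√S) ratios with weights truncated at S^{3/4}·mean; trials with
shape diagnostic k > 0.7 are reported, never dropped.  elpd = Σ pointwise,
SE = √(n·var(pointwise)); model differences are taken against the best
model with **paired** SEs from the pointwise contribution differences.
The suite checks the estimator against exact brute-force leave-one-out
refits (40 trials, every refit a full MCMC run) and requires agreement
within one SE.

## Psychometrics

Per participant, a logistic regression predicts P("comparison longer")
from the centered comparison duration, the presentation order, and their
interaction; per-order intercepts β0 and slopes β (logit/ms) follow from
the coefficients.  Maximum likelihood is the default (deterministic); a
maximum-a-posteriori variant under weak zero-mean Gaussian priors is
available and doubles as the fallback under complete separation (detected
as slopes above 0.3 logit/ms — a difference limen under 4 ms — or
intercepts beyond ±30).  Derived quantities:

* PSE = standard − β0/β (50% point),
* DL = (75th − 25th percentile)/2 = ln 3 / β,
* Type A = PSE_sc − PSE_cs,  Type B = DL_sc − DL_cs.

Sign conventions are fixed package-wide: a negative Type B is the
classical pattern (better discrimination when the standard precedes).
The proportional weight difference is computed on weight magnitudes,
(w1 − w2)/(w1 + w2) with w1 = v1 and w2 = −v2; using raw signed
coefficients instead would make the denominator v1 + v2 near-degenerate
(the two coefficients have opposite signs and similar magnitudes), so the
magnitude mapping is the implemented reading.

## Posterior predictive checks

Replicate datasets are generated from draws selected uniformly **without**
replacement over post-warm-up draws (with replacement plus a warning when
more replicates than draws are requested; 500 replicates by default),
each regenerating the full design per participant.  Per design cell
(comparison level × order) the summary reports P("comparison longer"),
the median RT and the 10/30/50/70/90% RT quantiles (pooled across
participants, matching the averaged presentation of such checks;
per-participant summaries are available by summarizing single-participant
datasets), each with the mean over replicates and its 95% HDI across
replicates, next to the identical statistics of the empirical data and a
coverage flag.

## Validation problem sizes

The validation suite (`tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) runs the full pipeline at sizes chosen to keep a
complete run in tens of minutes on one CPU while preserving statistical
power; the statistical bands themselves are not relaxed:

* Wiener core: 27-point grid (a ∈ {0.8, 1.5, 2.5} × v ∈ {−2, 0, 2} ×
  z ∈ {0.3, 0.5, 0.7}), 5·10^4 trials per setting, defective-CDF KS
  < 0.01 (the 95% pure-noise level at this n is ≈ 0.006) and choice
  probabilities within 3 Monte-Carlo SEs.
* Reduction identities: 500 trials, exact equality.
* Hierarchical recovery: 12 participants × 90 trials, 3 seeds, 4 chains ×
  2600 iterations (chain length escalating 1.5× — `fit_until_converged` —
  when the R-hat contract is unmet, as one would in practice); all split
  R-hat < 1.01 and ≥ 6/7 group means inside their 95% HDIs in a majority
  of seeds.  HDI coverage is a calibration
  property and does not depend on cohort size; smaller cohorts simply
  yield wider intervals.
* LOO oracle: 40 trials × 1500 draws against 40 exact refits, within 1 SE.
* Model selection: 4 participants × 162 trials, 5 seeds, variant 6 vs 1.
* Context effects: 21 participants × 720 trials, 5 seeds; negative median
  Type B and r > 0.5 between weight asymmetry and Type B (weight
  asymmetry taken from the generating weights; fitting 21 individual
  posteriors per seed would test the same association at far higher cost).
* Screening: 100 replicates of a 1000-trial fixture (15% fast guesses
  below 250 ms at chance; genuine responses from 300 ms at 90% accuracy
  with a shifted-exponential RT tail), cutoff within [200, 320] ms in
  ≥ 95%.

## Known limitations

* No inter-trial variability parameters (sv, sz, st) — deliberately out of
  scope — and no lapse/contaminant mixture inside the likelihood.
* Random-walk-free but gradient-free: the sampler's cost grows linearly
  with trials and participants, and very large cohorts (hundreds of
  participants) would warrant a gradient-based sampler instead.
* The EWMA chart's startup artifact (see above) makes cutoffs from very
  short sessions unreliable; screening expects a few hundred trials.
* Psychometric fits assume a logistic link without lapse rates;
  participants with near-flat curves yield unstable PSE/DL (surfaced as
  errors, not numbers).
* RT summaries pool across participants within a cell; strong individual
  differences can make pooled quantile bands look wider than any single
  participant's data.
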