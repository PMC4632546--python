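# Methods

## Model

One observation is a gravid female whose brooded eggs were subsampled
and scored in three counting replicates of 100 units each, giving a
fertilized-unit count `y` out of `n = 300` (fertilized eggs plus
developing glochidia count as successes; a record is unusable when the
two egg classes could not be told apart). Counts are binomial with a
logit-linear predictor combining

- nine quadrat-level terms: local adult density (DEN, individuals per
  0.25 m² quadrat), current velocity (VEL, cm/s), water depth (DEP, cm),
  substrate coarseness (SUB, a cover-weighted code in [1, 4] built from
  sand/gravel/cobble/boulder proportions), the three DEN-by-flow
  interactions, distance from the upstream bed edge (LOC, m), and shell
  length (SHELL, mm);
- a bed-replicate intercept built from bed-level covariates: mean bed
  density (P_DEN, the mean of quadrat densities over the replicate's
  records) and catchment area (CAT, km²), their interaction, and a
  normal deviation `omega` per bed-year replicate;
- a normal date-within-year effect `gamma` (each bed is sampled on one
  date; dates are coded nested in year by construction of the label);
- a normal observation-level effect `eps`, the standard overdispersion
  construction for extra-binomial variation.

All eight main covariates are z-scored over female rows with the
sample (n−1) standard deviation; interaction columns are products of the
standardized mains, so main effects are conditional effects at covariate
means. The standardization spec is stored (JSON sidecar) and used to
map prediction axes back to natural units. Missing covariate cells are
rejected rather than imputed. A collinearity screen reports all
pairwise Pearson correlations among the eight mains and passes iff every
|r| < 0.5. Note that P_DEN is the bed mean of DEN, so their
correlation is structurally positive (~0.4–0.5 in study-shaped data);
the screen's threshold is strict.

Priors are vague: every coefficient N(0, variance 100) — "variance"
read literally, sd = 10, not a BUGS-style precision — and each variance
component sigma² Uniform(0, 100) *on the variance scale*. Both
alternatives (precision parameterization, uniform-on-sd) would be easy
to add via `PriorSpec`, but the default follows the printed convention
of the field protocol this package models. The binomial coefficient is
included in the likelihood so reported log-likelihoods are absolute.

`omega` is indexed per bed-year replicate: the intercept is explicitly a
property of the bed in a given year, and a bed resampled in the second
year gets an independent deviation. P_DEN is likewise per replicate
(re-derived from that year's quadrats); CAT is per bed, shared across
years, being a property of the river location.

## Sampler

Adaptive random-walk Metropolis-within-Gibbs over all scalars, BUGS
style, with no gradients:

- each of the 13 fixed effects is updated by a scalar random-walk
  proposal; step sizes adapt toward 44% acceptance during burn-in only
  (Robbins–Monro on the log step with gain 2/(t+20)^0.6) and are frozen
  afterwards, preserving detailed balance for every kept draw;
- one *joint* fixed-effect proposal per scan uses a multivariate normal
  step whose covariance is the running estimate of the burn-in draws
  (classic adaptive Metropolis, scaled by 2.38²/13 and tuned toward 23%
  acceptance, frozen at burn-in's end). Without it, correlated design
  columns (the interactions share their parent mains) mix slowly;
- the latent blocks `eps`, `gamma`, `omega` are updated element-wise in
  vectorized blocks — their elements touch disjoint likelihood rows, so
  simultaneous element-wise accept/reject is exactly a componentwise
  scan — with per-element adapted steps;
- variances are updated on the sigma² scale by random walk with
  reflection at the prior bounds (0, 100);
- ridge moves: hierarchical intercepts trade off against latent-block
  means along likelihood-flat directions, so the scan includes
  likelihood-invariant proposals accepted on the prior ratio alone:
  (alpha_global + d, gamma − d), (alpha_global + d, eps − d), the
  population-level coefficient swaps (fixed_k + d, omega − d·Xp[:, k])
  for the intercept/P_DEN/CAT/interaction columns, and gamma↔omega
  exchanges for bed-date pairs whose groups coincide exactly (in this
  design every first-year bed has its own date, making the two effects
  interchangeable there). These moves are what make the weakly
  identified bed-level coefficients mix (R-hat drops from ~2.5 to
  ~1.02 at the default problem sizes).

Chains start from overdispersed points: coefficients from
N(0, `init_scale`²) with `init_scale = 2.5`, variances Uniform(0.2, 5),
latents from their priors; initialization retries up to 100 times for a
finite log-posterior. A much wider dispersal (e.g. 2× the prior sd)
puts chains at |logit| ≈ 20–40 where the binomial likelihood is flat to
double precision and random-walk chains take very long to return, so the
default is deliberately moderate — still far wider than any posterior
encountered here. Three chains by default; the chain count and the
field-scale run lengths (100 000 iterations, 20 000 burn-in, thin 20,
hence 4 000 kept draws per chain) are the package defaults, while the
experiment batteries use reduced settings (below).

The per-female linear predictor is stored for every kept draw, so
posterior predictive checks reuse the latent effects exactly. Latent
effects themselves are stored as posterior means/sds by default (full
storage is a flag). Everything is reproducible bit-for-bit from the
chain seed (per-chain generators spawned from one seed sequence).

## Diagnostics and summaries

R-hat is the split-chain, rank-normalized potential scale reduction
factor; constant draws define R-hat = 1 (an all-constant parameter has
trivially "converged"); a single chain raises rather than returning a
number. ArviZ supplies effective sample sizes and cross-checks R-hat in
the tests. Summaries report the pooled median, central 95% interval by
empirical percentiles, sign probabilities as draw fractions (a draw at
exactly 0, a measure-zero event, counts as positive), and a significance
flag for intervals excluding zero.

The Bayesian p-value compares, draw by draw, a discrepancy on the
observed counts against the same discrepancy on counts replicated from
that draw's fitted rates; the p-value is the fraction of draws whose
replicate is at least as discrepant. The default discrepancy is the
Pearson chi-square for binomial counts; absolute-residual and deviance
alternatives are built in (the choice is pluggable because no single
statistic is canonical). Fitted rates are clipped at 1e-12 from the
boundary, and draws that touch the clip are counted in the result.

Prediction curves and the four interaction panels condition on the
dataset's empirical 25th/75th percentiles of VEL and DEP (computed in
natural units, standardized through the stored spec), hold all other
covariates at their means (standardized zero) and latent effects at
zero, i.e. they show population-average expectations.

## Synthetic data

The generator emulates the field design: 10 beds (three rivers), four
re-sampled the next year (14 bed-year replicates), 1–12 females per bed
in year one and 4–20 in year two, 91 total; females sit on cross-channel
transects 3–5 m apart with LOC measured from the upstream-most transect.
Covariates are drawn from range-truncated distributions calibrated so
that the *population* moments of the truncated two-level draw (bed
centers plus within-bed spread, integrated by Gauss–Hermite quadrature)
match the published summary table: DEN mean 18.9, sd 18.6 on [0, 79]
(negative-binomial quadrat counts, dispersion 1.4 — mean < sd rules out
Poisson); VEL 16.5 (14.4) on [0.2, 76.5], DEP 29.7 (13.6) on [10, 62],
SUB 2.7 (0.3) on [1.3, 3.3] (truncated normals); CAT 77.6 (63.5) on
[19.1, 252.6] (truncated lognormal, one value per bed); SHELL has no
tabulated sd, so 12 mm was chosen to reproduce the reported 53–114 mm
range around the 78 mm mean. The bed-level density target (18.4, 11.0
on [0.5, 31.8]) is not exactly attainable — no truncated normal on a
31-unit interval carries sd 11 with that mean — so the calibration
weights the mean and accepts the closest sd (~9). A sampling-intensity
factor of 1.09 on the within-bed density mean reflects that sampled
quadrats (where gravid females sit) skew denser than the bed average,
and offsets truncation loss. P_DEN is then *derived* as the mean of the
generated quadrat densities, exactly as the field protocol derives it,
so at small bed sample sizes it inherits sampling noise. A single seed
drives everything, with sub-generators spawned per bed so local changes
do not reshuffle other beds.

Two outcome flavors:

- **regression** — counts drawn from the hierarchical model itself at
  known coefficients. The default truth (modest effects: beta_den 0.8,
  beta_den_x_vel −0.6, weak bed-level terms, sigma²_eps 0.5) is a
  plausible mussel world with a clear but not overwhelming local Allee
  effect; it is *not* an estimate of any real dataset.
- **mechanistic** — no logit-linear structure anywhere: males broadcast
  sperm whose exposure at distance d is exp(−d/lambda), summed over
  males (the female's own-quadrat males at distance zero, plus a
  background male field on a 0.5 m grid with four lateral quadrat
  columns, half of adults male); fertilization probability saturates as
  E/(E + K). The decay length lambda = lambda0 (1 + a·VEL/16.5)
  (1 + b·DEP/29.7) grows with velocity and depth, so fast or deep water
  homogenizes exposure.

The mechanistic constants are deliberately invented and exposed in the
configuration. The defaults (lambda0 = 0.02 m, a = 10, b = 1, K = 15,
flow variance 80% between beds, bed-density spread sd 1.0) were fixed by
a brute-force oversampled check and then frozen: they are the regime in
which the Allee effect is *cryptic* — bed mean density and bed mean
fertilization essentially uncorrelated (|r| < 0.2 at 30 beds × 100
females) while local density and fertilization correlate strongly
(r > 0.4) in the slowest-velocity quartile. Two modelling choices make
this regime possible and are worth stating plainly: sperm transport at
slow flow is of quadrat scale (centimetres to decimetres, consistent
with steep fertilization–distance declines in broadcast spawners), so a
female's own-quadrat males dominate her exposure; and adult aggregation
is micro-scale patchiness within beds of broadly similar overall
density, so bed means carry little density signal while flow differences
between beds dominate them. With bed-scale density contrasts as large
as the between-bed flow contrasts, no parameterization of this scene
keeps the bed-level correlation near zero — the masking *is* the
phenomenon being generated.

What the generator does not emulate: hydrodynamic realism (turbulence,
plume anisotropy, discharge-mediated dilution), host-fish dynamics,
multi-year demography, measurement error in covariates, and real
spatial covariance between flow and density. Passing tests therefore
show that the inference machinery recovers truth under the stated
sampling design and noise model — not that any real population behaves
this way.

## Experiment batteries and problem sizes

The packaged experiments (also used by `scripts/acceptance.py`) run at
sizes chosen for single-CPU minutes:

- *recovery*: 8 beds × 300 females, chains 20 000/5 000/10 × 3, five
  seeds; scored by max split R-hat over the 13 fixed effects and by 95%
  interval coverage of the truth (nominally ≥ 12/13 per seed, with one
  seed in five allowed to miss that bar — at 95% nominal coverage two
  simultaneous misses in thirteen intervals are expected occasionally);
- *posterior predictive calibration*: 20 simulate-fit replicates at
  study size (91 females), chains 6 000/1 500/5 × 3; the p-value should
  avoid (0, 0.05] and [0.95, 1) in ≥ 18/20 replicates, and the key
  effect intervals should cover truth in ≥ 85%;
- *conjugate limit*: one female, covariates and latents stripped; the
  N(0, 100) logit prior is locally flat with Jacobian 1/(p(1−p)), so
  the rate posterior is Beta(y, n−y) to high accuracy and sampled
  2.5/50/97.5 percentiles must match within 0.005;
- *cryptic fit*: one study-size mechanistic dataset, chains
  20 000/5 000/10 × 3; scored by P(beta_den > 0), P(beta_den_x_vel < 0)
  and whether the bed-density coefficient's interval includes zero.

## Numerical choices

- Binomial log-likelihood via log p = eta − log(1+e^eta) and
  log(1−p) = −log(1+e^eta) (logaddexp), finite for any representable
  eta; rates are clipped only inside posterior predictive discrepancies.
- Sample sd uses the n−1 denominator throughout.
- Step-size logs are clamped to [log 1e-5, log 50].
- The truncated-moment calibrations solve bounded least-squares
  problems; infeasible targets return the closest achievable moments
  rather than failing.
- Degenerate inputs: constant covariates, missing cells, inconsistent
  count protocols, variance targets outside the prior support, empty
  draw sets and single-chain R-hat all raise typed errors.

## Known limitations

- The bed-level coefficients rest on 14 replicates; their posteriors
  are wide and prior-influenced (Uniform(0,100) on a variance is vague
  but not innocuous at 8–14 groups). This mirrors the design being
  emulated rather than a removable flaw.
- In the first-year design each bed is sampled on its own date, so the
  date and bed effects are exchangeable there; only their sum is
  identified, and the two variances separate only through the prior and
  the second-year beds that share dates.
- The sampler is random-walk based; posteriors with strong curvature
  would mix better under gradient-based methods, which are intentionally
  out of scope here.
- Real fertilization data are not shipped or reproduced: all empirical
  statements in this repository are about synthetic data with known
  truth.
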