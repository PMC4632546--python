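# allee — hierarchical Bayesian analysis of density-dependent fertilization in stream mussels

Sessile river mussels fertilize by filtering sperm from the water
column, so a female's fertilization success depends on how many males
sit near her and on how the flow spreads their sperm. A decline in
fertilization at low conspecific density is a *component Allee effect* —
and it can be **cryptic**: invisible when densities are compared between
whole mussel beds, or when flow conditions homogenize sperm around the
females, yet real at the quadrat scale under slow, shallow water.

This package implements, as tested reusable code, the statistical
machinery for detecting such a two-scale effect, together with a
synthetic-data generator that reproduces the field sampling design (10
beds in three rivers, four re-sampled the next year, ~91 gravid females
on cross-channel transects, 300 scored egg units per female) so the
whole chain of inference can be validated end to end against known
ground truth.

## The model

For gravid female *i* in bed-year replicate *(j, t)*:

    y_ijt ~ Binomial(300, p_ijt)

    logit(p_ijt) = alpha_jt
                 + b1 DEN + b2 VEL + b3 DEP + b4 SUB
                 + b5 DEN·VEL + b6 DEN·DEP + b7 DEN·SUB
                 + b8 LOC + b9 SHELL
                 + gamma_k(j),t + eps_ijt

    alpha_jt = alpha_global + a1 P_DEN + a2 CAT + a3 P_DEN·CAT + omega_jt

with quadrat-level covariates (local adult density DEN, current velocity
VEL, water depth DEP, substrate coarseness SUB, distance from the
upstream bed edge LOC, shell length SHELL) and bed-level covariates
(mean density P_DEN, catchment area CAT), all standardized before
fitting. `gamma` is a sampling-date-within-year random effect, `eps` an
observation-level overdispersion effect, `omega` a bed-replicate
intercept deviation; each is normal with its own variance. Priors are
vague: N(0, variance 100) on every coefficient, Uniform(0, 100) on each
variance. Inference is adaptive Metropolis-within-Gibbs (see
`docs/methods.md`); fit adequacy is scored by a posterior predictive
Bayesian p-value with a Pearson chi-square discrepancy, convergence by
the split-chain rank-normalized R-hat.

## Layout

- `src/allee/` — the library: `records` (egg counts, substrate index,
  filtering), `design` (standardization, collinearity screen, design
  matrix), `io` (CSV/JSON tables), `model` (log-densities, prediction
  curves), `mcmc` (sampler, R-hat, summaries), `checking` (posterior
  predictive checks, effect tables, panels, pipeline), `synthetic`
  (study-design generator, regression and mechanistic flavors),
  `experiments` (recovery / calibration / conjugate batteries).
- `analysis/01_simulate.py … 04_report.py` — numbered drivers that
  generate the datasets, fit, check and report, writing under `results/`.
- `tests/` — unit, property and end-to-end suites.

## Worked example

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_fit.py --seed 1
python analysis/03_check.py --seed 1
python analysis/04_report.py --seed 1
```

`01_simulate` writes a mechanistic sperm-dilution dataset (91 females,
14 bed-year replicates) in which, by construction, local density drives
fertilization only where sperm transport is short-ranged. At study size
it prints, for seed 1:

```
cryptic contrast at study size: bed-scale r = +0.19, slow-quartile local r = +0.85
```

`02_fit` then recovers the two-scale contrast from the counts alone
(excerpt of the printed summary, seed 1):

```
parameter         median  ci_lo  ci_hi  p_positive  p_negative   rhat
alpha_pden        -0.035 -0.392  0.271       0.403       0.597  1.019
beta_den           0.360  0.211  0.465       0.994       0.006  1.011
beta_den_x_vel    -0.244 -0.363 -0.032       0.021       0.979  1.018
beta_den_x_dep    -0.134 -0.255  0.111       0.048       0.952  1.020
```

The local density effect is credibly positive and its interaction with
current velocity credibly negative (the Allee effect fades in fast
water), the depth interaction is negative with probability 0.95 but its
interval touches zero, and none of the bed-scale terms is
distinguishable from zero — the effect is invisible at the bed scale.
`03_check` prints `Bayesian p-value (pearson_chi2): 0.468`, i.e. no
evidence of misfit, and `04_report` writes the caterpillar plot and the
density-by-flow prediction panels.

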