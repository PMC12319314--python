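# Methods

`chlorotraits` estimates the life-history traits of lytic viruses from
replicate-level assay data, predicts population growth rates from those
traits, and runs panel-level comparative statistics. This note records
the models, the numerical choices, and what the synthetic validation
does and does not demonstrate.

## Life-cycle model and trait definitions

A free virion of a lytic virus such as a chlorovirus encounters host
cells at rate `k*H` (adsorption constant `k`, mL/h; host density `H`,
cells/mL). A fraction `a` of virions is capable of attaching at all; an
attached virion depolarizes the host membrane with probability `d`; a
depolarized cell completes the infection and lyses with probability
`r`, after a lysis time that is normally distributed with mean `mu_l`
and SD `sigma_l` (truncated at zero), releasing `b_r` progeny. Two
composite traits follow by definition: the burst size per depolarized
cell `b_d = r*b_r` and the specific infectivity `s = a*d*r`, the overall
probability that a virion is infectious. Outside the host, infectious
titer decays biphasically: a persistent fraction `p` resists decay
while the remainder is lost at mortality rate `m` (1/h), giving
`S(t) = S0*[p + (1-p)*exp(-m*t)]`.

The attaching fraction `a` is an auxiliary trait: it is what the
plateau of the adsorption curve `V(t) = v0*[(1-a) + a*exp(-k*H*t)]`
identifies, and it makes `s` estimable as a product of per-stage
probabilities. When an assay design saturates adsorption (`a` near 1)
the model collapses to simple log-linear decay with slope `-k*H`.

## Estimation

Each trait comes from the assay that isolates it:

* `k`, `a` — nonlinear least squares of the adsorption curve on log
  titer (Poisson-weighted linear scale when zero counts occur; no
  pseudocounts).
* `d` — inversion of the Poisson infection model `F = 1 - exp(-d*MOI)`
  at the pooled depolarized fraction. Counts are pooled across
  replicates because per-well counts may be small; replicate-level
  uncertainty re-enters through the bootstrap.
* `r`, `mu_l`, `sigma_l` — least squares of the cumulative release
  fraction `C(t) = r*Phi((t - mu_l)/sigma_l)` (truncated-normal CDF),
  where `C` is computed per replicate from the decline of infectious
  centers normalized by the depolarized-cell density. An isotonic
  smooth of the pooled curve supplies starting values and the plateau
  check; the fit itself uses the raw replicate-level points so the
  error structure is untouched. `sigma_l` is bounded below by half the
  median sampling interval to prevent degenerate zero-SD fits on coarse
  grids.
* `b_d`, `b_r` — final free-progeny yield minus residual inoculum,
  per depolarized cell (`b_d`), divided by `r` (`b_r`). Requires the
  release curve to have plateaued within the sampled window.
* `m`, `p` — nonlinear least squares of the biphasic decay curve on log
  titer. The SSE surface is multimodal, so fits are multi-started over
  `m` in {fast-slope estimate, 10x that} and `p` in {0, last/first titer
  ratio}; ties go to the smaller `m`. With `p` fixed at 0 the problem
  is linear and solved exactly by log-linear regression. Constant
  titers return `(m, p) = (0, 1)` with a "no decay detected" flag.

Estimators are invariant to row order and replicate relabeling, and
per-trait failures flag the trait rather than aborting the profile.

### Confidence intervals

All intervals are nonparametric bootstrap intervals that resample whole
replicates (the assays' exchangeable unit) and refit, warm-starting
each refit at the original solution. Composite traits are recomputed
inside every bootstrap replicate, so the intervals of `s` and `b_r`
reflect joint uncertainty rather than naive interval arithmetic.

Interval endpoints use *expanded* percentile levels rather than the raw
2.5/97.5 percentiles. With `n` resampling units the bootstrap
distribution understates the sampling SD by roughly `sqrt((n-1)/n)`,
and normal-theory quantiles ignore the t-tail; both effects make raw
percentile intervals systematically narrow at the ~10 replicates
typical of these assays (measured coverage 86–92% at nominal 95%). The
expanded levels are `Phi(t_{alpha/2, n-1} * sqrt(n/(n-1)))`, which
reduces to the ordinary percentile interval as `n` grows. Default
`n_boot = 1000`.

A trait is flagged poorly resolved — and excluded from comparative
analyses — when its interval spans more than two orders of magnitude
(positive-scale traits) or more than 0.8 (probabilities), or when more
than 20% of bootstrap refits fail.

## Growth-rate prediction

The population growth rate `lambda` solves the Euler–Lotka
characteristic equation for a lytic life cycle with exponential
adsorption waiting time and a point lysis delay:

    1 = s * b_r * (k*H / (k*H + lambda)) * exp(-lambda * mu_l)

Only the four traits that determine lifetime reproduction and
generation time enter; `sigma_l` and mortality are excluded (mortality
is examined separately in the trade-off tests). The equation has a
unique root in `(-k*H, infinity)` whenever `s*b_r > 0`; `lambda = 0`
exactly when `s*b_r = 1`. The solver brackets the root (using the
infinite-host bound `ln(s*b_r)/mu_l` above, or walking toward `-k*H`
below), runs Brent's method on the better-conditioned log form of the
equation, and Newton-polishes until the residual of the original form
is at most 1e-9. Predictions are made at a configurable host density
(default 1e7 cells/mL, reported with every prediction). The functional
form sits behind a single function so a different delay model can be
swapped without touching the interface.

Observed growth rates are log-linear OLS slopes of growth-assay titers
over a configurable window (default: the full series), with replicate
bootstrap CIs; non-positive titers are dropped with a flag.

## Comparative statistics

* **Fold range** — max/min over non-missing positive estimates.
* **Type-host variance partition** — `R^2 = SS_between/SS_total` on
  trait point estimates, with a permutation P-value (label shuffling,
  `(count + 1)/(n_perm + 1)`, default `n_perm = 9999`). Permutation is
  preferred over a parametric F test because group sizes are small and
  unbalanced. Note that in real panels the type host is confounded with
  viral phylogeny; the statistic attributes variance, not causation.
* **Predicted vs observed growth** — Spearman rank correlation with
  average ranks; exact pairing-permutation P for `n <= 10`, asymptotic
  otherwise.
* **All-subsets regression** — OLS of observed growth on every subset
  of {`s`, `ln k`, `ln mu_l`, `ln b_r`} (16 models), with
  `AIC = n*ln(RSS/n) + 2K` (K counts coefficients plus the error
  variance). The consensus set is the intersection of predictors over
  all models within 2 AIC units of the best; rank-deficient subsets are
  flagged and excluded.
* **Trade-off tests** — CI-breadth-weighted Pearson correlations for
  growth vs mortality, burst size vs lysis time, and burst size vs
  genome size, within each species with at least 5 complete cases;
  smaller species are reported untested. Weights are inverse products
  of the two CI breadths (`1/(bx*by)`, normalized; the additive rule
  `1/(bx+by)` is available by config) so a point uncertain in either
  coordinate is down-weighted. P-values come from weight-preserving
  permutations of `y` (each `y` travels with its own breadth, weights
  recomputed per pairing). Rates and sizes are correlated on the log
  scale, where CI breadths become log-ratio breadths; probabilities and
  signed growth rates stay on the natural scale. Genome sizes carry no
  CI and receive unit breadth. Point estimates feed all statistics;
  uncertainty enters only through the weights.

## Synthetic data

The generator emulates the statistical structure the estimators assume:
exponential adsorption kinetics with a non-attaching plateau, Poisson
MOI statistics for depolarization, truncated-normal lysis times,
biphasic decay, and exponential growth. Counting noise follows plaque
assay practice: each observation is scored at the dilution that yields
about `count_target` (default 100) countable events, so counts are
Poisson with that mean and titers carry ~10% relative error; growth
titers instead carry multiplicative lognormal noise (default CV 0.15)
centered on the log scale so log-linear fits are unbiased.

Default design: 10 replicates per assay; adsorption sampled over 4 h at
1e8 cells/mL; one-step curves hourly over 28 h at 1e7 cells/mL and
adsorbed MOI 3; decay sampled to 600 h (25 days, typical of survival
assays run over weeks); growth sampled to 72 h. Default trait ranges
are log-uniform for rates and burst sizes (burst size spanning 77-fold,
10–770) and uniform for probabilities and lysis-time parameters,
spanning variation of the scale reported for chlorovirus panels while
keeping every trait identifiable from the default grids — e.g. decay
times extend far enough that the persistent plateau is informative, and
one-step grids span `mu_l + 3*sigma_l`. Panels assign species and type
host 1:1 in groups (default sizes 12/12/10 scaled to the panel),
mirroring the type-host confounding of real panels, and each strain's
growth assay is simulated at the rate predicted from its own true
traits so end-to-end recovery has a known answer.

What the generator does **not** emulate: detection limits and plate
saturation, host physiological variation between assays, pipetting
error beyond the lognormal term, co-infection and lysis-from-without at
high MOI, host growth or death during assays, and any true biological
correlation between traits or with host/species identity (traits are
drawn independently). Passing the synthetic study therefore shows that
the estimators are correct and calibrated under the assumed error
model, not that the error model captures every feature of real assays.

## Problem sizes for validation

The shipped validation uses 20 noise-free strains for exact recovery;
200 noisy strains with `n_boot = 200` for bias and coverage; 100 random
parameter sets for the growth solver against an independent dense root
scan; 50 random datasets for the model-selection oracle; 200 replicates
for the permutation-P uniformity checks; and 34-strain panels (21 for
the dominant-trait consensus) for the end-to-end study — sizes chosen
so the full suite runs in minutes on one core while keeping Monte Carlo
error well below the tolerances being checked.

## Known limitations

* Percentile-type intervals, even expanded, are approximate at very few
  replicates (< 5); profile-likelihood or studentized intervals would
  be better there.
* The burst-size estimator assumes the release curve plateaus within
  the sampled window; truncated curves are flagged but not extrapolated.
* The decay fit reports `p` as an upper-bound-style estimate when the
  plateau sits below the informative range of the sampled times (the
  interval then spans to zero and the trait is flagged).
* The growth model assumes constant host density and ignores mortality
  during the growth assay; it is a prediction target, not a full
  population-dynamics model.
* Host-variance partitioning cannot separate host effects from viral
  phylogeny when the two are confounded, as in real panels.
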