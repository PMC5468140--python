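# Methods

## The model

Habitat use is measured by yearly fecal pellet-group counts on permanent
plots, cleared after each survey (fecal accumulation rate). Counts are so
zero-inflated (>80% of plots empty each year, and at most ~2% of nonzero
counts above one group) that only presence/absence is modelled. For
plot-year unit *i* with presence `y_i ∈ {0,1}`:

```
logit(p_i) = x_i' β + u_i,        u ~ N(0, τ (I − ρD)⁻¹)
```

`D` is a symmetric binary neighborhood matrix with zero diagonal: units are
neighbors when their plot centers lie within 350 m (inclusive) and — by
default — belong to the same survey year, so `D` is block-diagonal across
years and random effects are independent between years. ρ must keep
`I − ρD` positive definite, i.e. lie in `(1/λ_min(D), 1/λ_max(D))`.

Fixed effects (defaults of `ModelSpec.pellet_default()`):

* vegetation class, five levels merged from the national landcover map
  (forest, clear-cut, young forest, mire, other), reference **mire**;
* `sqrt(distance to nearest turbine / 100 m)` — the square-root transform
  damps the influence of plots far from the turbines;
* development phase (preconstruction / construction / operation), reference
  **preconstruction**; the clearing year is excluded from analysis;
* previous-season (May–October) precipitation in 10⁻¹ m, one value per
  survey year;
* distance × phase interactions — the before–after contrast of interest.

Covariates are screened for collinearity with variance inflation factors
(`VIF_j = 1/(1−R²_j)`, removal threshold 3.0).

## Estimation

Estimation is h-likelihood with quasi-likelihood inference:

1. **Given dispersions (τ, ρ, and optionally an extra variance σ² for an
   iid random intercept such as year):** (β, u) maximize the joint
   h-likelihood by damped Newton iteration. The augmented information
   matrix is factorized by a block-Schur scheme: the u-block `W + Q`
   (`W = diag(μ(1−μ))`, `Q = (I−ρD)/τ`) is block-diagonal by year and gets
   one sparse LU per block; the dense fixed-effect border is solved through
   a small Schur complement. Cost is linear in plot-years.
2. **Dispersions:** Nelder-Mead maximizes the adjusted profile criterion —
   the restricted (REML) likelihood of the model linearized at the current
   fit (working response `z = η + (y−μ)/W`, weights `W`), evaluated through
   the augmented least-squares identity
   `−2 l_R = log|A| − log|P| + Σ(y−μ)²/w + u'Qu` — with the inner Newton
   refit nested inside every evaluation, so the reported (β, u, τ, ρ) are
   self-consistent. ρ is searched through a logistic map onto its
   positive-definiteness interval (clamped 10⁻⁶ inside; a boundary hit
   warns); τ and σ² are searched on the log scale with wide clips so a
   collapsing variance component stays finite.
3. **Dispersion of the mean model:** φ is the leverage-corrected Pearson
   statistic `Σ (y−μ̂)²/(μ̂(1−μ̂)) / (n − p_D)`, with `p_D` the effective
   number of mean-model parameters (trace of the augmented hat matrix over
   data rows). φ multiplies the covariance of β̂ (quasi-likelihood);
   p-values use the normal reference. A `dispersion="deviance"` option uses
   the leverage-corrected mean deviance instead; on rare binary outcomes
   that estimator sits far below 1 (≈0.2–0.5) even for well-specified data,
   which is the natural reading of the strong "underdispersion" (0.16–0.33)
   reported for the real surveys. The Pearson default is calibrated:
   φ ≈ 1 on well-specified Bernoulli data, and φ ≈ 0.5 when responses are
   generated with half-binomial variance.

Degenerate inputs: an all-0 or all-1 response is an error; an edgeless
neighborhood fixes ρ = 0 (it has no effect); `fix_tau` near zero with an
edgeless graph reduces the fit to ordinary logistic regression (verified
against an independent Newton oracle to 1e-4); extreme linear predictors
trigger a quasi-separation warning. Convergence requires the inner Newton
step to fall below 1e-9 relative and the dispersion search to terminate;
everything is deterministic given inputs and options.

### Known limitation: conditional-scale bias for binary data

First-order h-likelihood / PQL-type estimation — including the estimation
family used for the original analysis — is biased for Bernoulli responses
with one random effect per observation: random-effect predictions are
shrunk, fixed effects are attenuated toward their marginal values, and the
dispersion pair (τ, ρ) is not consistently recovered. Three criterion
variants were evaluated (full Laplace; frozen-weight REML score fixed
point; the shipped self-consistent variant): the first two collapse τ
toward 0 on simulated surveys, while the shipped variant reproduces the
qualitative regime of the real-data fits (large τ with small φ) and gives
accurately calibrated Wald tests (type-I error 0.05 at the nominal 5%
level in simulation). Simulation recovery of generating parameters in
absolute terms remains biased (intercepts attenuated ~8%, τ not
recoverable from weak binary signal) — an inherent property of the method
family, documented rather than patched, since exact marginal likelihood is
not computable for a correlated CAR field and MCMC is out of scope. Tests
of *terms* (the scientific contrasts) are unaffected in level; effect
magnitudes on the conditional scale should be read with this caveat.

## Backward elimination

Terms are dropped one at a time: at each step the droppable term with the
largest p-value above the 10% level is removed and the model refit. A main
effect is droppable only when no retained interaction involves it, so the
final model always respects the hierarchy principle. For a multi-level
factor the term-level p is by default the largest single-coefficient Wald p
among its non-reference levels (a joint Wald chi-square option exists —
note the max rule can discard a factor whose strongest level is
significant, which the joint rule would keep). Ties prefer interactions
over main effects, then the later-listed term. Degenerate thresholds are
conventions: `alpha ≥ 1` strips to forced terms, `alpha ≤ 0` disables
elimination.

Two sensitivity refits mirror the original robustness checks: replacing
the phase factor by {first, second, third survey year, operation} with the
first year as reference, and adding an exchangeable random year intercept
beside the CAR effect (with a logged caution that a handful of year levels
cannot support a stable variance estimate).

## Synthetic surveys

The generator reproduces the study conditions, not any one realization:

* **Layout:** two local transect grids (300 m between transects, 100 m
  between plots, 3 km square each → 341 plots per mountain) around turbine
  clusters of 8 and 10 machines in two rows at 400-m spacing, 4 km apart;
  29 regional 1×1 km squares with 20 perimeter plots every 200 m, placed by
  rejection sampling in a 15-km disc with ≥1,400 m separation. Total
  ~1,262 plots — the order of the real survey (1,162–1,315 per year).
* **Covariates:** vegetation iid per plot from the study-area composition
  (34.7% forest, 9.9% clear-cut, 20.3% young forest, 27.1% mire, 7.9%
  other; stored normalized to sum exactly to 1), held fixed across years;
  one uniform May–October precipitation value per year on 47–93 mm;
  distances computed from the actual plot–turbine geometry.
* **Response:** linear predictor from the published combined-data
  coefficients (the unreported "other" class sits at the reference value 0),
  CAR effects drawn via blockwise Cholesky of the precision with τ = 1.96,
  ρ = 0.05, presence Bernoulli, and a 2% chance that a present plot holds
  two groups. The excluded clearing year is simulated and flagged so the
  exclusion path is exercised.

With these defaults the simulated surveys show >80% zero plots in every
analysis year and ≤2% multi-group records, matching the raw-data skew.
What the generator does **not** emulate: spatial autocorrelation of
vegetation (an optional smoothing pass is deliberately off — no structure
is reported to calibrate it against), correlation between vegetation and
distance on the mountains, pellet decay, and herding events. Passing tests
therefore demonstrate correctness of the machinery under the stated
statistical structure, not faithfulness to every feature of the field data.

## Monte Carlo power

No closed-form power exists for this model family, so power is estimated
by simulation: `n_sim` surveys are generated from stated truth, the
generating model is refit to each (no re-selection, the standard
post-selection convention; a flag enables selection per replicate), and the
rejection rate of the term's Wald test at level α is returned with its
Monte Carlo standard error `sqrt(p(1−p)/n_converged)`. Non-converged
replicates are excluded and counted; more than 20% of them triggers a
warning. Replicates share the simulated design's adjacency (and its cached
spectrum), and multiple terms can share the same fits.

Problem sizes used by the shipped checks (chosen to keep full runs in the
tens of minutes on one CPU): the acceptance script uses 80 replicates of
the full ~7,600-unit design for the power targets; the test suite uses 20
replicates there, 100 replicates of a ~2,000-unit lattice for recovery, and
200 replicates of a ~1,000-unit lattice for type-I calibration.

## Numerical choices

* Inclusive 350-m neighbor rule (`≤`), with a relative-epsilon KD-tree
  radius so exact-threshold pairs are kept despite float rounding.
* Grid origin convention: transects run along the y axis from the west
  edge; plot counts equal `(⌊2h/Δt⌋+1)(⌊2h/Δp⌋+1)` deterministically.
* Square placement: rejection sampling, default cap 10,000 attempts, then
  a placement-failure error.
* Sparse precision algebra throughout; dense inverses only for small
  graphs and tests (covariance route verified against dense inversion to
  1e-8 up to 50 nodes).
* Reported estimates are rounded half-away-from-zero to 2 decimals;
  reference categories render as `0.00 (-)`; every fit significant in at
  least one analysis subset appears in all columns of the aligned table.
* Pipelines and the power study are bit-reproducible from their seed; all
  derived seeds stay below 2³¹.
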