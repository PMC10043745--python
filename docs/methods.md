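# Methods

This note documents the models, conventions and design choices behind
`planshare`, in the spirit of a statistical package's methods appendix. It
describes what is computed and why; every empirical statement here is the
output of the test suite or of `scripts/acceptance.py`, not an external
claim.

## 1. Cost-sharing mechanics and the synthetic universe

A claim's patient cost share decomposes into three components applied in a
fixed order per enrollee and calendar year:

* **deductible**: `min(remaining annual deductible, allowed amount)`; the
  accumulator resets every calendar year (deductibles are annual
  constructs; the convention is ours, as claims data do not state it).
* **coinsurance**: `rate × (allowed − deductible portion)`.
* **copay**: the plan's flat per-visit amount, capped so the three
  components never exceed the allowed amount.

Screening mammograms carry zero cost sharing and do not consume
deductible, mirroring the statutory exemption of screening from patient
cost sharing.

The generator plants four plan types with component profiles (means ± SD,
shrinking with the `separation` knob):

| type | copay | coinsurance | deductible |
|---|---|---|---|
| copay-dominated | $85 ± 8 | 2% ± 1 | $80 ± 40 |
| coinsurance-dominated | $4 ± 2 | 25% ± 3 | $80 ± 40 |
| deductible-dominated | $4 ± 2 | 2% ± 1 | $1300 ± 200 |
| balanced | $20 ± 3 | 12% ± 1.5 | $500 ± 100 |

`separation ≥ 1` divides the trivial components and all spreads, so at
`separation ≥ 2` between-type distances dominate within-type spread in
scaled triplet space. Dominant magnitudes were chosen once so that the
implied mean annual OOPC orders the types the way claims data order them —
coinsurance cheapest, balanced and copay close together in the middle,
deductible most expensive; the $85 copay is a per-visit average over an
office/specialist/ER mix rather than a primary-care copay. Claim counts
are `1 + Poisson(11)` per enrollee-year and allowed amounts log-normal
(median $150, σ = 0.8) — right-skewed, as claims costs are; the exact
shape is immaterial to what the pipeline infers.

Outcome counts follow the exact estimand: a Bernoulli indicator from a
logistic index, then a zero-truncated NB2 count drawn by inverse CDF
(uniform on `(P(Y=0), 1)` through the untruncated quantile function, which
is exact; below α = 1e−6 the zero-truncated Poisson limit is used).
Default parameters (`OutcomeParams.typical()`) reproduce per-type recall
rates of 10.5–12.1% (overall ≈ 10.9%) and a per-tester mean of ≈ 1.96
services with SD ≈ 1.05 (α = 0.05, near the Poisson limit); plan-type
count-part contrasts are derived analytically so the implied conditional
average marginal effects are ≈ −0.007 (balanced), −0.024 (copay) and
−0.016 (deductible) services per tester versus the coinsurance reference —
the magnitudes reported for real cohorts. Total counts are split across
service categories by a multinomial whose shares follow typical per-tester
composition (diagnostic mammography and ultrasound ≈ 93% of services, MRI
≈ 4.5%, biopsy ≈ 2.5%).

**What the generator does not emulate**: coordination of benefits, claim
denials and reversals, out-of-pocket maxima, family-level deductibles,
mid-year plan switches, supplemental screening for high-risk women, and
real CPT/ICD ontologies beyond the codes the pipeline consumes. Passing
recovery tests therefore certify the *pipeline's* correctness under the
stated model, not the model's fidelity to any particular insurer's
adjudication system.

All randomness flows from one master seed through named CRC-32-keyed
substreams (`planshare.rng.substream`), so stages re-run in isolation
reproduce a full-pipeline run bit for bit.

## 2. Cohort and episodes

Inclusion rules are applied in a fixed order with one reason code per
excluded enrollee: demographics present → female → age ≥ 40 *at study
start* (the age-group covariate, by contrast, is evaluated at the index
date) → one enrollment span covering the whole study period in one plan →
alive at period end (via an optional death-date field; absent means
assumed alive) → an index screening claim in the index year → no
breast-cancer diagnosis (prefixes `174.`, `C50.`) in the 365 days before
the index date.

The index event is the *earliest* qualifying screening claim in the index
year. Episodes are half-open windows `(index, min(index + 365 d, first
post-index cancer claim)]`: the index claim itself never counts as a
follow-on service. Category counts count claim lines; a `dedup_same_day`
switch collapses same-day duplicates of one CPT for sensitivity analyses.
Diagnosis matching is prefix-based on normalised codes with dots retained
(`C50.` matches `C50.1`), which implements the `174.x / C50.x` wildcard
convention.

Charlson scoring uses a configurable `{ICD prefix → (condition, weight)}`
map with standard weights (ICD-10 prefixes after Quan et al., plus
classic ICD-9 rubrics). Distinct conditions count once regardless of claim
multiplicity; the longest matching prefix wins so complicated-diabetes
codes shadow the uncomplicated rubric. The published prospective-CCI
variant is not fully specified anywhere we can reproduce, so the shipped
map is a documented stand-in and fully swappable.

## 3. Mechanism inference

* **Triplet**: mode copay over claims; mode of per-claim
  coinsurance/allowed ratios (zero-allowed claims skipped), rounded to two
  decimals *before* the mode because real coinsurance rates are quoted in
  whole percents and the raw ratio is continuous; maximum over enrollees
  of the enrollee's *annual* deductible sum ("maximum deductible paid"
  read as an annual accumulation, not a per-claim maximum). Mode ties
  break to the smaller value, for determinism. A config flag can exclude
  zero-cost-share claims from the modes.
* **Scaling**: the printed formula `(max − x)/(max − min)` inverts the
  conventional orientation — the plan attaining a component's global
  maximum scales to 0. The default (`as_printed`) honours that;
  `standard` provides the conventional orientation, because the intent of
  the origin-seeded cluster differs between the two readings and we do
  not guess. Cluster labeling undoes the inversion before interpreting
  centers, so labels agree across orientations for well-separated plans.
  A degenerate component (max = min) maps to 0 with a warning.
* **k-means**: Lloyd iteration, exact Euclidean nearest-center assignment
  (ties to the lowest index), all four centers recomputed as assigned-point
  means each round (the origin-seeded center included — "the cluster
  centers are recalculated" is read as all four; a `pin_origin` flag
  freezes it for sensitivity). Termination when assignments repeat. An
  empty cluster is re-seeded to the point farthest from its nearest
  center, logged. Within-cluster SSE is recorded per iteration and is
  non-increasing whenever no re-seed fires.
* **Restarts**: the default single run follows the described procedure
  exactly, but a single Lloyd run from one uniform random init can land in
  a poor basin — two centers splitting one plan-type cloud while two
  clouds merge, a state no empty-cluster rule can repair because nothing
  is empty. This failure is a property of the init geometry, not of type
  separation (it persists when separation doubles). `n_restarts > 1`
  draws additional seed-derived inits and keeps the lowest-SSE solution;
  with 3 restarts, plan-type recovery on separated universes is
  essentially exact, and `scripts/acceptance.py` reports single-run and
  3-restart accuracies side by side.
* **Labeling**: centers are re-expressed so larger = more cost sharing;
  the center with the smallest across-dimension range is `balanced`, the
  rest take the type of their largest coordinate, conflicts resolved
  greedily by larger coordinate (the loser takes its largest unclaimed
  dimension).
* **Ranking**: the type-level OOPC statistic is an unweighted mean over
  plans of the plan's enrollee-mean annual OOPC — plans, not enrollees,
  are the units, so a huge plan cannot dominate its type's statistic.

## 4. The hurdle model

Part 1 is a logistic regression (IRLS via statsmodels GLM) on the
any-testing indicator over the full cohort; degenerate outcomes and
separation (detected as runaway coefficients) raise a convergence error.
Part 2 is the zero-truncated NB2 likelihood, written in log space:
`log f(y) − log(1 − f(0))` with `log(1 − e^a)` computed by the
`log1p/expm1` split, and the `gammaln(y+r) − gammaln(r)` difference
replaced by its expansion `y log r + y(y−1)/2r` once `r = 1/α > 1e6`,
which keeps the Poisson limit accurate to ~1e−8 where naive evaluation
loses six digits to cancellation.

The MLE runs in `(β, log α)` by L-BFGS-B with the analytic gradient
(including the truncation terms), `log α` bounded in `[log 1e−6, log 100]`
— at tiny α the model degenerates to a zero-truncated Poisson and the
likelihood goes flat in `log α`, so the boundary is treated explicitly:
the observed-information eigenvalue in the flat direction is clipped
before inversion and the fit is reported at the boundary. Standard errors
come from the observed information (central finite-difference Hessian of
the log-likelihood at the optimum); a non-positive-definite information
away from the boundary raises an error advising a ridge. Covariate levels
absent among testers are dropped from part 2 (they cannot enter the count
model) and the two parts track their own column lists.

NB2 (Var = μ + αμ²) is the parameterisation throughout — the ecosystem
default. CIs and p-values use the normal reference: at cohort sizes where
these effects are estimable, MLE asymptotics are the operative regime.

**Marginal effects.** The conditional (default) AME of plan type `t`
averages `m(x with t on) − m(x with reference on)` over the part-2
estimation sample, where `m = μ/(1 − f(0; μ, α))` is the zero-truncated
mean — the change in expected services *among testers*, which is how such
tables are titled. An unconditional two-part effect (part-1 probability ×
truncated mean, part-1 parameters held fixed) sits behind
`conditional=False`. Standard errors propagate the part-2 `(β, log α)`
covariance through a central finite-difference gradient of the AME; the
delta-method SE matches the analytic closed form in an intercept + single
dummy model to 5 decimal places (tested).

**Duan smearing.** The retransformation factor is the mean of
exponentiated log-scale residuals among testers, `mean(yᵢ/μ̂ᵢ)`, applied
multiplicatively to μ inside the truncated mean when enabled. The exact
recipe appropriate to a zero-truncated count MLE is ambiguous in the
literature; this convention is documented rather than asserted, default-on
in the pipeline to follow the published method, and treated as a
sensitivity knob. Note that under a correctly specified ZTNB the factor
converges not to 1 but to `E[tm(μ)/μ] ≈ 1.3` at these parameter values —
smearing deliberately rescales the conditional mean — so recovery
comparisons against planted effects are made with smearing off.

**Coverage.** "Planted-effect CI coverage" is evaluated on the part-2
plan-type *coefficient* over 200 scaled-down replications (700 testers
each): the coefficient is the quantity with a fixed planted value across
replications, whereas the AME's finite-sample estimand varies with each
replication's covariate draw.

## 5. Reporting

Percentages are rounded half-up to one decimal (journal convention), and
every emitted table re-checks that each percentage cell recomputes from
its own count cell to within the 0.05 rounding slack. The utilization
table orders plan types by ascending OOPC rank. Published tables of this
kind can disagree with each other across tables (the same tester count
printed differently in two tables); the self-consistency check is
therefore strictly per-table.

## 6. Pipeline

Five stages (`simulate`, `build-cohort`, `infer-plans`, `fit-hurdle`,
`report`) run from one YAML config and one master seed; each stage writes
plain CSV/JSON artifacts and the manifest records SHA-256 hashes, so a
repeated run with the same seed reproduces identical hashes. Stage
failures halt with the stage name and reason. The hurdle stage takes its
reference plan type from the OOPC ranking computed in the same run
(lowest rank), not from a hard-coded label.

## 7. Problem sizes

The test suite exercises the chain at desk scale: a 300-plan/6k-enrollee
study for cohort logic, 2 000-plan universes over 20 seeds for mechanism
recovery, 50 000 patients (and 50 000 testers) for hurdle parameter
recovery, and 200 replications of 700 testers for CI calibration.
`scripts/acceptance.py` uses a 2 000-plan / ~60 000-enrollee universe and
a 250 000-patient outcome simulation with a 150 000-tester draw for
marginal-effect recovery — the tester count at which Monte-Carlo precision
(SE ≈ 0.007 services) matches the magnitude of the planted effects.

## 8. Known limitations

* Plan-type labels come from cluster geometry; a universe whose plans do
  not actually separate into four mechanism regimes will still be forced
  into four labels.
* The single-run k-means default is faithful to the described procedure
  but carries an irreducible init-basin risk; use restarts when the goal
  is recovery rather than procedure replication.
* Charlson weights/prefixes are a standard stand-in, not a certified
  crosswalk; swap the map for production epidemiology.
* The hurdle model assumes the two parts are independent given
  covariates; correlated selection into testing is out of scope, as are
  random effects, survey weights and zero-inflated (as opposed to
  hurdle) formulations.
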