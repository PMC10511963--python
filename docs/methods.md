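# Methods

## Design

`matchdid` estimates the average effect on the treated of a binary status
transition between consecutive panel waves. The design has four stages.

**Treatment coding.** For the *entry* direction, a treated observation is a
person non-employed at wave t−1 and employed at wave t; eligible controls
are non-employed at both. *Exit* is the mirror image. Transition waves are
restricted to a configurable calendar window (default 2012–2018 within a
biennial 2006–2020 panel) and, optionally, to people at least `min_age`
(default 65) at the transition. Eligibility further requires employment and
outcome observed at every wave from t−L through t+F<sub>max</sub> — with
the defaults L = 3, F<sub>max</sub> = 1 that is five consecutive
interviews — and every filter reports its exclusion count so the tallies
read like a sample flowchart and conserve.

**Exact history matching.** The matched set of a treated (i, t) is every
eligible control observation at the same t whose employment vector over
t−L..t−1 is identical. Conditioning on the recent treatment history absorbs
persistent selection into work (work attitudes, attachment, insecurity)
insofar as it expresses itself in the observed employment path; the
potential outcome is assumed independent of treatment history beyond L
waves. A person may serve as control for any number of treated events
(reuse is handled by weights, not exclusion), and a treated event with no
history-sharing control is dropped and counted.

**Refinement.** Within each matched set, controls are re-weighted (or
pruned) using their pre-treatment covariate histories: time-invariant
covariates at t, time-varying covariates (including the outcome itself) at
each of t−1..t−L. Four methods share this interface; all produce
non-negative weights summing to one per non-empty set, and applying a
fitted model twice changes nothing.

- `cbps_weight` (default): a logistic score fitted by just-identified
  covariate-balancing estimating equations targeting the treated,
  mean[(T − (1−T)·e/(1−e))·x̃] = 0. At the solution the odds-weighted
  control covariate means equal the unweighted treated means exactly — the
  same e/(1−e) weighting the refinement applies, so fitted balance carries
  to the estimator. The treated-target form is used rather than the
  inverse-probability (ATE) form precisely because the estimand is the
  effect on the treated. The moment function is the gradient of a strictly
  concave objective; a damped Newton ascent initialised at the logistic
  MLE (via a Powell-hybrid start) converges globally whenever a root
  exists, to max |mean moment| < 1e−8.
- `ps_weight`: the same odds weighting with the score fitted by maximum
  likelihood.
- `ps_match` / `mahalanobis`: keep the J (default 5) controls nearest in
  fitted score / in average per-wave Mahalanobis distance (covariance
  pooled over the event-eligible sample per calendar wave, pseudo-inverse,
  diagonal fallback if singular), equal weights, ties broken by unit id so
  runs are reproducible.

Scores are fitted once, pooled over all treated events and the unique
controls of their matched sets (per direction); per-set fits would be
underdetermined. Features without variation within both groups (typically
a missingness indicator that is all-observed among treated) are dropped
from the balance conditions with a warning: their just-identified moment
has no finite root, as matching a degenerate point would force boundary
propensities.

**Estimation and inference.** The point estimate at lead F averages, over
treated matched events, the treated outcome change from t−1 to t+F minus
the weighted control change over the same waves. Uncertainty comes from a
weighted block bootstrap: the estimator is decomposed into per-person
contributions c<sub>j</sub> (own changes as treated, minus weight×change
terms over control memberships) and counts d<sub>j</sub> (treated matched
events), whole persons are resampled with replacement, and the ratio
Σc*/Σd* recomputed; replicates with no treated person are redrawn and
counted. Matched sets and weights stay frozen inside the bootstrap (an
opt-in refit flag exists for honesty checks). The default interval is the
2.5/97.5 percentile; a normal (±1.96·SE) mode is available.

## Covariate construction

Time-varying covariates enter lag-wise (value at each of t−1..t−L), so
trajectories, not just levels, are balanced. Income and asset are replaced
by their within-wave tertile rank (1/2/3) computed over the event-eligible
sample — relative economic position, invariant to any monotone
transformation of the amounts, hence also to the currency-harmonisation
factors (`harmonise_currency` scales by deflator / PPP / 1000 and is
injective). Partially observed covariates use classic dummy adjustment:
the value 0-filled plus a 0/1 observedness indicator per slot; fully
missing covariates are a hard error. Categoricals are one-hot encoded
against a declared reference level. Tertile cut-points are per wave (not
pooled) because relative position is a within-period notion; this is
configurable in spirit by pre-transforming the panel.

## The synthetic cohort generator

The generator emulates the *structure* the design must handle, not any
real cohort's margins: a biennial 2006–2020 panel; baseline age uniform
55–75; two-state employment dynamics with per-wave retention
p_stay_employed = 0.88 and re-entry 1 − p_stay_out = 0.10 at age 65, both
shrinking with age on the logit scale (0.05/year); a bounded integer
cognition score built from an education gradient (0.8 pts/level), a person
intercept (SD 2.0), linear age decline (0.08 pts/year past 65), additive
treatment effects at the transition wave (defaults +0.65 entry, −0.44
exit; carry-over at the next wave defaults to 0), and rounded N(0, 1.5)
noise clipped to the instrument range; absorbing attrition (5%/wave) and
item missingness (5%) on health, income and asset. All randomness flows
from one seed; identical configs give byte-identical panels, and the truth
record (effects, per-person confounders, transition waves) is returned for
scoring.

Switchable violations: `confounding_on` with `selection_strength` makes
the transition propensity load on standardised self-reported health
(weight 0.9) and the lagged observed cognition score (weight 0.1), while
`health_slope_per_year` steepens decline for worse health — together these
create selection on *trends*, which history matching alone does not remove
and refinement must. The `confounded_scenario()` preset (strength 1.5,
health slope 0.40, true effects zero) yields an unadjusted entry bias of
about +0.35 points that CBPS weighting cuts by roughly two thirds.
`pretrend_violation` adds a treated-specific pre-transition drift for
power checks of the pre-trend diagnostic. Because lagged cognition enters
the selection with a small weight, a mean-reversion component (selection
on outcome noise) partially offsets the health-slope bias; the preset's
loadings keep the net unadjusted bias clearly positive.

What passing tests on this generator do **not** show: realism of marginal
distributions (amounts are lognormal toys), informative attrition
(dropout is random given survival), measurement change over modes, or
spillover between persons (none is generated, matching the design's
no-interference assumption).

## Numerical and design choices

- **Lead-1 estimand.** Matched sets condition on history through t only,
  so during the lead both groups may transition again; the F = 1 contrast
  is an intention-to-treat-style quantity under natural follow-on
  dynamics. With the default transition rates this contributes about
  −0.06 points to the F = 1 entry contrast when the true carry-over is 0.
- **SMD convention.** Balance SMDs divide by the treated-group SD, the
  matching-diagnostics convention; slots with zero treated SD report 0
  when means agree and are flagged undefined otherwise. Pre-trend tables
  report outcome levels at t−1..t−L and lag-to-lag changes. Note that
  refinement balances lagged outcomes by construction, so an injected
  pre-trend is visible on the *unrefined* sets; the pipeline reports the
  refined table as the assumption check, and the unrefined one is a
  diagnostic-power tool.
- **Bootstrap conservatism.** The frozen-weight block bootstrap
  reproduces the variance of the frozen per-person decomposition (its SE
  matches the delta-method SE of that decomposition) but does not credit
  the variance-reducing re-matching/refit step, so it over-covers
  somewhat: in the package's own calibration study (effect scenario,
  1000 units, ~110 treated events, 200 simulations × 500 replicates) the
  95% interval covers the truth ≈ 99% of the time and the mean bootstrap
  SE is ~25% above the empirical SE. This is a known property of
  resampling for matching estimators; intervals err on the wide side.
- **Validation sizes.** The standard validation runs used by the test
  suite and the acceptance script: oracle equivalence on 100 random
  panels (≤30 units × ≤6 waves); null calibration with 100 cohorts of
  2000; effect recovery with 200 cohorts of 2000; confounding correction
  with 50 cohorts of 2000; coverage with 200 cohorts of 1000 at 500
  bootstrap replicates; lag-2 vs lag-3 parity with 30 paired cohorts.
- **Ties and determinism.** Nearest-J ties break by unit id; bootstrap
  resampling uses a canonical unit ordering; full runs are bit-for-bit
  reproducible from (input, config, seed).
- **Degenerate inputs.** Zero matched treated events raise a hard
  "no estimable events" error (subgroup cells degrade to NA with a reason
  instead of aborting the run); perfectly separable score-fitting samples
  raise rather than silently returning boundary weights; singular
  Mahalanobis covariances fall back to the diagonal with a warning.

## Limitations

Exact history matching discards treated events with no history-sharing
control and, combined with the consecutive-participation requirement,
can remove a large share of observations — the exclusion tallies make
this visible. The CBPS is just-identified (balance conditions only), not
the over-identified GMM variant. Subgroup analyses rerun the entire
matching within each subgroup, so matched controls share subgroup
membership; cross-country or cross-instrument magnitude comparisons are
out of scope, as are survey weights and caliper/coarsened matching
variants.
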