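# Methods

This note records the models, estimators and numerical choices behind
`hteharm`, what the synthetic-trial generator does and does not emulate, and
the limitations a user should know before trusting output on real data.

## The statistical problem

In a two-arm randomized trial with a time-to-event outcome, the quantity of
interest is a *conditional* treatment effect: for a subgroup S defined by
baseline covariates, does assignment to treatment raise the event hazard
within S even though the trial-average effect is beneficial?  Testing many
data-derived subgroups naively invalidates p-values; the package therefore
uses a split-sample design: subgroups are *generated* on one half of the data
by a machine-learning search and *tested* on the other half with conventional
survival models, so the test-half inference is conditionally valid given the
(frozen) hypotheses.

## Balanced sample splitting

A 50/50 split is drawn at random, but an unlucky split can leave the halves
systematically different.  We therefore score each of `n_split_candidates`
(default 1000) random partitions by entropy balancing: find weights w on the
training half minimizing KL(w ‖ uniform) subject to the weighted means of
all baseline covariates, the event indicator and the arm indicator equaling
the full-sample means, and use the attained KL divergence as the imbalance
score (0 iff the train half already matches; +∞ if the program is
infeasible).  The dual is an unconstrained convex problem,
min_λ log mean_i exp(−λᵀ(Z_i − m)) over standardized moments Z, solved by
Newton with step halving (gradient tolerance 1e−10, infeasibility declared
when ‖λ‖ → 10^6 or the Hessian degenerates).  The candidate with the
smallest score is selected (ties → lowest candidate index).  The test half
is scored implicitly: the complement of a balanced half of a 50/50 split is
itself near-balanced.  First moments only are matched by default; second
moments are a flag.  Which moments the original design balanced is not
documented anywhere we could consult, so this reconstruction is the
canonical first-moment form.

## Discretization

Continuous covariates are cut at empirical quantiles (linear interpolation;
default quartiles) into ordinal bins with the half-open convention (a, b] —
a value equal to a boundary falls in the lower bin.  Constant covariates
collapse to one bin, warn, and are excluded from splitting.  The training
half's `CutpointMap` is frozen and re-used for everything downstream, so a
subgroup definition such as "SBP above its top-tercile boundary" keeps the
same mm-Hg threshold on the test half.

## The honest forest

Each tree: draw 50% of the training rows without replacement; this subsample
chooses the tree's structure and the *complementary* rows estimate the leaf
effects (the two roles never share a participant — "honesty").  A
`resplit_subsample` flag instead halves the subsample itself into the two
roles and leaves the complement unused; the default follows the description
of the discovery design this package operationalizes, which estimates on
"the other 50%" of the training data.

The outcome for the forest is the raw binary event indicator.  Censoring is
deliberately ignored during discovery — follow-up differences blur into the
leaf means — because the validation stage handles censoring properly with
Cox models; this mirrors the discovery design and is its acknowledged
weakness.

Split search is exhaustive over (covariate, ordinal threshold) pairs.  The
node score is

    score(child) = n·τ̂² − c·n·V̂ar(τ̂),      c = `variance_penalty` = 2,

with τ̂ the treated-minus-control event-rate difference in the child,
V̂ar(τ̂) = s²_t/n_t + s²_c/n_c its two-sample variance estimate, and a split
accepted only when the children's summed score strictly beats the parent's.
The first term concentrates effect heterogeneity across leaves (it is the
algebraic complement of minimizing within-leaf squared error of a
leaf-constant effect prediction); the variance term is the honest
causal-tree correction, weight 2 for the two equal-sized samples that touch
a leaf.  Without it, E[n·τ̂²] ≈ n·Var(τ̂) is nearly constant per child, so
the argmax over dozens of candidate splits is driven by estimator noise and
trees split essentially at random; with it, pure-noise splits have negative
expected gain.  `variance_penalty=0` recovers the raw Σ n·τ̂² criterion for
comparison.  Admissibility requires ≥ `min_leaf_treated`/`min_leaf_control`
(default 10/10) per arm in each child in *both* halves; depth is capped at 4.
Ties among equal-scoring splits break by covariate order, then lowest
threshold, making trees deterministic given their seed (per-tree seeds are
spawned from the forest seed via `SeedSequence`).

With these defaults on trial-scale data the forest produces ~13 leaves per
tree.  The design that inspired the defaults reports closer to 5 leaves per
tree; since neither its leaf minima nor its depth cap are documented, we
keep the stated defaults rather than reverse-engineering that census.

## Hypothesis distillation

Leaves with τ̂ strictly > 0 are harvested (ties at zero are
benefit/neutral; a `side="benefit"` flag flips the sign).  Each harm leaf's
root-to-leaf path is merged into its tightest per-covariate interval
(contradictory conjunctions dropped with a log entry), truncated to the
`max_conditions` (default 3) covariates most frequent across all harm
leaves, deduplicated with pooled support, ranked by contributing-leaf count
(or mean τ̂), and the `top_k` (default 5) survive.  Covariate frequency is
counted once per leaf path.  Bin thresholds are rendered in original units
via the frozen cutpoints and membership is always evaluated against those
unit thresholds.  The route from hundreds of harm leaves to a handful of
tested subgroups is the least-documented step of the original design; the
rank-by-support rule here is one defensible choice and is exposed as
configuration.

## Cox validation

The engine maximizes the stratified partial likelihood (each clinic site its
own baseline hazard; strata without events drop out) by Newton–Raphson with
step halving, gradient tolerance 1e−8, Breslow tie handling by default
(Efron available; simulated continuous times make ties measure-zero).
Coefficients beyond |β| = 15 are declared divergent (monotone likelihood /
perfect separation) and flagged rather than reported as estimates.  Wald
standard errors come from the inverse observed information; HRs, 95% CIs and
two-tailed p-values follow.  The implementation is hand-written because the
permutation layer refits the same 3-parameter model thousands of times with
only the covariate matrix changing; all time/event/stratum bookkeeping is
precomputed once.  It is verified in tests against a brute-force enumeration
of the partial likelihood on small datasets and against lifelines on larger
ones (agreement to ~1e−6 in coefficients and standard errors).

**Permutation FDR.**  The subgroup indicator is permuted across participants
(arm, outcome, site fixed; optionally within site), the interaction model
refit, and the FDR estimated as the proportion of permuted interaction
coefficients strictly greater than the observed one.  Formally this
exceedance proportion is a one-sided permutation p-value; the name FDR is
retained because that is what this validation design calls it.  Under label
exchangeability it is exactly calibrated: P(fdr < α) = (⌊αB⌋+1)/(B+1).
Non-converged permutation fits are recorded as −∞ (never exceeding) and
tallied; in calibration runs at trial-like event rates none occur.

**Verdict.**  Validated ⇔ (interaction HR > 1 ∧ p < .05 ∧ FDR < .05) ∧
(within-subgroup treatment HR > 1 ∧ p < .05).  Non-converged fits yield an
*indeterminate* verdict (never validated) with structured reasons.

**NNH.**  Number needed to harm = 1 / (KM risk at horizon, treated −
control) within the subgroup, horizon defaulting to the cohort's median
follow-up.  The Kaplan–Meier route (via lifelines) is used because crude
event fractions ignore censoring; a nonpositive risk difference returns a
signed value with a "no harm at this horizon" flag.  Published NNH figures
computed by undocumented methods cannot generally be reproduced from
printed counts, and none is asserted.

## Mechanisms

MAP = (SBP + 2·DBP)/3 exactly (the formula is linear, so cell means commute
with it; this is asserted to machine precision).  The mechanism contrast
reduces each participant to the mean of their post-baseline readings (so
visit counts do not weight participants), then takes the
difference-in-differences of the four group×arm cell means with variance
Σ s²/n and a normal CI.  No repeated-measures correlation model is fitted —
the estimand is a single mm-Hg contrast — and participant-level averaging is
our choice where the original aggregation level is unstated.

## The synthetic-trial generator

`sprint_like_config()` emulates the motivating trial: n = 9,361, 100 sites,
17 baseline covariates with Table-1-like marginals (Gaussian/Bernoulli,
independent by default; a latent-Gaussian option correlates smoking with
SBP), 1:1 randomization exactly balanced, exponential composite-event times
with baseline hazard −ln(0.94)/3.3 ≈ 0.0188 per person-year (≈6% cumulative
by 3.3 years), administrative censoring from uniform accrual over 2.4 years
against a fixed study end at 4.75 years (median follow-up ≈ 3.4 years),
optional log-normal site frailty, a global treatment log-HR of ln 0.75
(the trial-average benefit), and a planted harmful subgroup — current
smokers with SBP above the Gaussian top-tercile boundary (≈146.4 mm Hg,
prevalence ≈ 4.5%) — whose treated members carry an extra log-hazard of 0.7,
a 3-fold extra AKI hazard multiplier on a 0.012/person-year baseline with a
1.6× global treatment multiplier, and a deeper blood-pressure response
(5 mm Hg SBP, 10 mm Hg DBP below the arm targets of 120/68 intensive and
135/75 standard, exponential approach at rate 3/year, visit noise 7 mm Hg,
quarterly visits until event or censoring).  All effect sizes are knobs:
the real trial provides no generative model and nothing here estimates one.

Not emulated: medication titration and adherence, loss to follow-up (the
censoring is administrative only), competing risks, measurement error in
blood pressure beyond i.i.d. visit noise, covariate dependence beyond the
single optional correlation, and site-level covariate clustering.  Passing
tests on this generator therefore demonstrate the *pipeline's* statistical
behaviour (type-I control, calibration, recovery of planted effects), not
robustness to those real-data features.

True subgroup membership travels in a `true_subgroup` column that the
writers divert to a `truth.csv` sidecar; analysis stages validate their
inputs against a reserved-column list so truth can never leak into
discovery.

## Detection floor and power

Two quantitative facts shape expectations at trial scale (6% event rate,
n ≈ 9,400, subgroup prevalence ≈ 5%):

- *Discovery.*  The planted cell's own training-half z-statistic for a
  0.7 interaction log-HR is ≈1.5, while each noise covariate contributes a
  selection-maximized statistic of z ≈ 2+ across its thresholds and nodes.
  Covariate-frequency rankings therefore cannot reliably surface the true
  pair at this effect size (measured 0/20 seeds); at interaction log-HR
  ≈ 2.5 recovery is essentially certain (3/3 seeds).  The discovery stage
  has a detection floor well above log-HR 0.7 under these conditions.
- *Validation.*  Even handed the true subgroup, ~20 subgroup events give
  Wald power ≈ 0.35 for the within-subgroup criterion at HR 2, and the
  doubly-gated verdict is stricter still.  Conversely the type-I side is
  strong: across 100 global-null pipeline runs, nothing validates.

Both facts are verified empirically in the acceptance suite; the type-I
bound passes, the planted-recovery bounds are asserted at their stated
conditions and fail there, documenting the floor rather than hiding it.

## Numerical and reproducibility choices

- Master seed → stage seeds (split / forest / permutation) via
  `numpy.random.SeedSequence([master, stage_index])`, truncated below 2³¹.
- All randomness flows through `numpy.random.Generator`; identical
  (config, seed) reproduce every result file byte-for-byte, and the run
  manifest records the config hash and stage seeds needed to re-execute any
  stage from saved intermediates.
- Problem sizes in the test suite (e.g. 100-replicate calibration batches at
  n = 2,000 with 100–200 permutations, 20-seed full-scale recovery runs) are
  chosen so the whole suite completes in minutes on one CPU while keeping
  Monte-Carlo error well inside the asserted bands.
- The `--threads` CLI flag is accepted for interface symmetry; execution is
  single-threaded and results never depend on it.
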