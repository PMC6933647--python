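# Methods

`bwsweight` implements a patient-centered weighting technique for composite
endpoints in two-arm trials.  The chain has four stages: (1) design a
best-worst scaling (BWS) choice experiment over a catalog of clinical
outcomes; (2) estimate outcome utilities from the responses with a
hierarchical Bayesian multinomial logit; (3) convert utilities into
component weights for a chosen composite; (4) compare treatment arms with
unweighted and weighted analyses.  A synthetic-data layer generates both
questionnaire responses and trial event data so that every stage is
testable end to end.

## Choice model

A choice set shows a respondent a subset S (here a triple) of outcome
labels; the respondent marks the best and the worst.  With part-worth
utilities u over the items, the sequential ("exploded") best-worst logit
factorizes each answer as

    P(best = b) = exp(u_b) / Σ_{j∈S} exp(u_j)
    P(worst = w | best = b) = exp(−u_w) / Σ_{j∈S, j≠b} exp(−u_j).

Utilities are identified only up to an additive constant within each choice
set, so a reference outcome ("perfect health") anchors the scale at zero.
The reference is eligible to appear in choice sets by default
(`include_reference=True`); this is what pins down the *location* of the
scale — a design that never shows the anchor identifies utilities only
relative to one another, which the package supports but flags (the
estimation tests demonstrate the resulting translation invariance).

## Design construction

`generate_design` builds a blocked design (versions × choice sets × items
per set; the default 4 × 10 × 3 mirrors the questionnaire the default
catalog comes from).  Construction is two-phase: a balanced deal — each
version's slot multiset gives every item ⌊slots/n⌋ appearances and hands
the remainder to the items with the lowest running overall counts, with
within-task duplicates repaired by cross-task swaps — followed by greedy
single-item swaps that lexicographically improve (overall frequency
spread, within-version spread, duplicate-triple count, D-criterion of the
column-centered dummy-coded task × item matrix).  `diagnose_design` reports
appearance counts, the pairwise co-occurrence matrix, the balance score
(max − min appearance count) and a relative D-efficiency normalized
against the best of 50 internally-seeded random designs (so the value lies
in (0, 1]).  This is an open re-implementation of the *behaviour* of
commercial MaxDiff designers (balance first, information second), not of
any proprietary algorithm.

## Synthetic respondents and trials

`simulate_choices` draws respondent part-worths β_r ~ MVN(μ, Σ) (reference
fixed at 0 for everyone), optionally adds covariate-specific shift vectors
to μ, assigns questionnaire versions round-robin, and answers every task
from the exploded logit above.  Defaults emulate the study conditions the
published utilities come from: 396 respondents, the published means as μ,
and 0.25·I heterogeneity where a test needs a between-respondent spread.

`simulate_trial` draws, per patient, an independent Bernoulli event for
each composite component with arm-specific probabilities, with event times
uniform over follow-up (365 days default) or truncated-exponential.  The
shipped event profile is the hypothetical 1000-patient pilon-fracture
trial (arms 498/502; per-component events 61/30/98 vs 91/55/42).  The
printed totals of that table (168/174) do not equal the per-component
sums; the generator targets the per-component counts and never hard-codes
totals.  Deliberately *not* modeled: competing risks, within-patient
correlation of component occurrence, item-position effects, respondent
inattention.  Passing tests therefore show correctness of the machinery
under these idealized conditions, not robustness to real-data artifacts.

## Hierarchical Bayesian estimation

`fit_hb_mnl` samples the mixed-logit posterior with one Gibbs scan per
iteration:

1. μ | β, Σ from its conjugate normal full conditional
   (prior μ ~ N(0, 100·I));
2. Σ | β, μ from its conjugate inverse-Wishart full conditional
   (prior Σ ~ IW(K+2, I), K the number of non-reference outcomes);
3. each β_r by one random-walk Metropolis-Hastings step
   β′ = β + ρ·L·z with L the Cholesky factor of the current Σ; ρ is
   multiplied by 1.1 (0.9) when the rolling acceptance rate is above
   (below) 0.30 — during burn-in only, frozen after.

Defaults are 10,000 iterations with 5,000 burn-in.  All respondents are
updated in one vectorized likelihood evaluation, so full-length chains on
396 respondents take well under a minute.  Respondents missing a best or
worst pick on any task are dropped entirely before fitting.

Reported utilities are posterior means with equal-tailed 2.5/97.5%
intervals of the μ draws.  Two anchoring modes exist: `fixed` keeps the
reference structurally at zero (degenerate reference interval); `shifted`
(default) centers each draw to sum to zero across all outcomes and then
point-shifts by the reference's posterior mean, which leaves the adverse
outcomes' posterior means identical to `fixed` while giving the reference
a non-degenerate interval around an exact zero mean.

Known bias: with only ~10 tasks per respondent the IW(K+2, I) prior is
informative relative to the β_r likelihood and pulls the heterogeneity
estimate toward its prior scale; overestimated heterogeneity inflates
|μ| slightly (typically ≲0.2, occasionally up to ~0.6 for the
least-severe outcomes, depending on the design realization).  Longer
chains reduce but do not remove this.  Covariates do not enter the upper
level of the sampler; heterogeneity is assessed post hoc (below).

`fit_pooled_mnl` maximizes the same likelihood with one shared β
(quasi-Newton, Wald intervals).  It initializes the sampler, serves as the
independent oracle in the homogeneity limit, and raises a named error when
the MLE is unbounded (detected by checking that doubling the fitted vector
does not improve the likelihood).

## Heterogeneity cascade

Respondent-level posterior-mean part-worths are the unit of analysis
throughout (matching mean ± SD stratified reporting).  Screening tests
each covariate for a joint shift of the whole utility vector via a
multivariate general linear hypothesis (Wilks' Λ with Rao's F
approximation — cross-checked against statsmodels MANOVA in the tests) at
the Bonferroni threshold α/m (0.05/10 = 0.005 for a ten-covariate screen);
survivors are re-tested jointly in one model at the same threshold.
Stratified follow-up uses one-way ANOVA per outcome, Tukey-Kramer
post-hoc pairwise comparisons (statsmodels, unequal group sizes
honored), and an equal-variance Student's t-test for experienced-vs-not
contrasts.  Testing posterior means in a second stage is a tractable
approximation to in-model interaction testing; it ignores posterior
uncertainty in each respondent's β_r, so its p-values are mildly
optimistic when respondent-level information is weak.

## Composite weights

For components with utilities u_1..u_k the weight of component a is

    W_a = (Σ_{j≠a} e^{u_j}) / (Σ_j e^{u_j}) = 1 − softmax_a(u),

computed with log-sum-exp stabilization.  For k = 3 this is exactly the
three-component conditional-logit form; the softmax-complement form is its
unique natural k-component generalization.  Identities that follow (and
are tested): Σ W_a = k − 1 exactly; each W_a ∈ (0,1); u_a < u_b ⇔
W_a > W_b; invariance to a common utility shift.  The denominator runs
over composite components only — the reference level is not a component.
Subgroup adjustment substitutes stratum-specific utilities before applying
the same formula.  `weight_sensitivity` propagates utility uncertainty by
sampling utilities independently from normals matched to each (mean, 95%
interval) — approximate, because posterior correlations between outcomes
are not carried — and reports percentile intervals of the weights.

On the published utilities (−5.69, −5.20, −3.29) the pilon composite
weights are 0.9268, 0.8805, 0.1928 — i.e. 0.93 / 0.88 / 0.19 at two
decimals.  The source table prints 0.20 for the third component; the
formula applied to the printed utilities gives 0.19 (0.1928), so the
printed 0.20 presumably reflects unrounded inputs and is not asserted
anywhere.

## Trial analyses

Orientation: ratios are arm A vs arm B; the Probability Index is
P(score_A < score_B) + ½ P(tie), so values below 0.5 favor A.

Unweighted: Fisher's exact test on the per-patient any-event 2×2 table
(conditional-MLE odds ratio, exact CI); Cox time-to-first-event (earliest
component event per patient, later events discarded); random-effects
logistic model (below) with unit weights; global rank with unit weights.

Weighted: (a) a marginal Cox model over repeated events — every component
event is a record from randomization carrying its component weight as an
observation weight, event-free patients contribute one censored record,
and the variance is cluster-robust by patient.  This formulation was
chosen over an Andersen-Gill gap-time layout because it reduces *exactly*
to the time-to-first-event model when weights are 1 and events are single,
while still letting every event count.  (b) The global rank test: each
patient's severity score is the sum (default; `max` available) of their
event weights, compared across arms by Wilcoxon rank-sum with midranks;
the effect is reported as the Probability Index with a placement-variance
(DeLong-type) normal CI.  (c) A weighted random-effects logistic model:
patient × component Bernoulli outcomes, arm fixed effect, patient random
intercept integrated by 25-node Gauss-Hermite quadrature, each
observation's log-likelihood multiplied by its component weight.  Weights
are normalized to mean 1 inside this fit so that constant weights reduce
exactly to the unweighted model; the Cox partial likelihood needs no such
normalization (it is scale-invariant in the weights).

`analyze_all` runs all seven entries (4 unweighted + 3 weighted) and
emits a comparison table; `km_coordinates` writes Kaplan-Meier-style
survival coordinates (first-event, and weighted event-record curves) as
plain text.

## Reproducibility and problem sizes

Every stochastic function is a pure function of (inputs, seed).  The
`pipeline` command fans one seed into stage seeds with
`numpy.random.SeedSequence(seed).spawn`, records a config hash in each
JSON artifact, and keeps timestamps out of artifacts so identical
invocations are byte-identical.  The test suite runs the estimation chain
at 2,000 iterations / 1,000 burn-in (posterior means at this length are
within ~0.1 of full-length chains on the default problem) and the
calibration studies at 500–2,000 replicates with 100–200 patients or
respondents; `scripts/acceptance.py` uses full 10,000-iteration chains and
five replicate 1000-patient trials, combining ratio effects on the log
scale.

## Limitations

- Case-1 (object) BWS only; no multi-attribute profiles, no positional
  effects.
- The utility location is identified only when the reference appears in
  choice sets; otherwise estimates are relative and the anchor is a
  reporting convention.
- The sensitivity analysis treats outcome utilities as independent.
- The two-stage heterogeneity cascade is an approximation to in-model
  interaction terms.
- The weighted analyses assume weights are known constants; uncertainty
  in the weights is addressed only through `weight_sensitivity`, not
  propagated into trial p-values.
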