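# Methods

## The game

Ten rounds of the investor–trustee exchange. Each round the investor receives
an endowment of 20 coins and transfers `a_I` of them; the transfer is tripled
and the trustee returns `a_T ∈ [0, 3·a_I]`. Monetary round outcomes are

    χ_I = (20 − a_I) + a_T        χ_T = 3·a_I − a_T,

so `χ_I + χ_T = 20 + 2·a_I` (money is conserved up to the experimenter's
tripling). Analysis runs on a coarse action grid: investments bin to
{0, 5, 10, 15, 20} via the ranges {[0,2], [3,7], [8,12], [13,17], [18,20]},
and returns bin to the rounded fractions {0, 1/6, 1/3, 1/2, 2/3} of the
tripled investment. Nearest-amount mapping with ties toward the lower
fraction; amounts are rounded half-up to whole coins; returns above 2/3 clamp
to the 2/3 bin so the five-point grid is closed.

## Preferences

Investor round utility combines multiplicative risk aversion ω on the kept
endowment with advantageous-inequality aversion (guilt) α:

    χ_I^true = ω·(20 − a_I) + a_T
    u_I = χ_I^true − α·max(χ_I^true − χ_T, 0).

The guilt comparison uses the ω-weighted outcome, exactly as the utility is
defined, even though this mixes subjective and monetary scales. The trustee
has no kept-endowment term (all his money flows through the exchange), hence
no ω: `u_T = χ_T − α_T·max(χ_T − χ_I, 0)`.

Grids: α ∈ {0, 0.4, 1}; ω ∈ {0.4, 0.6, …, 1.8}; theory-of-mind level
k ∈ {0…4}; planning horizon P ∈ {1…4}; irritability ζ ∈ {0, 0.25, …, 1};
irritation-awareness index q ∈ {0…4}; inverse temperature
β ∈ {1/4, 1/3, 1/2, 1}.

## The interactive agent

A level-k agent models its partner *exclusively* at level k−1 and maintains
discrete Bayesian beliefs over the partner's α and ζ; all other partner
parameters (ω, P, β, q) are assumed equal to its own. Action values come
from finite-horizon expectimax: immediate expected utility under the
marginal partner model, plus the softmax-weighted continuation value of the
advanced belief state, to depth min(P, rounds remaining). Choice is
`softmax(β·Q)`.

Irritation is a mixture weight w on a punitive policy (horizon 0, guilt
removed, no mentalizing — the investor keeps everything, the trustee returns
nothing). Each partner action at or below the model's probability-weighted
expectation escalates w by ζ (capped at 1); actions at or above it while
irritated de-escalate by ζ (floored at 0). The agent tracks the analogous
weight for each candidate partner-ζ, and the q index selects the prior over
partner ζ: a linear interpolation from a point mass on ζ=0 (q=0) to
(0, .05, .10, .15, .70) (q=4), which is strictly ordered by stochastic
dominance. The numerical prior vectors and the escalation predicate are not
dictated by the model's verbal description; both are configurable
(`ModelConfig`), and the defaults above are used throughout.

Specific resolutions of points the model statement leaves open:

- **Level −1 semantics.** The non-mentalizing investor evaluates
  `ω·(20 − a_I)` — guilt is dropped, consistent with the irritated state's
  removal of α, and the modal action is invest-0 for any ω > 0. The
  non-mentalizing *trustee model keeps its candidate* α_T — the likelihood
  of a return under each α_T is exactly what the investor's guilt inference
  consumes.
- **Expectation at the modelling boundary.** A level −1 partner model has no
  partner model of its own; its action expectation for the irritation
  predicate falls back to the uniform mean over legal actions (investments:
  10 coins; returns: the mean of the legal return set).
- **Timing.** Both players' beliefs and irritation weights advance at end of
  round; a round-t action changes policy from round t+1 on.
- **Branch semantics.** Planning branches advance the full belief state,
  including the agent's own irritation weight (true interactive-inference
  semantics); a frozen-belief fast mode is available in `ModelConfig`.
  Irritated policy components are always myopic.
- **Skip rule.** Investments of 0 (the trustee cannot act) and 5 (returning
  nothing already achieves the fair split) are uninformative: Bayesian
  updating is skipped, irritation dynamics still advance.

The engine memoizes policies, values and belief updates keyed by parameters
and a belief signature rounded to 1e−12. A level-0 trustee model is
state-free (its level −1 investor model is candidate-independent, so nothing
it computes reads its belief state); the engine exploits this, and the test
suite verifies the engine against an independent brute-force enumerator that
takes no such shortcut (equality to 1e−9 on randomized states).

## Classification

A subject is classified by exhaustive grid search: the negative
log-likelihood of the ten observed investments under the effective
(irritation-mixed) policy, beliefs advanced along the observed history. Ties
(within 1e−9 nats) break on the lexicographic order (α, ω, k, P, ζ, q, β
ascending) and are reported. Probabilities below 1e−10 contribute a log-floor
and set a diagnostic flag; the softmax makes exact zeros impossible, so the
floor only guards underflow. For grids confined to k=0, P=1 a vectorised
path evaluates the whole (α, ω, ζ, q, β) product from one belief replay per
(β, q); it is asserted equal to the general path in the tests.

### Why restricted grids

On ten-round myopic trajectories several parameters act as behavioural
mimics of risk aversion: guilt α > 0 removes the value of keeping the
endowment and therefore labels near-ceiling investment; a pessimistic
irritability prior (high q) suppresses investment exactly as high ω does on
runs where the trustee is never observed. Under the full product grid these
mimics absorb variance that belongs to ω. The shipped analyses therefore
classify on:

- `DECOMPOSITION_GRID` (ω × β) for the variance decomposition of total
  investment,
- `DEMOGRAPHIC_GRID` (α × ω × β) for the demographic regressions, where
  guilt is itself an outcome,
- `RECOVERY_GRID` (ω × β × k ≤ 1 × P ≤ 2) for the recovery confusion
  analysis, which frees the structural axes most confusable with ω.

This is a deliberate desk-scale concession; with richer behaviour (more
rounds, multiple games per subject, mentalizing populations) the full grid
becomes identifiable.

## Recovery confusion analysis

Stage 1 draws 100 investors uniformly from the restricted family (with
stochastic-play temperatures β ≤ 1/2), simulates one dyad each against a
trustee drawn from the cohort's trustee distribution, and classifies them.
Stage 2 regenerates one dyad per subject from the *fitted* parameters,
refits, and tabulates conditional re-estimation frequencies. Regenerating
from fitted values mirrors a re-estimation check on classified subjects and
is the meaningful question for downstream regressions (are the labels
stable?). Direct truth-recovery from uniformly drawn generators was also
measured during development (~75% within one grid step): the shortfall is
concentrated in floor/ceiling trajectories (a subject who never invests is
consistent with every sufficiently high ω), a genuine identifiability limit
rather than an estimator defect.

## Synthetic cohort

The generator emulates a cross-sectional adolescent/young-adult cohort:
n = 784, age uniform on [14, 25], balanced sex (male = 0, female = 1), IQ
normal (100, 15), socio-economic adversity standard normal (higher = more
adverse). Parameter links operate on z-scored demographics:

- ω: latent grid index `3.5 − z_age − z_IQ + sex + 0.5·z_SES −
  0.3·(z_SES² − 1) + ε`, ε ~ N(0, 1.5²), rounded and clamped to the grid.
  Risk aversion spans the full grid in both sexes, decreases with age and
  IQ, is higher in females, and has opposing linear/quadratic adversity
  effects.
- α: ordered thresholds (1.7, 2.9) on `sex + ε`, ε ~ N(0, 1): ≈86% of
  subjects carry no guilt, full guilt is rare, and females are markedly more
  often inequality-averse.
- k = 0, P = 1 (myopic non-mentalizers, for tractability at cohort scale);
  ζ ∈ {0: .8, .25: .2}; q ∈ {0: .8, 1: .2}; β ∈ {1/4: .3, 1/3: .3, 1/2: .3,
  1: .1}. The β mix is weighted toward stochastic play so that per-choice
  likelihoods land in a realistic range (≈0.55 under the default fits,
  chance = 0.2) instead of the degenerate all-or-none trajectories that
  deterministic myopic agents produce.
- Trustees are cooperative guilt-averse agents (α_T ∈ {0.4, 1.0} equally,
  ζ_T = 0, β_T = 1, ω ≡ 1), standing in for the original experiment's
  database-driven algorithm that emulated healthy adult play. This is a
  stand-in, not a reproduction.

All of these are `CohortConfig` fields and can be overridden, including
setting every link coefficient to zero (in which case downstream demographic
regressions should — and in tests do — select near-empty models).

**What the generator does not emulate:** mentalizing or planning investors
(the cohort is myopic), session effects, within-subject retest structure,
the original trustee algorithm's database matching, and any real demographic
joint distribution. Passing tests therefore show that the pipeline recovers
structure *that the generator put in* under the model's own dynamics; they
do not validate the model against human data.

## Statistics

Demographics are z-scored before squaring; squared terms are squares of
z-scores. Linear models are ordinary least squares (statsmodels), with
adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1); fitted parameters enter as
ordinal numerics, and rank-deficient terms (e.g. parameters held constant by
a restricted grid) are dropped with a warning. Ordinal outcomes use the
proportional-odds cumulative-logit model (statsmodels `OrderedModel`);
slopes follow the convention that a positive coefficient shifts mass toward
higher categories, threshold p-values are not reported, and empty top levels
are dropped before fitting. Backward stepwise selection deletes the single
term whose removal most improves AIC (= 2p − 2·logLik, p counting
thresholds) until no deletion improves it; with the Gaussian log-likelihood
this ranks models identically to R's `stepAIC` on the same data. Kendall
correlations are tie-adjusted tau-b with asymptotic p-values (ties are
certain on discrete grids). Group comparisons are Welch two-sample tests
with a 95% CI on the mean difference and Cohen's d on the pooled SD.

## Problem sizes and determinism

Default analysis sizes: one n = 784 cohort for the decomposition, ten
replicate cohorts for the demographic-link study, 100 dyads for the recovery
analysis, 100 randomized states for the enumerator equivalence. Every
stochastic step takes an explicit seed (NumPy `default_rng`); identical
seeds give byte-identical output files.

## Known limitations

- The cohort generator's myopic investors make guilt a strong direct driver
  of investment; with the full fitting grid this lets α, ζ and q absorb
  risk-aversion variance (see "Why restricted grids"). The shipped grids are
  the desk-scale answer, not a general one.
- The trustee-side belief parameter about investor risk aversion is fixed at
  ω ≡ 1 and never fitted; all analysed subjects are investors.
- Irritation-prior vectors and the escalation predicate are reasonable
  defaults satisfying the stated ordering constraints, not uniquely
  determined by the model description.
- Levels k ≥ 2 and horizons P ≥ 3 are implemented and tested for
  correctness-by-construction (the enumerator covers k ≤ 1, P ≤ 2) but are
  computationally heavy; cohort-scale analyses do not use them.
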