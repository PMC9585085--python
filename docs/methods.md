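# Methods

## Task environment

One session is 300 trials in 12 blocks — three each of 20, 24, 26 and
30 trials — permuted uniformly at random per participant, so the
reversal interval averages 25 trials. Contingencies attach to the
response side (left/right seat): within a block one side yields an
avoidance outcome with probability `p_avoid_optimal = 0.8` and the
other with the complementary `p_avoid_nonoptimal = 0.2`; the optimal
side alternates deterministically at every block boundary. The first
block's optimal side is drawn uniformly. All schedule and outcome
randomness flows from explicit integer seeds through
`numpy.random.Generator` / `SeedSequence`, so every dataset is exactly
reproducible.

Trials can be invalid (no response within the time limit). No feedback
is shown on invalid trials, so learning agents perform no value update
there, and invalid trials contribute no likelihood term. Response
times are drawn from a lognormal (median 450 ms, σ = 0.3, clipped to
(100, 1500] ms) purely so the exclusion filters have something to act
on; no model reads them. Injected anticipations are valid responses
with RT drawn below the 100 ms cutoff.

## Learning models

Both RL variants track, per response side, an instrumental value Q
(initialized 0.5), a habit value H (initialized 0), and a combined
decision value D = w·H + (1 − w)·Q. Rewards are coded 1 for avoidance
and 0 for approach. The chosen Q moves toward the obtained reward with
learning rate α; under the counterfactual variant the unchosen Q
additionally moves toward the complementary outcome 1 − R with the
same α (no separate counterfactual rate is introduced). H updates on
every valid trial for both sides — chosen toward 1, unchosen toward 0,
at rate α_hab — so it is a pure choice kernel measuring perseveration.
Choices follow a two-option softmax on the D difference with inverse
temperature β ≥ 0; β = 0 gives 0.5 exactly.

Within a trial the order is: choice probability from the pre-feedback
state, then the Q update, then the H update, then D is recomputed.
The stated D initialization of 0.5 is nominally inconsistent with
D = w·H + (1 − w)·Q at H = 0 (which gives 0.5(1 − w)), but both sides
are equal either way so the first-trial choice probability, and hence
every likelihood, is unaffected; D is stored as 0.5 before the first
update and recomputed from the formula afterwards.

Useful identities the test suite enforces: counterfactual updating
preserves Q(left) + Q(right) = 1 exactly from the symmetric start
(the summed update is α(1 − ΣQ) = 0); with w = 0 the habit kernel is
choice-irrelevant and the model reduces to plain Q-learning softmax;
with α = 0, w = 1 it reduces to pure perseveration; the likelihood is
invariant to relabelling left/right throughout a dataset.

Numerical guards: per-trial log choice probabilities are floored at
`log(1e-12)` (`avoidrl.models.LOG_FLOOR`) so extreme β cannot produce
−inf inside the optimizer, and the softmax exponent is clamped before
`exp` overflow.

## MAP fitting

"Weighting the negative log-likelihood by priors" is implemented as
MAP: the objective is −LL − Σ log prior pdf, with β ~ Gamma(k = 1.2,
θ = 5) and α, α_hab, w ~ Beta(1.1, 1.1). The Beta(1.1, 1.1) densities
vanish at 0 and 1, so the objective is +∞ on the support boundary;
parameters are boxed to [ε, 1 − ε] with ε = 1e−6, and β to [ε, 30]
(the gamma prior's mass above 30 is negligible, and unbounded β yields
degenerate step-function likelihoods). Optimization is L-BFGS-B with
finite-difference gradients, objective tolerance 1e−8, from the single
fixed start (α, α_hab, w) = 0.5, β = 1. A descent contract is
enforced: if the optimizer ends above the start-point objective, the
start point is returned and flagged non-converged. An optional
multistart mode (`FitOptions(n_restarts=k)`) draws additional starts
from the priors for robustness studies; it is off by default. Both the
raw log-likelihood and the penalized objective are stored per fit, so
model comparison can be run on either scale; the comparison module
uses raw log-likelihoods by default (the compared models carry equal
parameter counts, and the baseline none).

Posterior-predictive simulation is generative by default: the fitted
agent is re-run on the subject's own block schedule with fresh choice
and feedback draws, 100 repetitions, and per-trial indicators are
averaged. A conditional variant (replaying the observed choices and
feedback and reporting the model's per-trial choice probabilities) is
exposed via `conditional=True`; the generative reading is the default
because it tests the model as a data generator rather than a one-step
predictor. Note that posterior-predictive agreement across subjects
(Spearman ρ between real and simulated hit rates) is informative only
for heterogeneous cohorts: with identical generating parameters the
across-subject variance is schedule noise and the correlation is near
zero, whereas per-subject fits on a heterogeneous cohort reproduce the
ordering at ρ ≈ 0.9 in the test suite.

## Synthetic cohorts

The default population mixes two counterfactual-learner profiles in
154:60 proportions — the median fitted parameters of participants
without and with an explicit avoidance strategy: non-explicit
α = 0.50, α_hab = 0.084, β = 1.50, w = 0.78; explicit α = 0.74,
α_hab = 0.06, β = 1.84, w = 0.63. These defaults reproduce the
qualitative group differences (higher hit rates and steeper hyperbolic
learning curves in the explicit group) but not, and not intended to,
any single-subject statistics of real data: real participants vary
continuously in parameters, strategy is self-reported rather than
latent, and real choice sequences contain structure (fatigue, pauses,
stimulus identity effects) the generator does not emulate. Passing
tests on these cohorts demonstrate internal consistency of the
simulator–fitter–analysis chain, not external validity.

The subjective-evaluation generator emits 40 scenario instances per
subject (10 identity pairs × 2 anger positions × 2 seat positions; 20
approach, 20 avoidance) with rating = 25.34 + 37.05·[avoidance]
+ subject intercept + residual noise, truncated to [0, 100]. The
condition means are the study-level defaults; the dispersions
(subject SD 8, residual SD 6) are package choices set small enough
that truncation at 0 biases the approach mean by well under 0.1
rating units, keeping the generator's recovered means faithful to its
configuration. Stimulus identity sequencing constraints are out of
scope, so pair identity is a label only.

## Behavioural analyses

Hits are choices of the currently optimal side, scored over valid
trials, with an exact two-sided binomial test against 0.5 per subject.
Learning curves pool the first 20 trials after each reversal
(within-block index 0–19) and regress hit on the hyperbolic predictor
hyp(x) = 1 − 1/(1 + x) by binomial GLM with subject-clustered standard
errors. Per-subject summaries plus pooled clustered GLMs deliberately
replace maximal random-effects mixed logistic models: the directions
of effects are preserved while the inferential machinery stays
off-the-shelf; mixed-model odds ratios are therefore not comparable
quantities here. A pooled-hit curve that is exactly constant (oracle
cohorts) is returned as a degenerate fit with slope 0 rather than a
separation failure.

Repetition is choice_t = choice_{t−1} over consecutive valid pairs,
computed across block boundaries (reversals are invisible at choice
time); win-stay is repetition after avoidance, lose-shift is one minus
repetition after approach. The subjective-value analysis attaches to
each eligible pair the subject's mean rating (divided by 100) of the
scenario class received at t−1 — mean over the 20 matching-class
instances, with exact-stimulus matching left to callers who carry
per-stimulus ratings — and fits a pooled clustered logistic of
repetition on that value.

Exclusions: valid-response rate < 90% of trials, or anticipations
(valid RT < 100 ms) exceeding 15% of valid responses. Parameter-
covariate screens use Spearman ρ with Benjamini–Hochberg FDR applied
matrix-wide by default (per-parameter scope available), constant
columns flagged undefined.

## Model comparison

The Friedman test uses within-subject midranks, the classic rank-sum
statistic with the standard tie-correction divisor, df = k − 1; it
matches `scipy.stats.friedmanchisquare` to 1e−9 on random matrices.
Pairwise contrasts are two-sided Wilcoxon signed-rank tests, exact for
n ≤ 25 without ties and normal-approximated with continuity correction
otherwise, Bonferroni-corrected by the number of pairs; group
contrasts are Mann-Whitney tests. Effect sizes are rank-biserial
correlations throughout: (W+ − W−)/(W+ + W−) for paired designs and
2U/(n₁n₂) − 1 for unpaired. Rank-sum statistics are reported alongside
the z approximation because at cohort sizes above 200 the two scales
differ by orders of magnitude and published values are typically rank
sums.

## Recovery studies and problem sizes

Parameter recovery simulates subjects at known parameters (α, α_hab, w
from the priors; β from the gamma prior truncated to [3, 10], since
rank recovery is only meaningful when choices carry signal), refits,
and reports Spearman correlations and mean signed biases; at 50
subjects × 300 trials the fitted α and w rank-correlate with truth at
ρ ≈ 0.7 and ≈ 0.9. Model recovery draws generating parameters from
moderate-signal ranges (α ∈ [0.4, 0.8], α_hab ∈ [0.05, 0.2],
β ∈ [2, 5], w ∈ [0.2, 0.5]) and counts wins by penalized objective
with the random model's fixed −LL as the parameter-free baseline;
counterfactual-generated cohorts are majority-recovered and
random-generated cohorts are majority-won by the baseline. The test
suite runs these studies at 16–50 subjects — sizes chosen as the
smallest at which the rank statistics are stable across seeds — and
`scripts/acceptance.py` pools 100 sessions (30,000 trials) per
environment statistic.

## Known limitations

Two response options only; no hierarchical (group-level) estimation,
no information-criterion or Bayesian model selection; response times
are generator scaffolding, not modelled; subjective values are static
per subject (ratings are collected once, so within-task drift in
outcome value is invisible); the strategy-group label is an input of
the generator, not something the package infers from behaviour.
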