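# Methods

This note documents the models, generative conventions, numerical choices,
and known limitations of `epinc`. It is written for someone who wants to
understand *why* the package behaves as it does, not just what it computes.

## Task model

Two decks pay 0–100¢ on a 20¢ grid. At any moment one deck is lucky
(expected value 63¢) and the other unlucky (37¢); the assignment reverses
at unsignaled bout boundaries. Environments are 160-trial blocks: low
volatility has 8 bouts drawn uniformly from 15–24 trials, high volatility
16 bouts from 6–14. Bout lengths are drawn independently and then repaired
by ±1 steps (respecting the bounds) until they sum to exactly 160, then
shuffled; whether the original design constrained bout sums this way is
not documented, and the repair rule is our choice — it preserves both the
stated bounds and the stated per-block trial count. The luckiness
(re)assignment at block onset is counted as a reversal event, so the
number of reversal events equals the number of bouts (8 and 16);
reversal-aligned analyses use interior boundaries only, where a genuine
flip occurs.

Outcomes are drawn without replacement from per-deck pools rebuilt at
every reversal. The lucky pool holds 40 values with multiplicities
(2, 4, 7, 8, 11, 8) over (0, 20, 40, 60, 80, 100)¢ — the composition is a
free design choice constrained by an exact 63¢ mean on the 20¢ grid and a
pool at least as long as the longest bout; the unlucky pool is its
100¢ complement (exact 37¢ mean). The implied outcome SD, σ_n = 0.2883
dollars, is treated as known by all learners, since it is fixed by design
rather than estimated.

In the combined task each card carries a trial-unique object. An object
chosen exactly once may reappear on its original deck 9–30 trials after
that choice. Reappearance is gated and sampled in the order: (gate) a
Bernoulli(0.6) draw on every trial whose eligible-candidate set is
non-empty; (i) candidates must have a payout still present in their deck's
current outcome pool (choosing the reappearing card then consumes that
pool entry, which is what keeps realized deck values unskewed); (ii) if
any candidate's value is incongruent with its deck's current luckiness,
the candidate set narrows to those; (iii) if the running mean of old-object
values shown so far exceeds 50¢ the lowest-valued candidate is shown,
otherwise one is sampled uniformly. Whether the original task evaluated
the gate before or after the congruency step is not documented; we gate
first (the most literal reading), so the measured firing rate on eligible
trials estimates 60%. Note that step (ii) *by construction* anti-correlates
an old object's value with its own deck's current expected value (that is
what produces conflict trials); what stays uncorrelated is object value
and which deck *color* is lucky.

The memory test holds 48 old probes (per environment: 4 per payout value,
drawn from objects the subject actually chose) and 32 new probes. Cells
short of 4 objects backfill from the nearest-value cell in the same
environment with a logged warning rather than failing, so short or unlucky
sessions still produce a complete test.

## Learning filters

All filters work in [0, 1] dollar units internally, start from symmetric
uninformative states (deck values 0.5, RU 0.5, uniform context posterior),
and reset at environment-block boundaries — a new casino re-randomizes
luckiness, so carrying beliefs across the boundary has no generative
justification. Environment-indexed parameters (two learning rates or two
hazard rates) switch at the same boundaries.

The reduced Bayesian filter implements the canonical
changepoint-approximation recursion: changepoint probability as a
hazard-weighted density ratio with predictive variance σ_n²/(1−τ),
learning rate α = Ω + (1−Ω)τ, a delta-rule value update of the chosen deck
only, and the RU recursion mixing change and no-change variances
(ν = Ωσ² + (1−Ω)τσ² + Ω(1−Ω)[δ(1−τ)]², τ' = ν/(ν+σ²)). A single RU/CPP is
shared across the two decks — uncertainty is about "deck value" as a
whole — while value estimates are per deck. The exact parameterization of
the original implementation is not fully documented; these forms are the
standard ones for this model family and are exposed as plain functions
(`compute_cpp`, `compute_learning_rate`, `rb_step`) so alternates can be
swapped in.

**Approximation quality.** The reduced filter is not exact Bayes. Against
an exact grid changepoint filter at design conditions (H = 0.1,
σ_n = 0.2883), the mean absolute value error is ≈ 0.05 with transient
worst-case deviations up to ≈ 0.3 immediately after changepoints, where the
exact posterior is bimodal and a single-Gaussian collapse cannot follow
it; RU is systematically coarser (mean error ≈ 0.1). The test suite pins
this envelope. Implementation correctness is established separately, by
exact oracles: the CPP density ratio against direct density evaluation,
the contextual-inference filter against exhaustive path enumeration
(1e-10), and limit/monotonicity properties.

The CI model is a two-state forward HMM over "which deck is lucky" with
switch probability H and Gaussian emissions at the design means; RW1Q
updates a single luckiness estimate with signed evidence. Neither carries
an RU series.

Filter series are aligned to choice time: deck values and RU reported for
trial *t* are the pre-outcome state (what could have driven the choice);
CPP, APE, learning rate, and post-update RU derive from trial *t*'s
outcome. "Encoding-time" RU for an object is the post-update RU on the
trial its payout was revealed.

## Synthetic agents

Agents couple an RB2H filter (default true hazards 0.05/0.10, matching the
two environments' generative rates of 1/20 and 1/10) to a combined choice
policy with weights w0 (deck bias, 0), w_deck (4.0 per dollar of value
difference), w_old (0.3 on the ±0.5 old-indicator), w_oldval (3.0 on the
±0.5 coded object value), w_oldval_env (1.0), and w_oldval_ru. The
arbitration weight w_oldval_ru is defined in *standard units*: it
multiplies (OldVal/0.31)·((RU−0.33)/0.09), where 0.31, 0.33, and 0.09 are
the design-typical SD of the coded old-object value and the mean and SD of
the RB filter's RU trajectory under the task design, measured once from
the generative design itself. This makes the generative weight directly
comparable to the standardized coefficient the fitted combined choice
model reports (default 1.0). All other generative covariates are raw; the
fitting stage z-scores.

Episodic imperfection is a two-parameter fidelity model: an old object is
recognized with probability p_recognize (default 0.8) and its remembered
value perturbed by Gaussian noise (SD 15¢); unrecognized objects exert no
episodic influence. Objects the agent engaged episodically during the task
receive a recognition-logit boost (1.0) and halved value noise at the
subsequent-memory test — the minimal mechanism that yields the
choice-type/memory correlations the analyses probe. Reaction times are
log-normal (base 750 ms) with additive log-scale effects of switching
(0.10), RU (0.04 per SD), and episodic engagement (0.08), noise SD 0.20.
No published generative RT or memory-response model exists for this task;
these are stand-ins for testing the analysis pipeline, not claims about
data.

Cohorts draw each agent's parameters independently around the group means
(logit scale for probabilities and hazards, log scale for the inverse
temperature), and counterbalance the combined task's environment order by
subject parity. In the deck-only task the low-volatility block always
comes first.

## Hierarchical inference

Learning-model parameters are fit to the deck-only task with partial
pooling: subject-level parameters on transformed scales (logit for hazards
and learning rates, log for the inverse temperature) are Normal around
group means, with Normal hyperpriors on the means (location −2.2 ≈ 0.1 for
learning parameters, 1.6 ≈ 5 for temperature; scales 1.5 and 1.0) and
inverse-gamma (2.5, 1.0) hyperpriors on the group variances — weakly
informative on the natural scales.

The sampler is Gibbs-within-Metropolis: per-coordinate random-walk
Metropolis updates of every subject's parameters simultaneously (subjects
are conditionally independent given the group level), with proposal scales
adapted toward 0.44 acceptance during warmup, and exact conjugate draws
for group means and variances. Likelihoods are numba-compiled; chains are
fully determined by the seed. Defaults are 4 chains × (1000 warmup + 1000
draws); a reduced configuration (2 × 400+400) is provided for desk-scale
recovery runs. Convergence is summarized by split-R̂ and ESS (via arviz);
R̂ ≥ 1.01 raises a warning and flags the fit, never silently passes. The
same machinery fits the mixed-effects regressions (logistic and linear):
random-effect terms are subject-level coefficients centered on the fixed
effect with conjugate Normal/inverse-gamma group updates, fixed-only terms
get Normal(0, 5²) priors, and linear models carry a conjugate residual
variance.

Transfer to the combined task uses subject-level posterior means on the
natural scale (medians by flag) to drive the filters out of sample.

k-fold leave-subjects-out ELPD uses one deterministic fold assignment per
seed shared across model variants. Held-out subjects are evaluated at the
group level: for each retained posterior draw, subject coefficients are
sampled from that draw's group distribution, and the pointwise predictive
density is averaged across draws before taking logs. The SE is the usual
√(N·var) of pointwise lppd. Ties are reported with their SEs
(`ModelComparison.is_decisive`), never silently broken.

## Behavioral analyses

Exclusions: (i) responses below the group mean minus 1 SD, (ii) mean RT
below the group mean minus 1 SD, (iii) a non-positive subject-level slope
(fixed + random) of TSinceRev×Env in the post-reversal logistic model on
deck-only trials 1–5 after each reversal event. On synthetic reduced
Bayesian agents criterion (iii) is a weaker classifier than one might
expect: agents with equal hazards still adapt learning rates through
changepoint probability, and the short bouts of the volatile block give
all agents a structural head start after reversals; the slope does order
cohorts correctly by their true hazard adaptation.

Incongruent trials are old-object trials where the object's value (> 50¢
or < 50¢) opposes its deck's *model-derived* luckiness; 50¢ objects and
value-tied trials are excluded (luckiness undefined). EBCI is 1 when the
episodic response was given. For recognition scoring, "Definitely/Probably
Old" count as old responses and "Don't Know" as new — a conservative,
deterministic collapse. d′ uses the log-linear correction
z((h+0.5)/(n+1)) − z((f+0.5)/(m+1)); the per-environment variant shares
the false-alarm rate. Predictors flagged for standardization are z-scored
pooled per dataset (the standardization set is otherwise ambiguous; a flag
exposes it). RU is mean-centered per dataset in the RU analyses.
RUDifference is post-reversal RU minus the mean of the four pre-reversal
trials, so the expected signature is a positive spike at t+1 decaying by
t+4.

## Problem sizes in the test suite

Recovery checks run at desk scale as the package's own validation design:
40-agent cohorts, 20 replicates for hazard-rate recovery (true H = 0.05 /
0.10) and for each choice-weight calibration condition (true arbitration
weight 0.5 and 0), reduced samplers (2 chains, 250–400 warmup/draws), and
k = 5 folds for ELPD comparisons. Oracle checks use 100 random 200-trial
sequences (grid filter) and ≤ 10-trial sequences (path enumeration).

## Known limitations

* The generator omits stimulus images, fixation jitter, payment logic, and
  any within-session parameter drift, lapses, or primacy/recency memory
  structure; passing tests validate the pipeline's statistical behavior on
  this idealized generative world, not on human data.
* The reduced Bayesian filter is an approximation (envelope above); its RU
  overstates exact posterior uncertainty in stable stretches.
* The random-walk Gibbs sampler mixes more slowly than gradient-based
  samplers on strongly correlated posteriors; reduced-draw runs can show
  R̂ above 1.01 (they are flagged). Reported recovery checks depend only
  on group-level summaries, which are stable at these sizes.
* Held-out ELPD marginalizes random effects by Monte Carlo over the group
  distribution; with few retained draws the lppd of extreme subjects is
  noisy, which the reported SE reflects.
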