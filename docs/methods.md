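# Methods

## Model

The agent is a minimal dynamical model of rule selection in the Wisconsin
Card Sorting Test. Perception and card placement are abstracted to exact
symbolic attribute matching: the four target cards carry each attribute
value exactly once, so for every card and rule there is a unique correct
target, and the only sources of behavioural variability are the
working-memory dynamics and the stochastic selector. This abstraction is
deliberate — the four free parameters all act on rule selection, not on
perception — but it also means the model has no perceptual lapses (see
Limitations).

Working memory holds one priority per rule, `p_i ∈ [0, 1]`, initialised at
the baseline `b = 0.5`. The per-trial loop is:

1. **Decay.** `p_i ← p_i + φ·(b − p_i)` for every rule. φ ∈ [0, 1] is the
   forgetting speed; φ = 1 collapses memory to baseline each trial.
2. **Inner-speech rehearsal.** The component carries the last evaluated
   rule and its valence (+1 after positive feedback, −1 after negative)
   and re-applies it to working memory: `p_r ← clip(p_r + λ·v)`. The
   rehearsal is applied *after* the decay step, so the bias enters
   selection undamped. This ordering is essential to the component's
   compensating role: if the bias were written before decay, it would be
   multiplied by (1 − φ) before ever being used and high-decay agents
   could not benefit from inner speech, contrary to the compensation
   property the model is meant to exhibit (verified by a one-sided
   contrast in the test suite).
3. **Selection.** Boltzmann softmax on the raw priorities,
   `P(i) ∝ exp(p_i/τ)`, τ ∈ (0, 1]. One uniform variate per trial.
4. **Motivational update.** A Rescorla–Wagner pair on the selected rule
   only: reward pulls toward 1 with a fixed gain α = 0.8,
   `p_s ← p_s + α·(1 − p_s)`; punishment pulls toward 0 at the
   error-sensitivity rate, `p_s ← (1 − μ)·p_s`. The reward gain is an
   architectural constant shared by all groups — the model has exactly
   four free parameters — and was calibrated once, jointly with the
   functional forms below, against the full set of 32 published group
   index means before the test suite was frozen.

Priorities are clipped to [0, 1] after every update so τ retains a stable
meaning across regimes.

### Why these functional forms

The parameter semantics (decay speed, punishment magnitude, selection
randomness, bias strength) admit several functional forms. The shipped
choices are the simplest ones that reproduce the qualitative structure of
all eight published regimes simultaneously:

* a motivational component that updates on punishment only leaves the two
  λ = 0 regimes with no channel that ever favours the correct rule; those
  agents complete ~0 categories while their published profiles complete
  ~5. A symmetric RL pair (reward toward 1, punishment toward 0) restores
  them without adding a free parameter;
* multiplicative punishment (toward 0 at rate μ) mirrors the reward form
  and outperformed the additive variant across regimes, mainly by
  lengthening perseverative bouts in the low-μ regimes;
* the rehearsal ordering of the inner-speech bias (point 2 above).

Each form is isolated behind a single operation so alternates remain a
one-line change.

## Scoring conventions

* **CC** — categories completed (runs of 10 consecutive positive
  feedbacks), capped at 6.
* **PE** — an error whose selected rule repeats the rule selected on the
  immediately preceding trial (choosing an incorrect, previously chosen
  rule). This convention produces perseverative errors within the first
  category as well, which the near-random high-τ regime requires (its
  published profile has PE ≈ 25 with CC ≈ 0.1).
* **NPE** — every other error.
* **FMS** — an error breaking a trailing run of ≥ 5 correct responses
  whose selected rule matched the current rule (unambiguously
  principle-consistent sorts; a lucky match obtained with a wrong rule
  resets the run), counted once per broken run. FMS errors are also
  classified PE or NPE, so PE + NPE always equals the error count.
* A "lucky match" (ambiguous card, wrong rule, same target) counts toward
  the 10-correct criterion: feedback is the only signal the environment
  emits, and the criterion is feedback-driven.

## Fitting

`simulate_group(params, n, seed)` runs n sessions with per-session seeds
derived deterministically from the master seed and summarises each index
with mean and population SD (population rather than sample SD is an
arbitrary fixed choice, documented so the alternative is a one-line
change). The search objective is the unweighted MSE over the four index
means; dispersions are not part of the objective. `random_search` samples
configurations uniformly in [0, 1]³ × [0.01, 1] (τ bounded away from 0),
evaluates every configuration on the same bank of session random streams
(common random numbers — the ranking becomes deterministic and
between-configuration noise cancels), and returns results sorted by MSE
with ties broken by sampling order. Defaults: 2000 configurations,
n equal to the target group's sample size.

Identifiability caveat: group profiles alone admit parameter trade-offs
(e.g. between φ and λ). The parameter-recovery experiments therefore
assert ordering — targets generated at λ = 0.0 vs 0.4 must yield
correctly ordered recovered λ — not point identification.

## Statistics

Group contrasts use two-sided Welch t-tests (robust to the unequal group
sizes, e.g. 9 vs 10), one-way ANOVA across the four age groups of a
condition with all six pairwise post-hoc Welch tests when the ANOVA is
significant at α = 0.05, and Bonferroni correction with explicit family
sizes (8 for the per-group PE-vs-NPE contrasts, 6 for post-hocs, 4 for
the per-age control-vs-ASC contrasts). Family sizes are arguments, not
constants, because only thresholded p-bands are published and the exact
correction families are not. Zero-variance-in-both-samples contrasts
(possible: one published SD is 0.0) fall back to an exact equality check,
reported with a degenerate flag. PE-vs-NPE is tested unpaired; a paired
test is arguable since both counts come from the same sessions, but the
unpaired Welch form is the conservative default.

## Simulation engine

The object-level API (`run_session`) and a compiled batch kernel share
the same per-session random stream layout (two 64-card permutations, then
128 selection uniforms) and the same floating-point operation order, so
their profiles agree bit-exactly; the test suite asserts this. Searches
and acceptance checks use the kernel (~10⁴ sessions/s on one CPU); traces
and trial logs come from the reference path.

## Problem sizes

Defaults used by the test suite: 200 sessions per regime for profile
reproduction and regime signatures, 250 per arm for the behavioural
gradient contrasts, 2000 configurations × 50 sessions × 10 replicates for
parameter recovery, 1000 scripted sessions for scorer/oracle agreement,
and 500 replicate pairs (n = 13 each) for the type-I-error check. These
sizes give sub-percent Monte-Carlo error on the asserted quantities.

## What the synthetic data does and does not emulate

Simulated groups are i.i.d. sessions of a single parameter configuration.
Real groups mix heterogeneous individuals, carry within-participant
learning and fatigue effects across the session, and are scored by human
administrators applying Heaton's ambiguity rules to card placements
rather than to known rule selections. Passing tests therefore show that
the model family and fitting machinery behave as specified under the
model's own generative assumptions — not that those assumptions exhaust
the structure of human WCST data.

## Limitations

* The published model's update equations are not printed in the source
  material's main text; the forms here are a declared reconstruction. The
  published group profiles are reproduced within one published SD for
  29 of 32 index means (at n = 1000 precision). The three misses are all
  NPE means in sharply greedy regimes (control teenagers, ASC children,
  ASC young adults — the latter two marginal), where simulated NPE runs
  low: without perceptual noise the agent commits too few
  non-perseverative errors once a rule is locked in. Reinstating a
  perceptual lapse rate would close this gap but conflicts with the
  near-zero published FMS of the ASC-young-adult regime and would add a
  fifth constant; the deviation is reported rather than hidden.
* CC saturates at 6 by design; profiles with more than six completions
  cannot occur.
* The fitted λ is identified only up to the trade-offs noted above.
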