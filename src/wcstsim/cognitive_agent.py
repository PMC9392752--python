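"""Rule-selection dynamics of the card-sorting agent.

The agent keeps a working-memory priority in [0, 1] for each of the three
sorting rules. Per trial:

1. every priority decays linearly toward a common baseline at speed φ;
2. the inner-speech component rehearses its last evaluation — the rule
   selected on the previous trial receives a bias λ·valence (valence is
   +1 after positive feedback, −1 after negative feedback); because the
   rehearsal is applied after the decay step it is not itself decayed
   before it is used, which is what lets inner speech compensate a fast
   working-memory decay;
3. a rule is drawn from a Boltzmann softmax over the priorities with
   temperature τ;
4. the card is placed on the target matching the selected rule's
   attribute and the operator returns feedback;
5. the motivational component applies a reinforcement-learning update to
   the selected rule's priority: toward 1 with a fixed gain on reward,
   toward 0 at rate μ on punishment.

μ, φ, τ and λ are the four free parameters; the reward gain is an
architectural constant shared by every simulated group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .wcst_task import (
    BehaviouralProfile,
    Classification,
    Feedback,
    Rule,
    TaskState,
    TrialRecord,
    advance,
    classify_trial,
    give_feedback,
    initial_state,
    score_session,
    shuffled_deck,
    targets_for,
)

__all__ = [
    "AgentParams",
    "WorkingMemory",
    "InnerSpeechSignal",
    "BASELINE",
    "REWARD_GAIN",
    "decay",
    "select_rule",
    "softmax_probabilities",
    "motivational_update",
    "inner_speech_update",
    "run_trial",
    "run_session",
    "session_random_stream",
]

#: Resting activation every priority decays toward; also the initial value.
BASELINE = 0.5

#: Fixed learning rate of the motivational component on positive feedback
#: (the pull of the selected priority toward 1). Architectural constant,
#: not a free parameter: the four free parameters are μ, φ, τ, λ.
REWARD_GAIN = 0.8


@dataclass(frozen=True)
class AgentParams:
    """The four free parameters of the agent.

    mu : error sensitivity — punishment learning rate (μ).
    phi : memory refresh / forgetting speed — decay toward baseline (φ).
    tau : distractibility / explorative tendency — softmax temperature (τ).
    lam : inner-speech contribution — rehearsal bias magnitude (λ).
    """

    mu: float
    phi: float
    tau: float
    lam: float

    def __post_init__(self) -> None:
        validate_params(self.mu, self.phi, self.tau, self.lam)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.mu, self.phi, self.tau, self.lam)


def validate_params(mu: float, phi: float, tau: float, lam: float) -> None:
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")


@dataclass
class WorkingMemory:
    """Three rule priorities plus their common baseline, all in [0, 1]."""

    priorities: np.ndarray = field(
        default_factory=lambda: np.full(3, BASELINE, dtype=float)
    )
    baseline: float = BASELINE

    def copy(self) -> "WorkingMemory":
        return WorkingMemory(self.priorities.copy(), self.baseline)


@dataclass(frozen=True)
class InnerSpeechSignal:
    """What inner speech rehearses: the last evaluated rule and its valence."""

    rule: Rule
    valence: int  # +1 positive feedback, -1 negative

    def __post_init__(self) -> None:
        if self.valence not in (-1, 1):
            raise ValueError("valence must be +1 or -1")


def decay(wm: WorkingMemory, phi: float) -> WorkingMemory:
    """Linear decay of every priority toward the baseline at speed φ."""
    p = wm.priorities + phi * (wm.baseline - wm.priorities)
    return WorkingMemory(p, wm.baseline)


def softmax_probabilities(wm: WorkingMemory, tau: float) -> np.ndarray:
    """Boltzmann distribution over rules: p_i ∝ exp(priority_i / τ)."""
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    logits = wm.priorities / tau
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def select_rule(wm: WorkingMemory, tau: float, rng_or_u) -> Rule:
    """Draw a rule from the softmax; consumes exactly one uniform variate.

    ``rng_or_u`` may be a numpy Generator or a pre-drawn uniform in [0, 1).
    """
    u = rng_or_u if isinstance(rng_or_u, float) else float(rng_or_u.random())
    probs = softmax_probabilities(wm, tau)
    acc = 0.0
    for i in range(3):
        acc += probs[i]
        if u < acc:
            return Rule(i)
    return Rule(2)


def motivational_update(
    wm: WorkingMemory, selected: Rule, feedback: Feedback, mu: float
) -> WorkingMemory:
    """Reinforcement-learning update of the selected rule's priority.

    Reward pulls toward 1 with the fixed gain ``REWARD_GAIN``; punishment
    pulls toward 0 at the error-sensitivity rate μ.
    """
    out = wm.copy()
    p = out.priorities
    if feedback is Feedback.POSITIVE:
        p[selected] = min(1.0, p[selected] + REWARD_GAIN * (1.0 - p[selected]))
    else:
        p[selected] = max(0.0, p[selected] - mu * p[selected])
    return out


def inner_speech_update(
    wm: WorkingMemory, signal: InnerSpeechSignal, lam: float
) -> WorkingMemory:
    """Apply the rehearsed valence bias: p_rule ← clip(p_rule + λ·valence)."""
    out = wm.copy()
    p = out.priorities
    p[signal.rule] = min(1.0, max(0.0, p[signal.rule] + lam * signal.valence))
    return out


def session_random_stream(seed: int, rng: np.random.Generator | None = None):
    """Deck order and per-trial selection uniforms for one session.

    The layout (two 64-permutations, then 128 uniforms) is shared with the
    batch engine so that both paths are bit-identical for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    deck = shuffled_deck(rng)
    uniforms = rng.random(128)
    return deck, uniforms


def run_trial(
    state: TaskState,
    wm: WorkingMemory,
    params: AgentParams,
    u: float,
    signal: InnerSpeechSignal | None,
):
    """One complete trial; returns (record, next state, next wm, next signal)."""
    if state.terminated:
        raise RuntimeError("cannot run a trial on a terminated session")
    card = state.remaining_deck[0]

    wm = decay(wm, params.phi)
    if signal is not None:
        wm = inner_speech_update(wm, signal, params.lam)
    sel = select_rule(wm, params.tau, u)
    chosen = targets_for(card)[sel]
    fb = give_feedback(state, card, chosen)
    wm = motivational_update(wm, sel, fb, params.mu)
    record = TrialRecord(card=card, selected_rule=sel, chosen_target_index=chosen, feedback=fb)
    record = classify_trial(record, state)
    next_state = advance(state, record)
    next_signal = InnerSpeechSignal(sel, 1 if fb is Feedback.POSITIVE else -1)
    return record, next_state, wm, next_signal


def run_session(params: AgentParams, seed: int):
    """Play one full task to termination.

    Returns ``(profile, records, trace)`` where ``trace`` is a list with
    one dict per trial holding the three priorities as they entered the
    softmax, the selected rule, the feedback and the classification —
    enough to plot working-memory activation traces with error markers.
    """
    deck, uniforms = session_random_stream(seed)
    state = initial_state(deck)
    wm = WorkingMemory()
    signal: InnerSpeechSignal | None = None
    records: list[TrialRecord] = []
    trace: list[dict] = []

    t = 0
    while not state.terminated:
        # re-create the pre-selection memory for the trace
        pre = decay(wm, params.phi)
        if signal is not None:
            pre = inner_speech_update(pre, signal, params.lam)
        record, state, wm, signal = run_trial(state, wm, params, float(uniforms[t]), signal)
        records.append(record)
        trace.append(
            {
                "trial": t,
                "priority_colour": float(pre.priorities[0]),
                "priority_shape": float(pre.priorities[1]),
                "priority_size": float(pre.priorities[2]),
                "selected_rule": record.selected_rule.name.lower(),
                "feedback": record.feedback.value,
                "classification": record.classification.value,
                "fms_flag": record.fms_flag,
            }
        )
        t += 1

    return score_session(records), records, trace
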