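"""Wisconsin Card Sorting Test environment.

The simulated task mirrors the computerised Heaton-style administration:
two 64-card decks (full factorial over colour × shape × size, each category
taking four values), four fixed target cards on which every attribute value
appears exactly once, a hidden sorting rule that cycles colour → shape →
size after every run of ten consecutive positive feedbacks, and termination
after six completed categories or deck exhaustion.

Scoring produces the four standard behavioural indices:

* CC  — completed categories (capped at 6);
* PE  — perseverative errors: an error whose selected rule repeats the
  rule selected on the immediately preceding trial;
* NPE — every other error;
* FMS — failure to maintain set: an error that breaks a run of five or
  more consecutive correct responses whose selected rule matched the
  current sorting rule (lucky matches with a wrong rule do not extend
  the run).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Colour",
    "Shape",
    "Size",
    "Rule",
    "Card",
    "Feedback",
    "Classification",
    "TaskState",
    "TrialRecord",
    "BehaviouralProfile",
    "TARGET_CARDS",
    "RULE_SCHEDULE",
    "DECK_SIZE",
    "N_CATEGORIES_TO_COMPLETE",
    "CRITERION_RUN",
    "FMS_RUN_THRESHOLD",
    "full_deck",
    "build_task",
    "targets_for",
    "give_feedback",
    "advance",
    "classify_trial",
    "score_session",
]


class Colour(IntEnum):
    RED = 0
    GREEN = 1
    BLUE = 2
    YELLOW = 3


class Shape(IntEnum):
    TRIANGLE = 0
    CIRCLE = 1
    SQUARE = 2
    BAR = 3


class Size(IntEnum):
    SMALL = 0
    MEDIUM_SMALL = 1
    MEDIUM_LARGE = 2
    LARGE = 3


class Rule(IntEnum):
    """The three sorting categories."""

    COLOUR = 0
    SHAPE = 1
    SIZE = 2


class Feedback(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Classification(Enum):
    CR = "CR"
    PE = "PE"
    NPE = "NPE"


@dataclass(frozen=True)
class Card:
    """A stimulus card: one attribute per category."""

    colour: Colour
    shape: Shape
    size: Size

    def attribute(self, rule: Rule) -> int:
        return (self.colour, self.shape, self.size)[rule]


#: The four target cards. Each attribute value appears on exactly one
#: target, so for every deck card and rule there is a unique matching
#: target (the standard WCST key-card property).
TARGET_CARDS: tuple[Card, ...] = (
    Card(Colour.RED, Shape.TRIANGLE, Size.SMALL),
    Card(Colour.GREEN, Shape.CIRCLE, Size.MEDIUM_SMALL),
    Card(Colour.BLUE, Shape.SQUARE, Size.MEDIUM_LARGE),
    Card(Colour.YELLOW, Shape.BAR, Size.LARGE),
)

#: Hidden-rule schedule, repeated for the second block of three categories.
RULE_SCHEDULE: tuple[Rule, ...] = (Rule.COLOUR, Rule.SHAPE, Rule.SIZE)

DECK_SIZE = 128  # two full-factorial 64-card decks
N_CATEGORIES_TO_COMPLETE = 6
CRITERION_RUN = 10  # consecutive positive feedbacks per category
FMS_RUN_THRESHOLD = 5  # principle-consistent correct run length


def full_deck() -> list[Card]:
    """All 64 colour × shape × size combinations, in lexicographic order."""
    return [
        Card(Colour(c), Shape(s), Size(z))
        for c in range(4)
        for s in range(4)
        for z in range(4)
    ]


@dataclass
class TaskState:
    """Mutable-through-`advance` task bookkeeping for one session."""

    trial_index: int
    current_rule: Rule
    previous_rule: Rule | None
    consecutive_correct: int
    completed_categories: int
    remaining_deck: tuple[Card, ...]
    terminated: bool
    #: Length of the trailing run of correct responses whose selected rule
    #: matched the current rule (feeds the FMS flag).
    principle_run: int = 0
    #: Rule selected on the immediately preceding trial (feeds the PE flag).
    previous_selection: Rule | None = None


@dataclass(frozen=True)
class TrialRecord:
    card: Card
    selected_rule: Rule
    chosen_target_index: int
    feedback: Feedback
    classification: Classification | None = None
    fms_flag: bool = False


@dataclass(frozen=True)
class BehaviouralProfile:
    """The four WCST indices for one session."""

    cc: int
    pe: int
    npe: int
    fms: int

    def as_dict(self) -> dict[str, int]:
        return {"cc": self.cc, "pe": self.pe, "npe": self.npe, "fms": self.fms}

    def as_array(self) -> np.ndarray:
        return np.array([self.cc, self.pe, self.npe, self.fms], dtype=float)


def shuffled_deck(rng: np.random.Generator) -> tuple[Card, ...]:
    """Two independently shuffled 64-card decks, concatenated.

    Consumes exactly two 64-element permutations from ``rng``.
    """
    base = full_deck()
    order = np.concatenate([rng.permutation(64), rng.permutation(64)])
    return tuple(base[i] for i in order)


def build_task(seed: int) -> TaskState:
    """Seeded initial task state with a 128-card shuffled deck."""
    rng = np.random.default_rng(seed)
    return initial_state(shuffled_deck(rng))


def initial_state(deck: Sequence[Card]) -> TaskState:
    return TaskState(
        trial_index=0,
        current_rule=RULE_SCHEDULE[0],
        previous_rule=None,
        consecutive_correct=0,
        completed_categories=0,
        remaining_deck=tuple(deck),
        terminated=False,
    )


def targets_for(card: Card) -> Mapping[Rule, int]:
    """For each rule, the index of the unique target sharing that attribute."""
    out: dict[Rule, int] = {}
    for rule in Rule:
        for i, target in enumerate(TARGET_CARDS):
            if target.attribute(rule) == card.attribute(rule):
                out[rule] = i
                break
    return out


def give_feedback(state: TaskState, card: Card, chosen_target: int) -> Feedback:
    """Feedback from the external operator.

    Positive iff the chosen target is the one matching the *current* rule.
    A card that maps a wrongly-selected rule onto the same target as the
    current rule yields a lucky positive.
    """
    if not 0 <= chosen_target <= 3:
        raise ValueError(f"chosen_target must be in [0, 3], got {chosen_target}")
    correct = targets_for(card)[state.current_rule]
    return Feedback.POSITIVE if chosen_target == correct else Feedback.NEGATIVE


def classify_trial(record: TrialRecord, state: TaskState) -> TrialRecord:
    """Attach the CR/PE/NPE classification and the FMS flag.

    Must be called on the state as it was *before* `advance`.
    """
    if record.feedback is Feedback.POSITIVE:
        return replace(record, classification=Classification.CR, fms_flag=False)
    is_pe = (
        state.previous_selection is not None
        and record.selected_rule == state.previous_selection
    )
    cls = Classification.PE if is_pe else Classification.NPE
    fms = state.principle_run >= FMS_RUN_THRESHOLD
    return replace(record, classification=cls, fms_flag=fms)


def advance(state: TaskState, record: TrialRecord) -> TaskState:
    """Consume one classified trial and return the next task state."""
    if state.terminated:
        raise RuntimeError("cannot advance a terminated session")

    deck = state.remaining_deck[1:]
    rule = state.current_rule
    prev_rule = state.previous_rule
    cons = state.consecutive_correct
    cats = state.completed_categories
    prun = state.principle_run

    if record.feedback is Feedback.POSITIVE:
        cons += 1
        prun = prun + 1 if record.selected_rule == rule else 0
        if cons == CRITERION_RUN:
            cats += 1
            prev_rule = rule
            rule = RULE_SCHEDULE[cats % len(RULE_SCHEDULE)]
            cons = 0
            prun = 0
    else:
        cons = 0
        prun = 0

    terminated = cats >= N_CATEGORIES_TO_COMPLETE or len(deck) == 0
    return TaskState(
        trial_index=state.trial_index + 1,
        current_rule=rule,
        previous_rule=prev_rule,
        consecutive_correct=cons,
        completed_categories=cats,
        remaining_deck=deck,
        terminated=terminated,
        principle_run=prun,
        previous_selection=record.selected_rule,
    )


def score_session(records: Sequence[TrialRecord]) -> BehaviouralProfile:
    """Score a sequence of classified trial records.

    Pure function of the records: CC is recovered from the feedback
    stream (runs of ten), PE/NPE/FMS are counted from the attached
    classifications.
    """
    cc = 0
    run = 0
    pe = npe = fms = 0
    for rec in records:
        if rec.feedback is Feedback.POSITIVE:
            run += 1
            if run == CRITERION_RUN:
                cc += 1
                run = 0
        else:
            run = 0
            if rec.classification is Classification.PE:
                pe += 1
            else:
                npe += 1
            if rec.fms_flag:
                fms += 1
    return BehaviouralProfile(cc=cc, pe=pe, npe=npe, fms=fms)


def records_to_frame(records: Sequence[TrialRecord]):
    """Tab-separable trial log as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "trial": i,
                "colour": r.card.colour.name.lower(),
                "shape": r.card.shape.name.lower(),
                "size": r.card.size.name.lower(),
                "selected_rule": r.selected_rule.name.lower(),
                "chosen_target": r.chosen_target_index,
                "feedback": r.feedback.value,
                "classification": r.classification.value if r.classification else "",
                "fms_flag": r.fms_flag,
            }
        )
    return pd.DataFrame(rows)
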