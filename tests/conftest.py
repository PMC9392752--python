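"""Shared fixtures and the independent scoring oracle.

The oracle rescores a session from its bare (selected rule, feedback)
stream using a different algorithmic route than the package (run-length
groupby for category completions, vectorised pairwise comparison for the
error split), so scoring agreement is a genuine cross-check.
"""

from __future__ import annotations

from itertools import groupby

import numpy as np
import pytest

from wcstsim.wcst_task import (
    Rule,
    TrialRecord,
    advance,
    build_task,
    classify_trial,
    give_feedback,
    targets_for,
)


def oracle_rescore(sels: np.ndarray, pos: np.ndarray) -> tuple[int, int, int, int]:
    """Brute-force (cc, pe, npe, fms) from selection and feedback streams."""
    sels = np.asarray(sels, dtype=int)
    pos = np.asarray(pos, dtype=bool)
    n = len(sels)

    # CC: every contiguous positive streak of length L yields L // 10
    # completions; rule after k completions is k mod 3.
    cc = 0
    for val, grp in groupby(pos):
        if val:
            cc += len(list(grp)) // 10
    cc = min(cc, 6)

    # PE/NPE: an error is perseverative iff it repeats the previous
    # trial's selection (the first trial can never be a PE).
    err = ~pos
    repeat = np.concatenate([[False], sels[1:] == sels[:-1]])
    pe = int((err & repeat).sum())
    npe = int(err.sum()) - pe

    # FMS: walk the stream tracking the current rule (advances after each
    # tenth consecutive positive) and the trailing run of positives whose
    # selection matched the rule; an error after a run >= 5 is an FMS.
    fms = 0
    completions = 0
    streak = 0
    matched_run = 0
    for t in range(n):
        rule = completions % 3
        if pos[t]:
            streak += 1
            matched_run = matched_run + 1 if sels[t] == rule else 0
            if streak == 10:
                completions += 1
                streak = 0
                matched_run = 0
        else:
            if matched_run >= 5:
                fms += 1
            streak = 0
            matched_run = 0
    return cc, pe, npe, fms


def play_random_session(seed: int) -> list[TrialRecord]:
    """Drive the environment with a uniform-random rule policy."""
    rng = np.random.default_rng(seed)
    state = build_task(seed)
    records: list[TrialRecord] = []
    while not state.terminated:
        card = state.remaining_deck[0]
        sel = Rule(int(rng.integers(0, 3)))
        chosen = targets_for(card)[sel]
        fb = give_feedback(state, card, chosen)
        rec = classify_trial(
            TrialRecord(card=card, selected_rule=sel, chosen_target_index=chosen, feedback=fb),
            state,
        )
        state = advance(state, rec)
        records.append(rec)
    return records


@pytest.fixture(scope="session")
def specs():
    from wcstsim.fixtures import group_specs

    return group_specs()
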