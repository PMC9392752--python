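"""Task environment: deck, targets, feedback, progression and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_rescore, play_random_session
from wcstsim.wcst_task import (
    Card,
    Classification,
    Colour,
    Feedback,
    Rule,
    Shape,
    Size,
    TARGET_CARDS,
    TrialRecord,
    advance,
    build_task,
    classify_trial,
    full_deck,
    give_feedback,
    score_session,
    targets_for,
)


class TestDeck:
    def test_two_full_factorial_decks(self):
        state = build_task(0)
        assert len(state.remaining_deck) == 128
        counts = {}
        for card in state.remaining_deck:
            counts[card] = counts.get(card, 0) + 1
        assert len(counts) == 64
        assert all(c == 2 for c in counts.values())

    def test_seeded_determinism(self):
        assert build_task(7).remaining_deck == build_task(7).remaining_deck
        assert build_task(7).remaining_deck != build_task(8).remaining_deck


class TestTargets:
    def test_each_attribute_value_on_exactly_one_target(self):
        for rule in Rule:
            values = [t.attribute(rule) for t in TARGET_CARDS]
            assert sorted(values) == [0, 1, 2, 3]

    def test_known_card(self):
        card = Card(Colour.RED, Shape.CIRCLE, Size.LARGE)
        assert dict(targets_for(card)) == {Rule.COLOUR: 0, Rule.SHAPE: 1, Rule.SIZE: 3}

    def test_card_identical_to_target_maps_all_rules_to_it(self):
        mapping = targets_for(TARGET_CARDS[2])
        assert set(mapping.values()) == {2}

    def test_exhaustive_total_and_single_valued(self):
        for card in full_deck():
            mapping = targets_for(card)
            assert set(mapping) == set(Rule)
            for rule, idx in mapping.items():
                assert TARGET_CARDS[idx].attribute(rule) == card.attribute(rule)
                others = [
                    i
                    for i, t in enumerate(TARGET_CARDS)
                    if t.attribute(rule) == card.attribute(rule)
                ]
                assert others == [idx]


class TestFeedback:
    def test_correct_rule_is_positive(self):
        state = build_task(0)
        card = state.remaining_deck[0]
        chosen = targets_for(card)[state.current_rule]
        assert give_feedback(state, card, chosen) is Feedback.POSITIVE

    def test_wrong_rule_distinct_target_is_negative(self):
        state = build_task(0)  # current rule: colour
        card = Card(Colour.RED, Shape.CIRCLE, Size.LARGE)
        assert give_feedback(state, card, targets_for(card)[Rule.SHAPE]) is Feedback.NEGATIVE

    def test_ambiguous_cards_yield_lucky_positives(self):
        # enumerate cards whose shape-target coincides with the colour-target
        state = build_task(0)  # current rule: colour
        lucky = 0
        for card in full_deck():
            mapping = targets_for(card)
            if mapping[Rule.SHAPE] == mapping[Rule.COLOUR]:
                assert give_feedback(state, card, mapping[Rule.SHAPE]) is Feedback.POSITIVE
                lucky += 1
        # colour fixes the target; 1 of 4 shapes agrees; any size: 16 cards
        assert lucky == 16

    def test_out_of_range_target_rejected(self):
        state = build_task(0)
        with pytest.raises(ValueError):
            give_feedback(state, state.remaining_deck[0], 4)


def _correct_record(state):
    card = state.remaining_deck[0]
    sel = state.current_rule
    rec = TrialRecord(card, sel, targets_for(card)[sel], Feedback.POSITIVE)
    return classify_trial(rec, state)


def _error_record(state, sel):
    card = state.remaining_deck[0]
    mapping = targets_for(card)
    rec = TrialRecord(card, sel, mapping[sel], Feedback.NEGATIVE)
    return classify_trial(rec, state)


class TestProgression:
    def test_ten_consecutive_correct_completes_category(self):
        state = build_task(1)
        for _ in range(10):
            state = advance(state, _correct_record(state))
        assert state.completed_categories == 1
        assert state.current_rule is Rule.SHAPE
        assert state.previous_rule is Rule.COLOUR
        assert state.consecutive_correct == 0

    def test_error_resets_counter(self):
        state = build_task(1)
        for _ in range(9):
            state = advance(state, _correct_record(state))
        wrong = Rule.SHAPE if state.current_rule is not Rule.SHAPE else Rule.SIZE
        state = advance(state, _error_record(state, wrong))
        assert state.completed_categories == 0
        assert state.consecutive_correct == 0

    def test_six_categories_terminates(self):
        state = build_task(1)
        for _ in range(60):
            state = advance(state, _correct_record(state))
        assert state.terminated
        assert state.completed_categories == 6
        with pytest.raises(RuntimeError):
            advance(state, _correct_record(state))

    def test_deck_exhaustion_terminates(self):
        state = build_task(1)
        wrong_then_right = 0
        while not state.terminated:
            # alternate errors to never complete a category
            sel = (
                state.current_rule
                if wrong_then_right % 2
                else Rule((state.current_rule + 1) % 3)
            )
            card = state.remaining_deck[0]
            fb = give_feedback(state, card, targets_for(card)[sel])
            rec = classify_trial(TrialRecord(card, sel, targets_for(card)[sel], fb), state)
            state = advance(state, rec)
            wrong_then_right += 1
        assert len(state.remaining_deck) == 0
        assert state.trial_index == 128


class TestClassification:
    def test_positive_is_cr(self):
        state = build_task(2)
        rec = _correct_record(state)
        assert rec.classification is Classification.CR
        assert not rec.fms_flag

    def test_repeat_of_previous_selection_is_pe(self):
        state = build_task(2)  # rule: colour
        state = advance(state, _error_record(state, Rule.SHAPE))
        rec = _error_record(state, Rule.SHAPE)
        assert rec.classification is Classification.PE

    def test_non_repeat_error_is_npe(self):
        state = build_task(2)
        state = advance(state, _error_record(state, Rule.SHAPE))
        rec = _error_record(state, Rule.SIZE)
        assert rec.classification is Classification.NPE

    def test_error_after_long_principle_run_sets_fms(self):
        state = build_task(2)
        for _ in range(7):
            state = advance(state, _correct_record(state))
        wrong = Rule((state.current_rule + 1) % 3)
        rec = _error_record(state, wrong)
        assert rec.fms_flag
        # and the same error after only 4 correct does not
        state2 = build_task(2)
        for _ in range(4):
            state2 = advance(state2, _correct_record(state2))
        assert not _error_record(state2, wrong).fms_flag


class TestScoring:
    def test_perfect_session_scores_six_zero_zero_zero(self):
        state = build_task(3)
        records = []
        while not state.terminated:
            rec = _correct_record(state)
            state = advance(state, rec)
            records.append(rec)
        assert score_session(records).as_dict() == {"cc": 6, "pe": 0, "npe": 0, "fms": 0}

    def test_all_error_session_has_no_cc_and_no_fms(self):
        state = build_task(3)
        records = []
        while not state.terminated:
            wrong = Rule((state.current_rule + 1) % 3)
            card = state.remaining_deck[0]
            mapping = targets_for(card)
            # a target matching no attribute always exists (<=3 are taken)
            bad = next(i for i in range(4) if i not in mapping.values())
            fb = give_feedback(state, card, bad)
            assert fb is Feedback.NEGATIVE
            rec = classify_trial(TrialRecord(card, wrong, bad, fb), state)
            state = advance(state, rec)
            records.append(rec)
        profile = score_session(records)
        assert profile.cc == 0
        assert profile.fms == 0
        assert profile.pe + profile.npe == len(records)

    def test_empty_records_scores_zero(self):
        assert score_session([]).as_dict() == {"cc": 0, "pe": 0, "npe": 0, "fms": 0}

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_independent_oracle_on_random_sessions(self, seed):
        records = play_random_session(seed)
        profile = score_session(records)
        sels = [r.selected_rule for r in records]
        pos = [r.feedback is Feedback.POSITIVE for r in records]
        assert (profile.cc, profile.pe, profile.npe, profile.fms) == oracle_rescore(sels, pos)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_rescoring_purity(self, seed):
        records = play_random_session(seed)
        profile = score_session(records)
        n_errors = sum(r.feedback is Feedback.NEGATIVE for r in records)
        n_cr = sum(r.classification is Classification.CR for r in records)
        assert profile.pe + profile.npe == n_errors
        assert n_cr + n_errors == len(records)
        assert 0 <= profile.cc <= 6
        assert len(records) <= 128
        # scoring is a pure function of the records
        assert score_session(records) == profile


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3))
def test_targets_for_is_total_for_any_card(c, s, z):
    card = Card(Colour(c), Shape(s), Size(z))
    mapping = targets_for(card)
    assert len(mapping) == 3
    assert all(0 <= i <= 3 for i in mapping.values())
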