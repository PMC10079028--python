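"""Transition classification against examples, invariants, and the
1 ms-grid floor-tracking oracle."""

from __future__ import annotations

import numpy as np
import pytest

from oracles import grid_classify, random_grid_channels
from turntaking import (
    build_state_timeline,
    classify_transitions,
    filter_for_timing,
    within_overlap_profile,
)
from turntaking.types import (
    BETWEEN_OVERLAP,
    GAP,
    WITHIN_OVERLAP,
    CanonicalChannel,
    IPU,
    Transition,
)


def mk(speaker, *intervals, labels=None):
    labels = labels or [f"w{i}" for i in range(len(intervals))]
    return CanonicalChannel(
        speaker,
        tuple(IPU(speaker, s, e, lab) for (s, e), lab in zip(intervals, labels)),
    )


def kinds(transitions):
    return [t.kind for t in transitions]


class TestStateTimeline:
    def test_gap_between_speakers(self):
        tl = build_state_timeline(mk("A", (0, 1)), mk("B", (2, 3)))
        assert [(iv.start, iv.end, set(iv.active)) for iv in tl] == [
            (0, 1, {"A"}),
            (1, 2, set()),
            (2, 3, {"B"}),
        ]

    def test_overlap(self):
        tl = build_state_timeline(mk("A", (0, 2)), mk("B", (1, 3)))
        assert [set(iv.active) for iv in tl] == [{"A"}, {"A", "B"}, {"B"}]

    def test_tiles_task_span_with_distinct_neighbours(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a_ms, b_ms = random_grid_channels(rng, total_ms=15000)
            a = mk("A", *[(s / 1000, e / 1000) for s, e in a_ms])
            b = mk("B", *[(s / 1000, e / 1000) for s, e in b_ms])
            tl = build_state_timeline(a, b, (0.0, 15.0))
            assert tl[0].start == 0.0 and tl[-1].end == 15.0
            for prev, nxt in zip(tl, tl[1:]):
                assert prev.end == nxt.start
                assert prev.active != nxt.active


class TestClassification:
    def test_simple_gap_600ms(self):
        transitions, turns = classify_transitions(mk("A", (0.0, 1.0)), mk("B", (1.6, 3.0)))
        (t,) = transitions
        assert t.kind == GAP and t.fto_ms == pytest.approx(600.0)
        assert (t.outgoing, t.incoming, t.index) == ("A", "B", 1)
        assert [u.speaker for u in turns] == ["A", "B"]

    def test_between_overlap_minus_400ms(self):
        transitions, _ = classify_transitions(mk("A", (0.0, 2.0)), mk("B", (1.6, 3.0)))
        (t,) = transitions
        assert t.kind == BETWEEN_OVERLAP and t.fto_ms == pytest.approx(-400.0)
        assert t.anchor_time == pytest.approx(1.6)

    def test_latching_is_a_gap(self):
        transitions, _ = classify_transitions(mk("A", (0.0, 1.0)), mk("B", (1.0, 2.0)))
        assert kinds(transitions) == [GAP]
        assert transitions[0].fto_ms == 0.0

    def test_embedded_vocalisation_is_within_overlap(self):
        transitions, turns = classify_transitions(
            mk("A", (0.0, 3.0)), mk("B", (1.0, 1.3))
        )
        (t,) = transitions
        assert t.kind == WITHIN_OVERLAP
        assert t.fto_ms is None
        assert t.duration_ms == pytest.approx(300.0)
        assert t.outgoing == t.incoming == "A"
        assert len(turns) == 1  # no floor transfer

    def test_interjection_in_the_clear_is_two_transfers(self):
        # B speaks entirely inside A's silent pause: no overlapping speech,
        # hence two genuine floor transfers rather than a within-overlap
        transitions, _ = classify_transitions(
            mk("A", (0.0, 1.0), (2.5, 4.0)), mk("B", (1.4, 1.9))
        )
        assert kinds(transitions) == [GAP, GAP]
        assert [t.fto_ms for t in transitions] == pytest.approx([400.0, 600.0])
        assert [t.index for t in transitions] == [1, 2]

    def test_joint_stop_then_other_resumes_is_one_transfer(self):
        # A and B stop together, then B resumes: one floor transfer whose
        # FTO is measured on turn boundaries (negative despite the silence)
        transitions, _ = classify_transitions(
            mk("A", (0.0, 2.0)), mk("B", (1.5, 2.0), (2.4, 3.5))
        )
        (t,) = transitions
        assert t.kind == BETWEEN_OVERLAP
        assert t.fto_ms == pytest.approx(-500.0)
        assert t.anchor_time == pytest.approx(1.5)

    def test_multiple_within_overlaps_in_one_turn(self):
        transitions, _ = classify_transitions(
            mk("A", (0.0, 5.0)), mk("B", (1.0, 1.2), (2.0, 2.4))
        )
        assert kinds(transitions) == [WITHIN_OVERLAP, WITHIN_OVERLAP]

    def test_time_shift_invariance(self):
        a = mk("A", (0.0, 1.0), (2.0, 3.0))
        b = mk("B", (1.2, 1.8), (3.4, 4.0))
        base, _ = classify_transitions(a, b)
        shift = 17.25
        a2 = CanonicalChannel("A", tuple(u.shifted(shift) for u in a.ipus))
        b2 = CanonicalChannel("B", tuple(u.shifted(shift) for u in b.ipus))
        moved, _ = classify_transitions(a2, b2)
        assert kinds(base) == kinds(moved)
        assert [t.fto_ms for t in base] == pytest.approx([t.fto_ms for t in moved])

    def test_speaker_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            a_ms, b_ms = random_grid_channels(rng, total_ms=12000)
            a = mk("A", *[(s / 1000, e / 1000) for s, e in a_ms])
            b = mk("B", *[(s / 1000, e / 1000) for s, e in b_ms])
            fwd, _ = classify_transitions(a, b)
            rev, _ = classify_transitions(b, a)
            assert kinds(fwd) == kinds(rev)
            for x, y in zip(fwd, rev):
                assert (x.outgoing, x.incoming) == (y.outgoing, y.incoming)
                assert (x.fto_ms or 0.0) == pytest.approx(y.fto_ms or 0.0)

    def test_sign_law_and_alternation(self, analysed_corpus):
        for analysed in analysed_corpus[:20]:
            incomings = []
            for t in analysed.transitions:
                if t.kind == GAP:
                    assert t.fto_ms >= 0
                elif t.kind == BETWEEN_OVERLAP:
                    assert t.fto_ms < 0
                else:
                    assert t.fto_ms is None
                if t.is_floor_transfer:
                    incomings.append(t.incoming)
            assert all(x != y for x, y in zip(incomings, incomings[1:]))
            indices = [t.index for t in analysed.floor_transfers]
            assert indices == list(range(1, len(indices) + 1))


class TestGridOracle:
    def test_matches_grid_oracle_on_random_dialogues(self):
        rng = np.random.default_rng(2024)
        total_ms = 15000
        n_events = 0
        for _ in range(250):
            a_ms, b_ms = random_grid_channels(rng, total_ms=total_ms)
            a = mk("A", *[(s / 1000, e / 1000) for s, e in a_ms])
            b = mk("B", *[(s / 1000, e / 1000) for s, e in b_ms])
            got, _ = classify_transitions(a, b, (0.0, total_ms / 1000))
            want = grid_classify(a_ms, b_ms, total_ms)
            assert len(got) == len(want), (a_ms, b_ms)
            for g, w in zip(got, want):
                assert g.kind == w["kind"]
                assert g.outgoing == w["outgoing"] and g.incoming == w["incoming"]
                assert round(g.anchor_time * 1000) == w["anchor_ms"]
                if g.is_floor_transfer:
                    assert round(g.fto_ms) == w["fto_ms"]
                else:
                    assert round(g.duration_ms) == w["duration_ms"]
            n_events += len(want)
        assert n_events > 1000  # the suite actually exercised transitions


class TestFiltering:
    def test_accounting_conserves_counts(self, analysed_corpus):
        for analysed in analysed_corpus[:10]:
            timing, acc = filter_for_timing(analysed.transitions)
            assert acc.n_total == len(analysed.transitions)
            assert acc.n_timing == len(timing) == acc.n_gap + acc.n_between
            assert all(t.kind != WITHIN_OVERLAP for t in timing)

    def test_all_gap_input_is_identity(self):
        ts = [
            Transition(GAP, "A", "B", 1.0, fto_ms=100.0, index=1),
            Transition(GAP, "B", "A", 2.0, fto_ms=50.0, index=2),
        ]
        timing, acc = filter_for_timing(ts)
        assert timing == ts and (acc.n_gap, acc.n_between, acc.n_within) == (2, 0, 0)


class TestWithinOverlapProfile:
    def test_no_events_reports_unavailable(self):
        profile = within_overlap_profile([])
        assert profile.n == 0
        assert profile.mean_duration_ms is None
        assert profile.backchannel_proportion is None

    def test_backchannel_share_half(self):
        ts = [
            Transition(WITHIN_OVERLAP, "A", "A", 1.0, duration_ms=200.0, label="Mhm."),
            Transition(WITHIN_OVERLAP, "A", "A", 2.0, duration_ms=400.0,
                       label="so I think"),
        ]
        profile = within_overlap_profile(ts)
        assert profile.backchannel_proportion == pytest.approx(0.5)
        assert profile.mean_duration_ms == pytest.approx(300.0)
        assert ts[0].is_backchannel and not ts[1].is_backchannel

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError, match="lexicon"):
            within_overlap_profile([], frozenset())
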