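"""Turn derivation, transition classification and Floor Transfer Offset.

The analysis views a dialogue as a sequence of *floor transfers*: moments
at which the right to speak passes from one interlocutor to the other.
Each floor transfer carries a Floor Transfer Offset (FTO): the signed time
from the outgoing turn's final IPU offset to the incoming turn's first IPU
onset. Positive FTOs are silent gaps, negative FTOs are between-overlaps
(the incoming speaker starts before the outgoing stops); exact latching
(FTO = 0) counts as a gap. Overlapping speech that is *not* followed by a
change of speaker — a listener's "mhm" inside an ongoing turn — is a
within-overlap: an event, not a floor transfer, and it is excluded from
all timing statistics.

Conventions for the rare degenerate configurations (documented in the
methods note): when both parties stop simultaneously the previous floor
holder keeps the floor until someone speaks alone again; if the *other*
speaker resumes after such a joint stop, the whole chain is a single floor
transfer whose FTO is measured on turn boundaries (and may be negative
even though joint silence intervened). A vocalisation falling entirely
inside the floor holder's silent pause — "in the clear" — is two genuine
floor transfers, not a within-overlap, because no speech overlaps.
"""

from __future__ import annotations

import string
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from .types import (
    BETWEEN_OVERLAP,
    GAP,
    WITHIN_OVERLAP,
    CanonicalChannel,
    IPU,
    Transition,
    TransitionAccounting,
    Turn,
)

DEFAULT_BACKCHANNEL_LEXICON = frozenset(
    {"mhm", "mmhm", "hm", "mm", "ja", "okay", "ok", "genau", "yeah", "right"}
)

_EPS = 1e-9


@dataclass(frozen=True)
class StateInterval:
    """A maximal interval of constant joint activity."""

    start: float
    end: float
    active: frozenset[str]  # subset of the two speaker IDs


def build_state_timeline(
    channel_a: CanonicalChannel,
    channel_b: CanonicalChannel,
    task_span: Optional[tuple[float, float]] = None,
) -> list[StateInterval]:
    """Tile the task span with maximal intervals labelled by who speaks.

    Labels are the active-speaker sets: one speaker, both, or neither.
    Adjacent intervals always differ in label.
    """
    ipus = list(channel_a.ipus) + list(channel_b.ipus)
    if task_span is None:
        if not ipus:
            return []
        task_span = (min(u.start for u in ipus), max(u.end for u in ipus))
    t0, t1 = task_span
    bounds = {t0, t1}
    for u in ipus:
        bounds.add(min(max(u.start, t0), t1))
        bounds.add(min(max(u.end, t0), t1))
    cuts = sorted(bounds)

    starts_a = [u.start for u in channel_a.ipus]
    starts_b = [u.start for u in channel_b.ipus]

    def covering(starts: list[float], ipu_list, t: float) -> bool:
        idx = bisect_right(starts, t + _EPS) - 1
        return idx >= 0 and ipu_list[idx].end > t + _EPS

    intervals: list[StateInterval] = []
    for lo, hi in zip(cuts, cuts[1:]):
        if hi - lo <= _EPS:
            continue
        active = set()
        if covering(starts_a, channel_a.ipus, lo):
            active.add(channel_a.speaker)
        if covering(starts_b, channel_b.ipus, lo):
            active.add(channel_b.speaker)
        label = frozenset(active)
        if intervals and intervals[-1].active == label:
            intervals[-1] = StateInterval(intervals[-1].start, hi, label)
        else:
            intervals.append(StateInterval(lo, hi, label))
    return intervals


def _ipu_at(channel: CanonicalChannel, starts: list[float], t: float) -> IPU:
    """The channel's IPU active at time ``t`` (half-open semantics)."""
    idx = bisect_right(starts, t + _EPS) - 1
    if idx < 0 or channel.ipus[idx].end <= t + _EPS:
        raise ValueError(f"speaker {channel.speaker!r} not active at t={t}")
    return channel.ipus[idx]


def _last_end_before(ends: list[float], t: float) -> float:
    """Latest IPU end at or before ``t``."""
    idx = bisect_right(ends, t + _EPS) - 1
    if idx < 0:
        raise ValueError(f"no IPU ends at or before t={t}")
    return ends[idx]


def classify_transitions(
    channel_a: CanonicalChannel,
    channel_b: CanonicalChannel,
    task_span: Optional[tuple[float, float]] = None,
) -> tuple[list[Transition], list[Turn]]:
    """Classify every between-speaker event and derive the turn sequence.

    Returns the transition list in time order (floor transfers indexed
    consecutively from 1; within-overlaps unindexed) and the list of
    turns, which alternate speakers by construction.
    """
    timeline = build_state_timeline(channel_a, channel_b, task_span)
    channels = {channel_a.speaker: channel_a, channel_b.speaker: channel_b}
    starts = {s: [u.start for u in ch.ipus] for s, ch in channels.items()}
    ends = {s: [u.end for u in ch.ipus] for s, ch in channels.items()}

    def other(speaker: str) -> str:
        for s in channels:
            if s != speaker:
                return s
        return speaker

    transitions: list[Transition] = []
    turns: list[Turn] = []
    floor: Optional[str] = None
    turn_first_ipu: Optional[IPU] = None
    pending: list[StateInterval] = []  # unresolved overlap intervals
    n_transfers = 0

    def close_turn(up_to: float) -> float:
        """Close the floor holder's turn at its last IPU ending <= up_to."""
        assert floor is not None and turn_first_ipu is not None
        ch = channels[floor]
        last_end = _last_end_before(ends[floor], up_to)
        i0 = bisect_left(starts[floor], turn_first_ipu.start - _EPS)
        i1 = bisect_right(ends[floor], last_end + _EPS)
        turns.append(Turn(speaker=floor, ipus=ch.ipus[i0:i1]))
        return last_end

    def emit_within(intervals: Sequence[StateInterval], holder: str) -> None:
        for iv in intervals:
            guest = other(holder)
            embedded = _ipu_at(channels[guest], starts[guest], iv.start)
            transitions.append(
                Transition(
                    kind=WITHIN_OVERLAP,
                    outgoing=holder,
                    incoming=holder,
                    anchor_time=embedded.start,
                    duration_ms=embedded.duration * 1000.0,
                    label=embedded.label,
                )
            )

    for iv in timeline:
        if len(iv.active) == 2:
            if floor is not None:
                pending.append(iv)
            continue
        if len(iv.active) == 0:
            continue
        (speaker,) = iv.active
        if floor is None:
            floor = speaker
            turn_first_ipu = _ipu_at(channels[speaker], starts[speaker], iv.start)
            pending.clear()
            continue
        if speaker == floor:
            if pending:
                emit_within(pending, floor)
                pending.clear()
            continue
        # floor transfer: the other speaker holds the floor alone
        if pending:
            incoming_ipu = _ipu_at(channels[speaker], starts[speaker], pending[0].start)
        else:
            incoming_ipu = _ipu_at(channels[speaker], starts[speaker], iv.start)
        outgoing_offset = close_turn(iv.start)
        fto_s = incoming_ipu.start - outgoing_offset
        n_transfers += 1
        transitions.append(
            Transition(
                kind=GAP if fto_s >= 0 else BETWEEN_OVERLAP,
                outgoing=floor,
                incoming=speaker,
                anchor_time=incoming_ipu.start,
                fto_ms=fto_s * 1000.0,
                index=n_transfers,
            )
        )
        floor = speaker
        turn_first_ipu = incoming_ipu
        pending.clear()

    if floor is not None:
        # an overlap never followed by speech from either party is, by
        # definition, not followed by a change of speaker
        if pending:
            emit_within(pending, floor)
        close_turn(float("inf"))

    transitions.sort(key=lambda t: (t.anchor_time, t.kind))
    return transitions, turns


def filter_for_timing(
    transitions: Sequence[Transition],
) -> tuple[list[Transition], TransitionAccounting]:
    """Drop within-overlaps, keeping full accounting of all three kinds."""
    accounting = TransitionAccounting(
        n_gap=sum(t.kind == GAP for t in transitions),
        n_between=sum(t.kind == BETWEEN_OVERLAP for t in transitions),
        n_within=sum(t.kind == WITHIN_OVERLAP for t in transitions),
    )
    return [t for t in transitions if t.is_floor_transfer], accounting


_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def is_backchannel_label(label: Optional[str], lexicon: frozenset[str]) -> bool:
    if not label:
        return False
    cleaned = label.translate(_PUNCT_TABLE).strip().lower()
    return cleaned in lexicon


@dataclass(frozen=True)
class WithinOverlapProfile:
    n: int
    mean_duration_ms: Optional[float]
    backchannel_proportion: Optional[float]


def within_overlap_profile(
    transitions: Sequence[Transition],
    backchannel_lexicon: frozenset[str] = DEFAULT_BACKCHANNEL_LEXICON,
) -> WithinOverlapProfile:
    """Mean duration and backchannel share of within-overlap events.

    Marks each within-overlap's ``is_backchannel`` flag in place by
    case-insensitive whole-label match after punctuation stripping. With
    no within-overlaps both statistics are reported as unavailable.
    """
    if not backchannel_lexicon:
        raise ValueError("backchannel lexicon must be non-empty")
    events = [t for t in transitions if t.kind == WITHIN_OVERLAP]
    for t in events:
        t.is_backchannel = is_backchannel_label(t.label, backchannel_lexicon)
    if not events:
        return WithinOverlapProfile(n=0, mean_duration_ms=None, backchannel_proportion=None)
    mean_dur = sum(t.duration_ms for t in events) / len(events)
    share = sum(t.is_backchannel for t in events) / len(events)
    return WithinOverlapProfile(
        n=len(events), mean_duration_ms=mean_dur, backchannel_proportion=share
    )
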