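"""End-to-end analysis of dialogue records.

Chains the stages — canonicalise each channel, classify transitions,
partition into dialogue stages — and flattens corpora into the tabular
form the descriptive and modelling layers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .epoch_partition import assign_epochs
from .ipu_processing import canonicalise_channel
from .transition_core import (
    DEFAULT_BACKCHANNEL_LEXICON,
    classify_transitions,
    filter_for_timing,
    within_overlap_profile,
)
from .types import (
    WITHIN_OVERLAP,
    DialogueRecord,
    Transition,
    TransitionAccounting,
    Turn,
)


@dataclass
class AnalysedDialogue:
    record: DialogueRecord
    transitions: list[Transition]  # all kinds, time-ordered, epoch-labelled
    turns: list[Turn]
    accounting: TransitionAccounting

    @property
    def floor_transfers(self) -> list[Transition]:
        return [t for t in self.transitions if t.is_floor_transfer]

    @property
    def within_overlaps(self) -> list[Transition]:
        return [t for t in self.transitions if t.kind == WITHIN_OVERLAP]


def analyse_dialogue(
    record: DialogueRecord,
    min_pause_ms: float = 200.0,
    backchannel_lexicon: frozenset[str] = DEFAULT_BACKCHANNEL_LEXICON,
) -> AnalysedDialogue:
    """Canonicalise, classify and (when marks exist) epoch-label one dialogue."""
    sp_a, sp_b = record.speakers
    chan_a = canonicalise_channel(record.channels[sp_a], min_pause_ms)
    chan_b = canonicalise_channel(record.channels[sp_b], min_pause_ms)
    # an entirely silent channel loses its speaker ID in canonical form
    if not chan_a.ipus:
        chan_a = type(chan_a)(speaker=sp_a, ipus=(), min_pause_ms=min_pause_ms)
    if not chan_b.ipus:
        chan_b = type(chan_b)(speaker=sp_b, ipus=(), min_pause_ms=min_pause_ms)
    transitions, turns = classify_transitions(chan_a, chan_b, record.task_span)
    if record.epoch_marks is not None:
        assign_epochs(transitions, record.epoch_marks, record.task_span)
    within_overlap_profile(transitions, backchannel_lexicon)  # sets flags
    _, accounting = filter_for_timing(transitions)
    return AnalysedDialogue(record, transitions, turns, accounting)


def analyse_corpus(
    records: Iterable[DialogueRecord], min_pause_ms: float = 200.0
) -> list[AnalysedDialogue]:
    return [analyse_dialogue(r, min_pause_ms) for r in records]


def _base_row(a: AnalysedDialogue, t: Transition) -> dict:
    return {
        "dialogue_id": a.record.dialogue_id,
        "dyad": a.record.dyad_id,
        "group": a.record.group,
        "index": t.index,
        "fto_ms": t.fto_ms,
        "type": t.kind,
        "outgoing": t.outgoing,
        "incoming": t.incoming,
        "time_s": t.anchor_time,
        "epoch2": t.epoch_two,
        "epoch3": t.epoch_three,
    }


def transfers_frame(analysed: Sequence[AnalysedDialogue]) -> pd.DataFrame:
    """One row per floor transfer (within-overlaps excluded), unrounded ms."""
    rows = [_base_row(a, t) for a in analysed for t in a.floor_transfers]
    return pd.DataFrame(rows)


def within_overlap_frame(analysed: Sequence[AnalysedDialogue]) -> pd.DataFrame:
    """One row per within-overlap event."""
    rows = []
    for a in analysed:
        for t in a.within_overlaps:
            row = _base_row(a, t)
            row.update(
                {"duration_ms": t.duration_ms, "label": t.label,
                 "is_backchannel": t.is_backchannel}
            )
            rows.append(row)
    return pd.DataFrame(rows)


def corpus_accounting(analysed: Sequence[AnalysedDialogue]) -> TransitionAccounting:
    return TransitionAccounting(
        n_gap=sum(a.accounting.n_gap for a in analysed),
        n_between=sum(a.accounting.n_between for a in analysed),
        n_within=sum(a.accounting.n_within for a in analysed),
    )
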