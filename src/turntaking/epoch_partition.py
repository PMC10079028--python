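"""Dialogue-stage assignment around the first Mismatch.

The first Mismatch — the first deliberately discrepant landmark the
interlocutors discover — marks a turning point in a Map Task dialogue.
Two partitions of the floor-transfer sequence are supported:

* two-way: ``beginning`` (all transitions before detection) vs
  ``remainder``;
* three-way: ``before_detection`` / ``during_discussion`` /
  ``after_resolution``, requiring a resolution timestamp.

A transition is located by its anchor time — the incoming turn's onset —
with boundary ties resolved as "at or after the mark belongs to the later
epoch". Marks are metadata inputs; no lexical detection is attempted.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .types import (
    AFTER_RESOLUTION,
    BEFORE_DETECTION,
    BEGINNING,
    DURING_DISCUSSION,
    REMAINDER,
    DialogueRecord,
    EpochMarks,
    Transition,
)


def assign_epochs(
    transitions: Sequence[Transition],
    marks: EpochMarks,
    task_span: Optional[tuple[float, float]] = None,
) -> list[Transition]:
    """Label each transition with its two-way (and, when a resolution
    time exists, three-way) dialogue stage. Labels are set in place; the
    input list is returned for chaining."""
    if task_span is not None:
        t0, t1 = task_span
        if not (t0 <= marks.detection_time <= t1):
            raise ValueError(
                f"detection_time {marks.detection_time} outside task span [{t0}, {t1}]"
            )
        if marks.resolution_time is not None and not (t0 <= marks.resolution_time <= t1):
            raise ValueError(
                f"resolution_time {marks.resolution_time} outside task span [{t0}, {t1}]"
            )
    for t in transitions:
        before = t.anchor_time < marks.detection_time
        t.epoch_two = BEGINNING if before else REMAINDER
        if marks.resolution_time is None:
            t.epoch_three = None
        elif before:
            t.epoch_three = BEFORE_DETECTION
        elif t.anchor_time < marks.resolution_time:
            t.epoch_three = DURING_DISCUSSION
        else:
            t.epoch_three = AFTER_RESOLUTION
    return list(transitions)


def _first_index_at_or_after(
    transitions: Sequence[Transition], mark: float
) -> Optional[int]:
    indexed = [t for t in transitions if t.is_floor_transfer and t.index is not None]
    for t in sorted(indexed, key=lambda t: t.index):
        if t.anchor_time >= mark:
            return t.index
    return None


def epoch_index_summary(
    corpus: Sequence[tuple[Sequence[Transition], EpochMarks]],
) -> dict[str, float]:
    """Average floor-transfer index at detection and at resolution.

    ``corpus`` pairs each dialogue's classified transitions with its epoch
    marks. For each dialogue the first floor-transfer index whose anchor
    falls at or after the mark is taken; the summary averages these over
    dialogues. Dialogues in which no transfer follows a mark contribute
    nothing to that mark's mean. Returns NaN when no dialogue contributes.
    """
    det_indices: list[int] = []
    res_indices: list[int] = []
    for transitions, marks in corpus:
        idx = _first_index_at_or_after(transitions, marks.detection_time)
        if idx is not None:
            det_indices.append(idx)
        if marks.resolution_time is not None:
            idx = _first_index_at_or_after(transitions, marks.resolution_time)
            if idx is not None:
                res_indices.append(idx)
    return {
        "mean_detection_index": (
            sum(det_indices) / len(det_indices) if det_indices else math.nan
        ),
        "mean_resolution_index": (
            sum(res_indices) / len(res_indices) if res_indices else math.nan
        ),
    }
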