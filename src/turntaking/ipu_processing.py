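"""Channel canonicalisation under the minimum-pause rule.

An interpausal unit is speech bounded by at least ``min_pause_ms`` of
silence. Input annotations may contain shorter within-speaker silences
(e.g. after label-to-silence remapping); canonicalisation merges any two
consecutive same-speaker IPUs separated by less than the threshold, so the
output channel satisfies the IPU definition by construction. A pause of
exactly the threshold is a valid pause and is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .types import CanonicalChannel, DialogueRecord, IPU


class ChannelOverlapError(ValueError):
    """Same-speaker IPUs overlap, which no annotation should produce."""


def canonicalise_channel(
    channel: Sequence[IPU], min_pause_ms: float = 200.0
) -> CanonicalChannel:
    """Sort, validate and merge a single speaker's IPU sequence.

    Consecutive IPUs separated by silence strictly shorter than
    ``min_pause_ms`` are merged, labels concatenated with a space; the
    filled-pause-only flag survives only if both parts carry it. Merging
    cascades left-to-right until no sub-threshold pause remains.
    """
    if min_pause_ms <= 0:
        raise ValueError(f"min_pause_ms must be positive, got {min_pause_ms}")
    ipus = sorted(channel, key=lambda u: (u.start, u.end))
    if not ipus:
        return CanonicalChannel(speaker="", ipus=(), min_pause_ms=min_pause_ms)
    speakers = {u.speaker for u in ipus}
    if len(speakers) > 1:
        raise ValueError(f"channel mixes speakers: {sorted(speakers)}")
    min_pause_s = min_pause_ms / 1000.0
    merged: list[IPU] = [ipus[0]]
    for nxt in ipus[1:]:
        cur = merged[-1]
        if nxt.start < cur.end:
            raise ChannelOverlapError(
                f"speaker {cur.speaker!r}: IPU [{cur.start}, {cur.end}] overlaps "
                f"[{nxt.start}, {nxt.end}]"
            )
        # a pause of exactly the threshold is a valid pause; the 1 ns guard
        # keeps float subtraction from flipping that boundary case
        if nxt.start - cur.end < min_pause_s - 1e-9:
            merged[-1] = IPU(
                speaker=cur.speaker,
                start=cur.start,
                end=nxt.end,
                label=" ".join(filter(None, [cur.label, nxt.label])),
                is_filled_pause_only=cur.is_filled_pause_only and nxt.is_filled_pause_only,
            )
        else:
            merged.append(nxt)
    return CanonicalChannel(
        speaker=ipus[0].speaker, ipus=tuple(merged), min_pause_ms=min_pause_ms
    )


@dataclass
class ValidationReport:
    """Accumulated violations; an empty report means the record is analysable."""

    violations: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_dialogue(
    record: DialogueRecord, min_pause_ms: float = 200.0
) -> ValidationReport:
    """Report structural problems without raising.

    Checks: within-channel overlap, IPUs outside the task span, missing or
    inconsistent epoch marks.
    """
    report = ValidationReport()
    t0, t1 = record.task_span
    for speaker, ipus in record.channels.items():
        ordered = sorted(ipus, key=lambda u: u.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start < prev.end:
                report.add(
                    f"speaker {speaker!r}: overlapping IPUs "
                    f"[{prev.start}, {prev.end}] and [{nxt.start}, {nxt.end}]"
                )
        for u in ordered:
            if u.start < t0 - 1e-9 or u.end > t1 + 1e-9:
                report.add(
                    f"speaker {speaker!r}: IPU [{u.start}, {u.end}] outside "
                    f"task span [{t0}, {t1}]"
                )
    marks = record.epoch_marks
    if marks is None:
        report.add("missing epoch marks")
    else:
        if not (t0 <= marks.detection_time <= t1):
            report.add(
                f"detection_time {marks.detection_time} outside task span [{t0}, {t1}]"
            )
        if marks.resolution_time is not None:
            if marks.resolution_time < marks.detection_time:
                report.add("resolution_time precedes detection_time")
            if not (t0 <= marks.resolution_time <= t1):
                report.add(
                    f"resolution_time {marks.resolution_time} outside task span "
                    f"[{t0}, {t1}]"
                )
    return report
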