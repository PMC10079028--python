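"""Core domain types for dyadic turn-timing analysis.

Times are stored in seconds (floating point) throughout; Floor Transfer
Offsets (FTOs) are carried in unrounded milliseconds internally and rounded
to integer milliseconds only when written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

GROUPS = ("ASD", "CTR")

#: transition kinds
GAP = "gap"
BETWEEN_OVERLAP = "between_overlap"
WITHIN_OVERLAP = "within_overlap"

#: two-way dialogue stages (split at detection of the first Mismatch)
BEGINNING = "beginning"
REMAINDER = "remainder"

#: three-way dialogue stages
BEFORE_DETECTION = "before_detection"
DURING_DISCUSSION = "during_discussion"
AFTER_RESOLUTION = "after_resolution"


@dataclass(frozen=True)
class IPU:
    """One speaker's interpausal unit: a continuous vocalisation interval.

    An IPU is a stretch of speech bounded by silences of at least the
    minimum pause duration (200 ms by convention). Filled pauses such as
    "<uhm>" count as speech, never silence; an IPU whose label consists
    only of filled-pause tokens is flagged so downstream analyses can
    optionally filter it.
    """

    speaker: str
    start: float
    end: float
    label: str = ""
    is_filled_pause_only: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"IPU must have end > start, got [{self.start}, {self.end}] "
                f"for speaker {self.speaker!r}"
            )
        if self.start < 0:
            raise ValueError(f"IPU start must be >= 0, got {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def shifted(self, offset: float) -> "IPU":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class EpochMarks:
    """Timestamps partitioning a dialogue around its first Mismatch.

    ``detection_time`` is the first mention of the first mismatching
    landmark; ``resolution_time`` (optional) is when the interlocutors
    finished discussing it. Both are in seconds on the dialogue clock.

    ``detection_time <= resolution_time`` is expected; violations are
    surfaced by :func:`turntaking.ipu_processing.validate_dialogue` rather
    than raised here, so defective metadata can still be loaded and
    reported.
    """

    detection_time: float
    resolution_time: Optional[float] = None


@dataclass
class DialogueRecord:
    """Two-channel dialogue: one Map-Task-style interaction of one dyad.

    ``channels`` maps the two speaker IDs to their IPU sequences. Tasks are
    never concatenated: each task of a dyad is its own record.
    """

    dyad_id: str
    group: str
    channels: dict[str, list[IPU]]
    epoch_marks: Optional[EpochMarks] = None
    task_span: tuple[float, float] = (0.0, 0.0)
    dialogue_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if len(self.channels) != 2:
            raise ValueError(
                f"DialogueRecord needs exactly two speakers, got {sorted(self.channels)}"
            )
        if self.dialogue_id is None:
            self.dialogue_id = self.dyad_id

    @property
    def speakers(self) -> tuple[str, str]:
        return tuple(sorted(self.channels))  # type: ignore[return-value]


@dataclass(frozen=True)
class CanonicalChannel:
    """A validated, time-ordered IPU sequence for one speaker.

    Invariants: strictly increasing non-overlapping IPUs, and every
    within-channel silent interval is at least ``min_pause_ms`` long.
    Produced by :func:`turntaking.ipu_processing.canonicalise_channel`.
    """

    speaker: str
    ipus: tuple[IPU, ...]
    min_pause_ms: float = 200.0


@dataclass(frozen=True)
class Turn:
    """A maximal stretch of one speaker's IPUs between floor transfers."""

    speaker: str
    ipus: tuple[IPU, ...]

    @property
    def onset(self) -> float:
        return self.ipus[0].start

    @property
    def offset(self) -> float:
        return self.ipus[-1].end


@dataclass
class Transition:
    """One classified between-speaker event.

    Floor transfers (gaps and between-overlaps) carry a signed FTO in
    milliseconds: positive for silent gaps, negative for overlapped starts,
    zero for perfect latching (counted as a gap). Within-overlaps — an
    interlocutor vocalisation embedded in an ongoing turn without a change
    of speaker — carry no FTO; they carry the embedded vocalisation's
    duration and label instead, and are excluded from timing analyses.
    """

    kind: str
    outgoing: str
    incoming: str
    anchor_time: float
    fto_ms: Optional[float] = None
    index: Optional[int] = None
    duration_ms: Optional[float] = None
    label: Optional[str] = None
    is_backchannel: Optional[bool] = None
    epoch_two: Optional[str] = None
    epoch_three: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == GAP and (self.fto_ms is None or self.fto_ms < 0):
            raise ValueError(f"gap requires fto_ms >= 0, got {self.fto_ms}")
        if self.kind == BETWEEN_OVERLAP and (self.fto_ms is None or self.fto_ms >= 0):
            raise ValueError(f"between_overlap requires fto_ms < 0, got {self.fto_ms}")
        if self.kind == WITHIN_OVERLAP and self.fto_ms is not None:
            raise ValueError("within_overlap carries no FTO")

    @property
    def is_floor_transfer(self) -> bool:
        return self.kind in (GAP, BETWEEN_OVERLAP)


@dataclass(frozen=True)
class TransitionAccounting:
    """Counts of the three transition kinds with derived shares."""

    n_gap: int
    n_between: int
    n_within: int

    @property
    def n_total(self) -> int:
        return self.n_gap + self.n_between + self.n_within

    @property
    def n_timing(self) -> int:
        """Transitions remaining after within-overlap exclusion."""
        return self.n_gap + self.n_between

    @property
    def gap_share_all(self) -> float:
        return self.n_gap / self.n_total if self.n_total else float("nan")

    @property
    def gap_share_timing(self) -> float:
        return self.n_gap / self.n_timing if self.n_timing else float("nan")

    @property
    def overlap_share_timing(self) -> float:
        return self.n_between / self.n_timing if self.n_timing else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_gap": self.n_gap,
            "n_between_overlap": self.n_between,
            "n_within_overlap": self.n_within,
            "n_total": self.n_total,
            "n_timing": self.n_timing,
            "gap_share_all": self.gap_share_all,
            "gap_share_timing": self.gap_share_timing,
            "overlap_share_timing": self.overlap_share_timing,
        }


def transitions_of_kind(transitions: Sequence[Transition], kind: str) -> list[Transition]:
    return [t for t in transitions if t.kind == kind]
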