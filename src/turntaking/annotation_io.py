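"""Reading and writing dialogue annotations.

Supported on-disk forms:

* Praat TextGrid interval tiers (long or short dialect), one tier per
  speaker; empty-label intervals are silence and are dropped on read.
* Flat delimited IPU tables (tab or comma, autodetected) with columns
  ``speaker``, ``start``, ``end``, ``label``.
* A YAML metadata sidecar carrying dyad ID, group label, epoch marks and
  task span.
* Delimited transition tables (the classifier's output schema).

Both ingestion routes yield the same in-memory :class:`DialogueRecord`.
Labels are taken at face value: audible in-breaths, clicks etc. must
already have been annotated as silence upstream, though a configurable
``silence_labels`` set lets callers map additional labels to silence.
Filled pauses (e.g. ``<uhm>``) are speech; IPUs consisting solely of
filled-pause tokens are flagged, never dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import textgrid
from .types import (
    GROUPS,
    WITHIN_OVERLAP,
    DialogueRecord,
    EpochMarks,
    IPU,
    Transition,
)

#: labels treated as silence on read (beyond these, trust the annotation)
DEFAULT_SILENCE_LABELS = frozenset({""})

#: tokens that mark a filled pause in the transcription conventions used here
DEFAULT_FILLED_PAUSE_TOKENS = frozenset(
    {"<uh>", "<uhm>", "<um>", "<äh>", "<ähm>", "<hm>", "<mm>"}
)

TRANSITION_COLUMNS = [
    "dialogue_id",
    "dyad",
    "group",
    "index",
    "type",
    "fto_ms",
    "duration_ms",
    "outgoing",
    "incoming",
    "time_s",
    "epoch2",
    "epoch3",
    "label",
    "is_backchannel",
]


def is_filled_pause_only(label: str, tokens: frozenset[str] = DEFAULT_FILLED_PAUSE_TOKENS) -> bool:
    parts = label.split()
    return bool(parts) and all(p.lower() in tokens for p in parts)


def read_textgrid(
    path: str | Path,
    tier_names: Sequence[str],
    silence_labels: frozenset[str] = DEFAULT_SILENCE_LABELS,
    filled_pause_tokens: frozenset[str] = DEFAULT_FILLED_PAUSE_TOKENS,
) -> dict[str, list[IPU]]:
    """Read the named interval tiers into per-speaker IPU sequences.

    Every non-silence interval becomes an IPU whose speaker is the tier
    name; interval times are preserved to file precision.
    """
    if len(tier_names) != 2:
        raise ValueError(f"expected two tier names, got {list(tier_names)}")
    grid = textgrid.read(path)
    channels: dict[str, list[IPU]] = {}
    for name in tier_names:
        tier = grid.tier(name)
        if tier.tier_class != "IntervalTier":
            raise ValueError(f"tier {name!r} is a {tier.tier_class}, not an IntervalTier")
        ipus = []
        for iv in tier.intervals:
            label = iv.text.strip()
            if label in silence_labels:
                continue
            ipus.append(
                IPU(
                    speaker=name,
                    start=iv.xmin,
                    end=iv.xmax,
                    label=label,
                    is_filled_pause_only=is_filled_pause_only(label, filled_pause_tokens),
                )
            )
        channels[name] = ipus
    return channels


def write_textgrid(
    record: DialogueRecord, path: str | Path, dialect: str = "long"
) -> None:
    """Write a dialogue as a two-tier TextGrid, padding silences with
    empty-label intervals so the tiers tile the task span."""
    t0, t1 = record.task_span
    tiers = []
    for speaker in record.speakers:
        intervals: list[textgrid.Interval] = []
        cursor = t0
        for ipu in sorted(record.channels[speaker], key=lambda u: u.start):
            if ipu.start > cursor:
                intervals.append(textgrid.Interval(cursor, ipu.start, ""))
            intervals.append(textgrid.Interval(ipu.start, ipu.end, ipu.label))
            cursor = ipu.end
        if cursor < t1:
            intervals.append(textgrid.Interval(cursor, t1, ""))
        tiers.append(textgrid.Tier(speaker, "IntervalTier", t0, t1, tuple(intervals)))
    textgrid.write(textgrid.TextGrid(t0, t1, tuple(tiers)), path, dialect=dialect)


def _load_meta(meta: str | Path | Mapping) -> dict:
    if isinstance(meta, (str, Path)):
        with open(meta, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh)
    return dict(meta)


def _record_from_meta(channels: dict[str, list[IPU]], meta: Mapping) -> DialogueRecord:
    group = meta["group"]
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    marks = None
    if meta.get("detection_time") is not None:
        res = meta.get("resolution_time")
        marks = EpochMarks(float(meta["detection_time"]),
                           None if res is None else float(res))
    span = meta.get("task_span")
    if span is None:
        ends = [u.end for ipus in channels.values() for u in ipus]
        starts = [u.start for ipus in channels.values() for u in ipus]
        span = (min(starts, default=0.0), max(ends, default=0.0))
    return DialogueRecord(
        dyad_id=str(meta["dyad_id"]),
        group=group,
        channels=channels,
        epoch_marks=marks,
        task_span=(float(span[0]), float(span[1])),
        dialogue_id=str(meta.get("dialogue_id", meta["dyad_id"])),
    )


def read_dialogue_textgrid(
    path: str | Path, tier_names: Sequence[str], meta: str | Path | Mapping
) -> DialogueRecord:
    """TextGrid + metadata sidecar -> :class:`DialogueRecord`."""
    return _record_from_meta(read_textgrid(path, tier_names), _load_meta(meta))


def read_ipu_table(
    path: str | Path,
    meta: str | Path | Mapping | None = None,
    filled_pause_tokens: frozenset[str] = DEFAULT_FILLED_PAUSE_TOKENS,
) -> DialogueRecord:
    """Delimited IPU table + metadata sidecar -> :class:`DialogueRecord`.

    When ``meta`` is omitted, a sidecar ``<table>.yaml`` next to the file
    is used.
    """
    path = Path(path)
    if meta is None:
        meta = path.with_suffix(path.suffix + ".yaml")
        if not meta.exists():
            raise FileNotFoundError(f"no metadata sidecar found at {meta}")
    df = pd.read_csv(path, sep=None, engine="python", dtype={"speaker": str},
                     keep_default_na=False)
    required = {"speaker", "start", "end", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    speakers = sorted(df["speaker"].unique())
    if len(speakers) > 2:
        raise ValueError(f"{path}: more than two speakers: {speakers}")
    channels: dict[str, list[IPU]] = {s: [] for s in speakers}
    for row in df.itertuples(index=False):
        start, end = float(row.start), float(row.end)
        if not (math.isfinite(start) and math.isfinite(end)):
            raise ValueError(f"{path}: non-numeric times in row {row}")
        label = str(row.label)
        channels[str(row.speaker)].append(
            IPU(str(row.speaker), start, end, label,
                is_filled_pause_only=is_filled_pause_only(label, filled_pause_tokens))
        )
    meta_dict = _load_meta(meta)
    # a two-channel record may legitimately have one silent speaker in a
    # short excerpt; fill missing channels from metadata speaker list
    for s in meta_dict.get("speakers", []):
        channels.setdefault(str(s), [])
    return _record_from_meta(channels, meta_dict)


def write_ipu_table(
    record: DialogueRecord, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a dialogue as a delimited IPU table plus YAML sidecar."""
    path = Path(path)
    rows = [
        {"speaker": s, "start": round(u.start, 6), "end": round(u.end, 6),
         "label": u.label}
        for s in record.speakers
        for u in record.channels[s]
    ]
    pd.DataFrame(rows, columns=["speaker", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False
    )
    meta = {
        "dyad_id": record.dyad_id,
        "dialogue_id": record.dialogue_id,
        "group": record.group,
        "speakers": list(record.speakers),
        "task_span": [round(record.task_span[0], 6), round(record.task_span[1], 6)],
        "detection_time": None,
        "resolution_time": None,
    }
    if record.epoch_marks is not None:
        meta["detection_time"] = round(record.epoch_marks.detection_time, 6)
        if record.epoch_marks.resolution_time is not None:
            meta["resolution_time"] = round(record.epoch_marks.resolution_time, 6)
    if meta_path is None:
        meta_path = path.with_suffix(path.suffix + ".yaml")
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False, allow_unicode=True)


def transitions_to_frame(
    transitions: Iterable[Transition],
    dyad: Optional[str] = None,
    group: Optional[str] = None,
    dialogue_id: Optional[str] = None,
) -> pd.DataFrame:
    """Flatten classified transitions into the canonical table schema.

    FTO and duration are rounded to integer milliseconds here, at the
    reporting boundary; in-memory values stay unrounded.
    """
    rows = []
    for t in transitions:
        rows.append(
            {
                "dialogue_id": dialogue_id,
                "dyad": dyad,
                "group": group,
                "index": t.index,
                "type": t.kind,
                "fto_ms": None if t.fto_ms is None else round(t.fto_ms),
                "duration_ms": None if t.duration_ms is None else round(t.duration_ms),
                "outgoing": t.outgoing,
                "incoming": t.incoming,
                "time_s": round(t.anchor_time, 6),
                "epoch2": t.epoch_two,
                "epoch3": t.epoch_three,
                "label": t.label,
                "is_backchannel": t.is_backchannel,
            }
        )
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


def write_transitions(
    transitions: Iterable[Transition] | pd.DataFrame,
    path: str | Path,
    **frame_kwargs,
) -> pd.DataFrame:
    """Write a transition table (tab-separated); returns the frame written."""
    if isinstance(transitions, pd.DataFrame):
        df = transitions.reindex(columns=TRANSITION_COLUMNS)
    else:
        df = transitions_to_frame(transitions, **frame_kwargs)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_transitions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    return df.reindex(columns=TRANSITION_COLUMNS)
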