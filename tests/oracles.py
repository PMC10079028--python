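"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's event-sweep implementation: the
transition oracle rasterises both channels onto a 1 ms grid and tracks
the floor holder explicitly over run-length-encoded grid states; the
merge oracle applies the minimum-pause rule by repeated fixpoint passes.
"""

from __future__ import annotations

import numpy as np


def rasterise(ipus_ms: list[tuple[int, int]], total_ms: int) -> np.ndarray:
    act = np.zeros(total_ms, dtype=bool)
    for s, e in ipus_ms:
        act[s:e] = True
    return act


def _streak_start(act: np.ndarray, t: int) -> int:
    """Start of the contiguous activity streak containing ms ``t``."""
    s = t
    while s > 0 and act[s - 1]:
        s -= 1
    return s


def _streak_end(act: np.ndarray, t: int) -> int:
    e = t
    while e < len(act) and act[e]:
        e += 1
    return e


def _last_offset_before(act: np.ndarray, t: int) -> int:
    """End (exclusive ms) of the speaker's last activity streak ending <= t."""
    s = t
    while s > 0 and not act[s - 1]:
        s -= 1
    return s


def grid_classify(
    ipus_a: list[tuple[int, int]],
    ipus_b: list[tuple[int, int]],
    total_ms: int,
) -> list[dict]:
    """Classify transitions on a 1 ms grid with explicit floor tracking.

    Input IPUs are integer-millisecond intervals per speaker ("A"/"B").
    Returns dicts with kind, fto_ms (transfers), outgoing/incoming,
    anchor_ms, and duration_ms (within-overlaps), in time order.
    """
    act = {"A": rasterise(ipus_a, total_ms), "B": rasterise(ipus_b, total_ms)}
    state = act["A"].astype(np.int8) * 2 + act["B"].astype(np.int8)
    # run-length encode the joint state
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [total_ms]))
    labels = state[starts]

    def other(s: str) -> str:
        return "B" if s == "A" else "A"

    floor = None
    pending: list[int] = []  # start ms of unresolved overlap runs
    events: list[dict] = []

    def resolve_within(holder: str) -> None:
        guest = other(holder)
        for p in pending:
            gs = _streak_start(act[guest], p)
            ge = _streak_end(act[guest], p)
            events.append(
                {
                    "kind": "within_overlap",
                    "outgoing": holder,
                    "incoming": holder,
                    "anchor_ms": gs,
                    "duration_ms": ge - gs,
                }
            )
        pending.clear()

    for s0, _e0, lab in zip(starts, ends, labels):
        if lab == 0:
            continue
        if lab == 3:
            if floor is not None:
                pending.append(s0)
            continue
        speaker = "A" if lab == 2 else "B"
        if floor is None:
            floor = speaker
            pending.clear()
            continue
        if speaker == floor:
            if pending:
                resolve_within(floor)
            continue
        # floor transfer
        onset = _streak_start(act[speaker], pending[0] if pending else s0)
        offset = _last_offset_before(act[floor], s0)
        fto = onset - offset
        events.append(
            {
                "kind": "gap" if fto >= 0 else "between_overlap",
                "outgoing": floor,
                "incoming": speaker,
                "anchor_ms": onset,
                "fto_ms": fto,
            }
        )
        floor = speaker
        pending.clear()

    if floor is not None and pending:
        resolve_within(floor)
    events.sort(key=lambda d: (d["anchor_ms"], d["kind"]))
    return events


def fixpoint_merge(
    ipus_ms: list[tuple[int, int]], min_pause_ms: int
) -> list[tuple[int, int]]:
    """Merge sub-threshold pauses by repeated passes until nothing changes."""
    current = sorted(ipus_ms)
    while True:
        for i in range(len(current) - 1):
            if current[i + 1][0] - current[i][1] < min_pause_ms:
                merged = (current[i][0], current[i + 1][1])
                current = current[:i] + [merged] + current[i + 2:]
                break
        else:
            return current


def random_grid_channels(
    rng: np.random.Generator,
    total_ms: int = 20000,
    snap_p: float = 0.3,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Two random canonical channels on an integer-ms grid.

    Channel B's boundaries are snapped onto channel A's with probability
    ``snap_p`` to provoke touching boundaries, simultaneous starts/stops,
    nested overlaps and interjections inside pauses.
    """
    def one_channel() -> list[tuple[int, int]]:
        out = []
        t = int(rng.integers(0, 800))
        while t < total_ms - 300:
            dur = int(rng.integers(80, 3000))
            end = min(t + dur, total_ms)
            out.append((t, end))
            t = end + 200 + int(rng.integers(0, 1500))
        return out

    a = one_channel()
    b = one_channel()
    a_bounds = [x for iv in a for x in iv]
    snapped = []
    for s, e in b:
        if a_bounds and rng.random() < snap_p:
            target = a_bounds[int(rng.integers(len(a_bounds)))]
            shift = target - (s if rng.random() < 0.5 else e)
            s, e = s + shift, e + shift
        if s >= 0 and e <= total_ms and e > s:
            snapped.append((s, e))
    # snapping may have broken ordering/pause rule; re-impose it
    snapped.sort()
    b_fixed: list[tuple[int, int]] = []
    for s, e in snapped:
        if b_fixed and s < b_fixed[-1][1] + 200:
            continue
        b_fixed.append((s, e))
    return a, b_fixed
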