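"""Minimal Praat TextGrid reader/writer (long and short text dialects).

Only what dialogue annotation needs: interval tiers (point tiers are
parsed and skipped). Both dialects are reduced to the same token stream —
quoted strings and numbers in file order — which makes the two parsers one.
Encoding follows Praat practice: UTF-8 first, UTF-16 fallback.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path


class TextGridParseError(ValueError):
    """Raised when a file cannot be interpreted as a TextGrid."""


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass(frozen=True)
class Tier:
    name: str
    tier_class: str  # "IntervalTier" or "TextTier"
    xmin: float
    xmax: float
    intervals: tuple[Interval, ...]  # for TextTier: degenerate xmin==xmax


@dataclass(frozen=True)
class TextGrid:
    xmin: float
    xmax: float
    tiers: tuple[Tier, ...]

    def tier(self, name: str) -> Tier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise KeyError(
            f"tier {name!r} not found; available tiers: "
            f"{[t.name for t in self.tiers]}"
        )


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    if raw.startswith(b"\xff\xfe") or raw.startswith(b"\xfe\xff"):
        return raw.decode("utf-16")
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("utf-16")


# quoted string (with "" escapes, may span lines) or a bare number
_TOKEN = re.compile(r'"(?:[^"]|"")*"|[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?')
_BRACKETED = re.compile(r"\[[^\]]*\]")


def _tokenize(text: str) -> list[str | float]:
    # strip "[1]"-style indices of the long dialect so their digits do not
    # leak into the numeric stream
    body = _BRACKETED.sub("", text)
    toks: list[str | float] = []
    for m in _TOKEN.finditer(body):
        tok = m.group(0)
        if tok.startswith('"'):
            toks.append(tok[1:-1].replace('""', '"'))
        else:
            toks.append(float(tok))
    return toks


class _Stream:
    def __init__(self, toks: list[str | float], path: Path):
        self._toks = toks
        self._pos = 0
        self._path = path

    def _next(self) -> str | float:
        if self._pos >= len(self._toks):
            raise TextGridParseError(
                f"{self._path}: truncated TextGrid (token {self._pos})"
            )
        tok = self._toks[self._pos]
        self._pos += 1
        return tok

    def number(self) -> float:
        tok = self._next()
        if not isinstance(tok, float):
            raise TextGridParseError(
                f"{self._path}: expected number at token {self._pos - 1}, got {tok!r}"
            )
        return tok

    def string(self) -> str:
        tok = self._next()
        if not isinstance(tok, str):
            raise TextGridParseError(
                f"{self._path}: expected string at token {self._pos - 1}, got {tok!r}"
            )
        return tok


def read(path: str | Path) -> TextGrid:
    """Parse a TextGrid file (either dialect) into a :class:`TextGrid`."""
    path = Path(path)
    text = _read_text(path)
    stream = _Stream(_tokenize(text), path)
    ftype = stream.string()
    oclass = stream.string()
    if ftype != "ooTextFile" or oclass != "TextGrid":
        raise TextGridParseError(
            f"{path}: not a TextGrid (file type {ftype!r}, class {oclass!r})"
        )
    xmin = stream.number()
    xmax = stream.number()
    n_tiers = int(stream.number())
    tiers = []
    for _ in range(n_tiers):
        tier_class = stream.string()
        name = stream.string()
        t_xmin = stream.number()
        t_xmax = stream.number()
        n_items = int(stream.number())
        intervals = []
        if tier_class == "IntervalTier":
            for _ in range(n_items):
                i_min = stream.number()
                i_max = stream.number()
                intervals.append(Interval(i_min, i_max, stream.string()))
        elif tier_class == "TextTier":
            for _ in range(n_items):
                t = stream.number()
                intervals.append(Interval(t, t, stream.string()))
        else:
            raise TextGridParseError(f"{path}: unknown tier class {tier_class!r}")
        tiers.append(Tier(name, tier_class, t_xmin, t_xmax, tuple(intervals)))
    return TextGrid(xmin, xmax, tuple(tiers))


def _q(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write(grid: TextGrid, path: str | Path, dialect: str = "long") -> None:
    """Write a :class:`TextGrid` in the requested dialect (UTF-8)."""
    if dialect not in ("long", "short"):
        raise ValueError(f"dialect must be 'long' or 'short', got {dialect!r}")
    lines: list[str] = []
    if dialect == "long":
        lines += [
            'File type = "ooTextFile"',
            'Object class = "TextGrid"',
            "",
            f"xmin = {grid.xmin:.6f}",
            f"xmax = {grid.xmax:.6f}",
            "tiers? <exists>",
            f"size = {len(grid.tiers)}",
            "item []:",
        ]
        for ti, tier in enumerate(grid.tiers, start=1):
            lines += [
                f"    item [{ti}]:",
                f"        class = {_q(tier.tier_class)}",
                f"        name = {_q(tier.name)}",
                f"        xmin = {tier.xmin:.6f}",
                f"        xmax = {tier.xmax:.6f}",
                f"        intervals: size = {len(tier.intervals)}",
            ]
            for ii, iv in enumerate(tier.intervals, start=1):
                lines += [
                    f"        intervals [{ii}]:",
                    f"            xmin = {iv.xmin:.6f}",
                    f"            xmax = {iv.xmax:.6f}",
                    f"            text = {_q(iv.text)}",
                ]
    else:
        lines += [
            'File type = "ooTextFile"',
            'Object class = "TextGrid"',
            "",
            f"{grid.xmin:.6f}",
            f"{grid.xmax:.6f}",
            "<exists>",
            f"{len(grid.tiers)}",
        ]
        for tier in grid.tiers:
            lines += [
                _q(tier.tier_class),
                _q(tier.name),
                f"{tier.xmin:.6f}",
                f"{tier.xmax:.6f}",
                f"{len(tier.intervals)}",
            ]
            for iv in tier.intervals:
                lines += [f"{iv.xmin:.6f}", f"{iv.xmax:.6f}", _q(iv.text)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
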