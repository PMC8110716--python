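"""Canonical interval/timeline data model and Praat TextGrid I/O.

Everything downstream (VAD output, turn-taking segmentation, feature
extraction) works with the three types defined here:

``Interval``
    a half-open [start, end) span in seconds,
``ActivityTrack``
    one speaker's binary speech/silence timeline for one trial,
``TimingEvent``
    a labelled interval (IPU, turn, pause, gap or transition overlap)
    with its owning speaker(s).

Times are seconds throughout; thresholds given in milliseconds at the CLI
are converted before they reach this module.  Adjacency (one interval's end
equal to the next one's start) is not overlap.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRIALS = ("describe", "match", "describe_and_match")

EVENT_KINDS = ("ipu", "turn", "pause", "gap", "transition_overlap")

#: labels treated as silence when reading TextGrids
DEFAULT_SILENCE_LABELS = frozenset({"", "sil", "#"})


class TextGridParseError(ValueError):
    """Raised when a TextGrid file cannot be parsed; carries the line number."""


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open time interval [start, end) in seconds.

    Zero duration (end == start) is permitted only so that a flush speaker
    transition — no silence and no overlap — can be recorded as a gap of
    duration 0; speech intervals and timing units are always positive.
    """

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start) and math.isfinite(self.end)):
            raise ValueError("interval bounds must be finite")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end must not precede start: ({self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ActivityTrack:
    """One speaker's binary speech timeline for one trial.

    Intervals are sorted by onset, non-overlapping, and bounded by
    ``session_end``.
    """

    speaker_id: str
    trial: str
    speech_intervals: list[Interval] = field(default_factory=list)
    session_end: float = 0.0

    def __post_init__(self) -> None:
        if self.trial not in TRIALS:
            raise ValueError(f"unknown trial {self.trial!r}; expected one of {TRIALS}")
        self.speech_intervals = sorted(self.speech_intervals, key=lambda iv: iv.start)
        prev_end = 0.0
        for iv in self.speech_intervals:
            if iv.duration <= 0:
                raise ValueError(f"speech intervals must have positive duration: {iv}")
            if iv.start < prev_end:
                raise ValueError(
                    f"overlapping intervals in track {self.speaker_id!r}: "
                    f"interval starting {iv.start} overlaps previous end {prev_end}"
                )
            prev_end = iv.end
        if self.speech_intervals:
            last = self.speech_intervals[-1].end
            if self.session_end < last:
                self.session_end = last

    @property
    def total_speech(self) -> float:
        return sum(iv.duration for iv in self.speech_intervals)


@dataclass(frozen=True)
class TimingEvent:
    """A labelled timing unit.

    ``owner`` is the producing speaker for ipu/turn/pause; for a gap it is
    the speaker taking the floor (the responder) and ``other`` the speaker
    yielding it; a transition overlap carries both ids the same way.
    """

    kind: str
    interval: Interval
    owner: str
    other: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind in ("gap", "transition_overlap") and self.other is None:
            raise ValueError(f"{self.kind} events need both speaker ids")

    @property
    def duration(self) -> float:
        return self.interval.duration


# ---------------------------------------------------------------------------
# frame <-> interval conversion

def intervals_to_frames(track: ActivityTrack, step: float) -> np.ndarray:
    """Rasterise a track onto a boolean frame grid.

    Frame *i* covers [i*step, (i+1)*step); it is True iff its centre lies
    inside a speech interval.  Length is ceil(session_end / step).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(math.ceil(track.session_end / step))
    frames = np.zeros(n, dtype=bool)
    for iv in track.speech_intervals:
        # frame centres (i + 0.5)*step in [start, end)
        lo = int(math.ceil(iv.start / step - 0.5))
        hi = int(math.ceil(iv.end / step - 0.5))
        frames[max(lo, 0):min(hi, n)] = True
    return frames


def frames_to_intervals(frames: Sequence[bool], step: float) -> list[Interval]:
    """Turn maximal runs of True frames into intervals [i*step, (j+1)*step)."""
    if step <= 0:
        raise ValueError("step must be positive")
    arr = np.asarray(frames, dtype=bool)
    if arr.size == 0 or not arr.any():
        return []
    padded = np.concatenate(([False], arr, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [Interval(s * step, e * step) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Praat TextGrid I/O
#
# Both the verbose "long" format and the bare "short" format are supported,
# in UTF-8 or UTF-16.  Any non-whitespace label outside the configured
# silence set marks speech.

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")
_STR_RE = re.compile(r'"((?:[^"]|"")*)"')


def _grab_number(line: str, lineno: int) -> float:
    m = _NUM_RE.search(line)
    if m is None:
        raise TextGridParseError(f"line {lineno}: expected a number in {line!r}")
    return float(m.group())


def _grab_string(line: str, lineno: int) -> str:
    m = _STR_RE.search(line)
    if m is None:
        raise TextGridParseError(f"line {lineno}: expected a quoted string in {line!r}")
    return m.group(1).replace('""', '"')


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    if raw[:2] in (b"\xff\xfe", b"\xfe\xff"):
        return raw.decode("utf-16")
    return raw.decode("utf-8")


def read_textgrid(
    path: str | Path,
    trial: str = "describe",
    silence_labels: Iterable[str] = DEFAULT_SILENCE_LABELS,
) -> list[ActivityTrack]:
    """Read a Praat TextGrid; one ActivityTrack per interval tier.

    Tier names become speaker ids.  Intervals with labels in
    ``silence_labels`` (after stripping whitespace) are silence; every other
    labelled interval is speech.  Zero-length intervals are dropped.
    Point (TextTier) tiers are ignored.
    """
    silence = {s.strip() for s in silence_labels} | {""}
    text = _read_text(path)
    lines = text.splitlines()
    # locate header
    it = iter(enumerate(lines, start=1))
    header_seen = False
    for lineno, line in it:
        if "ooTextFile" in line:
            header_seen = True
        if "TextGrid" in line and header_seen:
            break
    else:
        raise TextGridParseError("line 1: not a Praat TextGrid (missing ooTextFile header)")

    # collect every number/string token with its line number, in order;
    # this handles long and short formats uniformly because the long
    # format's extra text ("xmin = ") never contains digits or quotes.
    tokens: list[tuple[int, str, object]] = []
    for lineno, line in it:
        stripped = line.strip()
        if not stripped:
            continue
        m = _STR_RE.search(stripped)
        if m is not None:
            tokens.append((lineno, "s", m.group(1).replace('""', '"')))
            continue
        if "exists" in stripped:  # "tiers? <exists>" flag line
            continue
        m = _NUM_RE.search(stripped)
        if m is not None:
            # skip pure index lines of the long format: "item [1]:", "intervals [3]:"
            if stripped.startswith(("item", "intervals [", "points [")):
                continue
            tokens.append((lineno, "n", float(m.group())))

    pos = 0

    def need(kind: str) -> tuple[int, object]:
        nonlocal pos
        while pos < len(tokens) and tokens[pos][1] != kind:
            pos += 1
        if pos >= len(tokens):
            raise TextGridParseError(f"line {len(lines)}: truncated TextGrid (expected {kind!r} token)")
        lineno, _, val = tokens[pos]
        pos += 1
        return lineno, val

    _, _gxmin = need("n")
    _, _gxmax = need("n")
    _, ntiers = need("n")
    tracks: list[ActivityTrack] = []
    for _ in range(int(ntiers)):
        _, tier_class = need("s")
        name_line, tier_name = need("s")
        _, txmin = need("n")
        lineno, txmax = need("n")
        _, nitems = need("n")
        if tier_class == "IntervalTier":
            intervals: list[Interval] = []
            for _ in range(int(nitems)):
                _, xmin = need("n")
                xline, xmax = need("n")
                lline, label = need("s")
                if str(label).strip() in silence:
                    continue
                if xmax <= xmin:  # zero-length: drop
                    continue
                if xmin < 0:
                    raise TextGridParseError(f"line {xline}: negative interval start {xmin}")
                intervals.append(Interval(float(xmin), float(xmax)))
            try:
                tracks.append(
                    ActivityTrack(
                        speaker_id=str(tier_name),
                        trial=trial,
                        speech_intervals=intervals,
                        session_end=float(txmax),
                    )
                )
            except ValueError as exc:
                raise TextGridParseError(f"tier {tier_name!r} near line {name_line}: {exc}") from exc
        else:
            # point tier: consume number+string per point, ignore
            for _ in range(int(nitems)):
                need("n")
                need("s")
    return tracks


def write_textgrid(tracks: Sequence[ActivityTrack], path: str | Path, speech_label: str = "s") -> None:
    """Write ActivityTracks as a long-format TextGrid, one tier per track.

    Silence between speech intervals is written as empty-labelled intervals
    so Praat renders a contiguous tier.
    """
    if not tracks:
        raise ValueError("no tracks to write")
    xmax = max(t.session_end for t in tracks)
    out: list[str] = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tracks)}",
        "item []:",
    ]
    for ti, track in enumerate(tracks, start=1):
        pieces: list[tuple[float, float, str]] = []
        cursor = 0.0
        for iv in track.speech_intervals:
            if iv.start > cursor:
                pieces.append((cursor, iv.start, ""))
            pieces.append((iv.start, iv.end, speech_label))
            cursor = iv.end
        if cursor < xmax:
            pieces.append((cursor, xmax, ""))
        if not pieces:
            pieces.append((0.0, max(xmax, 1e-6), ""))
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{track.speaker_id}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(pieces)}",
        ]
        for ii, (a, b, lab) in enumerate(pieces, start=1):
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {a:.6f}",
                f"            xmax = {b:.6f}",
                f'            text = "{lab}"',
            ]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def events_to_frame(events: Iterable[TimingEvent], trial: str | None = None) -> pd.DataFrame:
    """Tabulate TimingEvents with columns (speaker, trial, kind, start, end, duration)."""
    rows = [
        {
            "speaker": ev.owner,
            "trial": trial,
            "kind": ev.kind,
            "start": ev.interval.start,
            "end": ev.interval.end,
            "duration": ev.duration,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["speaker", "trial", "kind", "start", "end", "duration"])
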