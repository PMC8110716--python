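"""The ten speech-timing measures, per speaker per trial.

Measures: number of pauses normalised to the speaker's turns; the
gap/transition-overlap ratio (gaps divided by overlaps at the speaker's
floor-takings — the higher the ratio, the more the speaker waits rather
than overlaps when taking a turn); per-event mean and SD of pause, gap,
transition-overlap, IPU and turn durations; and speech rate (syllable
nuclei per second over the turn span, pauses included), averaged over the
speaker's turns.

A ratio with zero overlaps is missing (NaN), never infinity or zero; SDs
are missing when fewer than two events exist.  Feature extraction is a
pure function of (timeline, nuclei).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .acoustic import speech_rate
from .turn_taking import DyadTimeline

log = logging.getLogger(__name__)

#: canonical feature order used in tables and by the classifier
FEATURE_NAMES = (
    "n_pauses_norm",
    "gap_overlap_ratio",
    "pause_dur",
    "gap_dur",
    "tov_dur",
    "ipu_dur",
    "turn_dur",
    "speech_rate",
)

_DURATION_KINDS = {"pause_dur": "pause", "gap_dur": "gap", "tov_dur": "transition_overlap",
                   "ipu_dur": "ipu", "turn_dur": "turn"}


@dataclass
class SpeakerTrialFeatures:
    speaker: str
    trial: str
    group: str | None = None
    n_turns: int = 0
    n_pauses_raw: int = 0
    n_pauses_norm: float = math.nan
    gap_overlap_ratio: float = math.nan
    pause_dur: float = math.nan
    pause_dur_sd: float = math.nan
    gap_dur: float = math.nan
    gap_dur_sd: float = math.nan
    tov_dur: float = math.nan
    tov_dur_sd: float = math.nan
    ipu_dur: float = math.nan
    ipu_dur_sd: float = math.nan
    turn_dur: float = math.nan
    turn_dur_sd: float = math.nan
    speech_rate: float = math.nan
    speech_rate_sd: float = math.nan


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else math.nan
    return float(arr.mean()), sd


def compute_features(
    timeline: DyadTimeline,
    nuclei: list[float] | None,
    speaker: str,
    group: str | None = None,
) -> SpeakerTrialFeatures:
    """Extract the ten timing measures for one speaker of a segmented trial.

    ``nuclei`` are the speaker's syllable-nucleus times; when None, speech
    rate is left missing.  A speaker with zero turns yields all-missing
    features (with a warning), never zeros.
    """
    out = SpeakerTrialFeatures(speaker=speaker, trial=timeline.trial, group=group)
    turns = timeline.of_kind("turn", owner=speaker)
    out.n_turns = len(turns)
    if not turns:
        log.warning("speaker %r owns no turns in trial %r: all features missing",
                    speaker, timeline.trial)
        return out

    pauses = timeline.of_kind("pause", owner=speaker)
    gaps = timeline.of_kind("gap", owner=speaker)          # owner = floor-taker
    overlaps = timeline.of_kind("transition_overlap", owner=speaker)
    ipus = timeline.of_kind("ipu", owner=speaker)

    out.n_pauses_raw = len(pauses)
    out.n_pauses_norm = len(pauses) / len(turns)
    out.gap_overlap_ratio = len(gaps) / len(overlaps) if overlaps else math.nan

    for attr, events in (
        ("pause_dur", pauses), ("gap_dur", gaps), ("tov_dur", overlaps),
        ("ipu_dur", ipus), ("turn_dur", turns),
    ):
        mean, sd = _mean_sd([ev.duration for ev in events])
        setattr(out, attr, mean)
        setattr(out, attr + "_sd", sd)

    if nuclei is not None:
        rates = [speech_rate(nuclei, t.interval) for t in turns]
        out.speech_rate, out.speech_rate_sd = _mean_sd(rates)
    return out


def build_feature_table(
    records: list[SpeakerTrialFeatures],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-speaker×trial features into a wide analysis table.

    One row per speaker×trial; ten mean columns and ten SD columns (counts
    stand in for the SDs of the two count-based measures), plus group and —
    when ``covariates`` indexed by speaker is given — age, sex, education
    and any other per-speaker columns.  Duplicate speaker×trial records are
    an error; missing ratios propagate as NaN.
    """
    if not records:
        raise ValueError("no feature records")
    rows = [{f.name: getattr(r, f.name) for f in fields(SpeakerTrialFeatures)} for r in records]
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["speaker", "trial"])
    if dup.any():
        pairs = df.loc[dup, ["speaker", "trial"]].itertuples(index=False)
        raise ValueError(f"duplicated speaker×trial rows: {[tuple(p) for p in pairs]}")
    if covariates is not None:
        df = df.merge(covariates, left_on="speaker", right_index=True, how="left",
                      suffixes=("", "_cov"))
    return df.sort_values(["speaker", "trial"]).reset_index(drop=True)


def events_long_table(timelines: list[DyadTimeline]) -> pd.DataFrame:
    """One row per timing event over many trials, for repeated-measures models."""
    rows = []
    for tl in timelines:
        for ev in tl.events:
            rows.append({
                "speaker": ev.owner,
                "other": ev.other,
                "trial": tl.trial,
                "kind": ev.kind,
                "start": ev.interval.start,
                "end": ev.interval.end,
                "duration": ev.duration,
            })
    return pd.DataFrame(rows, columns=["speaker", "other", "trial", "kind", "start", "end", "duration"])
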