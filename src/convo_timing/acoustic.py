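"""Audio front-end: voice activity detection and syllable-nucleus detection.

The VAD is a frame-wise likelihood-ratio detector: each frame's power
spectrum is compared with a noise model estimated from the lowest-energy
frames and tracked by minimum statistics, the per-frame log likelihood
ratio is thresholded, and the binary decision is smoothed by a hangover
scheme.  Because the noise model is re-estimated from the signal itself,
decisions are invariant to global gain changes.

Syllable nuclei are intensity peaks: a candidate peak on the dB intensity
contour counts as a nucleus iff it rises above an adaptive floor, is
flanked by dips of at least ``min_dip_db``, and falls inside a speech
interval.  Nuclei per second over a turn (pauses included in the
denominator) give the speech rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_timeline import ActivityTrack, Interval, frames_to_intervals


@dataclass
class VadConfig:
    frame_len: float = 0.025      # s, analysis window
    hop: float = 0.010            # s, frame step
    noise_init_frames: int = 10   # initial noise model = mean of this many lowest-energy frames
    llr_threshold: float = 0.5    # nats; decision threshold on the mean log likelihood ratio
    hangover_frames: int = 5      # dips up to this many frames are bridged; with
                                  # ~25 ms analysis-window smearing a larger value
                                  # would start swallowing genuine 100 ms pauses
    min_speech: float = 0.10      # s, shorter speech runs are deleted
    min_silence: float = 0.05     # s, shorter silence runs are bridged

    def __post_init__(self) -> None:
        for name in ("frame_len", "hop", "llr_threshold", "min_speech", "min_silence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_init_frames < 1 or self.hangover_frames < 0:
            raise ValueError("frame counts must be non-negative (noise_init_frames >= 1)")
        if self.min_silence > 0.1:
            raise ValueError(
                "min_silence must be <= 0.1 s: silences near the pause threshold "
                "must survive the VAD for the segmenter to see them"
            )


@dataclass
class SyllableConfig:
    intensity_floor_db: float = 10.0  # dB below the loudest peak: candidate floor
    min_dip_db: float = 2.0           # dB dip required on both sides of a nucleus
    min_nucleus_gap: float = 0.05     # s; closer nuclei merge to the louder one
    voicing_check: bool = False       # optional periodicity gate (autocorrelation)

    def __post_init__(self) -> None:
        if self.min_dip_db <= 0 or self.min_nucleus_gap <= 0:
            raise ValueError("min_dip_db and min_nucleus_gap must be positive")


def _frame_signal(x: np.ndarray, sr: int, frame_len: float, hop: float) -> np.ndarray:
    nper = max(int(round(frame_len * sr)), 2)
    nhop = max(int(round(hop * sr)), 1)
    if x.size < nper:
        x = np.pad(x, (0, nper - x.size))
    n_frames = 1 + (x.size - nper) // nhop
    idx = np.arange(nper)[None, :] + nhop * np.arange(n_frames)[:, None]
    return x[idx] * np.hanning(nper)[None, :]


def detect_speech(
    audio: np.ndarray,
    sr: int,
    config: VadConfig | None = None,
    speaker_id: str = "spk",
    trial: str = "describe",
) -> ActivityTrack:
    """Likelihood-ratio VAD -> ActivityTrack.

    Parameters
    ----------
    audio : 1-D float array (mono waveform)
    sr : sample rate, >= 8000 Hz
    """
    if sr < 8000:
        raise ValueError(f"sample rate must be >= 8 kHz, got {sr}")
    cfg = config or VadConfig()
    x = np.asarray(audio, dtype=np.float64).ravel()
    duration = x.size / sr
    if x.size == 0 or not np.any(x):
        return ActivityTrack(speaker_id, trial, [], session_end=duration)

    frames = _frame_signal(x, sr, cfg.frame_len, cfg.hop)
    psd = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (n_frames, n_bins)
    n_frames = psd.shape[0]
    eps = np.finfo(float).tiny

    # initial noise PSD: mean over the lowest-energy frames
    energy = psd.sum(axis=1)
    k = min(cfg.noise_init_frames, n_frames)
    quiet = np.argsort(energy)[:k]
    noise_psd = psd[quiet].mean(axis=0) + eps

    llr = np.empty(n_frames)
    xi_prev = np.ones_like(noise_psd)
    alpha_dd = 0.98       # decision-directed a-priori SNR smoothing
    alpha_noise = 0.95    # noise PSD update during non-speech
    gain_prev = np.ones_like(noise_psd)
    for t in range(n_frames):
        gamma = psd[t] / noise_psd                     # a-posteriori SNR
        xi = alpha_dd * (gain_prev ** 2) * xi_prev + (1 - alpha_dd) * np.maximum(gamma - 1.0, 0.0)
        xi = np.maximum(xi, 1e-3)
        # per-bin LLR for Gaussian speech+noise vs noise, averaged over bins
        lr = gamma * xi / (1.0 + xi) - np.log1p(xi)
        llr[t] = lr.mean()
        gain_prev = xi / (1.0 + xi)
        xi_prev = xi
        if llr[t] < cfg.llr_threshold:                 # update noise model in non-speech
            noise_psd = alpha_noise * noise_psd + (1 - alpha_noise) * psd[t]
            noise_psd = np.maximum(noise_psd, eps)

    raw = llr > cfg.llr_threshold

    # hangover: speech is held across dips of up to hangover_frames, i.e.
    # raw speech runs separated by such dips are bridged (this keeps run
    # boundaries where the statistic actually crossed the threshold)
    intervals = frames_to_intervals(raw, cfg.hop)
    merged: list[Interval] = []
    for iv in intervals:
        if merged and iv.start - merged[-1].end <= cfg.hangover_frames * cfg.hop:
            merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    intervals = _clean_runs(merged, cfg.min_speech, cfg.min_silence, duration)
    intervals = [Interval(iv.start, min(iv.end, duration)) for iv in intervals if iv.start < duration]
    return ActivityTrack(speaker_id, trial, intervals, session_end=duration)


def _clean_runs(
    intervals: list[Interval], min_speech: float, min_silence: float, duration: float
) -> list[Interval]:
    """Bridge silences shorter than min_silence, then delete speech shorter than min_speech."""
    if not intervals:
        return []
    merged = [intervals[0]]
    for iv in intervals[1:]:
        if iv.start - merged[-1].end < min_silence:
            merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return [iv for iv in merged if iv.duration >= min_speech]


def intensity_contour(audio: np.ndarray, sr: int, hop: float = 0.005, frame_len: float = 0.020):
    """dB RMS intensity per frame; returns (times, intensity_db)."""
    x = np.asarray(audio, dtype=np.float64).ravel()
    frames = _frame_signal(x, sr, frame_len, hop)
    rms = np.sqrt(np.mean(frames ** 2, axis=1)) + np.finfo(float).tiny
    db = 20.0 * np.log10(rms)
    t = hop * np.arange(frames.shape[0]) + frame_len / 2.0
    return t, db


def detect_syllable_nuclei(
    audio: np.ndarray,
    sr: int,
    config: SyllableConfig | None = None,
    restrict_to: ActivityTrack | None = None,
) -> list[float]:
    """Detect syllable nuclei as intensity peaks; returns nucleus times (s).

    A peak qualifies iff (a) its intensity exceeds the median candidate-peak
    intensity minus ``intensity_floor_db``, (b) the contour dips by at least
    ``min_dip_db`` between it and each neighbouring kept peak, and (c) it
    lies inside a speech interval of ``restrict_to`` when given.  Nuclei
    closer than ``min_nucleus_gap`` merge to the louder one.
    """
    cfg = config or SyllableConfig()
    x = np.asarray(audio, dtype=np.float64).ravel()
    if x.size == 0 or not np.any(x):
        return []
    t, db = intensity_contour(audio, sr)
    if db.size < 3:
        return []
    peaks, _ = sps.find_peaks(db)
    if peaks.size == 0:
        return []
    floor = db[peaks].max() - cfg.intensity_floor_db
    peaks = peaks[db[peaks] >= floor]
    if peaks.size == 0:
        return []

    # dip criterion between consecutive candidates
    kept: list[int] = []
    for p in peaks:
        if not kept:
            kept.append(p)
            continue
        prev = kept[-1]
        valley = db[prev:p + 1].min()
        if min(db[prev], db[p]) - valley >= cfg.min_dip_db:
            kept.append(p)
        elif db[p] > db[prev]:       # same nucleus: keep the louder frame
            kept[-1] = p

    if cfg.voicing_check:
        kept = [p for p in kept if _is_voiced(x, sr, t[p])]

    if restrict_to is not None:
        kept = [
            p for p in kept
            if any(iv.contains(t[p]) for iv in restrict_to.speech_intervals)
        ]

    # merge nuclei closer than min_nucleus_gap, louder wins
    merged: list[int] = []
    for p in kept:
        if merged and t[p] - t[merged[-1]] < cfg.min_nucleus_gap:
            if db[p] > db[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    return [float(t[p]) for p in merged]


def _is_voiced(x: np.ndarray, sr: int, t_center: float, win: float = 0.03) -> bool:
    """Crude periodicity gate: normalised autocorrelation peak in 60-400 Hz."""
    half = int(win * sr / 2)
    c = int(t_center * sr)
    seg = x[max(c - half, 0):c + half]
    if seg.size < 32:
        return False
    seg = seg - seg.mean()
    denom = float(seg @ seg)
    if denom <= 0:
        return False
    ac = np.correlate(seg, seg, mode="full")[seg.size - 1:] / denom
    lo, hi = int(sr / 400), min(int(sr / 60), ac.size - 1)
    if hi <= lo:
        return False
    return bool(ac[lo:hi].max() > 0.3)


def speech_rate(nuclei: list[float], span: Interval) -> float:
    """Syllables per second over ``span``; pauses inside the span count in the denominator."""
    if span.duration <= 0:
        raise ValueError("span must have positive duration")
    n = sum(1 for t in nuclei if span.contains(t))
    return n / span.duration
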