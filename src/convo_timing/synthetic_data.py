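"""Synthetic dyadic conversations, cognitive scores and ROI volumes.

The generator emulates the collaborative referencing sessions the
analysis pipeline expects: three trials (describe, match,
describe-and-match) of alternating turns between a participant (HC, MCI
or AD profile) and a communication partner (HC profile), with
group-by-trial timing distributions calibrated to the published cohort
profiles and a whole session averaging about twelve minutes.

Durations are lognormal with moment-matched mean and SD — the printed
SD-of-the-order-of-the-mean regime rules out Gaussian durations, which
would go negative.  Each turn draws an IPU count so the expected number
of pauses per turn matches the profile (turn duration is therefore
emergent, the composition of IPU and pause draws, rather than separately
moment-matched).  At each speaker change the floor-taker draws a gap with
probability p_gap = r/(1+r) (r the profile's gap/overlap ratio), else a
transition overlap.  Syllable nuclei are placed inside IPUs at the
profile's speech rate with stochastic rounding, so re-extracted speech
rates are unbiased.

All operations take an explicit seed or Generator; the same seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_timeline import ActivityTrack, Interval, TimingEvent
from .turn_taking import DyadTimeline, Turn

GROUPS = ("HC", "MCI", "AD")
TRIALS = ("describe", "match", "describe_and_match")

#: target expected duration of one trial, seconds (3 trials ~ 12 min)
TRIAL_TARGET_S = 240.0

#: pauses are floored just above the segmentation threshold so that float
#: accumulation along a long session can never push one below it
PAUSE_FLOOR = 0.100 + 1e-6


# ---------------------------------------------------------------------------
# moment matching

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the requested mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.  sd = 0
    degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    mu, sigma = lognormal_params(mean, sd)
    if sigma == 0.0:
        return np.full(size, mean) if size is not None else mean
    return rng.lognormal(mu, sigma, size=size)


def floored_lognormal_mean(mean: float, sd: float, floor: float) -> float:
    """E[max(X, floor)] for X lognormal with the given first two moments."""
    mu, sigma = lognormal_params(mean, sd)
    if sigma == 0.0:
        return max(mean, floor)
    a = (math.log(floor) - mu) / sigma
    return floor * norm.cdf(a) + mean * norm.cdf(sigma - a)


# ---------------------------------------------------------------------------
# profiles

@dataclass(frozen=True)
class GroupTrialProfile:
    """Generative timing parameters for one group in one trial.

    ``moments`` maps feature name -> (mean, sd): n_pauses_norm,
    gap_overlap_ratio, pause_dur, gap_dur, tov_dur, ipu_dur, turn_dur,
    speech_rate.  Durations in seconds, speech rate in syllables/s.
    """

    group: str
    trial: str
    moments: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (m, s) in self.moments.items():
            if m <= 0 and name != "orientation":
                raise ValueError(f"{self.group}/{self.trial}/{name}: mean must be positive")
            if s < 0:
                raise ValueError(f"{self.group}/{self.trial}/{name}: sd must be >= 0")

    @property
    def p_gap(self) -> float:
        """Probability a floor-taking transition is a gap: r/(1+r)."""
        r = self.moments["gap_overlap_ratio"][0]
        return r / (1.0 + r)

    def mean(self, feature: str) -> float:
        return self.moments[feature][0]

    def sd(self, feature: str) -> float:
        return self.moments[feature][1]


@dataclass
class CohortProfile:
    """Per-group cognitive, demographic and volumetric distributions.

    Cognitive and demographic entries follow the published cohort tables;
    the ROI volume baselines are synthetic calibration values (plausible
    cm^3 magnitudes with group-level atrophy factors) since per-ROI
    descriptives were not printed.
    """

    demographics: dict[str, dict[str, tuple[float, float]]]
    female_pct: dict[str, float]
    cognitive: dict[str, dict[str, tuple[float, float]]]
    roi_base_cm3: dict[str, float]
    atrophy: dict[str, float]
    etiv: tuple[float, float] = (1450.0, 140.0)
    roi_noise_cv: float = 0.10

    @property
    def cognitive_scores(self) -> tuple[str, ...]:
        first = next(iter(self.cognitive.values()))
        return tuple(first)


# Group x trial speech-timing calibration: mean (sd) per feature.
_T2 = {
    ("AD", "describe"): dict(n_pauses_norm=(0.48, 0.17), gap_overlap_ratio=(10.35, 7.17),
                             pause_dur=(0.94, 1.38), gap_dur=(1.13, 1.45), tov_dur=(0.17, 0.12),
                             ipu_dur=(0.75, 0.56), turn_dur=(3.01, 3.78), speech_rate=(3.88, 1.76)),
    ("MCI", "describe"): dict(n_pauses_norm=(0.50, 0.14), gap_overlap_ratio=(8.88, 2.85),
                              pause_dur=(0.82, 1.28), gap_dur=(1.04, 1.55), tov_dur=(0.24, 0.18),
                              ipu_dur=(1.05, 0.76), turn_dur=(5.20, 5.96), speech_rate=(3.81, 1.61)),
    ("HC", "describe"): dict(n_pauses_norm=(0.42, 0.17), gap_overlap_ratio=(6.30, 4.16),
                             pause_dur=(0.60, 0.85), gap_dur=(0.69, 0.96), tov_dur=(0.34, 0.28),
                             ipu_dur=(1.03, 0.80), turn_dur=(3.12, 3.68), speech_rate=(4.27, 1.93)),
    ("AD", "match"): dict(n_pauses_norm=(0.35, 0.10), gap_overlap_ratio=(10.43, 7.02),
                          pause_dur=(0.85, 1.30), gap_dur=(1.36, 2.07), tov_dur=(0.22, 0.17),
                          ipu_dur=(0.65, 0.52), turn_dur=(1.41, 1.82), speech_rate=(4.28, 2.07)),
    ("MCI", "match"): dict(n_pauses_norm=(0.27, 0.12), gap_overlap_ratio=(9.42, 6.67),
                           pause_dur=(1.01, 1.53), gap_dur=(1.18, 1.83), tov_dur=(0.25, 0.20),
                           ipu_dur=(0.71, 0.54), turn_dur=(1.48, 2.16), speech_rate=(4.16, 2.03)),
    ("HC", "match"): dict(n_pauses_norm=(0.33, 0.14), gap_overlap_ratio=(5.25, 2.98),
                          pause_dur=(0.78, 1.34), gap_dur=(0.78, 1.43), tov_dur=(0.29, 0.18),
                          ipu_dur=(0.89, 0.67), turn_dur=(1.89, 3.04), speech_rate=(3.84, 2.09)),
    ("AD", "describe_and_match"): dict(n_pauses_norm=(0.36, 0.16), gap_overlap_ratio=(6.12, 3.36),
                                       pause_dur=(0.64, 0.98), gap_dur=(1.23, 1.96), tov_dur=(0.27, 0.23),
                                       ipu_dur=(0.81, 0.65), turn_dur=(2.74, 4.44), speech_rate=(4.42, 1.73)),
    ("MCI", "describe_and_match"): dict(n_pauses_norm=(0.44, 0.11), gap_overlap_ratio=(8.95, 4.94),
                                        pause_dur=(0.92, 1.38), gap_dur=(1.00, 1.67), tov_dur=(0.23, 0.20),
                                        ipu_dur=(0.97, 0.74), turn_dur=(3.19, 4.77), speech_rate=(3.99, 1.51)),
    ("HC", "describe_and_match"): dict(n_pauses_norm=(0.37, 0.08), gap_overlap_ratio=(5.43, 2.29),
                                       pause_dur=(0.66, 0.96), gap_dur=(0.69, 1.31), tov_dur=(0.25, 0.19),
                                       ipu_dur=(0.97, 0.68), turn_dur=(2.63, 4.31), speech_rate=(3.99, 2.03)),
}

_T1_COGNITIVE = {
    "AD": dict(rbans_total=(64.3, 11.8), moca_total=(16.8, 4.3), memory=(14.3, 7.7),
               language=(33.8, 15.0), wm_attention=(23.8, 18.6), visuo_ef=(18.3, 26.0),
               orientation=(-20.0, 51.1), total_gray_matter=(554.3, 55.5)),
    "MCI": dict(rbans_total=(84.9, 10.1), moca_total=(22.7, 2.5), memory=(29.3, 6.7),
                language=(43.0, 13.1), wm_attention=(38.5, 11.5), visuo_ef=(43.3, 19.3),
                orientation=(39.0, 17.1), total_gray_matter=(587.6, 37.2)),
    "HC": dict(rbans_total=(107.6, 12.7), moca_total=(27.0, 1.7), memory=(52.3, 6.9),
               language=(51.0, 6.1), wm_attention=(50.4, 8.1), visuo_ef=(49.1, 8.0),
               orientation=(47.7, 16.4), total_gray_matter=(581.0, 59.2)),
}

_T1_DEMOGRAPHICS = {
    "AD": dict(age=(71.8, 6.9), education=(13.3, 2.5)),
    "MCI": dict(age=(74.0, 8.1), education=(13.4, 1.6)),
    "HC": dict(age=(69.8, 6.5), education=(13.2, 1.9)),
}

_FEMALE_PCT = {"AD": 50.0, "MCI": 30.0, "HC": 42.0}

# synthetic ROI volume baselines (cm^3, per hemisphere), not printed values
_ROI_BASE = {
    "ifg": 8.5, "mfg": 14.0, "prec": 9.0, "ipl": 12.0, "itg": 9.5,
    "mtg": 11.0, "stg_pt": 2.2, "ffg": 7.5, "cereb": 55.0,
}
_ATROPHY = {"HC": 1.00, "MCI": 0.97, "AD": 0.93}


def profiles_from_yaml(path) -> dict[tuple[str, str], GroupTrialProfile]:
    """Timing profiles with overrides from a YAML file.

    The file maps group -> trial -> feature -> [mean, sd]; anything not
    listed keeps its default calibration value.  Example::

        AD:
          describe:
            speech_rate: [3.5, 1.8]
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profiles, _ = default_profiles()
    for group, trials in raw.items():
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r} in {path}")
        for trial, feats in (trials or {}).items():
            if (group, trial) not in profiles:
                raise ValueError(f"unknown trial {trial!r} in {path}")
            moments = dict(profiles[(group, trial)].moments)
            for feat, pair in (feats or {}).items():
                if feat not in moments:
                    raise ValueError(f"unknown feature {feat!r} in {path}")
                mean, sd = (float(pair[0]), float(pair[1]))
                moments[feat] = (mean, sd)
            profiles[(group, trial)] = GroupTrialProfile(group, trial, moments)
    return profiles


def default_profiles() -> tuple[dict[tuple[str, str], GroupTrialProfile], CohortProfile]:
    """The nine group-by-trial timing profiles and the cohort profile."""
    profiles = {
        key: GroupTrialProfile(group=key[0], trial=key[1], moments=dict(vals))
        for key, vals in _T2.items()
    }
    cohort = CohortProfile(
        demographics={g: dict(v) for g, v in _T1_DEMOGRAPHICS.items()},
        female_pct=dict(_FEMALE_PCT),
        cognitive={g: dict(v) for g, v in _T1_COGNITIVE.items()},
        roi_base_cm3=dict(_ROI_BASE),
        atrophy=dict(_ATROPHY),
    )
    return profiles, cohort


# ---------------------------------------------------------------------------
# dyad simulation

def _expected_turn_s(profile: GroupTrialProfile) -> float:
    """Exact expected turn duration under the compositional generator."""
    nu = profile.mean("n_pauses_norm")
    e_pause = floored_lognormal_mean(*profile.moments["pause_dur"], PAUSE_FLOOR)
    return (1.0 + nu) * profile.mean("ipu_dur") + nu * e_pause


_TRANSITION_CACHE: dict[tuple, float] = {}


def _expected_transition_s(responder: GroupTrialProfile, n_mc: int = 200_000) -> float:
    """Expected signed transition length: gaps add time, overlaps remove it.

    The overlap clamp (an overlap cannot exceed 80% of either flanking
    IPU) has no closed form, so its expectation is estimated once per
    profile by a large fixed-seed Monte-Carlo draw and cached.
    """
    key = (responder.group, responder.trial,
           tuple(sorted(responder.moments.items())), n_mc)
    if key in _TRANSITION_CACHE:
        return _TRANSITION_CACHE[key]
    p = responder.p_gap
    e_gap = responder.mean("gap_dur")
    rng = np.random.default_rng(123456789)
    ov = _draw_lognormal(rng, *responder.moments["tov_dur"], size=n_mc)
    ipu1 = _draw_lognormal(rng, *responder.moments["ipu_dur"], size=n_mc)
    ipu2 = _draw_lognormal(rng, *responder.moments["ipu_dur"], size=n_mc)
    ov_clamped = np.minimum(np.asarray(ov), 0.8 * np.minimum(ipu1, ipu2))
    val = p * e_gap - (1.0 - p) * float(ov_clamped.mean())
    _TRANSITION_CACHE[key] = val
    return val


def _gen_turn(rng: np.random.Generator, profile: GroupTrialProfile, speaker: str, t0: float):
    """Draw one turn starting at t0; returns (list of IPU events, pauses)."""
    n_pauses = int(rng.poisson(profile.mean("n_pauses_norm")))
    ipu_durs = np.atleast_1d(_draw_lognormal(rng, *profile.moments["ipu_dur"], size=n_pauses + 1))
    pause_durs = np.maximum(
        np.atleast_1d(_draw_lognormal(rng, *profile.moments["pause_dur"], size=n_pauses)),
        PAUSE_FLOOR,
    ) if n_pauses else np.empty(0)
    ipus, pauses = [], []
    t = t0
    for i, d in enumerate(ipu_durs):
        ipus.append(TimingEvent("ipu", Interval(t, t + float(d)), owner=speaker))
        t += float(d)
        if i < n_pauses:
            pauses.append(TimingEvent("pause", Interval(t, t + float(pause_durs[i])), owner=speaker))
            t += float(pause_durs[i])
    return ipus, pauses


def _place_nuclei(rng: np.random.Generator, ipus, rate: float) -> list[float]:
    """Place syllable nuclei inside a turn's IPUs at the given overall rate.

    The count is ``rate x turn-span`` with stochastic rounding (unbiased);
    positions are stratified over the concatenated IPU support so rendered
    bursts stay apart.
    """
    span = ipus[-1].interval.end - ipus[0].interval.start
    target = rate * span
    count = int(math.floor(target)) + (1 if rng.random() < target - math.floor(target) else 0)
    if count == 0:
        return []
    durs = np.array([ev.duration for ev in ipus])
    total = durs.sum()
    # stratified positions on [0, total)
    u = (np.arange(count) + rng.uniform(0.3, 0.7, size=count)) * (total / count)
    edges = np.concatenate(([0.0], np.cumsum(durs)))
    idx = np.searchsorted(edges, u, side="right") - 1
    idx = np.clip(idx, 0, len(ipus) - 1)
    return [float(ipus[i].interval.start + (u_k - edges[i])) for i, u_k in zip(idx, u)]


def simulate_dyad(
    profile: GroupTrialProfile,
    partner_profile: GroupTrialProfile,
    seed: int | np.random.Generator,
    speaker_ids: tuple[str, str] = ("P", "C"),
    target_duration_s: float = TRIAL_TARGET_S,
    n_turn_pairs: int | None = None,
) -> tuple[DyadTimeline, dict[str, list[float]]]:
    """Simulate one trial of dyadic conversation.

    Speaker ``speaker_ids[0]`` follows ``profile`` (the participant) and
    ``speaker_ids[1]`` follows ``partner_profile`` (the partner).  Turns
    alternate; the number of turn pairs is Poisson with mean calibrated so
    the trial averages ``target_duration_s``.  Returns the full, already
    classified DyadTimeline and per-speaker syllable-nucleus times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sid_a, sid_b = speaker_ids
    profs = {sid_a: profile, sid_b: partner_profile}

    if n_turn_pairs is None:
        cycle = (
            _expected_turn_s(profile) + _expected_turn_s(partner_profile)
            + _expected_transition_s(profile) + _expected_transition_s(partner_profile)
        )
        e_trans = (_expected_transition_s(profile) + _expected_transition_s(partner_profile)) / 2
        lam = (target_duration_s + e_trans) / cycle
        n_pairs = max(1, int(rng.poisson(lam)))
    else:
        n_pairs = n_turn_pairs

    order = [sid_a, sid_b] * n_pairs
    turns: list[Turn] = []
    events: list[TimingEvent] = []
    nuclei: dict[str, list[float]] = {sid_a: [], sid_b: []}
    last_end: dict[str, float] = {}
    t = 0.0
    for k, spk in enumerate(order):
        p = profs[spk]
        ipus, pauses = _gen_turn(rng, p, spk, t0=max(t, 0.0))
        if k > 0:
            # transition relative to the previous turn's end (t currently there)
            prev_turn = turns[-1]
            responder = p
            if rng.random() < responder.p_gap:
                start = t + float(_draw_lognormal(rng, *responder.moments["gap_dur"]))
            else:
                ov = float(_draw_lognormal(rng, *responder.moments["tov_dur"]))
                # an overlap may not swallow either flanking IPU
                ov = min(ov, 0.8 * prev_turn.ipus[-1].duration, 0.8 * ipus[0].duration)
                start = t - max(ov, 0.0)
            # a speaker's own turns must stay separated by at least the
            # pause threshold, or re-segmentation would merge across the
            # partner's interjacent turn
            if spk in last_end:
                start = max(start, last_end[spk] + PAUSE_FLOOR + 1e-6)
            if start >= t:  # silence (possibly zero) at the change of speaker
                ev = TimingEvent("gap", Interval(t, start), owner=spk, other=prev_turn.speaker)
            else:
                ev = TimingEvent("transition_overlap", Interval(start, t),
                                 owner=spk, other=prev_turn.speaker)
            # re-position the freshly drawn turn at the transition point
            delta = start - ipus[0].interval.start
            ipus = [TimingEvent("ipu", Interval(e.interval.start + delta, e.interval.end + delta),
                                owner=spk) for e in ipus]
            pauses = [TimingEvent("pause", Interval(e.interval.start + delta, e.interval.end + delta),
                                  owner=spk) for e in pauses]
            events.append(ev)
        turn = Turn(spk, ipus)
        turns.append(turn)
        events.extend(ipus)
        events.extend(pauses)
        events.append(TimingEvent("turn", turn.span, owner=spk))
        rate = float(_draw_lognormal(rng, *p.moments["speech_rate"]))
        nuclei[spk].extend(_place_nuclei(rng, ipus, rate))
        t = turn.span.end
        last_end[spk] = t

    timeline = DyadTimeline(
        speakers=(sid_a, sid_b),
        trial=profile.trial,
        events=sorted(events, key=lambda ev: (ev.interval.start, ev.kind != "turn")),
    )
    timeline._turns = turns  # type: ignore[attr-defined]
    return timeline, nuclei


def tracks_from_timeline(timeline: DyadTimeline) -> dict[str, ActivityTrack]:
    """Per-speaker ActivityTracks (IPU support) of a simulated timeline."""
    session_end = max(ev.interval.end for ev in timeline.events)
    out = {}
    for spk in timeline.speakers:
        ivs = [ev.interval for ev in timeline.of_kind("ipu", owner=spk)]
        out[spk] = ActivityTrack(spk, timeline.trial, ivs, session_end=session_end)
    return out


def simulate_session(
    group: str,
    seed: int | np.random.Generator,
    profiles: dict[tuple[str, str], GroupTrialProfile] | None = None,
    speaker_ids: tuple[str, str] = ("P", "C"),
) -> tuple[list[DyadTimeline], dict[str, list[float]], float]:
    """One full three-trial session; partner follows the HC profiles.

    Returns (timelines per trial, nuclei pooled per speaker, total session
    duration in seconds).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profiles is None:
        profiles, _ = default_profiles()
    timelines, nuclei_all = [], {s: [] for s in speaker_ids}
    total = 0.0
    for trial in TRIALS:
        tl, nuc = simulate_dyad(profiles[(group, trial)], profiles[("HC", trial)],
                                rng, speaker_ids=speaker_ids)
        timelines.append(tl)
        for s in speaker_ids:
            nuclei_all[s].extend(nuc[s])
        total += max(ev.interval.end for ev in tl.events)
    return timelines, nuclei_all, total


# ---------------------------------------------------------------------------
# cohort simulation (analysis tables with plantable effects)

#: speaker-intercept SD chosen so that on a log-feature with weak fixed
#: effects the conditional-minus-marginal R^2 gap is about 0.17:
#: sd^2 / (sd^2 + residual^2) ~ 0.17 with residual 0.5
DEFAULT_RANDOM_INTERCEPT_SD = 0.23
DEFAULT_RESIDUAL_SD = 0.50

_LOG_FEATURES = ("pause_dur", "gap_dur", "tov_dur", "ipu_dur", "turn_dur",
                 "speech_rate", "n_pauses_norm", "gap_overlap_ratio")


def simulate_cohort(
    n_per_group: dict[str, int] | tuple[int, int, int],
    seed: int | np.random.Generator,
    profiles: dict[tuple[str, str], GroupTrialProfile] | None = None,
    cohort: CohortProfile | None = None,
    planted_effects: dict[tuple[str, str, str | None], float] | None = None,
    random_intercept_sd: float = DEFAULT_RANDOM_INTERCEPT_SD,
    residual_sd: float = DEFAULT_RESIDUAL_SD,
) -> dict[str, pd.DataFrame]:
    """Generate analysis-ready speaker and feature tables.

    ``n_per_group`` maps group -> count (a 3-tuple is taken in HC, MCI, AD
    order).  Per speaker: demographics matched across groups, composite
    scores and ROI volumes (correlated with eTIV) from the cohort profile,
    and one feature row per trial.  Log-features follow the generative
    model the mixed-model stage assumes::

        log y_it = log m(group, trial) + sum(planted slopes x z-predictor)
                   + b_i + e_it,   b_i ~ N(0, random_intercept_sd^2),
                                   e_it ~ N(0, residual_sd^2)

    ``planted_effects`` maps (feature, predictor, trial-or-None) -> slope;
    the slope applies on the z-scale (per SD) of the predictor, in the
    named trial only, or in every trial when the key's trial is None.
    Returns {"speakers": ..., "features": ...}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profiles is None or cohort is None:
        dprof, dcoh = default_profiles()
        profiles = profiles or dprof
        cohort = cohort or dcoh
    if not isinstance(n_per_group, dict):
        n_per_group = dict(zip(GROUPS, n_per_group))
    for g, n in n_per_group.items():
        if n < 2:
            raise ValueError(f"need n >= 2 per group, got {n} for {g}")

    rows = []
    for g in GROUPS:
        for i in range(n_per_group.get(g, 0)):
            dem = cohort.demographics[g]
            row = {
                "speaker": f"{g}_{i:03d}",
                "group": g,
                "age": rng.normal(*dem["age"]),
                "sex": int(rng.random() < cohort.female_pct[g] / 100.0),
                "education": rng.normal(*dem["education"]),
                "etiv": rng.normal(*cohort.etiv),
            }
            for score, (m, s) in cohort.cognitive[g].items():
                row[score] = rng.normal(m, s)
            for roi, base in cohort.roi_base_cm3.items():
                scale = cohort.atrophy[g] * (0.6 + 0.4 * row["etiv"] / cohort.etiv[0])
                for hemi in ("l", "r"):
                    row[f"{hemi}_{roi}"] = base * scale * (1.0 + rng.normal(0.0, cohort.roi_noise_cv))
            rows.append(row)
    speakers = pd.DataFrame(rows).set_index("speaker")

    planted = planted_effects or {}
    valid_predictors = set(speakers.columns) - {"group"}
    for (feat, pred, trial) in planted:
        if feat not in _LOG_FEATURES:
            raise ValueError(f"unknown planted feature {feat!r}")
        if pred not in valid_predictors:
            raise ValueError(f"unknown planted predictor {pred!r}")
        if trial is not None and trial not in TRIALS:
            raise ValueError(f"unknown planted trial {trial!r}")

    # z-scores of every continuous predictor over the realized cohort
    zcols = {}
    for pred in {p for (_, p, _) in planted}:
        x = speakers[pred].to_numpy(float)
        zcols[pred] = (x - x.mean()) / x.std(ddof=0)

    intercepts = {
        feat: dict(zip(speakers.index, rng.normal(0.0, random_intercept_sd, size=len(speakers))))
        for feat in _LOG_FEATURES
    }

    feat_rows = []
    for spk, srow in speakers.iterrows():
        g = srow["group"]
        zi = {p: z[speakers.index.get_loc(spk)] for p, z in zcols.items()}
        for trial in TRIALS:
            prof = profiles[(g, trial)]
            frow = {"speaker": spk, "group": g, "trial": trial}
            for feat in _LOG_FEATURES:
                eta = math.log(prof.mean(feat))
                for (pf, pred, ptrial), slope in planted.items():
                    if pf == feat and (ptrial is None or ptrial == trial):
                        eta += slope * zi[pred]
                eta += intercepts[feat][spk] + rng.normal(0.0, residual_sd)
                frow[feat] = math.exp(eta)
            feat_rows.append(frow)
    features = pd.DataFrame(feat_rows)
    features = features.merge(
        speakers.drop(columns=["group"]), left_on="speaker", right_index=True
    )
    return {"speakers": speakers.reset_index(), "features": features}


# ---------------------------------------------------------------------------
# audio rendering

def render_audio(
    timeline: DyadTimeline,
    nuclei: dict[str, list[float]],
    snr_db: float = 20.0,
    seed: int | np.random.Generator = 0,
    sr: int = 16000,
) -> dict[str, np.ndarray]:
    """Render one waveform per speaker from a simulated timeline.

    Each IPU carries a continuous low-level harmonic bed (voiced
    continuants) with a band-limited harmonic burst at every syllable
    nucleus, so the voice-activity detector sees the full IPU extent while
    the intensity contour still dips between nuclei.  Background Gaussian
    noise is mixed at ``snr_db`` relative to the bed level; silence
    elsewhere.  An empty timeline yields pure noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    session_end = max((ev.interval.end for ev in timeline.events), default=1.0)
    n = int(math.ceil(session_end * sr)) + 1
    f0s = {spk: f0 for spk, f0 in zip(timeline.speakers, (120.0, 185.0))}
    out = {}
    burst_amp, bed_amp = 0.5, 0.12
    for spk in timeline.speakers:
        x = np.zeros(n)
        f0 = f0s[spk]

        def harmonic(tvec, amp):
            y = np.zeros_like(tvec)
            for h in range(1, 9):
                if h * f0 < 0.45 * sr:
                    y += (amp / h) * np.sin(2 * np.pi * h * f0 * tvec)
            return y

        for ipu in timeline.of_kind("ipu", owner=spk):
            i0, i1 = int(ipu.interval.start * sr), int(ipu.interval.end * sr)
            tvec = np.arange(i1 - i0) / sr
            seg = harmonic(tvec, bed_amp)
            ramp = min(int(0.01 * sr), max((i1 - i0) // 4, 1))
            env = np.ones(i1 - i0)
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
            x[i0:i1] += seg * env
        ipu_bounds = [(int(ipu.interval.start * sr), int(ipu.interval.end * sr))
                      for ipu in timeline.of_kind("ipu", owner=spk)]
        times = sorted(nuclei.get(spk, []))
        for k, t_nuc in enumerate(times):
            # adapt the burst width to the local nucleus spacing so that the
            # intensity contour dips between consecutive nuclei
            w = 0.075
            if k > 0:
                w = min(w, 0.45 * (t_nuc - times[k - 1]))
            if k + 1 < len(times):
                w = min(w, 0.45 * (times[k + 1] - t_nuc))
            half = max(int(w * sr), 8)
            c = int(t_nuc * sr)
            i0, i1 = max(c - half, 0), min(c + half, n)
            # a burst must not leak outside its IPU, or the VAD would see
            # speech where the timeline has silence
            for b0, b1 in ipu_bounds:
                if b0 <= c < b1:
                    i0, i1 = max(i0, b0), min(i1, b1)
                    break
            if i1 <= i0:
                continue
            tvec = np.arange(i1 - i0) / sr
            burst = harmonic(tvec, burst_amp) * np.hanning(i1 - i0)
            x[i0:i1] += burst
        bed_rms = bed_amp / math.sqrt(2) * math.sqrt(sum(1.0 / h**2 for h in range(1, 9)))
        noise_rms = bed_rms * 10.0 ** (-snr_db / 20.0)
        x += rng.normal(0.0, noise_rms, size=n)
        out[spk] = x
    return out
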