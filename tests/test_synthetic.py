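"""Synthetic-conversation generator: calibration, determinism, round trips."""

import math

import numpy as np
import pytest

import convo_timing as ct
from convo_timing.features import compute_features
from convo_timing.synthetic_data import (
    GROUPS,
    TRIALS,
    default_profiles,
    floored_lognormal_mean,
    lognormal_params,
    render_audio,
    simulate_cohort,
    simulate_dyad,
    simulate_session,
    tracks_from_timeline,
)
from convo_timing.turn_taking import segment_dyad


class TestLognormalParams:
    def test_degenerate_point_mass(self):
        assert lognormal_params(1.0, 0.0) == (0.0, 0.0)

    def test_unit_mean_unit_sd(self):
        mu, sigma = lognormal_params(1.0, 1.0)
        assert sigma**2 == pytest.approx(math.log(2), rel=1e-12)
        assert mu == pytest.approx(-math.log(2) / 2, rel=1e-12)

    @pytest.mark.parametrize("mean,sd", [(1.0, 1.0), (1.23, 1.96), (0.75, 0.56)])
    def test_moments_recovered_by_simulation(self, mean, sd):
        mu, sigma = lognormal_params(mean, sd)
        x = np.random.default_rng(0).lognormal(mu, sigma, 10**6)
        assert x.mean() == pytest.approx(mean, rel=0.02)
        assert x.std() == pytest.approx(sd, rel=0.02)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params(0.0, 1.0)

    def test_floored_mean_matches_simulation(self):
        analytic = floored_lognormal_mean(0.94, 1.38, 0.1)
        mu, sigma = lognormal_params(0.94, 1.38)
        x = np.random.default_rng(1).lognormal(mu, sigma, 10**6)
        assert analytic == pytest.approx(np.maximum(x, 0.1).mean(), rel=0.01)


class TestDefaultProfiles:
    def test_nine_group_trial_profiles(self, profiles):
        assert set(profiles) == {(g, t) for g in GROUPS for t in TRIALS}

    def test_calibration_values(self, profiles, cohort_profile):
        assert profiles[("AD", "describe")].mean("speech_rate") == 3.88
        assert profiles[("AD", "describe")].mean("ipu_dur") == 0.75
        assert profiles[("AD", "describe_and_match")].moments["gap_dur"] == (1.23, 1.96)
        assert profiles[("HC", "describe_and_match")].mean("gap_dur") == 0.69
        assert cohort_profile.cognitive["AD"]["rbans_total"] == (64.3, 11.8)
        assert cohort_profile.cognitive["AD"]["memory"][0] == 14.3

    def test_yaml_override_merges_over_defaults(self, tmp_path):
        from convo_timing.synthetic_data import profiles_from_yaml
        cfg = tmp_path / "override.yaml"
        cfg.write_text("AD:\n  describe:\n    speech_rate: [3.5, 1.8]\n")
        profs = profiles_from_yaml(cfg)
        assert profs[("AD", "describe")].moments["speech_rate"] == (3.5, 1.8)
        assert profs[("AD", "describe")].moments["ipu_dur"] == (0.75, 0.56)
        assert profs[("HC", "match")].moments["speech_rate"] == (3.84, 2.09)
        cfg.write_text("AD:\n  describe:\n    bogus: [1, 1]\n")
        with pytest.raises(ValueError, match="unknown feature"):
            profiles_from_yaml(cfg)

    def test_p_gap_transform(self, profiles):
        r = profiles[("MCI", "describe")].mean("gap_overlap_ratio")
        assert r == 8.88
        assert profiles[("MCI", "describe")].p_gap == pytest.approx(8.88 / 9.88)


class TestSimulateDyad:
    def test_seed_determinism(self, profiles):
        args = (profiles[("AD", "describe")], profiles[("HC", "describe")])
        tl1, n1 = simulate_dyad(*args, 77)
        tl2, n2 = simulate_dyad(*args, 77)
        assert [(e.kind, e.interval, e.owner) for e in tl1.events] == \
            [(e.kind, e.interval, e.owner) for e in tl2.events]
        assert n1 == n2

    def test_resegmentation_recovers_event_counts(self, profiles):
        """Generated tracks, pushed back through the segmenter, give the
        exact generated event inventory (pauses are >= threshold by
        construction)."""
        for seed in range(8):
            tl, _ = simulate_dyad(profiles[("MCI", "match")], profiles[("HC", "match")], seed)
            tracks = tracks_from_timeline(tl)
            tl2 = segment_dyad(tracks["P"], tracks["C"])
            for kind in ("ipu", "turn", "pause", "gap", "transition_overlap"):
                assert len(tl.of_kind(kind)) == len(tl2.of_kind(kind)), (seed, kind)

    def test_gap_moment_recovery(self, profiles):
        """Simulated AD describe-and-match gaps average ~1.23 s."""
        mean, sd = profiles[("AD", "describe_and_match")].moments["gap_dur"]
        mu, sigma = lognormal_params(mean, sd)
        x = np.random.default_rng(3).lognormal(mu, sigma, 20000)
        se = x.std(ddof=1) / math.sqrt(x.size)
        assert abs(x.mean() - 1.23) <= 3 * se

    def test_timeline_invariants_by_construction(self, profiles):
        tl, nuclei = simulate_dyad(profiles[("HC", "describe")], profiles[("HC", "describe")], 5)
        turns = tl.of_kind("turn")
        assert tl.n_transitions == len(turns) - 1
        # nuclei fall inside their speaker's IPUs
        for spk in tl.speakers:
            ipus = tl.of_kind("ipu", owner=spk)
            for t in nuclei[spk]:
                assert any(iv.interval.contains(t) for iv in ipus)


class TestFeatureMomentRecovery:
    def test_cohort_means_converge_to_profile(self, profiles):
        """Directly generated features converge to the profile means."""
        prof, partner = profiles[("AD", "describe")], profiles[("HC", "describe")]
        rng = np.random.default_rng(9)
        rates, ipus, pauses_norm = [], [], []
        for _ in range(80):
            tl, nuc = simulate_dyad(prof, partner, rng)
            f = compute_features(tl, nuc["P"], "P")
            rates.append(f.speech_rate)
            ipus.append(f.ipu_dur)
            pauses_norm.append(f.n_pauses_norm)
        for got, want, tol in ((np.mean(rates), 3.88, 0.12),
                               (np.mean(ipus), 0.75, 0.04),
                               (np.mean(pauses_norm), 0.48, 0.05)):
            assert abs(got - want) <= tol


class TestSimulateSession:
    def test_three_trials_about_twelve_minutes(self, profiles):
        rng = np.random.default_rng(4)
        durs = [simulate_session(g, rng)[2] for _ in range(12) for g in GROUPS]
        assert 10.0 <= np.mean(durs) / 60 <= 14.0


class TestSimulateCohort:
    def test_shape_and_determinism(self):
        t1 = simulate_cohort({"HC": 11, "MCI": 11, "AD": 10}, 2024)
        t2 = simulate_cohort({"HC": 11, "MCI": 11, "AD": 10}, 2024)
        assert len(t1["features"]) == 96 and len(t1["speakers"]) == 32
        assert t1["features"].equals(t2["features"])

    def test_unknown_planted_keys_rejected(self):
        with pytest.raises(ValueError, match="predictor"):
            simulate_cohort((3, 3, 3), 0, planted_effects={("turn_dur", "nope", None): 1.0})
        with pytest.raises(ValueError, match="feature"):
            simulate_cohort((3, 3, 3), 0, planted_effects={("nope", "memory", None): 1.0})

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            simulate_cohort((1, 3, 3), 0)

    def test_cognitive_profile_means(self):
        tabs = simulate_cohort({"HC": 60, "MCI": 60, "AD": 60}, 7)
        sp = tabs["speakers"]
        ad = sp[sp.group == "AD"]
        assert ad["rbans_total"].mean() == pytest.approx(64.3, abs=3 * 11.8 / math.sqrt(60))
        assert ad["memory"].mean() == pytest.approx(14.3, abs=3 * 7.7 / math.sqrt(60))


class TestRenderAudio:
    def test_empty_timeline_is_pure_noise(self):
        from convo_timing.turn_taking import DyadTimeline
        from convo_timing.core_timeline import Interval, TimingEvent
        tl = DyadTimeline(speakers=("A", "B"), trial="describe",
                          events=[TimingEvent("turn", Interval(0, 1.0), owner="A")])
        audio = render_audio(tl, {"A": [], "B": []}, seed=0)
        assert abs(np.std(audio["B"]) - np.std(audio["A"])) < 0.01
        # no harmonic content for the silent speaker: flat spectrum-ish RMS
        assert np.std(audio["B"]) < 0.05

    def test_vad_roundtrip_recovers_ipus(self, profiles):
        """VAD on rendered audio at +20 dB recovers >=95% of IPUs with
        boundary error <= 50 ms."""
        sr = 16000
        total = matched = 0
        for seed in range(3):
            tl, nuclei = simulate_dyad(profiles[("HC", "describe")],
                                       profiles[("HC", "describe")], seed, n_turn_pairs=6)
            audio = render_audio(tl, nuclei, snr_db=20, seed=seed, sr=sr)
            tracks = tracks_from_timeline(tl)
            for spk in tl.speakers:
                det = ct.detect_speech(audio[spk], sr, speaker_id=spk).speech_intervals
                for iv in tracks[spk].speech_intervals:
                    total += 1
                    hit = any(abs(d.start - iv.start) <= 0.05 and abs(d.end - iv.end) <= 0.05
                              for d in det)
                    matched += hit
        assert matched / total >= 0.95

    def test_nucleus_counts_recovered_per_ipu(self, profiles):
        """Detected nucleus count equals the rendered burst count in >=95%
        of IPUs."""
        sr = 16000
        ok = total = 0
        for seed in range(3):
            tl, nuclei = simulate_dyad(profiles[("HC", "describe")],
                                       profiles[("HC", "describe")], 10 + seed, n_turn_pairs=6)
            audio = render_audio(tl, nuclei, snr_db=25, seed=seed, sr=sr)
            for spk in tl.speakers:
                track = tracks_from_timeline(tl)[spk]
                det = ct.detect_syllable_nuclei(audio[spk], sr, restrict_to=track)
                for iv in track.speech_intervals:
                    total += 1
                    want = sum(1 for t in nuclei[spk] if iv.contains(t))
                    got = sum(1 for t in det if iv.contains(t))
                    ok += (want == got)
        assert ok / total >= 0.95
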