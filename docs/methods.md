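# Methods

`convo-timing` analyses the temporal organisation of dyadic conversation —
who speaks when, how quickly turns are exchanged — as a behavioural marker
of cognitive status (healthy ageing, mild cognitive impairment, mild
Alzheimer's disease). This note documents the models, the synthetic data
the package is tested on, the numerical choices, and the limits of what
passing tests demonstrate.

## Turn-taking model

Two speakers' binary speech/silence timelines are segmented into five unit
types. An **interpausal unit (IPU)** is a stretch of one speaker's speech
bounded by silences of at least the pause threshold (default **100 ms**;
shorter within-speaker silences are indistinguishable from silent plosives
and are absorbed into the IPU). A **turn** is a maximal run of one
speaker's consecutive IPUs before the other speaker takes the floor. A
**pause** is a within-turn silence of at least the threshold, owned by the
turn holder. Each speaker transition is exactly one of a **gap** (silence
between the outgoing turn's offset and the incoming turn's onset, possibly
of zero duration at a flush transition) or a **transition overlap** (the
incoming speaker starts before the outgoing one finishes). Gaps and
overlaps are attributed to the floor-taking speaker, since the gap/overlap
balance characterises how an individual takes a turn.

Intervals are half-open `[start, end)`; adjacency is not overlap.
Simultaneous onsets are broken by lexicographic speaker id, so segmentation
is deterministic. Backchannels (short interjections that do not take the
floor) are supported via `backchannel_max` but **disabled by default**
(`0`): in the default configuration every IPU can take the floor and no
hidden heuristic shapes the unit inventory. Non-transition simultaneous
speech then surfaces as a nested one-IPU turn and is flagged, as are
lapses (gaps ≥ 10 s), rather than silently dropped.

## Ten timing features

Per speaker per trial: pauses per turn (`n_pauses_norm`; the raw count is
also emitted), the gap/overlap ratio at the speaker's floor-takings
(missing — never zero or infinite — when the overlap count is 0), mean and
SD of pause, gap, overlap, IPU and turn durations (SD missing below two
events), and speech rate: syllable nuclei per second over the turn span,
pauses included in the denominator, averaged over the speaker's turns.
Computing the rate per turn (rather than per IPU or per trial) is a
documented choice: within-turn pauses dilute the rate, matching a
"including pauses" reading; the alternative spans are selectable.

## Acoustic front-end

The voice activity detector is a frame-wise likelihood-ratio test
(25 ms Hann windows, 10 ms hop): per-frequency posterior SNR against a
noise spectrum initialised from the lowest-energy frames and updated
during non-speech, with a decision-directed prior-SNR estimate. The mean
per-bin log-likelihood ratio is thresholded at 0.5 nats. Because the noise
model is estimated from the recording itself, decisions are invariant to
global gain. Hangover smoothing bridges dips of up to 5 frames (50 ms);
with ~25 ms of window smearing, a longer hangover would start swallowing
genuine 100 ms pauses that the segmenter must see, which also caps the
`min_silence` cleanup at 100 ms. Runs shorter than `min_speech` (100 ms)
are discarded.

Syllable nuclei are intensity peaks (20 ms RMS windows, 5 ms hop, dB
scale): a peak is a nucleus iff it rises above the loudest peak minus
`intensity_floor_db` (10 dB), is flanked by dips of at least 2 dB, and
falls inside a detected speech interval. Nuclei closer than 50 ms merge to
the louder one. An optional autocorrelation voicing gate is off by
default. On unrestricted noise the peak picker will fire — restriction to
sounding intervals is part of the contract, as in the classic
intensity-based nucleus detectors.

## Synthetic conversations

The generator emulates the collaborative referencing session: three trials
(describe / match / describe-and-match) of alternating turns between a
participant following a group×trial profile and a partner following the
healthy-control profile for the same trial. Nine calibration profiles give
per-feature mean and SD; the cohort profile gives cognitive composites,
demographics and head-size-correlated regional volumes. Cognitive and
timing calibration values are taken from the published cohort descriptives;
the per-ROI volume baselines are synthetic (plausible cm³ magnitudes with
group atrophy factors 1.00/0.97/0.93), since per-ROI descriptives were not
published.

**Durations are lognormal**, moment-matched via
`sigma² = ln(1+(sd/mean)²)`, `mu = ln(mean) − sigma²/2`: with SDs of the
order of the means, Gaussian durations would go negative. Each turn draws
`1 + Poisson(n_pauses_norm)` IPUs so the expected pauses per turn matches
the profile; within-turn pauses are floored just above 100 ms so the
segmenter can never absorb them. **Turn duration is therefore emergent**
(IPUs plus pauses), not separately moment-matched: the calibration table's
turn-duration means are not jointly consistent with its IPU, pause and
pause-count values under independent draws, and the pause-count rule wins.
At each transition the floor-taker draws a gap with probability
`p_gap = r/(1+r)` (r = their gap/overlap ratio), else an overlap, clamped
so it swallows no more than 80 % of either flanking IPU and so a speaker
never overlaps their own previous turn (their turns also stay at least one
pause threshold apart, or re-segmentation would merge across the partner's
interjection). Syllable nuclei are placed inside IPUs at a per-turn
lognormal rate with stochastic rounding, so re-extracted rates are
unbiased; placement is stratified so rendered bursts stay separable.

Turn-pair counts are Poisson with mean set from the exact expected turn
length and a Monte-Carlo estimate of the clamped transition length so that
each trial averages 240 s and a three-trial session ≈ 12 minutes.

`render_audio` produces one waveform per speaker: a low-level harmonic bed
(120/185 Hz fundamentals) spans each IPU — speech is acoustically
continuous — with a band-limited harmonic burst at each nucleus whose
width adapts to the local nucleus spacing, plus Gaussian background noise
at the requested SNR relative to the bed. What the generator does **not**
model: lexical content, prosody, channel cross-talk, reverberation,
between-speaker voice variability, or within-speaker correlation of
timing across trials beyond the cohort model's random intercept. Passing
closure tests therefore shows the pipeline is self-consistent at
conversational SNRs, not that the VAD or nucleus detector meet clinical
accuracy on real recordings.

For analysis tables, `simulate_cohort` draws per-speaker demographics,
composites and volumes, and generates each log-feature per trial as
`log m(group, trial) + Σ slope·z(predictor) + b_i + e`, with speaker
intercepts `b_i ~ N(0, 0.23²)` and residuals `e ~ N(0, 0.5²)`. The
intercept SD makes the conditional-minus-marginal R² gap ≈ 0.17 on a
feature with weak fixed effects, matching the magnitude reported for the
cohort; planted slopes act on the z-scale of the predictor (per SD).
Independence across trials given the intercept is assumed.

## Statistical stage

Each feature is the dependent variable of a speaker-random-intercept
linear mixed model (REML by default, ML for likelihood-ratio tests),
adjusted for age, sex and education (plus estimated total intracranial
volume in volume models). `log_dv="auto"` log-transforms a positive
feature when its raw skewness exceeds 1, and records the choice in the fit
metadata. Composite scores are mean-centred, ROI volumes z-scored. Wald
95 % confidence intervals match the symmetric intervals conventionally
reported. Interaction significance is the LRT of ML fits with
`df = parameter-count difference`; effect size is Nakagawa–Schielzeth
`R²m = σ²_f/(σ²_f+σ²_r+σ²_e)` and `R²c = (σ²_f+σ²_r)/(·)` with `σ²_f` the
variance of the fixed-effect linear predictor over the data. Bonferroni
thresholds are `0.05/8 = 0.006` and `0.05/16 = 0.003` at three-decimal
reporting. Stepwise selection alternates backward and forward moves on ML
fits under AIC (a p-value criterion is selectable); covariates, the trial
term and the random intercept are never dropped. Five cognitive composites
are arithmetic means of their corrected subscores (memory, language,
working memory/attention, visuoconstructional/executive, orientation);
missing constituents are skipped with a flag.

Degenerate inputs: with one observation per speaker the intercept variance
is unidentifiable and coefficients reduce to OLS; boundary fits
(zero intercept variance) are flagged, not fatal; optimizer fallbacks
(default → lbfgs → powell → cg) handle occasional non-convergence at
n = 32.

## Classifier

Cartesian genetic programming over the feature table: 50 nodes, function
set {+, −, ×, protected ÷ (returns 1 when |denominator| < 1e-9)}, arity 2,
unconstrained levels-back, per-gene mutation at rate 0.1 (an
exactly-10 %-of-genes mode is selectable), (1+λ) evolution with λ = 4 by
default, fitness = training accuracy, ties to the offspring so neutral
drift can cross plateaus, stop at 15,000 iterations. Mutants whose changed
genes are all silent are adopted without re-evaluation — their phenotype is
provably identical. The validation subset never touches fitness; it
selects the reported genotype across generations, with validation ties
broken toward the genotype with better training fitness (on 18-sample
validation folds the earliest validation maximum is usually a lucky,
poorly trained graph). Non-finite outputs are clamped to 0 before
classification; binary labels threshold the single output at 0, multi-class
labels are the argmax with ties to the lowest index.

Cross-validation is stratified 5-fold (test fold, rotating validation
fold, three training folds), repeated over independently seeded runs; both
the mean over per-run means and the pooled fold mean are reported, and the
per-run winning genotypes are exported as readable arithmetic expressions
and DOT graphs. `scale_inputs` min-max scales features to [0, 1] using the
training folds only: arithmetic graphs behave far better on bounded inputs,
and the scaling never sees held-out samples.

At the scale the tests run (90 synthetic speakers, three-trial log
features), evolved classifiers reach roughly 20 points above 3-class
chance; linear discriminants — effectively the Bayes rule for this
lognormal generator — reach about 70 %. That gap is expected: a generic
evolved program on 54 training samples cannot match the generator's own
parametric form, and nothing here asserts real-cohort accuracy.

## Problem sizes and tolerances

The test suite simulates at sizes chosen to make three-Monte-Carlo-SE
checks decisive: 20,000 gap/IPU events, 100,000 transitions, 10,000
cognitive draws, 500 dyads for rate recovery, 1,000 sessions for session
length, 200 mixed-model replicates. The audio closure check runs three
8-turn-pair dyads at 16 kHz and +20 dB SNR and requires IPU counts within
10 %, mean IPU duration within 0.05 s, speech rate within 0.5 syll/s and
pauses-per-turn within 0.15 of the generated timeline. Classification
sanity uses 8,000 generations, λ = 8, 4 runs.

## Known limitations

- The TextGrid reader covers interval tiers in long/short text format
  (UTF-8/UTF-16); Praat's binary and collection formats are out of scope.
- The VAD is a single-channel energy-model detector; it does not separate
  overlapped speech recorded on one channel — per-speaker channels or
  tiers are assumed.
- Speech-rate estimation counts intensity nuclei; on real speech,
  reduction and cross-talk will bias counts in ways the synthetic render
  cannot exhibit.
- The emergent turn-duration distribution is narrower than the published
  cohort's, because between-speaker heterogeneity enters the dyad
  generator only through event-level sampling.
- Stepwise selection inherits AIC's instability at n = 32 speakers; the
  trace is logged so selections can be audited.
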