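# Data dictionary

## `features_wide.csv` — one row per speaker × trial

| column | units | meaning |
|---|---|---|
| `speaker` | — | speaker identifier (TextGrid tier name / generator id) |
| `trial` | — | `describe`, `match` or `describe_and_match` |
| `group` | — | `HC`, `MCI` or `AD` (when known) |
| `n_turns` | count | turns owned by the speaker |
| `n_pauses_raw` | count | within-turn pauses owned by the speaker |
| `n_pauses_norm` | pauses/turn | `n_pauses_raw / n_turns` |
| `gap_overlap_ratio` | — | gaps ÷ overlaps at the speaker's floor-takings; empty when the overlap count is 0 |
| `pause_dur`, `pause_dur_sd` | s | mean / SD of within-turn pause durations |
| `gap_dur`, `gap_dur_sd` | s | mean / SD of gap durations at the speaker's floor-takings |
| `tov_dur`, `tov_dur_sd` | s | mean / SD of transition-overlap durations |
| `ipu_dur`, `ipu_dur_sd` | s | mean / SD of interpausal-unit durations |
| `turn_dur`, `turn_dur_sd` | s | mean / SD of turn-span durations |
| `speech_rate`, `speech_rate_sd` | syll/s | mean / SD over turns of nuclei-per-second (pauses included) |

SD columns are empty when fewer than two events exist. Missing values are
empty cells, never zeros.

## `events_long.csv` — one row per timing event

| column | units | meaning |
|---|---|---|
| `speaker` | — | owning speaker (floor-taker for gaps/overlaps) |
| `other` | — | the yielding speaker (gaps/overlaps only) |
| `trial` | — | trial label |
| `kind` | — | `ipu`, `turn`, `pause`, `gap`, `transition_overlap` |
| `start`, `end` | s | half-open interval bounds |
| `duration` | s | `end − start` (0 allowed only for flush-transition gaps) |

## Nuclei CSV

| column | units | meaning |
|---|---|---|
| `speaker` | — | speaker identifier |
| `time_s` | s | syllable-nucleus time |
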