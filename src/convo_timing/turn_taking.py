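"""Turn-taking segmentation of a dyadic conversation.

From two speakers' binary speech timelines this module derives the
turn-taking units used throughout the analysis:

interpausal unit (IPU)
    a stretch of one speaker's speech bounded by silences at or above the
    pause threshold; shorter within-speaker silences (silent plosives,
    stop closures) are absorbed into the IPU,
turn
    a maximal run of consecutive IPUs by the same speaker before the other
    speaker takes the floor,
pause
    a silence of at least the pause threshold between IPUs inside one
    speaker's turn,
gap
    the silence between one speaker's turn offset and the other's turn
    onset at a speaker change,
transition overlap
    simultaneous speech at a speaker change, when the incoming speaker
    starts before the outgoing speaker has finished.

Every speaker transition is classified as exactly one gap or one
transition overlap (a flush transition is a gap of duration zero), so
``#gaps + #overlaps == #transitions`` holds on every input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_timeline import ActivityTrack, Interval, TimingEvent

#: pause threshold in seconds: minimum within-speaker silence counted as a
#: pause (shorter silences are indistinguishable from silent plosives and
#: are absorbed into the surrounding IPU)
PAUSE_THRESHOLD = 0.100


@dataclass
class SegmentationConfig:
    pause_threshold: float = PAUSE_THRESHOLD
    #: maximum duration of an other-speaker interjection treated as a
    #: backchannel rather than a floor-taking turn; 0 disables the heuristic
    #: so that every IPU can take the floor
    backchannel_max: float = 0.0
    #: IPUs shorter than this are dropped before turn assignment (0 keeps all)
    min_ipu: float = 0.0

    def __post_init__(self) -> None:
        if self.pause_threshold <= 0:
            raise ValueError("pause_threshold must be positive")
        if self.backchannel_max < 0 or self.min_ipu < 0:
            raise ValueError("backchannel_max and min_ipu must be >= 0")


@dataclass
class Turn:
    """A turn with its member IPUs (internal working representation)."""

    speaker: str
    ipus: list[TimingEvent]

    @property
    def span(self) -> Interval:
        return Interval(self.ipus[0].interval.start, self.ipus[-1].interval.end)


@dataclass
class DyadTimeline:
    """Ordered timing events of one dyadic trial.

    ``events`` holds every IPU, turn, pause, gap and transition overlap,
    sorted by onset.  ``backchannels`` lists interjections excluded from
    turn accounting; ``flags`` surfaces conditions the segmentation does
    not silently resolve (non-transition overlaps, long lapses).
    """

    speakers: tuple[str, str]
    trial: str
    events: list[TimingEvent] = field(default_factory=list)
    backchannels: list[TimingEvent] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def of_kind(self, kind: str, owner: str | None = None) -> list[TimingEvent]:
        return [
            ev for ev in self.events
            if ev.kind == kind and (owner is None or ev.owner == owner)
        ]

    @property
    def n_transitions(self) -> int:
        return len(self.of_kind("gap")) + len(self.of_kind("transition_overlap"))


def segment_ipus(track: ActivityTrack, config: SegmentationConfig | None = None) -> list[TimingEvent]:
    """Merge a speaker's speech intervals into interpausal units.

    Consecutive speech intervals separated by silence shorter than the
    pause threshold fuse into one IPU (the sub-threshold silence is
    absorbed); silences at or above the threshold delimit IPUs.
    """
    cfg = config or SegmentationConfig()
    ipus: list[Interval] = []
    for iv in track.speech_intervals:
        if ipus and iv.start - ipus[-1].end < cfg.pause_threshold:
            ipus[-1] = Interval(ipus[-1].start, iv.end)
        else:
            ipus.append(iv)
    if cfg.min_ipu > 0:
        ipus = [iv for iv in ipus if iv.duration >= cfg.min_ipu]
    return [TimingEvent("ipu", iv, owner=track.speaker_id) for iv in ipus]


def assign_turns(
    ipus_a: list[TimingEvent],
    ipus_b: list[TimingEvent],
    config: SegmentationConfig | None = None,
    trial: str = "describe",
    speakers: tuple[str, str] | None = None,
) -> DyadTimeline:
    """Group the two speakers' IPUs into turns.

    IPUs are ordered by onset (exact onset ties broken by lexicographic
    speaker id); a turn is a maximal run of one speaker's IPUs.  With
    ``backchannel_max > 0`` a short interjection of the other speaker that
    is fully contained in the surrounding turn is flagged as a backchannel
    and excluded from turn accounting instead of breaking the run.
    """
    cfg = config or SegmentationConfig()
    if speakers is None:
        ids = {ev.owner for ev in ipus_a} | {ev.owner for ev in ipus_b}
        if len(ids) > 2:
            raise ValueError(f"more than two speakers in IPU lists: {sorted(ids)}")
        speakers = tuple(sorted(ids)) if len(ids) == 2 else (
            (ipus_a[0].owner if ipus_a else "A"), (ipus_b[0].owner if ipus_b else "B"))  # type: ignore[assignment]

    ordered = sorted(ipus_a + ipus_b, key=lambda ev: (ev.interval.start, ev.owner))

    # backchannel pass: mark short interjections whose surrounding run resumes
    backchannels: list[TimingEvent] = []
    if cfg.backchannel_max > 0:
        keep: list[TimingEvent] = []
        for i, ev in enumerate(ordered):
            prev_spk = keep[-1].owner if keep else None
            nxt = ordered[i + 1] if i + 1 < len(ordered) else None
            is_backchannel = (
                prev_spk is not None
                and ev.owner != prev_spk
                and ev.duration <= cfg.backchannel_max
                and nxt is not None
                and nxt.owner == prev_spk          # the interrupted run resumes...
                and nxt.interval.end > ev.interval.end  # ...and extends past the interjection
            )
            if is_backchannel:
                backchannels.append(ev)
            else:
                keep.append(ev)
        ordered = keep

    timeline = DyadTimeline(speakers=speakers, trial=trial)
    timeline.backchannels = backchannels

    turns: list[Turn] = []
    for ev in ordered:
        if turns and turns[-1].speaker == ev.owner:
            turns[-1].ipus.append(ev)
        else:
            turns.append(Turn(ev.owner, [ev]))

    events: list[TimingEvent] = []
    for turn in turns:
        events.extend(turn.ipus)
        events.append(TimingEvent("turn", turn.span, owner=turn.speaker))
    timeline.events = sorted(events, key=lambda ev: (ev.interval.start, ev.kind != "turn"))
    timeline._turns = turns  # type: ignore[attr-defined]
    return timeline


def classify_transitions(
    timeline: DyadTimeline,
    config: SegmentationConfig | None = None,
    lapse_threshold: float = 10.0,
) -> DyadTimeline:
    """Add pause, gap and transition-overlap events to a turn timeline.

    Within-turn inter-IPU silences (all at or above the pause threshold by
    IPU construction) become pauses owned by the turn holder.  Each speaker
    transition becomes exactly one gap (silence, possibly of duration zero)
    or one transition overlap (the incoming turn starts before the outgoing
    one ends), owned by the floor-taking speaker.
    """
    cfg = config or SegmentationConfig()
    turns: list[Turn] = getattr(timeline, "_turns", None)
    if turns is None:
        raise ValueError("timeline has no assigned turns; call assign_turns first")

    extra: list[TimingEvent] = []
    for turn in turns:
        for prev, nxt in zip(turn.ipus, turn.ipus[1:]):
            sil = nxt.interval.start - prev.interval.end
            if sil >= cfg.pause_threshold:
                extra.append(
                    TimingEvent("pause", Interval(prev.interval.end, nxt.interval.start), owner=turn.speaker)
                )

    for out_turn, in_turn in zip(turns, turns[1:]):
        out_end = out_turn.span.end
        in_start = in_turn.span.start
        if in_start >= out_end:  # silence (or flush) at the change of speaker
            ev = TimingEvent(
                "gap", Interval(out_end, in_start), owner=in_turn.speaker, other=out_turn.speaker
            )
            if ev.duration >= lapse_threshold:
                timeline.flags.append(
                    f"lapse: {ev.duration:.2f}s gap at t={out_end:.2f}s "
                    f"({out_turn.speaker}->{in_turn.speaker})"
                )
        else:
            ev = TimingEvent(
                "transition_overlap",
                Interval(in_start, min(out_end, in_turn.span.end)),
                owner=in_turn.speaker,
                other=out_turn.speaker,
            )
            if in_turn.span.end < out_end:
                timeline.flags.append(
                    f"nested turn: {in_turn.speaker} inside {out_turn.speaker} at t={in_start:.2f}s"
                )
        extra.append(ev)

    timeline.events = sorted(
        timeline.events + extra, key=lambda ev: (ev.interval.start, ev.kind != "turn")
    )
    return timeline


def segment_dyad(
    track_a: ActivityTrack,
    track_b: ActivityTrack,
    config: SegmentationConfig | None = None,
) -> DyadTimeline:
    """Full segmentation of one trial: IPUs -> turns -> transition classification."""
    if track_a.trial != track_b.trial:
        raise ValueError(f"tracks are from different trials: {track_a.trial!r} vs {track_b.trial!r}")
    cfg = config or SegmentationConfig()
    ipus_a = segment_ipus(track_a, cfg)
    ipus_b = segment_ipus(track_b, cfg)
    timeline = assign_turns(
        ipus_a, ipus_b, cfg, trial=track_a.trial,
        speakers=(track_a.speaker_id, track_b.speaker_id),
    )
    return classify_transitions(timeline, cfg)
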