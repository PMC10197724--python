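"""Time annotations: labels, repeating cycles, exact timelines.

An annotation *group* is one experimental condition dimension (light,
stimulus identity, displayed shape ...).  Its per-frame assignment is
declared either as a :class:`Cycle` — an ordered list of labeled
durations repeated from frame 1 until the recording ends, with the
repetition ("iteration") index tracked per frame — or as a
:class:`Timeline`, a one-shot sequence whose durations must sum exactly
to the recording length.  Expansion turns either into an
:class:`AnnotationTrack` holding one label name per frame.

Durations are in frames.  Iterations are stored 0-based; reports render
them ordinally ("second iteration" for iteration 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Label:
    """A named condition within an annotation group, e.g. light/'on'."""

    group: str
    name: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("label name must be non-empty")
        if not self.group:
            raise ValueError("label group must be non-empty")


@dataclass(frozen=True)
class Segment:
    """A label held for a fixed number of consecutive frames."""

    label: Label
    duration: int

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError(
                f"segment duration must be >= 1 frame, got {self.duration} "
                f"for label {self.label.group}/{self.label.name}"
            )


def _check_segments(group: str, segments: Sequence[Segment]) -> None:
    if len(segments) == 0:
        raise ValueError(f"annotation group {group!r} has no segments")
    for seg in segments:
        if seg.label.group != group:
            raise ValueError(
                f"segment label {seg.label.name!r} belongs to group "
                f"{seg.label.group!r}, expected {group!r}"
            )


@dataclass(frozen=True)
class Cycle:
    """An ordered segment sequence repeated to cover the recording."""

    group: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        _check_segments(self.group, self.segments)

    @property
    def cycle_length(self) -> int:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class Timeline:
    """A one-shot segment sequence that must cover the recording exactly."""

    group: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        _check_segments(self.group, self.segments)

    @property
    def total_duration(self) -> int:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-frame label assignment of one group over a whole recording.

    ``per_frame_label[f - 1]`` is the label name of 1-based frame ``f``.
    ``per_frame_iteration`` is present only for cycle-derived tracks and
    holds the 0-based repetition index of each frame.  ``segments``
    records the source declaration so the track can be persisted and
    rebuilt without the original :class:`Cycle`/:class:`Timeline`.
    """

    group: str
    per_frame_label: tuple[str, ...]
    source_kind: str  # "cycle" | "timeline"
    per_frame_iteration: tuple[int, ...] | None = None
    labels: tuple[Label, ...] = field(default=())
    segments: tuple[tuple[str, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.source_kind not in ("cycle", "timeline"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.per_frame_iteration is not None:
            if len(self.per_frame_iteration) != len(self.per_frame_label):
                raise ValueError("iteration list length must match label list")
            if self.per_frame_iteration and self.per_frame_iteration[0] != 0:
                raise ValueError("cycle iterations must start at 0")

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_label)

    @property
    def label_names(self) -> list[str]:
        """Declared label names in segment order, without duplicates."""
        return [lab.name for lab in self.labels]


def _unique_labels(segments: Iterable[Segment]) -> tuple[Label, ...]:
    seen: dict[str, Label] = {}
    for seg in segments:
        seen.setdefault(seg.label.name, seg.label)
    return tuple(seen.values())


def expand_cycle(cycle: Cycle, n_frames: int) -> AnnotationTrack:
    """Repeat a cycle from frame 1 until ``n_frames``, tracking iterations.

    Frame ``f`` (1-based) gets the label at within-cycle position
    ``(f - 1) mod cycle_length`` and iteration ``(f - 1) // cycle_length``;
    the final repetition may be truncated mid-segment.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    period = cycle.cycle_length
    one_cycle: list[str] = []
    for seg in cycle.segments:
        one_cycle.extend([seg.label.name] * seg.duration)

    labels = tuple(one_cycle[(f - 1) % period] for f in range(1, n_frames + 1))
    iterations = tuple((f - 1) // period for f in range(1, n_frames + 1))
    return AnnotationTrack(
        group=cycle.group,
        per_frame_label=labels,
        per_frame_iteration=iterations,
        source_kind="cycle",
        labels=_unique_labels(cycle.segments),
        segments=tuple((s.label.name, s.duration) for s in cycle.segments),
    )


def expand_timeline(timeline: Timeline, n_frames: int) -> AnnotationTrack:
    """Concatenate timeline segments; the durations must sum to ``n_frames``.

    Timelines are never repeated or truncated: a mismatch between the
    declared total duration and the recording length is an error.
    """
    total = timeline.total_duration
    if total != n_frames:
        raise ValueError(
            f"timeline for group {timeline.group!r} covers {total} frames "
            f"but the recording has {n_frames}; timelines must match exactly"
        )
    labels: list[str] = []
    for seg in timeline.segments:
        labels.extend([seg.label.name] * seg.duration)
    return AnnotationTrack(
        group=timeline.group,
        per_frame_label=tuple(labels),
        per_frame_iteration=None,
        source_kind="timeline",
        labels=_unique_labels(timeline.segments),
        segments=tuple((s.label.name, s.duration) for s in timeline.segments),
    )


def frames_with_label(track: AnnotationTrack, label_name: str) -> list[int]:
    """Sorted 1-based frame ids carrying ``label_name`` in this track.

    An unknown label yields an empty list (with a logged warning) so that
    compound queries degrade gracefully.
    """
    frames = [
        f for f, name in enumerate(track.per_frame_label, start=1)
        if name == label_name
    ]
    if not frames:
        logger.warning(
            "label %r matches no frame in group %r (known labels: %s)",
            label_name, track.group, sorted(set(track.per_frame_label)),
        )
    return frames


def iteration_of(track: AnnotationTrack, frame_id: int) -> int:
    """0-based cycle iteration of a frame; only defined for cycle tracks."""
    if track.per_frame_iteration is None:
        raise ValueError(
            f"group {track.group!r} was built from a timeline; "
            "cycle iterations are undefined"
        )
    if not 1 <= frame_id <= track.n_frames:
        raise ValueError(
            f"frame_id {frame_id} out of range; valid frames are "
            f"1..{track.n_frames}"
        )
    return track.per_frame_iteration[frame_id - 1]


def ordinal(iteration: int) -> str:
    """Render a 0-based iteration index ordinally: 0 -> '1st', 1 -> '2nd'."""
    n = iteration + 1
    if 10 <= n % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suffix}"
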