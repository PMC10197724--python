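"""Index arithmetic mapping global frame numbers to files and volumes.

A volumetric recording is acquired as a single sequence of 2D frames
spread over several image files.  Every ``frames_per_volume`` consecutive
frames form one 3D volume; a recording may start mid-volume (head frames)
or stop mid-volume (tail frames).  This module knows nothing about pixels:
it only answers "where does frame *f* live?" — in which file, at which
page, in which volume, at which slice.

Conventions
-----------
* Global frame ids are 1-based (``frame_id == 30`` is the 30th frame of
  the recording).
* File pages, volumes and slices are 0-based.
* Volume codes: ``0 .. n_full_volumes - 1`` for full volumes, ``-1`` for
  head frames preceding the first full volume, ``-2`` for tail frames
  after the last full volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

HEAD_CODE = -1
TAIL_CODE = -2


@dataclass(frozen=True)
class ImageFileRecord:
    """One image file of the recording.

    Parameters
    ----------
    path
        Location of the file on disk.
    order_index
        0-based position of the file within the recording.
    n_frames
        Number of 2D pages the file contains (>= 1).
    """

    path: Path
    order_index: int
    n_frames: int

    def __post_init__(self) -> None:
        if self.order_index < 0:
            raise ValueError(f"order_index must be >= 0, got {self.order_index}")
        if self.n_frames < 1:
            raise ValueError(
                f"file {self.path} reports {self.n_frames} frames; every file "
                "must contain at least one frame"
            )


@dataclass(frozen=True)
class FrameRef:
    """Storage location of one global frame: (file, page within file)."""

    frame_id: int
    file_order: int
    page_index: int


@dataclass(frozen=True)
class FileMap:
    """Ordered image files with cumulative frame offsets.

    ``cumulative_offsets[i]`` is the number of frames preceding file *i*,
    so global frame ``cumulative_offsets[i] + p + 1`` is page ``p`` of
    file ``i``.
    """

    files: tuple[ImageFileRecord, ...]
    cumulative_offsets: tuple[int, ...] = field(default=())
    total_frames: int = 0

    def __post_init__(self) -> None:
        offsets = []
        running = 0
        for i, rec in enumerate(self.files):
            if rec.order_index != i:
                raise ValueError(
                    f"file order indices must be 0..{len(self.files) - 1} "
                    f"without gaps; file {rec.path} has order_index "
                    f"{rec.order_index} at position {i}"
                )
            offsets.append(running)
            running += rec.n_frames
        object.__setattr__(self, "cumulative_offsets", tuple(offsets))
        object.__setattr__(self, "total_frames", running)

    @property
    def n_files(self) -> int:
        return len(self.files)


def build_file_map(
    paths: Sequence[str | Path], frame_counts: Sequence[int]
) -> FileMap:
    """Assemble a :class:`FileMap` from ordered paths and per-file counts.

    Raises
    ------
    ValueError
        If ``paths`` is empty, the lengths disagree, or any count is < 1.
    """
    if len(paths) == 0:
        raise ValueError("cannot build a file map from an empty list of files")
    if len(paths) != len(frame_counts):
        raise ValueError(
            f"{len(paths)} paths but {len(frame_counts)} frame counts"
        )
    files = tuple(
        ImageFileRecord(path=Path(p), order_index=i, n_frames=int(c))
        for i, (p, c) in enumerate(zip(paths, frame_counts))
    )
    return FileMap(files=files)


def locate_frame(file_map: FileMap, frame_id: int) -> FrameRef:
    """Resolve a 1-based global frame id to its (file, page) location."""
    if not 1 <= frame_id <= file_map.total_frames:
        raise ValueError(
            f"frame_id {frame_id} out of range; valid frames are "
            f"1..{file_map.total_frames}"
        )
    # cumulative_offsets is sorted; find the last file starting at or
    # before frame_id - 1.
    file_order = (
        int(np.searchsorted(file_map.cumulative_offsets, frame_id - 1, side="right"))
        - 1
    )
    page_index = frame_id - 1 - file_map.cumulative_offsets[file_order]
    return FrameRef(frame_id=frame_id, file_order=file_order, page_index=page_index)


@dataclass(frozen=True)
class VolumeMap:
    """Per-frame assignment of volume codes and slice indices.

    ``per_frame_volume[f - 1]`` is the volume code of global frame ``f``;
    ``per_frame_slice[f - 1]`` its 0-based slice position.  Slice indices
    of head/tail frames count 0-based within the partial group.
    """

    n_frames: int
    frames_per_volume: int
    head_offset: int
    n_full_volumes: int
    per_frame_volume: tuple[int, ...]
    per_frame_slice: tuple[int, ...]

    def frame_range_of_volume(self, volume_code: int) -> tuple[int, int]:
        """First and last 1-based frame id of a volume code (inclusive)."""
        if volume_code == HEAD_CODE:
            if self.head_offset == 0:
                raise ValueError("this recording has no head frames (code -1)")
            return 1, self.head_offset
        if volume_code == TAIL_CODE:
            first_tail = self.head_offset + self.n_full_volumes * self.frames_per_volume + 1
            if first_tail > self.n_frames:
                raise ValueError("this recording has no tail frames (code -2)")
            return first_tail, self.n_frames
        if not 0 <= volume_code < self.n_full_volumes:
            raise ValueError(
                f"unknown volume code {volume_code}; full volumes are "
                f"0..{self.n_full_volumes - 1}, head is -1, tail is -2"
            )
        first = self.head_offset + volume_code * self.frames_per_volume + 1
        return first, first + self.frames_per_volume - 1

    @property
    def full_volume_codes(self) -> list[int]:
        return list(range(self.n_full_volumes))

    @property
    def n_head_frames(self) -> int:
        return self.head_offset

    @property
    def n_tail_frames(self) -> int:
        return (
            self.n_frames
            - self.head_offset
            - self.n_full_volumes * self.frames_per_volume
        )


def build_volume_map(
    n_frames: int, frames_per_volume: int, head_offset: int = 0
) -> VolumeMap:
    """Assign every frame a volume code and a slice index.

    Parameters
    ----------
    n_frames
        Total frames in the recording (>= 1).
    frames_per_volume
        Slices per volume (>= 1).
    head_offset
        Frames acquired before the first full volume starts; they get
        code ``-1``.  Default 0.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if frames_per_volume < 1:
        raise ValueError(
            f"frames_per_volume must be >= 1, got {frames_per_volume}"
        )
    if not 0 <= head_offset < n_frames:
        raise ValueError(
            f"head_offset must be in [0, {n_frames - 1}], got {head_offset}"
        )

    n_full = (n_frames - head_offset) // frames_per_volume
    idx = np.arange(n_frames)  # 0-based frame positions

    volume = np.full(n_frames, TAIL_CODE, dtype=np.int64)
    slices = np.zeros(n_frames, dtype=np.int64)

    head = idx < head_offset
    volume[head] = HEAD_CODE
    slices[head] = idx[head]

    body = idx - head_offset
    in_full = ~head & (body < n_full * frames_per_volume)
    volume[in_full] = body[in_full] // frames_per_volume
    slices[in_full] = body[in_full] % frames_per_volume

    tail = ~head & ~in_full
    slices[tail] = body[tail] - n_full * frames_per_volume

    return VolumeMap(
        n_frames=n_frames,
        frames_per_volume=frames_per_volume,
        head_offset=head_offset,
        n_full_volumes=int(n_full),
        per_frame_volume=tuple(int(v) for v in volume),
        per_frame_slice=tuple(int(s) for s in slices),
    )


def volume_and_slice_of(volume_map: VolumeMap, frame_id: int) -> tuple[int, int]:
    """Return (volume_code, slice_index) of a 1-based global frame id."""
    if not 1 <= frame_id <= volume_map.n_frames:
        raise ValueError(
            f"frame_id {frame_id} out of range; valid frames are "
            f"1..{volume_map.n_frames}"
        )
    return (
        volume_map.per_frame_volume[frame_id - 1],
        volume_map.per_frame_slice[frame_id - 1],
    )


def frames_of_volumes(
    volume_map: VolumeMap, volume_codes: Sequence[int]
) -> list[int]:
    """All 1-based frame ids belonging to the given volume codes, sorted.

    The inverse of :func:`volume_and_slice_of`: requesting every code of
    the recording partitions ``1..n_frames`` exactly once.
    """
    frames: list[int] = []
    for code in volume_codes:
        first, last = volume_map.frame_range_of_volume(code)
        frames.extend(range(first, last + 1))
    return sorted(frames)
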