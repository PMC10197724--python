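"""The Experiment facade: map once, then query and load many times.

An :class:`Experiment` ties together the file map, the frame-to-volume
map, the expanded annotation tracks and (optionally) a database file.
Condition queries run against the database when one is attached and
against the in-memory tracks otherwise; both paths return identical
results.  Pixel data is loaded lazily — only the pages backing the
requested frames or volumes are decoded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import database as dbm
from .annotation import (
    AnnotationTrack,
    Cycle,
    Label,
    Segment,
    Timeline,
    expand_cycle,
    expand_timeline,
    frames_with_label,
)
from .core import (
    FileMap,
    VolumeMap,
    build_file_map,
    build_volume_map,
    frames_of_volumes,
    locate_frame,
    volume_and_slice_of,
)
from .loaders import probe

logger = logging.getLogger(__name__)


def _normalize_logic(
    conditions: Sequence[tuple[str, str]], logic: str | None
) -> str:
    if len(conditions) == 0:
        raise ValueError(
            "empty condition list: pass at least one (group, label) pair "
            "(selecting all frames implicitly is not supported)"
        )
    if len(conditions) >= 2 and logic not in ("and", "or"):
        raise ValueError(
            "logic must be 'and' or 'or' when combining two or more "
            f"conditions, got {logic!r}"
        )
    if logic is None:
        logic = "and"
    if logic not in ("and", "or"):
        raise ValueError(f"logic must be 'and' or 'or', got {logic!r}")
    return logic


@dataclass
class Experiment:
    """A fully mapped recording: files, volumes, annotations, database."""

    file_map: FileMap
    volume_map: VolumeMap
    tracks: dict[str, AnnotationTrack] = field(default_factory=dict)
    db: dbm.ExperimentDB | None = None

    # ------------------------------------------------------------- creation
    @classmethod
    def create(
        cls,
        files: str | Path | Sequence[str | Path],
        frames_per_volume: int,
        head_offset: int = 0,
        annotations: Sequence[Cycle | Timeline] = (),
    ) -> "Experiment":
        """Map a recording from a directory or an explicit ordered file list.

        A directory is expanded to its registered image files in
        lexicographic name order; an explicit list is used as given.
        Frame counts are probed from the files, the volume map is built,
        and every annotation is expanded to a per-frame track.  Any
        annotation that cannot cover the recording aborts creation with
        the offending group named.
        """
        if isinstance(files, (str, Path)) and Path(files).is_dir():
            data_dir = Path(files)
            paths = sorted(
                p for p in data_dir.iterdir()
                if p.suffix.lower() in (".tif", ".tiff")
            )
            if not paths:
                raise ValueError(f"no TIFF files found in {data_dir}")
        elif isinstance(files, (str, Path)):
            paths = [Path(files)]
        else:
            paths = [Path(p) for p in files]

        sources = [probe(p) for p in paths]
        file_map = build_file_map(paths, [s.n_pages for s in sources])
        volume_map = build_volume_map(
            n_frames=file_map.total_frames,
            frames_per_volume=frames_per_volume,
            head_offset=head_offset,
        )

        tracks: dict[str, AnnotationTrack] = {}
        for ann in annotations:
            try:
                if isinstance(ann, Cycle):
                    track = expand_cycle(ann, file_map.total_frames)
                elif isinstance(ann, Timeline):
                    track = expand_timeline(ann, file_map.total_frames)
                else:
                    raise TypeError(
                        f"annotations must be Cycle or Timeline, got "
                        f"{type(ann).__name__}"
                    )
            except ValueError as err:
                raise ValueError(
                    f"annotation group {ann.group!r} is invalid for this "
                    f"recording: {err}"
                ) from err
            if ann.group in tracks:
                raise ValueError(f"duplicate annotation group {ann.group!r}")
            tracks[ann.group] = track

        exp = cls(file_map=file_map, volume_map=volume_map, tracks=tracks)
        logger.info(
            "mapped experiment: %d files, %d frames, %d full volumes, "
            "%d head / %d tail frames, %d annotation groups",
            file_map.n_files, file_map.total_frames,
            volume_map.n_full_volumes, volume_map.n_head_frames,
            volume_map.n_tail_frames, len(tracks),
        )
        return exp

    @classmethod
    def from_config(cls, config: str | Path | Mapping) -> "Experiment":
        """Build an experiment from a YAML config file or equivalent dict.

        Expected keys: ``data_dir`` (or ``files``, an explicit ordered
        list), ``frames_per_volume``, optional ``head_offset``, optional
        ``annotations`` mapping group name to ``{kind: cycle|timeline,
        segments: [{label: duration}, ...]}``.
        """
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        if not isinstance(config, Mapping):
            raise ValueError("experiment config must be a mapping")

        if "files" in config:
            files: str | list = [str(p) for p in config["files"]]
        elif "data_dir" in config:
            files = str(config["data_dir"])
        else:
            raise ValueError("config needs either 'data_dir' or 'files'")

        annotations = []
        for group, spec in (config.get("annotations") or {}).items():
            kind = spec.get("kind")
            if kind not in ("cycle", "timeline"):
                raise ValueError(
                    f"annotation group {group!r}: kind must be 'cycle' or "
                    f"'timeline', got {kind!r}"
                )
            segments = []
            for entry in spec.get("segments", []):
                if not isinstance(entry, Mapping) or len(entry) != 1:
                    raise ValueError(
                        f"annotation group {group!r}: each segment must be a "
                        "single 'label: duration' mapping"
                    )
                (name, duration), = entry.items()
                segments.append(
                    Segment(
                        label=Label(group=group, name=str(name)),
                        duration=int(duration),
                    )
                )
            klass = Cycle if kind == "cycle" else Timeline
            annotations.append(klass(group=group, segments=tuple(segments)))

        return cls.create(
            files=files,
            frames_per_volume=int(config["frames_per_volume"]),
            head_offset=int(config.get("head_offset", 0)),
            annotations=annotations,
        )

    # ---------------------------------------------------------- persistence
    @property
    def state(self) -> dbm.ExperimentState:
        return dbm.ExperimentState(
            file_map=self.file_map,
            volume_map=self.volume_map,
            tracks=tuple(self.tracks.values()),
        )

    def save(self, db_path: str | Path) -> dbm.ExperimentDB:
        """Persist the experiment description; queries then run via SQL."""
        self.db = dbm.persist(self.state, db_path)
        return self.db

    @classmethod
    def load(cls, db_path: str | Path) -> "Experiment":
        """Restore an experiment from a database file.

        The restored experiment answers all queries without the original
        image files; only pixel loading requires them.
        """
        state = dbm.restore(db_path)
        return cls(
            file_map=state.file_map,
            volume_map=state.volume_map,
            tracks={t.group: t for t in state.tracks},
            db=dbm.ExperimentDB(db_path=Path(db_path)),
        )

    # -------------------------------------------------------------- queries
    def _frames_in_memory(
        self, conditions: Sequence[tuple[str, str]], logic: str
    ) -> list[int]:
        sets = []
        for group, label in conditions:
            if group not in self.tracks:
                raise dbm.UnknownGroupError(
                    f"unknown annotation group {group!r}; available groups: "
                    f"{sorted(self.tracks)}"
                )
            sets.append(set(frames_with_label(self.tracks[group], label)))
        combined = set.intersection(*sets) if logic == "and" else set.union(*sets)
        return sorted(combined)

    def choose_frames(
        self,
        conditions: Sequence[tuple[str, str]],
        logic: str | None = None,
    ) -> list[int]:
        """Sorted frame ids matching the conditions (and/or combination)."""
        logic = _normalize_logic(conditions, logic)
        if self.db is not None:
            result = dbm.query_frames(self.db, conditions, logic)
        else:
            result = self._frames_in_memory(conditions, logic)
        logger.info(
            "choose_frames(%s, %s) -> %d frames", conditions, logic, len(result)
        )
        return result

    def choose_volumes(
        self,
        conditions: Sequence[tuple[str, str]],
        logic: str | None = None,
    ) -> list[int]:
        """Sorted full-volume codes whose frames ALL match the conditions."""
        logic = _normalize_logic(conditions, logic)
        if self.db is not None:
            result = dbm.query_volumes(self.db, conditions, logic)
        else:
            frames = set(self._frames_in_memory(conditions, logic))
            result = [
                v for v in self.volume_map.full_volume_codes
                if set(frames_of_volumes(self.volume_map, [v])) <= frames
            ]
        logger.info(
            "choose_volumes(%s, %s) -> %d volumes", conditions, logic, len(result)
        )
        return result

    # -------------------------------------------------------- pixel loading
    def load_frames(self, frame_ids: Sequence[int]) -> np.ndarray:
        """Load the requested frames as a (frame, height, width) stack.

        Caller order (including duplicates) is preserved; only the
        backing file pages are decoded.
        """
        refs = [locate_frame(self.file_map, f) for f in frame_ids]
        by_file: dict[int, list[int]] = {}
        for ref in refs:
            by_file.setdefault(ref.file_order, []).append(ref.page_index)

        cache: dict[tuple[int, int], np.ndarray] = {}
        for order, pages in by_file.items():
            source = probe(self.file_map.files[order].path)
            unique = sorted(set(pages))
            stack = source.read_pages(unique)
            for p, img in zip(unique, stack):
                cache[(order, p)] = img

        if not refs:
            return np.empty((0, 0, 0))
        return np.stack([cache[(r.file_order, r.page_index)] for r in refs])

    def load_volumes(
        self, volume_codes: Sequence[int], allow_partial: bool = False
    ) -> np.ndarray | list[np.ndarray]:
        """Load volumes as a (volume, slice, height, width) stack.

        Full-volume codes stack into a 4D array in caller order.  Partial
        codes (-1 head, -2 tail) are only accepted with
        ``allow_partial=True``; their slice depth differs, so the result
        is then a list of per-code 3D stacks instead of one 4D array.
        """
        partial = [c for c in volume_codes if c < 0]
        if partial and not allow_partial:
            raise ValueError(
                f"codes {partial} refer to partial volumes; pass "
                "allow_partial=True to load them (as a list of 3D stacks)"
            )
        if allow_partial:
            return [
                self.load_frames(frames_of_volumes(self.volume_map, [c]))
                for c in volume_codes
            ]
        if len(volume_codes) == 0:
            return np.empty((0, self.volume_map.frames_per_volume, 0, 0))
        stacks = [
            self.load_frames(frames_of_volumes(self.volume_map, [c]))
            for c in volume_codes
        ]
        return np.stack(stacks)

    # -------------------------------------------------------------- summary
    def frame_report(self, frame_id: int) -> dict:
        """Everything known about one frame: location, volume, labels."""
        ref = locate_frame(self.file_map, frame_id)
        volume, slice_index = volume_and_slice_of(self.volume_map, frame_id)
        report = {
            "frame": frame_id,
            "file_order": ref.file_order,
            "file": str(self.file_map.files[ref.file_order].path),
            "page_index": ref.page_index,
            "volume_code": volume,
            "slice_index": slice_index,
            "labels": {},
            "iterations": {},
        }
        for group, track in self.tracks.items():
            report["labels"][group] = track.per_frame_label[frame_id - 1]
            if track.per_frame_iteration is not None:
                report["iterations"][group] = track.per_frame_iteration[frame_id - 1]
        return report

    def describe(self) -> dict:
        """Structured summary: files, totals, groups with label counts."""
        groups = {}
        for group, track in self.tracks.items():
            counts: dict[str, int] = {}
            for name in track.per_frame_label:
                counts[name] = counts.get(name, 0) + 1
            entry = {
                "kind": track.source_kind,
                "label_counts": counts,
            }
            if track.source_kind == "cycle":
                entry["cycle_length"] = sum(d for _, d in track.segments)
                entry["n_iterations"] = (
                    max(track.per_frame_iteration) + 1
                    if track.per_frame_iteration
                    else 0
                )
            groups[group] = entry
        return {
            "n_files": self.file_map.n_files,
            "files": [str(f.path) for f in self.file_map.files],
            "n_frames": self.file_map.total_frames,
            "frames_per_volume": self.volume_map.frames_per_volume,
            "head_offset": self.volume_map.head_offset,
            "n_full_volumes": self.volume_map.n_full_volumes,
            "n_head_frames": self.volume_map.n_head_frames,
            "n_tail_frames": self.volume_map.n_tail_frames,
            "n_groups": len(self.tracks),
            "groups": groups,
        }
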