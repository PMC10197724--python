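"""SQLite persistence of the experiment description and SQL condition queries.

The whole experiment description — file layout, frame-to-volume mapping,
annotation tracks with labels and cycle iterations — is written to a
single self-contained database file.  A restored database answers frame
and volume queries without the original image files; only pixel loading
touches the TIFFs.

Schema (version 1)
------------------
options(key, value)                    frames_per_volume, head_offset, ...
files(order_index, path, n_frames)
frames(frame_id, file_order, page_index)
volumes(frame_id, volume_code, slice_index)
annotation_groups(group_name, source_kind)
labels(group_name, label_name, description)
frame_labels(group_name, frame_id, label_name)
frame_iterations(group_name, frame_id, iteration)
cycles(group_name, segments_json)      source segments, cycle & timeline
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .annotation import AnnotationTrack, Label
from .core import FileMap, VolumeMap, build_file_map, build_volume_map

SCHEMA_VERSION = "1"

_TABLES = {
    "options": "CREATE TABLE options (key TEXT PRIMARY KEY, value TEXT NOT NULL)",
    "files": (
        "CREATE TABLE files (order_index INTEGER PRIMARY KEY, "
        "path TEXT NOT NULL, n_frames INTEGER NOT NULL)"
    ),
    "frames": (
        "CREATE TABLE frames (frame_id INTEGER PRIMARY KEY, "
        "file_order INTEGER NOT NULL, page_index INTEGER NOT NULL)"
    ),
    "volumes": (
        "CREATE TABLE volumes (frame_id INTEGER PRIMARY KEY, "
        "volume_code INTEGER NOT NULL, slice_index INTEGER NOT NULL)"
    ),
    "annotation_groups": (
        "CREATE TABLE annotation_groups (group_name TEXT PRIMARY KEY, "
        "source_kind TEXT NOT NULL)"
    ),
    "labels": (
        "CREATE TABLE labels (group_name TEXT NOT NULL, "
        "label_name TEXT NOT NULL, description TEXT, "
        "PRIMARY KEY (group_name, label_name))"
    ),
    "frame_labels": (
        "CREATE TABLE frame_labels (group_name TEXT NOT NULL, "
        "frame_id INTEGER NOT NULL, label_name TEXT NOT NULL, "
        "PRIMARY KEY (group_name, frame_id))"
    ),
    "frame_iterations": (
        "CREATE TABLE frame_iterations (group_name TEXT NOT NULL, "
        "frame_id INTEGER NOT NULL, iteration INTEGER NOT NULL, "
        "PRIMARY KEY (group_name, frame_id))"
    ),
    "cycles": (
        "CREATE TABLE cycles (group_name TEXT PRIMARY KEY, "
        "segments_json TEXT NOT NULL)"
    ),
}

_INDICES = (
    "CREATE INDEX idx_frame_labels ON frame_labels (group_name, label_name)",
    "CREATE INDEX idx_volumes_code ON volumes (volume_code)",
)


class CorruptDatabaseError(RuntimeError):
    """The file is not a recognizable experiment database."""


class SchemaVersionError(RuntimeError):
    """The database was written with an unsupported schema version."""


class UnknownGroupError(KeyError):
    """A query names an annotation group the database does not contain."""


@dataclass(frozen=True)
class ExperimentState:
    """The persistable description of one experiment (no pixel data)."""

    file_map: FileMap
    volume_map: VolumeMap
    tracks: tuple[AnnotationTrack, ...]


@dataclass
class ExperimentDB:
    """Handle to a single-file experiment database."""

    db_path: Path
    schema_version: str = SCHEMA_VERSION

    def connect(self) -> sqlite3.Connection:
        if not Path(self.db_path).exists():
            raise FileNotFoundError(f"database file not found: {self.db_path}")
        return sqlite3.connect(self.db_path)


def _validate_state(state: ExperimentState) -> None:
    n = state.file_map.total_frames
    if state.volume_map.n_frames != n:
        raise ValueError(
            f"volume map covers {state.volume_map.n_frames} frames but the "
            f"files hold {n}"
        )
    for track in state.tracks:
        if track.n_frames != n:
            raise ValueError(
                f"annotation group {track.group!r} covers {track.n_frames} "
                f"frames but the recording has {n}"
            )


def persist(state: ExperimentState, db_path: str | Path) -> ExperimentDB:
    """Write the full experiment description to ``db_path``.

    Persisting the same state twice yields equal logical content (row
    sets); an existing file at ``db_path`` is overwritten.
    """
    _validate_state(state)
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()

    con = sqlite3.connect(db_path)
    try:
        cur = con.cursor()
        for ddl in _TABLES.values():
            cur.execute(ddl)
        for ddl in _INDICES:
            cur.execute(ddl)

        vm = state.volume_map
        cur.executemany(
            "INSERT INTO options VALUES (?, ?)",
            [
                ("schema_version", SCHEMA_VERSION),
                ("frames_per_volume", str(vm.frames_per_volume)),
                ("head_offset", str(vm.head_offset)),
                ("n_frames", str(vm.n_frames)),
            ],
        )
        cur.executemany(
            "INSERT INTO files VALUES (?, ?, ?)",
            [(f.order_index, str(f.path), f.n_frames) for f in state.file_map.files],
        )
        frame_rows = []
        for order, rec in enumerate(state.file_map.files):
            offset = state.file_map.cumulative_offsets[order]
            frame_rows.extend(
                (offset + p + 1, order, p) for p in range(rec.n_frames)
            )
        cur.executemany("INSERT INTO frames VALUES (?, ?, ?)", frame_rows)
        cur.executemany(
            "INSERT INTO volumes VALUES (?, ?, ?)",
            [
                (f, vm.per_frame_volume[f - 1], vm.per_frame_slice[f - 1])
                for f in range(1, vm.n_frames + 1)
            ],
        )

        for track in state.tracks:
            cur.execute(
                "INSERT INTO annotation_groups VALUES (?, ?)",
                (track.group, track.source_kind),
            )
            cur.executemany(
                "INSERT INTO labels VALUES (?, ?, ?)",
                [(track.group, lab.name, lab.description) for lab in track.labels],
            )
            cur.executemany(
                "INSERT INTO frame_labels VALUES (?, ?, ?)",
                [
                    (track.group, f, name)
                    for f, name in enumerate(track.per_frame_label, start=1)
                ],
            )
            if track.per_frame_iteration is not None:
                cur.executemany(
                    "INSERT INTO frame_iterations VALUES (?, ?, ?)",
                    [
                        (track.group, f, it)
                        for f, it in enumerate(track.per_frame_iteration, start=1)
                    ],
                )
            cur.execute(
                "INSERT INTO cycles VALUES (?, ?)",
                (track.group, json.dumps(list(track.segments))),
            )
        con.commit()
    finally:
        con.close()
    return ExperimentDB(db_path=db_path)


def restore(db_path: str | Path) -> ExperimentState:
    """Rebuild the experiment state saved by :func:`persist`."""
    db = ExperimentDB(db_path=Path(db_path))
    con = db.connect()
    try:
        cur = con.cursor()
        existing = {
            row[0]
            for row in cur.execute(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            )
        }
        missing = set(_TABLES) - existing
        if missing:
            raise CorruptDatabaseError(
                f"{db_path} is missing required tables: {sorted(missing)}"
            )
        options = dict(cur.execute("SELECT key, value FROM options"))
        version = options.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"database schema version {version!r} is not supported "
                f"(this build reads version {SCHEMA_VERSION!r})"
            )

        file_rows = cur.execute(
            "SELECT order_index, path, n_frames FROM files ORDER BY order_index"
        ).fetchall()
        file_map = build_file_map(
            [r[1] for r in file_rows], [r[2] for r in file_rows]
        )
        volume_map = build_volume_map(
            n_frames=int(options["n_frames"]),
            frames_per_volume=int(options["frames_per_volume"]),
            head_offset=int(options["head_offset"]),
        )

        tracks = []
        for group, kind in cur.execute(
            "SELECT group_name, source_kind FROM annotation_groups ORDER BY group_name"
        ).fetchall():
            labels = tuple(
                Label(group=group, name=name, description=desc)
                for name, desc in cur.execute(
                    "SELECT label_name, description FROM labels "
                    "WHERE group_name = ? ORDER BY rowid",
                    (group,),
                )
            )
            per_frame = tuple(
                name
                for (name,) in cur.execute(
                    "SELECT label_name FROM frame_labels "
                    "WHERE group_name = ? ORDER BY frame_id",
                    (group,),
                )
            )
            iters = [
                it
                for (it,) in cur.execute(
                    "SELECT iteration FROM frame_iterations "
                    "WHERE group_name = ? ORDER BY frame_id",
                    (group,),
                )
            ]
            (segments_json,) = cur.execute(
                "SELECT segments_json FROM cycles WHERE group_name = ?",
                (group,),
            ).fetchone()
            tracks.append(
                AnnotationTrack(
                    group=group,
                    per_frame_label=per_frame,
                    per_frame_iteration=tuple(iters) if iters else None,
                    source_kind=kind,
                    labels=labels,
                    segments=tuple(
                        (name, dur) for name, dur in json.loads(segments_json)
                    ),
                )
            )
    finally:
        con.close()
    return ExperimentState(
        file_map=file_map, volume_map=volume_map, tracks=tuple(tracks)
    )


def _check_conditions(
    cur: sqlite3.Cursor,
    conditions: Sequence[tuple[str, str]],
    logic: str | None,
) -> str:
    if len(conditions) == 0:
        raise ValueError("at least one (group, label) condition is required")
    if len(conditions) >= 2:
        if logic not in ("and", "or"):
            raise ValueError(
                "logic must be 'and' or 'or' when combining two or more "
                f"conditions, got {logic!r}"
            )
    elif logic is None:
        logic = "and"
    elif logic not in ("and", "or"):
        raise ValueError(f"logic must be 'and' or 'or', got {logic!r}")

    known = [g for (g,) in cur.execute("SELECT group_name FROM annotation_groups")]
    for group, _ in conditions:
        if group not in known:
            raise UnknownGroupError(
                f"unknown annotation group {group!r}; available groups: "
                f"{sorted(known)}"
            )
    return logic


def query_frames(
    db: ExperimentDB,
    conditions: Sequence[tuple[str, str]],
    logic: str | None = None,
) -> list[int]:
    """Sorted 1-based frame ids matching the conditions.

    ``and`` intersects the per-condition frame sets, ``or`` unites them.
    ``logic`` may be omitted for a single condition.
    """
    con = db.connect()
    try:
        cur = con.cursor()
        logic = _check_conditions(cur, conditions, logic)
        single = (
            "SELECT frame_id FROM frame_labels "
            "WHERE group_name = ? AND label_name = ?"
        )
        joiner = " INTERSECT " if logic == "and" else " UNION "
        sql = joiner.join([single] * len(conditions))
        params = [x for cond in conditions for x in cond]
        return sorted(f for (f,) in cur.execute(sql, params))
    finally:
        con.close()


def query_volumes(
    db: ExperimentDB,
    conditions: Sequence[tuple[str, str]],
    logic: str | None = None,
) -> list[int]:
    """Sorted full-volume codes whose frames ALL match the conditions.

    Partial head/tail volumes (codes -1/-2) are never returned.
    """
    con = db.connect()
    try:
        cur = con.cursor()
        logic = _check_conditions(cur, conditions, logic)
        single = (
            "SELECT frame_id FROM frame_labels "
            "WHERE group_name = ? AND label_name = ?"
        )
        joiner = " INTERSECT " if logic == "and" else " UNION "
        matched = joiner.join([single] * len(conditions))
        params = [x for cond in conditions for x in cond]
        fpv = int(
            cur.execute(
                "SELECT value FROM options WHERE key = 'frames_per_volume'"
            ).fetchone()[0]
        )
        sql = (
            "SELECT volume_code FROM volumes "
            f"WHERE volume_code >= 0 AND frame_id IN ({matched}) "
            "GROUP BY volume_code HAVING COUNT(*) = ?"
        )
        return sorted(v for (v,) in cur.execute(sql, [*params, fpv]))
    finally:
        con.close()
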