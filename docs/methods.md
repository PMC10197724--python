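# Methods

## The bookkeeping model

A volumetric recording is a single global sequence of 2D frames,
numbered 1-based, stored across an ordered list of multi-page image
files. Two independent mappings are maintained:

* **frame → (file, page)**: from per-file page counts and their
  cumulative offsets. Page indices are 0-based within each file. File
  order defaults to the lexicographic sort of the file names when a
  directory is given; an explicit user-supplied list always overrides
  it, since acquisition software does not always name files sortably.
* **frame → (volume, slice)**: with `frames_per_volume = P` and
  `head_offset = h` (frames acquired before the first complete volume,
  default 0), frame *f* maps to volume `(f-1-h) div P` and slice
  `(f-1-h) mod P` while that volume index is below
  `n_full = (n_frames - h) div P`. Frames before the first full volume
  carry code −1, frames after the last carry code −2. Slice indices of
  head/tail frames restart at 0 within the partial group; nothing
  downstream depends on this choice, since partial volumes are loadable
  only through an explicit flag and are never returned by volume
  queries.

Frame ids are 1-based while pages, volumes and slices are 0-based. This
mixed convention is deliberate: it is the only one under which all of
the toy recording's facts (the "30th frame" being the "4th frame of the
3rd file" and the "9th slice, zero-based" of the 3rd volume, and the
and/or queries returning volume index 3 and volumes 2 and 3) hold
simultaneously. The "3rd volume" in prose is volume code 2; reports
render iterations ordinally for the same reason ("2nd iteration" is
iteration index 1).

## Annotations

An annotation group assigns one label per frame over the whole
recording, declared either as a **timeline** or a **cycle**:

* Timelines are one-shot: the segment durations must sum exactly to the
  recording length, and a mismatch is an error rather than a silent
  truncation or repetition — an off-by-a-few-frames annotation is
  precisely the mistake this package exists to catch.
* Cycles are anchored at frame 1 (a phase offset can be emulated with a
  leading segment) and repeat until the recording ends, truncating
  mid-segment on the final repetition if needed. The repetition index
  ("iteration", 0-based) is stored per frame, since habituation and
  learning analyses need to distinguish the first presentation of a
  stimulus from the tenth. A cycle longer than the recording is
  accepted and yields a single truncated iteration.

Querying an existing group with an unknown label returns an empty set
plus a logged warning rather than an error, so compound queries degrade
gracefully; naming a group that does not exist is an error that lists
the available groups, because that is almost certainly a typo.

## Persistence and queries

The complete experiment description — files, frame/volume maps, label
definitions, per-frame assignments, per-frame cycle iterations and the
source segment lists — is written to a single SQLite file (schema
version 1, stored in the file; unrecognized versions fail loudly).
Persist → restore → persist reproduces identical row sets.

Queries combine per-condition frame sets with `and` (intersection) or
`or` (union); `logic` is mandatory when two or more conditions are
combined, and an empty condition list is an error rather than
select-all. Two conditions from the same group under `and` intersect
like any others (empty unless the labels coincide). A volume query
returns a full volume iff every one of its P frames matches, expressed
in SQL as a `GROUP BY volume_code HAVING COUNT(*) = P` over the matched
frames, restricted to codes ≥ 0. When an experiment has a database
attached, queries run against it — a restored database is fully
functional without the image files — and otherwise against the
in-memory tracks; the test suite checks that both paths agree
exhaustively on the toy fixture and that the SQL results equal a
brute-force set evaluation.

## Lazy loading

Readers are looked up by file extension in a registry whose default
entries handle multi-page grayscale TIFF via tifffile; registering an
extension twice requires an explicit override. A reader exposes page
count, page shape and dtype without decoding pixels, and decodes only
requested pages, so retrieval cost scales with the request rather than
the dataset. Pixel dtype is preserved end-to-end. RGB pages are
rejected (functional imaging frames are single-channel) and only the
first series of a multi-series TIFF is used, with a warning.

## The toy dataset

The generator writes a 42-frame recording split 13/13/16 over three
TIFF files, 10 frames per volume, pages of 16×16 uint16 pixels, with
three groups: light (timeline off×25, on×17), label (cycle c1×10,
c2×10, c3×20) and shape (cycle circle×8, square×8). The published
description of this toy recording fixes its observable facts but not
the underlying parameters; the file split and segment durations used
here are the simplest values consistent with all of those facts (frame
30 on the 4th page of the 3rd file; light on there; c3 in the label
cycle's first iteration; square in the shape cycle's second; the shape
switching mid-volume; and the and/or queries returning volume 3 and
volumes 2–3). They are configuration on `ToySpec`, not hard-coded
truths, and the actual toy data distributed with the original study may
use different internals.

Each page encodes its own 1-based frame number as a constant pixel
value, which makes every loading path machine-checkable: the content of
any loaded frame or slice must equal its global frame id. Generation is
deterministic (byte-identical files for the same spec); the generator
takes a seed for interface symmetry, but no randomness is involved. The
toy data exercises indexing, annotation expansion, persistence and lazy
loading; it does not emulate realistic image statistics, noise, motion,
or annotation jitter relative to volume boundaries beyond the
mid-volume shape switch, so passing tests say nothing about image
content processing — by design, the package never touches pixel values.

## Scale and limitations

All tests run at desk scale (≤ 500 frames in randomized property
checks, 42 in the fixture), which is sufficient because every operation
is exact integer arithmetic or set algebra with no asymptotic regime to
probe. Known limitations: one recording per database; no concurrent
writers; volumes must be a fixed number of frames (no variable-depth
acquisitions); no motion correction, registration or any other pixel
processing; TIFF is the only built-in format, with other formats
intended to enter through the reader registry. The command-line
interface covers mapping, querying, describing and exporting; anything
further is expected to go through the Python API.
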