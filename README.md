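# voltime

Time annotation and condition-based retrieval for volumetric functional
imaging recordings.

In volumetric functional imaging (light-sheet or two-photon calcium
imaging, for example), a recording is acquired as one long sequence of 2D
frames: the microscope sweeps through depth, so every *N* consecutive
frames form one 3D volume. The frames are spread across several
multi-page TIFF files, and the experiment unfolds on top of them —
stimuli switch on and off, repeated stimulus cycles run, behaviors come
and go. Analyzing such data means answering questions like *"give me all
full volumes recorded while the light was on and the stimulus was c3"* —
which requires bookkeeping that links every frame to its file, its page,
its volume, its slice within that volume, and every experimental
condition (including which repetition of a stimulus cycle it belongs to,
which matters for habituation and learning analyses).

voltime does this bookkeeping once, saves it to a single SQLite file, and
then retrieves exactly the frames or volumes you ask for — decoding only
the TIFF pages that back the request, never the whole dataset.

## Model

* Frames are numbered globally, 1-based; file pages, volumes, and slices
  are 0-based.
* A **FileMap** stores the per-file frame counts and cumulative offsets,
  so frame *f* resolves to (file, page) in O(log n_files).
* A **VolumeMap** assigns every frame a volume code: `0..n_full-1` for
  full volumes, `-1` for leading (head) frames before the first full
  volume, `-2` for trailing (tail) frames. With head offset *h*,
  `n_full = floor((n_frames - h) / frames_per_volume)`.
* Annotation groups are declared as a **Timeline** (labeled durations
  that must cover the recording exactly) or a **Cycle** (labeled
  durations repeated from frame 1 until the recording ends; frame *f*
  gets the label at position `(f-1) mod L` and iteration
  `floor((f-1) / L)` for cycle length *L*).
* Frame queries combine per-condition frame sets with `and`
  (intersection) or `or` (union). A volume query returns a full volume
  only if **all** of its frames match; partial volumes are never
  returned.

## Worked example

The built-in toy recording has 42 frames in three TIFF files (13, 13 and
16 pages), 10 frames per volume — 4 full volumes plus 2 tail frames —
and three condition groups: `light` (timeline: off×25, on×17), `label`
(cycle: c1×10, c2×10, c3×20) and `shape` (cycle: circle×8, square×8).
Every page encodes its own frame number as a constant pixel value, so
loaded content is checkable by eye.

```python
from voltime import Experiment, generate_toy_dataset, toy_annotations, ToySpec

spec = ToySpec()
paths = generate_toy_dataset("toy/", spec)
exp = Experiment.create(files=paths, frames_per_volume=10,
                        annotations=toy_annotations(spec))

exp.frame_report(30)
# {'frame': 30, 'file_order': 2, 'file': 'toy/toy_002.tif', 'page_index': 3,
#  'volume_code': 2, 'slice_index': 9,
#  'labels': {'light': 'on', 'label': 'c3', 'shape': 'square'},
#  'iterations': {'label': 0, 'shape': 1}}

exp.choose_volumes([("label", "c3"), ("light", "on")], "and")   # [3]
exp.choose_volumes([("label", "c3"), ("light", "on")], "or")    # [2, 3]

exp.load_volumes([3]).shape   # (1, 10, 16, 16)
```

Frame 30 sits at page 3 (its 4th frame) of the 3rd file, is the last
slice (9, zero-based) of the 3rd volume (code 2), was recorded with the
light on, label c3, a square on screen, during the second repetition of
the shape cycle and the first of the label cycle. Volume 3 is the only
full volume that is entirely c3 *and* light-on; volumes 2 and 3 are the
ones that are c3 *or* light-on (the tail frames 41–42 also match, but
they do not form a full volume).

The same pipeline runs from the shell:

```bash
voltime make-toy -o toy/
voltime init -c exp.yaml -o exp.db
voltime query --db exp.db --condition label=c3 --condition light=on \
              --logic and --volumes        # prints: 3
voltime describe --db exp.db
voltime export --db exp.db --condition light=on -o on_volumes.tif
```

where `exp.yaml` declares `data_dir`, `frames_per_volume`, and the
annotation groups (see `tests/test_cli.py` for a complete example).
Once saved, `exp.db` answers every query without the TIFF files present;
only pixel loading needs them.

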