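"""Self-contained toy dataset generator for tests, demos and tutorials.

The toy recording is 42 frames split over three multi-page TIFF files
(13, 13 and 16 pages), imaged at 10 frames per volume — 4 full volumes
plus 2 trailing frames.  Three condition groups annotate it:

* ``light`` — a timeline: off for 25 frames, then on for 17;
* ``label`` — a 40-frame cycle c1x10, c2x10, c3x20;
* ``shape`` — a 16-frame cycle circle x 8, square x 8 (the shape
  switches mid-volume, so no full volume is uniformly one shape).

Every page encodes its own 1-based global frame number as a constant
pixel value, so loaded content is machine-checkable: the page holding
frame 30 is an image of all 30s.  Generation is deterministic — the same
spec always produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .annotation import Cycle, Label, Segment, Timeline
from .experiment import Experiment


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the toy recording; the defaults are the canonical set."""

    n_frames: int = 42
    file_split: tuple[int, ...] = (13, 13, 16)
    frames_per_volume: int = 10
    page_shape: tuple[int, int] = (16, 16)
    light_timeline: tuple[tuple[str, int], ...] = (("off", 25), ("on", 17))
    label_cycle: tuple[tuple[str, int], ...] = (("c1", 10), ("c2", 10), ("c3", 20))
    shape_cycle: tuple[tuple[str, int], ...] = (("circle", 8), ("square", 8))
    dtype: str = "uint16"

    def __post_init__(self) -> None:
        if sum(self.file_split) != self.n_frames:
            raise ValueError(
                f"file_split sums to {sum(self.file_split)}, "
                f"expected n_frames = {self.n_frames}"
            )
        light_total = sum(d for _, d in self.light_timeline)
        if light_total != self.n_frames:
            raise ValueError(
                f"light timeline covers {light_total} frames, "
                f"expected {self.n_frames}"
            )


def toy_annotations(spec: ToySpec | None = None) -> list[Timeline | Cycle]:
    """The three canonical annotation groups of the toy recording."""
    spec = spec or ToySpec()

    def segs(group: str, pairs) -> tuple[Segment, ...]:
        return tuple(
            Segment(label=Label(group=group, name=name), duration=dur)
            for name, dur in pairs
        )

    return [
        Timeline(group="light", segments=segs("light", spec.light_timeline)),
        Cycle(group="label", segments=segs("label", spec.label_cycle)),
        Cycle(group="shape", segments=segs("shape", spec.shape_cycle)),
    ]


def generate_toy_dataset(
    out_dir: str | Path, spec: ToySpec | None = None, seed: int = 0
) -> list[Path]:
    """Write the toy TIFF files into ``out_dir`` and return their paths.

    Page content is fully determined by the spec (constant frame-number
    encoding); ``seed`` is accepted for interface symmetry with other
    generators and does not affect the output.
    """
    spec = spec or ToySpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths = []
    frame = 1
    for i, count in enumerate(spec.file_split):
        pages = np.stack(
            [
                np.full(spec.page_shape, frame + p, dtype=spec.dtype)
                for p in range(count)
            ]
        )
        path = out_dir / f"toy_{i:03d}.tif"
        tifffile.imwrite(path, pages, photometric="minisblack")
        paths.append(path)
        frame += count
    return paths


def canonical_experiment(
    out_dir: str | Path, spec: ToySpec | None = None
) -> Experiment:
    """Generate (if needed) the toy data and return the mapped experiment."""
    spec = spec or ToySpec()
    out_dir = Path(out_dir)
    expected = [out_dir / f"toy_{i:03d}.tif" for i in range(len(spec.file_split))]
    if not all(p.exists() for p in expected):
        generate_toy_dataset(out_dir, spec)
    return Experiment.create(
        files=expected,
        frames_per_volume=spec.frames_per_volume,
        annotations=toy_annotations(spec),
    )
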