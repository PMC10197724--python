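"""Lazy page-level readers for image files, keyed by file extension.

A :class:`FrameSource` exposes a file's page count, page shape and pixel
dtype without decoding pixel data, and decodes only the pages that are
explicitly requested.  Readers are looked up in a registry by file
extension, so additional formats can be plugged in without touching the
rest of the package.  Multi-page grayscale TIFF is supported out of the
box via tifffile.
"""

from __future__ import annotations

import abc
import logging
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)


class UnsupportedFormatError(ValueError):
    """The file extension has no registered reader."""


class FrameSource(abc.ABC):
    """Lazy reader for one image file.

    Attributes
    ----------
    path : Path
    n_pages : int
        Number of 2D frames in the file.
    page_shape : tuple[int, int]
        (height, width) shared by all pages.
    dtype : numpy dtype
        Pixel scalar type, preserved end-to-end.
    """

    path: Path
    n_pages: int
    page_shape: tuple[int, int]
    dtype: np.dtype

    @abc.abstractmethod
    def read_pages(self, page_indices: Sequence[int]) -> np.ndarray:
        """Decode the requested 0-based pages, order preserved.

        Returns an array of shape ``(len(page_indices), H, W)``; only the
        requested pages are decoded.
        """


class TiffFrameSource(FrameSource):
    """Multi-page grayscale TIFF reader backed by tifffile.

    Only the first image series is read (others are ignored with a
    warning); RGB / multi-sample pages are rejected because functional
    imaging frames are single-channel.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"image file not found: {self.path}")
        with tifffile.TiffFile(self.path) as tif:
            if len(tif.series) > 1:
                logger.warning(
                    "%s contains %d image series; only the first is used",
                    self.path, len(tif.series),
                )
            series = tif.series[0]
            first = series.pages[0]
            if first.samplesperpixel != 1:
                raise ValueError(
                    f"{self.path} has {first.samplesperpixel} samples per "
                    "pixel; only grayscale (single-channel) pages are supported"
                )
            self.n_pages = len(series.pages)
            self.page_shape = tuple(first.shape[-2:])
            self.dtype = np.dtype(first.dtype)

    def read_pages(self, page_indices: Sequence[int]) -> np.ndarray:
        for i in page_indices:
            if not 0 <= i < self.n_pages:
                raise IndexError(
                    f"page {i} out of range for {self.path} "
                    f"(0..{self.n_pages - 1})"
                )
        if len(page_indices) == 0:
            return np.empty((0, *self.page_shape), dtype=self.dtype)
        with tifffile.TiffFile(self.path) as tif:
            pages = tif.series[0].pages
            # each page is decoded individually: work scales with the
            # request, not the file
            stack = np.stack([pages[i].asarray() for i in page_indices])
        return stack.astype(self.dtype, copy=False)


_REGISTRY: dict[str, Callable[[str | Path], FrameSource]] = {}


def register_format(
    extension: str,
    factory: Callable[[str | Path], FrameSource],
    override: bool = False,
) -> None:
    """Register a :class:`FrameSource` factory for a file extension.

    Extensions are matched case-insensitively, with or without the
    leading dot.  Re-registering an extension requires ``override=True``.
    """
    ext = extension.lower().lstrip(".")
    if ext in _REGISTRY and not override:
        raise ValueError(
            f"extension {'.' + ext!r} is already registered; pass "
            "override=True to replace the existing reader"
        )
    _REGISTRY[ext] = factory


def registered_formats() -> list[str]:
    return sorted("." + ext for ext in _REGISTRY)


def probe(path: str | Path) -> FrameSource:
    """Open a file lazily, reporting page count/shape/dtype without pixels."""
    path = Path(path)
    ext = path.suffix.lower().lstrip(".")
    if ext not in _REGISTRY:
        raise UnsupportedFormatError(
            f"no reader registered for {path.suffix!r}; supported "
            f"extensions: {registered_formats()}"
        )
    return _REGISTRY[ext](path)


def read_pages(source: FrameSource, page_indices: Sequence[int]) -> np.ndarray:
    """Functional alias for ``source.read_pages`` (order preserved)."""
    return source.read_pages(page_indices)


register_format("tif", TiffFrameSource)
register_format("tiff", TiffFrameSource)
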