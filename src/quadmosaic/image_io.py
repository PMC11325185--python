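"""Raster image and centroid table input/output.

Canonical in-memory conventions used throughout the package:

- images are 2-D ``float64`` arrays of non-negative, finite intensities;
  quantisation to 8/16-bit happens only at file boundaries;
- coordinates are ``(x, y)`` with ``x`` = column, ``y`` = row, origin at the
  top-left, ``y`` increasing downward, and pixel centres at integer positions.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "RasterImage",
    "CentroidSet",
    "UnsupportedFormatError",
    "read_image",
    "write_image",
    "read_centroids",
    "write_centroids",
]

VALID_LABELS = ("cone", "rod", "any")
VALID_SOURCES = ("automatic", "manual")

#: minimum separation below which two centroids are considered duplicates (px)
DUPLICATE_TOL = 1e-6


class UnsupportedFormatError(ValueError):
    """Raised for colour / multi-channel / unknown image formats."""


@dataclass
class RasterImage:
    """A single-channel image with optional physical pixel scale.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities. Stored as ``float64``.
    pixel_scale
        Microns per pixel, if known.
    """

    pixels: np.ndarray
    pixel_scale: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image intensities must be finite")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CentroidSet:
    """A list of sub-pixel cell-centre coordinates with per-point labels.

    ``points`` is an ``(N, 2)`` array of ``(x, y)`` coordinates (x = column,
    y = row). Labels are one of ``cone``, ``rod`` or ``any``; ``source``
    records whether the set came from automatic detection or manual
    annotation.
    """

    points: np.ndarray
    labels: Optional[list[str]] = None
    source: str = "automatic"
    pixel_scale: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("centroid coordinates must be finite")
        self.points = pts
        if self.labels is None:
            self.labels = ["any"] * len(pts)
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(pts):
            raise ValueError("labels length must match number of points")
        for l in self.labels:
            if l not in VALID_LABELS:
                raise ValueError(f"invalid label {l!r}; expected one of {VALID_LABELS}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"invalid source {self.source!r}")
        self._check_duplicates()

    def _check_duplicates(self) -> None:
        if len(self.points) < 2:
            return
        from scipy.spatial import cKDTree

        tree = cKDTree(self.points)
        pairs = tree.query_pairs(DUPLICATE_TOL)
        if pairs:
            i, j = sorted(pairs)[0]
            raise ValueError(
                f"duplicate centroids: points {i} and {j} are closer than {DUPLICATE_TOL} px"
            )

    def __len__(self) -> int:
        return len(self.points)

    def check_bounds(self, image: RasterImage) -> None:
        """Validate that every point lies within the bounds of ``image``."""
        if len(self.points) == 0:
            return
        x, y = self.points[:, 0], self.points[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() > image.width - 1 or y.max() > image.height - 1:
            raise ValueError("centroid outside image bounds")


def _sidecar_pixel_scale(path: Path) -> Optional[float]:
    """Read ``pixel_scale_um`` from a ``<image>.yaml`` sidecar if present."""
    sidecar = Path(str(path) + ".yaml")
    if not sidecar.exists():
        return None
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    value = meta.get("pixel_scale_um")
    return None if value is None else float(value)


def read_image(path: str | os.PathLike) -> RasterImage:
    """Read a single-channel 8- or 16-bit TIFF or PNG.

    Pixel values are converted to ``float64`` without rescaling. A pixel
    scale (um/px) is picked up from a ``<path>.yaml`` sidecar when present.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    UnsupportedFormatError
        For colour/multi-channel images or unsupported dtypes/extensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise UnsupportedFormatError(f"unsupported format: {suffix!r} (expected TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"unsupported format: expected single-channel image, got shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise UnsupportedFormatError(
            f"unsupported format: expected 8- or 16-bit integer pixels, got {arr.dtype}"
        )
    return RasterImage(arr.astype(np.float64), pixel_scale=_sidecar_pixel_scale(path))


def write_image(img: RasterImage, path: str | os.PathLike, bit_depth: int = 8) -> None:
    """Write ``img`` losslessly as an 8- or 16-bit TIFF or PNG.

    Values outside ``[0, 2**bit_depth - 1]`` are clipped; non-integer values
    are rounded half-to-even.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    vmax = 2**bit_depth - 1
    quantised = np.rint(np.clip(img.pixels, 0, vmax))
    out = quantised.astype(np.uint8 if bit_depth == 8 else np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    elif suffix == ".png":
        iio.imwrite(path, out)
    else:
        raise UnsupportedFormatError(f"unsupported format: {suffix!r} (expected TIFF or PNG)")
    if img.pixel_scale is not None:
        with open(str(path) + ".yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"pixel_scale_um": float(img.pixel_scale)}, fh)


def read_centroids(path: str | os.PathLike) -> CentroidSet:
    """Read a centroid CSV with columns ``x,y[,label]`` (header required).

    A missing label column, or an empty label cell, defaults to ``any``.
    Malformed rows raise a ``ValueError`` naming the offending line number.
    """
    path = Path(path)
    points: list[tuple[float, float]] = []
    labels: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row") from None
        cols = [c.strip().lower() for c in header]
        if len(cols) < 2 or cols[0] != "x" or cols[1] != "y":
            raise ValueError(f"{path}: line 1: expected header 'x,y[,label]', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                x, y = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}: line {lineno}: malformed row {row!r}") from None
            if x < 0 or y < 0:
                raise ValueError(f"{path}: line {lineno}: negative coordinate in {row!r}")
            label = row[2].strip() if len(row) > 2 and row[2].strip() else "any"
            points.append((x, y))
            labels.append(label)
    return CentroidSet(np.array(points, dtype=np.float64).reshape(-1, 2), labels=labels)


def write_centroids(cs: CentroidSet, path: str | os.PathLike) -> None:
    """Write a CentroidSet as ``x,y,label`` CSV, preserving point order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "label"])
        for (x, y), label in zip(cs.points, cs.labels):
            writer.writerow([f"{x:.6f}", f"{y:.6f}", label])
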