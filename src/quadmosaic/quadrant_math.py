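"""Directional split-detection combination of four quadrant channels.

Four non-confocal detectors sit on the diagonals of the pupil-conjugate
plane (default azimuths 45, 135, 225, 315 degrees, counter-clockwise from
+x with y up). For each of the four split axes (0, 45, 90, 135 degrees,
naming the dividing line) the two detector groups on either side are summed
and combined as a normalised difference ``(A - B) / (A + B)``, yielding a
signed contrast image in ``[-1, 1]`` whose gradient is orthogonal to the
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from quadmosaic.image_io import RasterImage

__all__ = [
    "QuadrantFrameSet",
    "SplitImage",
    "DEFAULT_AZIMUTHS",
    "DEFAULT_AXIS_MAPPING",
    "normalize_quadrant_means",
    "split_image",
    "directional_splits",
]

#: detector azimuth centres, degrees, for channels Q1..Q4
DEFAULT_AZIMUTHS = (45.0, 135.0, 225.0, 315.0)

#: split axes, degrees; each names the dividing line of the split
SPLIT_AXES = (0.0, 45.0, 90.0, 135.0)

#: axis -> (positive-side azimuths, negative-side azimuths).
#: Cardinal axes separate two detector pairs; diagonal axes pass through two
#: detectors, leaving a single opposing pair with disjoint non-empty sides.
#: Each split shows its bright rim toward its positive side and its dark rim
#: opposite. The sides are chosen so the four bright-rim directions (90, 315,
#: 0, 225 degrees) spread over the plane rather than clustering in one
#: half-plane, which keeps the one-sided emboss shifts of the four axes
#: nearly balanced in the MinIP fusion.
DEFAULT_AXIS_MAPPING: dict[float, tuple[tuple[float, ...], tuple[float, ...]]] = {
    0.0: ((45.0, 135.0), (225.0, 315.0)),  # bright rim toward azimuth 90
    45.0: ((315.0,), (135.0,)),  # bright rim toward azimuth 315
    90.0: ((45.0, 315.0), (135.0, 225.0)),  # legacy vertical: bright rim toward 0
    135.0: ((225.0,), (45.0,)),  # bright rim toward azimuth 225
}

#: axis -> emboss polarity pointing toward that split's dark rim under
#: DEFAULT_AXIS_MAPPING (dark rim sits at axis + polarity * 90)
DEFAULT_POLARITY: dict[float, int] = {0.0: -1, 45.0: 1, 90.0: 1, 135.0: -1}

#: denominator below this is treated as undefined
DENOM_EPS = 0.0
#: channel mean below this is a degenerate channel
MEAN_EPS = 1e-9


@dataclass
class QuadrantFrameSet:
    """Four co-registered grayscale channels plus their detector azimuths."""

    channels: Sequence[RasterImage]
    azimuths: Sequence[float] = DEFAULT_AZIMUTHS

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        if len(self.channels) != 4:
            raise ValueError(f"expected exactly 4 channels, got {len(self.channels)}")
        shapes = {ch.shape for ch in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channel shape mismatch: {sorted(shapes)}")
        self.azimuths = tuple(float(a) % 360.0 for a in self.azimuths)
        if len(self.azimuths) != 4:
            raise ValueError("expected exactly 4 azimuths")
        if len(set(self.azimuths)) != 4:
            raise ValueError(f"azimuths must be pairwise distinct, got {self.azimuths}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    def channel_at(self, azimuth: float) -> RasterImage:
        """Return the channel whose detector azimuth equals ``azimuth``."""
        target = float(azimuth) % 360.0
        for ch, az in zip(self.channels, self.azimuths):
            if abs(az - target) < 1e-9:
                return ch
        raise KeyError(f"no channel at azimuth {azimuth}; have {self.azimuths}")


@dataclass
class SplitImage:
    """Signed normalised contrast image for one split-axis angle.

    ``pixels`` lie in ``[-1, 1]``; where the denominator of the normalised
    difference was zero, the value is 0 and ``undefined_mask`` is set.
    """

    pixels: np.ndarray
    axis_angle: float
    undefined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.undefined_mask is None:
            self.undefined_mask = np.zeros(self.pixels.shape, dtype=bool)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.undefined_mask.shape != self.pixels.shape:
            raise ValueError("undefined_mask shape must match pixels")
        if np.any(np.abs(self.pixels) > 1 + 1e-12):
            raise ValueError("split-image pixels must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def normalize_quadrant_means(qset: QuadrantFrameSet) -> QuadrantFrameSet:
    """Rescale each channel multiplicatively so all four means are equal.

    The common target is the grand mean of the four input channel means,
    mirroring the balancing of detector gains during acquisition. Relative
    per-channel contrast is preserved; the operation is idempotent.
    """
    means = np.array([ch.pixels.mean() for ch in qset.channels])
    if np.any(means <= MEAN_EPS):
        bad = int(np.argmin(means))
        raise ValueError(f"degenerate channel {bad}: mean {means[bad]:g} <= {MEAN_EPS:g}")
    target = means.mean()
    channels = [
        RasterImage(ch.pixels * (target / m), pixel_scale=ch.pixel_scale)
        for ch, m in zip(qset.channels, means)
    ]
    return QuadrantFrameSet(channels, qset.azimuths)


def split_image(a: RasterImage, b: RasterImage, axis_angle: float = 90.0) -> SplitImage:
    """Per-pixel normalised difference ``(A - B) / (A + B)``.

    Where ``A + B == 0`` the result is 0 and the undefined mask is set,
    keeping downstream filters total.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa, pb = a.pixels, b.pixels
    if pa.min() < 0 or pb.min() < 0:
        raise ValueError("split inputs must be non-negative")
    total = pa + pb
    undefined = total <= DENOM_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(undefined, 0.0, (pa - pb) / np.where(undefined, 1.0, total))
    return SplitImage(s, axis_angle=float(axis_angle), undefined_mask=undefined)


def _sum_side(qset: QuadrantFrameSet, azimuths: Sequence[float]) -> RasterImage:
    total = np.zeros(qset.shape, dtype=np.float64)
    for az in azimuths:
        total += qset.channel_at(az).pixels
    return RasterImage(total, pixel_scale=qset.channels[0].pixel_scale)


def directional_splits(
    qset: QuadrantFrameSet,
    mapping: Optional[Mapping[float, tuple[Sequence[float], Sequence[float]]]] = None,
) -> list[SplitImage]:
    """Compute the four directional split images (axes 0, 45, 90, 135 deg).

    ``mapping`` assigns to each axis the detector azimuths on its positive
    and negative sides; sides must be non-empty and disjoint. The default
    mapping assumes detectors centred on the diagonals.
    """
    if mapping is None:
        mapping = DEFAULT_AXIS_MAPPING
    if set(float(k) for k in mapping) != set(SPLIT_AXES):
        raise ValueError(f"mapping must cover axes {SPLIT_AXES}, got {sorted(mapping)}")
    splits = []
    for axis in SPLIT_AXES:
        pos, neg = mapping[axis]
        if not pos or not neg:
            raise ValueError(f"axis {axis}: both sides must be non-empty")
        if set(pos) & set(neg):
            raise ValueError(f"axis {axis}: sides must be disjoint")
        splits.append(split_image(_sum_side(qset, pos), _sum_side(qset, neg), axis_angle=axis))
    return splits
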