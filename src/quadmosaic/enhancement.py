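"""Directional emboss filtering and minimum-intensity-projection fusion.

Each directional split image is mapped to the 8-bit display range, embossed
orthogonally to its split axis (grey-offset directional finite difference),
and the four embossed images are fused by pixel-wise minimum (MinIP). The
emboss definition::

    E(x, y) = clip_[0,255](128 + (amount / 100) * (I(x, y) - I(x + dx, y + dy)))

with ``(dx, dy) = (round(h * cos(theta)), round(-h * sin(theta)))`` and
out-of-bounds samples replicated from the nearest edge pixel. Angles are in
degrees counter-clockwise from +x in math orientation; ``dy`` carries the
minus sign because image y runs downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from quadmosaic.image_io import RasterImage
from quadmosaic.quadrant_math import DEFAULT_POLARITY, SplitImage

__all__ = [
    "EmbossParams",
    "EnhancedImage",
    "to_display_range",
    "quantize_8bit",
    "emboss",
    "emboss_angle_for_axis",
    "enhance_stack",
    "minip",
    "enhance",
]

DEFAULT_HEIGHT = 5  # px offset
DEFAULT_AMOUNT = 150.0  # percent gain
MID_GREY = 128.0


@dataclass(frozen=True)
class EmbossParams:
    """Emboss filter parameters: pixel offset, percent gain and direction."""

    height: int = DEFAULT_HEIGHT
    amount: float = DEFAULT_AMOUNT
    angle: float = 0.0

    def __post_init__(self) -> None:
        if int(self.height) != self.height or self.height < 1:
            raise ValueError(f"height must be an integer >= 1, got {self.height}")
        if self.amount <= 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        object.__setattr__(self, "height", int(self.height))
        object.__setattr__(self, "angle", float(self.angle) % 360.0)

    @property
    def offset(self) -> tuple[int, int]:
        """Integer sampling offset ``(dx, dy)`` for this height/angle."""
        theta = np.deg2rad(self.angle)
        return int(np.rint(self.height * np.cos(theta))), int(np.rint(-self.height * np.sin(theta)))


@dataclass
class EnhancedImage:
    """MinIP fusion of embossed directional images; values in [0, 255]."""

    pixels: np.ndarray
    provenance: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("enhanced image values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_display_range(s: SplitImage) -> RasterImage:
    """Affine map of a signed split image from [-1, 1] to [0, 255].

    ``p = 127.5 * (s + 1)``; pixels flagged undefined map to mid-grey 127.5.
    """
    p = 127.5 * (s.pixels + 1.0)
    p[s.undefined_mask] = 127.5
    return RasterImage(p)


def quantize_8bit(img: RasterImage) -> RasterImage:
    """Quantise to the 8-bit grid (clip to [0, 255], round half-to-even)."""
    return RasterImage(np.rint(np.clip(img.pixels, 0.0, 255.0)), pixel_scale=img.pixel_scale)


def emboss(img: RasterImage, params: EmbossParams) -> RasterImage:
    """Apply the grey-offset directional finite-difference emboss filter.

    Output has the same dimensions, values clipped to [0, 255]; a constant
    image maps to constant 128. Replicate padding avoids a spurious dark
    frame at image edges.
    """
    dx, dy = params.offset
    if abs(dx) >= img.shape[1] or abs(dy) >= img.shape[0]:
        raise ValueError(
            f"emboss offset {(dx, dy)} (height {params.height}) exceeds the "
            f"image dimensions {img.shape}"
        )
    h, w = img.shape
    rows = np.clip(np.arange(h) + dy, 0, h - 1)
    cols = np.clip(np.arange(w) + dx, 0, w - 1)
    shifted = img.pixels[np.ix_(rows, cols)]
    out = MID_GREY + (params.amount / 100.0) * (img.pixels - shifted)
    return RasterImage(np.clip(out, 0.0, 255.0), pixel_scale=img.pixel_scale)


def emboss_angle_for_axis(axis_angle: float, polarity: int = 1) -> float:
    """Emboss direction for a split axis: orthogonal, signed by ``polarity``."""
    if axis_angle not in (0.0, 45.0, 90.0, 135.0):
        raise ValueError(f"invalid split axis {axis_angle}; expected one of 0, 45, 90, 135")
    if polarity not in (1, -1):
        raise ValueError(f"polarity must be +1 or -1, got {polarity}")
    return (axis_angle + polarity * 90.0) % 360.0


def enhance_stack(
    splits: Sequence[SplitImage],
    height: int = DEFAULT_HEIGHT,
    amount: float = DEFAULT_AMOUNT,
    polarity: Union[int, Mapping[float, int], None] = None,
    quantize: bool = True,
) -> list[RasterImage]:
    """Map each split to display range and emboss it orthogonally to its axis.

    ``polarity`` is a single value applied to every axis, or a per-axis
    mapping; the default points each emboss toward its split's dark rim
    under the default side mapping. ``quantize`` mirrors the 8-bit stage of
    the reference workflow (applied once, between display mapping and
    emboss); pass ``False`` for the pure floating-point variant.
    """
    axes = [s.axis_angle for s in splits]
    if len(set(axes)) != len(axes):
        raise ValueError(f"split axes must be distinct, got {axes}")
    if polarity is None:
        polarity = DEFAULT_POLARITY
    out = []
    for s in splits:
        disp = to_display_range(s)
        if quantize:
            disp = quantize_8bit(disp)
        pol = polarity[s.axis_angle] if isinstance(polarity, Mapping) else int(polarity)
        angle = emboss_angle_for_axis(s.axis_angle, pol)
        out.append(emboss(disp, EmbossParams(height=height, amount=amount, angle=angle)))
    return out


def minip(stack: Sequence[RasterImage], provenance: Sequence[float] = ()) -> EnhancedImage:
    """Pixel-wise minimum intensity projection over an image stack."""
    if len(stack) == 0:
        raise ValueError("minip requires at least one image")
    shapes = {img.shape for img in stack}
    if len(shapes) != 1:
        raise ValueError(f"stack shape mismatch: {sorted(shapes)}")
    fused = np.minimum.reduce([img.pixels for img in stack])
    return EnhancedImage(fused, provenance=list(provenance))


def enhance(
    splits: Sequence[SplitImage],
    height: int = DEFAULT_HEIGHT,
    amount: float = DEFAULT_AMOUNT,
    polarity: Union[int, Mapping[float, int], None] = None,
    quantize: bool = True,
) -> EnhancedImage:
    """Full enhancement: emboss each split orthogonally, then MinIP-fuse."""
    stack = enhance_stack(splits, height=height, amount=amount, polarity=polarity, quantize=quantize)
    return minip(stack, provenance=[s.axis_angle for s in splits])
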