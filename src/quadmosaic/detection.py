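"""Simple cell identification: blur, trough threshold, watershed, centroids.

The routine mirrors a generic open-tool workflow: Gaussian blur (radius 2 px
mapped to sigma = 2), binarisation at the trough between the two histogram
peaks, distance-transform watershed to separate touching cells, and one
sub-pixel centroid per labelled region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from quadmosaic.enhancement import EnhancedImage
from quadmosaic.image_io import CentroidSet, RasterImage

__all__ = [
    "DetectionParams",
    "LabelMask",
    "TroughNotFoundWarning",
    "params_for_cell_radius",
    "gaussian_blur",
    "trough_threshold",
    "binarize",
    "watershed_split",
    "find_cell_centroids",
    "detect_cells",
]

logger = logging.getLogger(__name__)

# histogram/trough constants. The window/separation pair must bridge the
# comb artefacts that 8-bit emboss quantisation leaves in the histogram
# (value steps of amount/100 intensity units), otherwise two jagged maxima
# of a single mode can masquerade as the two peaks.
HIST_BINS = 256
SMOOTH_WINDOW = 11
MIN_PEAK_SEPARATION = 20  # bins
MIN_PEAK_FRACTION = 0.05  # of the main peak; rejects unimodal tail wiggles
SEED_SMOOTH_SIGMA = 1.0  # px, smoothing of the distance map before seeding


class TroughNotFoundWarning(UserWarning):
    """Emitted when no bimodal trough is found and Otsu's threshold is used."""


@dataclass
class DetectionParams:
    """Parameters of the cell-identification routine.

    ``threshold`` is ``"auto"`` (histogram trough with Otsu fallback),
    ``"otsu"``, or a fixed numeric cutoff. ``invert`` selects dark-cell
    polarity (foreground below the cutoff); the default targets bright cell
    interiors enclosed by dark rims, as produced by the MinIP enhancement.
    ``max_area`` (px^2) drops oversized connected components before the
    watershed — background plateaus much larger than any cell — and ``None``
    disables it. ``edge_margin`` (px) discards regions whose centroid falls
    within that distance of the image border, where partially imaged cells
    cannot be localised reliably; 0 disables it.
    """

    blur_radius: float = 2.0
    threshold: Union[str, float] = "auto"
    min_area: int = 4
    max_area: Optional[int] = None
    edge_margin: float = 0.0
    maxima_mode: str = "component-centroid"
    invert: bool = False

    def __post_init__(self) -> None:
        if self.blur_radius < 0:
            raise ValueError("blur_radius must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.edge_margin < 0:
            raise ValueError("edge_margin must be >= 0")
        if isinstance(self.threshold, str) and self.threshold not in ("auto", "otsu"):
            raise ValueError(f"threshold must be 'auto', 'otsu' or a number, got {self.threshold!r}")
        if self.maxima_mode not in ("component-centroid", "regional-maxima"):
            raise ValueError(f"invalid maxima_mode {self.maxima_mode!r}")


@dataclass
class LabelMask:
    """Integer label image: 0 = background, 1..K = cell regions."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def params_for_cell_radius(radius: float, **overrides) -> DetectionParams:
    """Detection parameters scaled to an expected cell radius (px).

    ``min_area`` admits regions down to ~10% of the nominal cell area,
    ``max_area`` rejects connected plateaus above twice the nominal area,
    and ``edge_margin`` excludes the border band where cells are cut.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    area = np.pi * radius**2
    defaults = dict(
        min_area=max(4, int(0.1 * area)),
        max_area=int(2.0 * area),
        edge_margin=round(0.8 * radius),
    )
    defaults.update(overrides)
    return DetectionParams(**defaults)


def gaussian_blur(img: RasterImage, radius: float) -> RasterImage:
    """Isotropic Gaussian smoothing with sigma = ``radius`` (px).

    Radius 0 is the identity. Replicate ('nearest') boundary handling keeps
    the mean intensity essentially unchanged.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return RasterImage(img.pixels.copy(), pixel_scale=img.pixel_scale)
    blurred = ndi.gaussian_filter(img.pixels, sigma=radius, mode="nearest")
    return RasterImage(blurred, pixel_scale=img.pixel_scale)


def _smooth_histogram(hist: np.ndarray, window: int) -> np.ndarray:
    """Moving average with reflected ends."""
    half = window // 2
    padded = np.pad(hist.astype(np.float64), half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of local maxima, edges allowed, plateau -> leftmost index.

    Compares each bin against the nearest differing value on either side so
    flat-topped peaks (common in sparse histograms) count exactly once.
    """
    idx = []
    n = len(values)
    for i in range(n):
        j = i - 1
        while j >= 0 and values[j] == values[i]:
            j -= 1
        left = values[j] if j >= 0 else -np.inf
        k = i + 1
        while k < n and values[k] == values[i]:
            k += 1
        right = values[k] if k < n else -np.inf
        if values[i] > left and values[i] > right:
            # leftmost index of the plateau only
            if i == 0 or values[i - 1] != values[i]:
                idx.append(i)
    return np.array(idx, dtype=int)


def trough_threshold(img: RasterImage) -> float:
    """Cutoff intensity at the trough between the two main histogram peaks.

    A 256-bin histogram over [min, max] is smoothed with a moving average;
    the two highest local maxima separated by at least
    ``MIN_PEAK_SEPARATION`` bins (the second at least ``MIN_PEAK_FRACTION``
    of the first in height) bracket the trough, whose lowest smoothed bin
    (ties -> median tied index) gives the cutoff. If no such pair of peaks
    exists, Otsu's threshold is returned and a
    :class:`TroughNotFoundWarning` is emitted.
    """
    values = img.pixels
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("constant image: no threshold exists")
    hist, edges = np.histogram(values, bins=HIST_BINS, range=(vmin, vmax))
    smoothed = _smooth_histogram(hist, SMOOTH_WINDOW)
    peaks = _local_maxima(smoothed)
    cutoff = None
    if len(peaks) >= 2:
        order = peaks[np.argsort(smoothed[peaks])[::-1]]
        p1 = order[0]
        p2 = None
        for cand in order[1:]:
            if (
                abs(cand - p1) >= MIN_PEAK_SEPARATION
                and smoothed[cand] >= MIN_PEAK_FRACTION * smoothed[p1]
            ):
                p2 = cand
                break
        if p2 is not None:
            lo, hi = sorted((int(p1), int(p2)))
            between = smoothed[lo + 1 : hi]
            if between.size:
                tied = np.flatnonzero(between == between.min())
                trough = lo + 1 + int(tied[len(tied) // 2])
                cutoff = 0.5 * (edges[trough] + edges[trough + 1])
    if cutoff is None:
        cutoff = float(threshold_otsu(values))
        warnings.warn(
            "no bimodal trough found; falling back to Otsu's threshold",
            TroughNotFoundWarning,
            stacklevel=2,
        )
    return float(cutoff)


def binarize(img: RasterImage, cutoff: float, invert: bool = False) -> np.ndarray:
    """Threshold to a boolean mask: foreground ``> cutoff`` (or ``<`` when
    ``invert``)."""
    if invert:
        return img.pixels < cutoff
    return img.pixels > cutoff


def watershed_split(
    mask: np.ndarray,
    min_area: int = 4,
    max_area: Optional[int] = None,
) -> LabelMask:
    """Distance-transform watershed of a binary mask.

    Seeds are the regional maxima of the Euclidean distance transform
    (smoothed with sigma = 1 px); the watershed of the inverted distance map
    is constrained to the mask with 4-connectivity. Connected components
    larger than ``max_area`` (if given) are removed *before* the watershed —
    they are background plateaus, not touching cells. Output regions smaller
    than ``min_area`` are discarded and the survivors relabelled 1..K.
    """
    mask = np.asarray(mask, dtype=bool)
    if max_area is not None and mask.any():
        comp, _ = ndi.label(mask)
        counts = np.bincount(comp.ravel())
        oversized = np.flatnonzero(counts > max_area)
        oversized = oversized[oversized > 0]
        if oversized.size:
            mask = mask & ~np.isin(comp, oversized)
    if not mask.any():
        return LabelMask(np.zeros(mask.shape, dtype=np.int32))
    distance = ndi.distance_transform_edt(mask)
    smooth_dist = ndi.gaussian_filter(distance, sigma=SEED_SMOOTH_SIGMA, mode="nearest")
    # regional maxima of the smoothed distance map, restricted to the mask
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (smooth_dist == ndi.maximum_filter(smooth_dist, footprint=footprint)) & mask
    markers, n_markers = ndi.label(local_max, structure=np.ones((3, 3), dtype=int))
    # 8-connected marker plateaus may straddle two 4-connected components;
    # split them so the watershed can never merge across components
    components, _ = ndi.label(mask)
    key = markers.astype(np.int64) * (components.max() + 1) + components
    key[markers == 0] = 0
    uniques, markers = np.unique(key, return_inverse=True)
    markers = markers.reshape(mask.shape).astype(np.int32)
    if uniques[0] != 0:  # fully seeded mask: keep labels positive
        markers += 1
    # distance-map smoothing can bleed across narrow gaps, leaving small
    # components without any regional maximum; seed those at their own
    # distance peak so no component is silently dropped
    n_components = int(components.max())
    seeded = np.unique(components[markers > 0])
    missing = np.setdiff1d(np.arange(1, n_components + 1), seeded)
    if missing.size:
        next_label = int(markers.max()) + 1
        positions = ndi.maximum_position(smooth_dist, components, missing)
        for pos in np.atleast_2d(positions):
            markers[tuple(pos)] = next_label
            next_label += 1
    labels = watershed(-smooth_dist, markers=markers, mask=mask, connectivity=1)
    labels = _filter_by_min_area(labels, min_area)
    return LabelMask(labels)


def _filter_by_min_area(labels: np.ndarray, min_area: int) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    remap = np.zeros(len(counts), dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return remap[labels]


def find_cell_centroids(
    lm: LabelMask,
    intensity: Optional[RasterImage] = None,
    mode: str = "component-centroid",
) -> CentroidSet:
    """One sub-pixel point per label.

    ``component-centroid`` returns the area centroid of each region;
    ``regional-maxima`` returns the brightest pixel of ``intensity`` within
    each region (requires ``intensity``).
    """
    k = lm.n_labels
    if k == 0:
        return CentroidSet(np.empty((0, 2)), source="automatic")
    index = np.arange(1, k + 1)
    if mode == "component-centroid":
        rc = ndi.center_of_mass(np.ones(lm.shape), lm.labels, index)
        points = np.array([(c, r) for r, c in rc], dtype=np.float64)
    elif mode == "regional-maxima":
        if intensity is None:
            raise ValueError("regional-maxima mode requires an intensity image")
        rc = ndi.maximum_position(intensity.pixels, lm.labels, index)
        points = np.array([(float(c), float(r)) for r, c in rc], dtype=np.float64)
    else:
        raise ValueError(f"invalid mode {mode!r}")
    return CentroidSet(points, source="automatic")


def detect_cells(
    img: Union[EnhancedImage, RasterImage],
    params: Optional[DetectionParams] = None,
) -> CentroidSet:
    """Full routine: blur -> threshold -> binarize -> watershed -> centroids.

    Per-stage statistics (cutoff used, region counts before and after the
    area filter) are logged at info level.
    """
    if params is None:
        params = DetectionParams()
    raster = img if isinstance(img, RasterImage) else RasterImage(img.pixels)
    blurred = gaussian_blur(raster, params.blur_radius)
    if isinstance(params.threshold, str):
        if params.threshold == "auto":
            cutoff = trough_threshold(blurred)
        else:
            cutoff = float(threshold_otsu(blurred.pixels))
    else:
        cutoff = float(params.threshold)
    logger.info("detect_cells: cutoff=%.3f", cutoff)
    mask = binarize(blurred, cutoff, invert=params.invert)
    n_components = int(ndi.label(mask)[1])
    lm = watershed_split(mask, min_area=params.min_area, max_area=params.max_area)
    logger.info(
        "detect_cells: %d connected components -> %d regions after watershed/area filter",
        n_components,
        lm.n_labels,
    )
    cs = find_cell_centroids(lm, intensity=blurred, mode=params.maxima_mode)
    if params.edge_margin > 0 and len(cs):
        h, w = raster.shape
        e = params.edge_margin
        x, y = cs.points[:, 0], cs.points[:, 1]
        keep = (x >= e) & (x <= w - 1 - e) & (y >= e) & (y <= h - 1 - e)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("detect_cells: dropped %d border regions (edge_margin=%g)", n_dropped, e)
        cs = CentroidSet(
            cs.points[keep], labels=[l for l, k in zip(cs.labels, keep) if k], source="automatic"
        )
    return cs
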