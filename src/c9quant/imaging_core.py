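"""Shared image primitives for the fluorescence-quantification assays.

All public operations work in physical units (micrometres), converting to
pixels internally through the calibration carried by :class:`ChannelImage`
and :class:`BinaryMask`. Coordinates are (row, col), 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, skeletonize, white_tophat

__all__ = [
    "ChannelImage",
    "BinaryMask",
    "RegionGeometry",
    "LabeledRegions",
    "PointSet",
    "ThresholdResult",
    "DegenerateInputWarning",
    "threshold_global",
    "label_regions",
    "circularity",
    "filter_by_circularity",
    "skeletonize_mask",
    "skeleton_length",
    "percent_positive_area",
    "local_maxima",
    "tophat_subtract",
    "boundary_distance",
]

_SQRT2 = float(np.sqrt(2.0))


class DegenerateInputWarning(UserWarning):
    """Raised (as a warning) when an input carries no usable signal."""


@dataclass
class ChannelImage:
    """A single-channel intensity image with a physical pixel calibration.

    Parameters
    ----------
    pixels : 2D array of finite, non-negative intensities.
    pixel_size : physical edge length of one pixel, in micrometres.
    channel_name : free-text label (e.g. ``"TUJ1"``, ``"DAPI"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean segmentation mask sharing the calibration of its source."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("mask must be a non-empty 2D grid")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def positive_area_um2(self) -> float:
        return float(np.count_nonzero(self.pixels)) * self.pixel_size**2


@dataclass
class RegionGeometry:
    """Per-region geometry in physical units.

    ``circularity`` is clipped to 1.0 for reporting; ``circularity_raw``
    keeps the unclipped estimate (rasterization can push it slightly
    above 1 on near-circular shapes).
    """

    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    circularity_raw: float
    centroid: tuple[float, float]
    pixel_count: int


@dataclass
class LabeledRegions:
    """Connected components with per-region geometry.

    Labels in ``labels`` are consecutive positive integers; 0 is background.
    """

    labels: np.ndarray
    pixel_size: float
    regions: list[RegionGeometry] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def mask_for(self, lab: int) -> BinaryMask:
        return BinaryMask(self.labels == lab, self.pixel_size)


@dataclass
class PointSet:
    """Detected points as (row, col) coordinates, possibly sub-pixel."""

    points: np.ndarray  # (n, 2) float
    pixel_size: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def points_um(self) -> np.ndarray:
        return self.points * self.pixel_size


@dataclass
class ThresholdResult:
    """Mask plus the threshold that produced it and a degenerate-input flag."""

    mask: BinaryMask
    threshold: float
    degenerate: bool = False


def _resolve_threshold(pixels: np.ndarray, method) -> tuple[float, bool]:
    """Return (threshold value, degenerate flag) for a method spec.

    ``method`` is ``"otsu"``, ``"quantile:q"``, ``"fixed:v"`` or a bare
    number (treated as a fixed threshold).
    """
    if isinstance(method, (int, float)):
        return float(method), False
    if not isinstance(method, str):
        raise ValueError(f"unrecognized threshold method: {method!r}")
    if method == "otsu":
        if np.ptp(pixels) == 0:  # constant image: Otsu is undefined
            return float(pixels.flat[0]), True
        return float(threshold_otsu(pixels)), False
    if method.startswith("quantile:"):
        q = float(method.split(":", 1)[1])
        if not 0.0 <= q <= 1.0:
            raise ValueError("quantile must lie in [0, 1]")
        return float(np.quantile(pixels, q)), False
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1]), False
    if method.startswith("mad:"):
        # robust background cut: median + k * 1.4826 * MAD
        k = float(method.split(":", 1)[1])
        med = float(np.median(pixels))
        mad = float(np.median(np.abs(pixels - med)))
        return med + k * 1.4826 * mad, mad == 0 and np.ptp(pixels) == 0
    raise ValueError(f"unrecognized threshold method: {method!r}")


def threshold_global(img: ChannelImage, method="otsu") -> ThresholdResult:
    """Threshold an image globally; mask is True where intensity > threshold.

    A constant image under ``otsu`` yields an empty mask with the
    ``degenerate`` flag set (and a :class:`DegenerateInputWarning`), never
    an exception.
    """
    thr, degenerate = _resolve_threshold(img.pixels, method)
    if degenerate:
        warnings.warn(
            f"constant image ({img.channel_name or 'unnamed'}): "
            "threshold undefined, returning empty mask",
            DegenerateInputWarning,
            stacklevel=2,
        )
        mask = np.zeros(img.shape, dtype=bool)
    else:
        mask = img.pixels > thr
    return ThresholdResult(BinaryMask(mask, img.pixel_size), thr, degenerate)


def _region_geometry(prop, pixel_size: float) -> RegionGeometry:
    area_px = int(prop.area)
    area = area_px * pixel_size**2
    # Crofton 4-direction line-intercept estimator, scaled to physical units.
    perim = float(prop.perimeter_crofton) * pixel_size
    if area_px == 1:
        circ_raw = circ = 1.0  # maximally compact by definition
    else:
        circ_raw = circularity(area, perim)
        circ = min(circ_raw, 1.0)
    r, c = prop.centroid
    return RegionGeometry(
        label=int(prop.label),
        area_um2=area,
        perimeter_um=perim,
        circularity=circ,
        circularity_raw=circ_raw,
        centroid=(float(r), float(c)),
        pixel_count=area_px,
    )


def label_regions(mask: BinaryMask, connectivity: int = 8) -> LabeledRegions:
    """Label connected components and populate per-region geometry.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent;
    the default, so that thin diagonal neurites survive as one object).
    Perimeters use the Crofton 4-direction line-intercept estimator.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    labels = sk_label(mask.pixels, connectivity=conn)
    regions = [_region_geometry(p, mask.pixel_size) for p in regionprops(labels)]
    return LabeledRegions(labels=labels, pixel_size=mask.pixel_size, regions=regions)


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity 4*pi*area / perimeter**2 (1.0 for a disc)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def filter_by_circularity(regions: LabeledRegions, min_circ: float) -> BinaryMask:
    """Union of regions whose (clipped) circularity is >= ``min_circ``."""
    if not 0.0 <= min_circ <= 1.0 + 0.1:
        raise ValueError("min_circ must lie in [0, 1.1]")
    keep = [r.label for r in regions.regions if r.circularity >= min_circ]
    out = np.isin(regions.labels, keep) if keep else np.zeros(regions.labels.shape, bool)
    return BinaryMask(out, regions.pixel_size)


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """Thin a mask to its one-pixel-wide medial representation."""
    return BinaryMask(skeletonize(mask.pixels), mask.pixel_size)


def skeleton_length(skel: BinaryMask) -> float:
    """Edge-weighted length of a skeleton in micrometres.

    Sums over undirected adjacent skeleton-pixel pairs: ``pixel_size`` for
    orthogonal neighbours, ``sqrt(2) * pixel_size`` for diagonal ones. Each
    edge is counted once.
    """
    m = skel.pixels
    horiz = np.count_nonzero(m[:, :-1] & m[:, 1:])
    vert = np.count_nonzero(m[:-1, :] & m[1:, :])
    diag1 = np.count_nonzero(m[:-1, :-1] & m[1:, 1:])
    diag2 = np.count_nonzero(m[:-1, 1:] & m[1:, :-1])
    return ((horiz + vert) + _SQRT2 * (diag1 + diag2)) * skel.pixel_size


def percent_positive_area(mask: BinaryMask, roi: BinaryMask | None = None) -> float:
    """Percentage of ROI pixels that are positive in ``mask``.

    With ``roi=None`` the whole image is the ROI. An empty ROI is an error.
    """
    if roi is None:
        roi_px = np.ones(mask.shape, dtype=bool)
    else:
        if roi.shape != mask.shape:
            raise ValueError("roi and mask shapes differ")
        roi_px = roi.pixels
    n_roi = np.count_nonzero(roi_px)
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return 100.0 * np.count_nonzero(mask.pixels & roi_px) / n_roi


def local_maxima(
    img: ChannelImage, min_distance_um: float, min_prominence: float
) -> PointSet:
    """Detect local intensity maxima ("Find Maxima"-style).

    A candidate pixel equals the maximum of its neighbourhood of physical
    radius ``min_distance_um`` and rises at least ``min_prominence`` above
    the neighbourhood minimum (the local background). Connected plateaus of
    equal maxima yield a single point at the plateau centroid. Surviving
    candidates are then greedily suppressed so that no two detections lie
    within ``min_distance_um`` of each other (brightest first; ties broken
    by (row, col) order).
    """
    if min_distance_um < 0:
        raise ValueError("min_distance_um must be >= 0")
    px = img.pixels
    r = max(1, int(round(min_distance_um / img.pixel_size)))
    footprint = disk(r).astype(bool)
    maxf = ndimage.maximum_filter(px, footprint=footprint, mode="nearest")
    minf = ndimage.minimum_filter(px, footprint=footprint, mode="nearest")
    prominence = px - minf
    cand = (px == maxf) & (prominence >= min_prominence) & (prominence > 0)
    if not cand.any():
        return PointSet(np.empty((0, 2)), img.pixel_size)
    lab = sk_label(cand, connectivity=2)
    pts, heights = [], []
    for p in regionprops(lab):
        pts.append(p.centroid)
        rr, cc = np.round(p.centroid).astype(int)
        heights.append(px[min(rr, px.shape[0] - 1), min(cc, px.shape[1] - 1)])
    pts = np.asarray(pts, dtype=float)
    order = np.lexsort((pts[:, 1], pts[:, 0], -np.asarray(heights)))
    kept: list[np.ndarray] = []
    min_dist_px = min_distance_um / img.pixel_size
    for i in order:
        p = pts[i]
        if all(np.hypot(*(p - q)) > min_dist_px for q in kept):
            kept.append(p)
    kept_arr = np.asarray(kept)
    kept_arr = kept_arr[np.lexsort((kept_arr[:, 1], kept_arr[:, 0]))]
    return PointSet(kept_arr, img.pixel_size)


def tophat_subtract(img: ChannelImage, radius_um: float) -> ChannelImage:
    """White top-hat: image minus its morphological opening with a disc.

    The structuring element is a disc of the given physical radius. Output
    is pointwise <= input and >= 0. A radius below one pixel is an error.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    radius_px = radius_um / img.pixel_size
    if radius_px < 1.0:
        raise ValueError(
            f"top-hat radius {radius_um} um is below one pixel "
            f"({img.pixel_size} um)"
        )
    out = white_tophat(img.pixels, footprint=disk(int(round(radius_px))))
    return ChannelImage(np.clip(out, 0.0, None), img.pixel_size, img.channel_name)


def boundary_distance(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (um) of each interior pixel to nearest background.

    Background pixels map to 0. All-true or all-false masks are errors
    (the distance field would be undefined or trivial).
    """
    n_true = np.count_nonzero(mask.pixels)
    if n_true == 0 or n_true == mask.pixels.size:
        raise ValueError("mask must contain both foreground and background")
    return ndimage.distance_transform_edt(mask.pixels) * mask.pixel_size
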