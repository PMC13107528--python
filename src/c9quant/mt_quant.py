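"""Microtubule depolymerization index and neurite density from TUJ1/NeuN fields.

The TUJ1 (beta-III-tubulin) channel is segmented with a dual-threshold
scheme: a low threshold captures all tubulin-positive structures, a high
threshold picks out the brighter, aggregate-like depolymerized tubulin,
which is then refined by a circularity filter (aggregates are compact,
polymerized filaments elongated). The depolymerization index is the
area ratio depolymerized / (depolymerized + polymerized); neurite density
is the skeleton length of the polymerized mask per NeuN-positive nucleus.
One field of view (FOV) is the unit of output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import (
    BinaryMask,
    ChannelImage,
    DegenerateInputWarning,
    label_regions,
    skeleton_length,
    skeletonize_mask,
    threshold_global,
)

__all__ = [
    "MTQuantParams",
    "MTSegmentation",
    "MTQuantResult",
    "segment_microtubules",
    "depolymerization_index",
    "count_neun_nuclei",
    "quantify_field",
]


@dataclass
class MTQuantParams:
    """Tunable parameters of the TUJ1/NeuN quantification.

    low_method / high_method follow the threshold-method grammar of
    :func:`c9quant.imaging_core.threshold_global`; in addition
    ``high_method="otsu_foreground"`` (the default) applies Otsu restricted
    to the pixels already inside the low mask, separating dim filaments
    from bright aggregates regardless of their relative abundance.
    """

    low_method: object = "mad:5"
    high_method: object = "otsu_foreground"
    min_circ: float = 0.5
    smooth_sigma_px: float = 0.0
    depoly_min_area_um2: float = 0.1
    neun_min_area_um2: float = 10.0
    neun_method: object = "otsu"
    close_radius_px: int = 1  # bridge 1-px gaps in the poly mask before skeletonizing


@dataclass
class MTSegmentation:
    all_mask: BinaryMask
    depoly_mask: BinaryMask
    poly_mask: BinaryMask
    low_threshold: float
    high_threshold: float
    degenerate: bool = False


@dataclass
class MTQuantResult:
    """Per-FOV quantification of microtubule state and neurite density."""

    field_id: str
    depoly_area_um2: float
    poly_area_um2: float
    depolymerization_index: float  # NaN when undefined
    index_defined: bool
    skeleton_length_um: float
    neun_count: int
    neurite_density_um_per_nucleus: float  # NaN when undefined
    density_defined: bool
    degenerate: bool = False


def _maybe_smooth(img: ChannelImage, sigma_px: float) -> ChannelImage:
    if sigma_px <= 0:
        return img
    smoothed = ndimage.gaussian_filter(img.pixels, sigma=sigma_px)
    return ChannelImage(smoothed, img.pixel_size, img.channel_name)


def segment_microtubules(
    tuj1: ChannelImage,
    low_method="mad:5",
    high_method="otsu_foreground",
    min_circ: float = 0.5,
    smooth_sigma_px: float = 0.0,
    depoly_min_area_um2: float = 0.1,
) -> MTSegmentation:
    """Dual-threshold segmentation of TUJ1 into depolymerized vs polymerized.

    Returns three mutually consistent masks: ``depoly | poly == all`` and
    ``depoly & poly == {}``. The depolymerized candidates (high threshold)
    are refined for specificity by requiring circularity >= ``min_circ``
    and area >= ``depoly_min_area_um2`` (shot-noise speckle along filaments
    is near-single-pixel and would otherwise pass as maximally compact);
    everything in the low mask not claimed by them is polymerized. A blank
    image yields three empty masks with the degenerate flag set.
    """
    work = _maybe_smooth(tuj1, smooth_sigma_px)
    low = threshold_global(work, low_method)
    if low.degenerate or not low.mask.pixels.any():
        empty = BinaryMask(np.zeros(tuj1.shape, bool), tuj1.pixel_size)
        return MTSegmentation(empty, empty, empty, low.threshold, low.threshold, True)

    if high_method == "otsu_foreground":
        fg = work.pixels[low.mask.pixels]
        if np.ptp(fg) == 0:
            high_thr = float(fg[0])  # uniform foreground: nothing is "bright"
            high_px = np.zeros(tuj1.shape, bool)
        else:
            from skimage.filters import threshold_otsu

            high_thr = float(threshold_otsu(fg))
            high_px = work.pixels > high_thr
    else:
        high = threshold_global(work, high_method)
        high_thr, high_px = high.threshold, high.mask.pixels

    if high_thr < low.threshold:
        raise ValueError(
            f"high threshold ({high_thr}) resolved below low ({low.threshold})"
        )
    candidates = label_regions(
        BinaryMask(high_px & low.mask.pixels, tuj1.pixel_size)
    )
    keep = [
        r.label
        for r in candidates.regions
        if r.circularity >= min_circ and r.area_um2 >= depoly_min_area_um2
    ]
    depoly_px = (
        np.isin(candidates.labels, keep)
        if keep
        else np.zeros(tuj1.shape, bool)
    )
    depoly = BinaryMask(depoly_px, tuj1.pixel_size)
    poly = BinaryMask(low.mask.pixels & ~depoly.pixels, tuj1.pixel_size)
    return MTSegmentation(low.mask, depoly, poly, low.threshold, high_thr, False)


def depolymerization_index(depoly_area_um2: float, poly_area_um2: float) -> float:
    """depoly / (depoly + poly); NaN (with a warning) when both areas are 0."""
    if depoly_area_um2 < 0 or poly_area_um2 < 0:
        raise ValueError("areas must be non-negative")
    total = depoly_area_um2 + poly_area_um2
    if total == 0:
        warnings.warn(
            "no tubulin signal: depolymerization index undefined",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return math.nan
    return depoly_area_um2 / total


def count_neun_nuclei(
    neun: ChannelImage, min_area_um2: float = 10.0, method="otsu"
) -> int:
    """Count NeuN-positive nuclei: thresholded regions of area >= min_area."""
    res = threshold_global(neun, method)
    if res.degenerate:
        return 0
    regs = label_regions(res.mask)
    return sum(1 for r in regs.regions if r.area_um2 >= min_area_um2)


def quantify_field(
    tuj1: ChannelImage,
    neun: ChannelImage,
    params: MTQuantParams | None = None,
    field_id: str = "",
) -> MTQuantResult:
    """Full per-FOV quantification: segmentation, index, length, density.

    Skeletonization applies to the polymerized mask only; depolymerized
    aggregates never contribute neurite length. A field without NeuN nuclei
    keeps its row but reports neurite density as undefined (NaN).
    """
    if tuj1.shape != neun.shape:
        raise ValueError("TUJ1 and NeuN channel shapes differ")
    if tuj1.pixel_size != neun.pixel_size:
        raise ValueError("TUJ1 and NeuN calibrations differ")
    p = params or MTQuantParams()
    seg = segment_microtubules(
        tuj1,
        p.low_method,
        p.high_method,
        p.min_circ,
        p.smooth_sigma_px,
        p.depoly_min_area_um2,
    )
    depoly_area = seg.depoly_mask.positive_area_um2
    poly_area = seg.poly_mask.positive_area_um2
    if depoly_area + poly_area > 0:
        index = depolymerization_index(depoly_area, poly_area)
        index_defined = True
    else:
        index, index_defined = math.nan, False
    poly_for_skel = seg.poly_mask
    if p.close_radius_px > 0:
        size = 2 * p.close_radius_px + 1
        closed = ndimage.binary_closing(
            seg.poly_mask.pixels, structure=np.ones((size, size), bool)
        )
        poly_for_skel = BinaryMask(closed, seg.poly_mask.pixel_size)
    skel_len = skeleton_length(skeletonize_mask(poly_for_skel))
    n_nuclei = count_neun_nuclei(neun, p.neun_min_area_um2, p.neun_method)
    if n_nuclei > 0:
        density, density_defined = skel_len / n_nuclei, True
    else:
        density, density_defined = math.nan, False
    return MTQuantResult(
        field_id=field_id,
        depoly_area_um2=depoly_area,
        poly_area_um2=poly_area,
        depolymerization_index=index,
        index_defined=index_defined,
        skeleton_length_um=skel_len,
        neun_count=n_nuclei,
        neurite_density_um_per_nucleus=density,
        density_defined=density_defined,
        degenerate=seg.degenerate,
    )
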