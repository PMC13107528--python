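"""Nuclear pore complex (NPC) mislocalization from STED images.

Nuclei are segmented from the DAPI channel (median filter, threshold,
hole filling, size filter); NPC (Mab414) foci are detected as local
intensity maxima. For each nucleus an annular band 0.7-1.2 um deep from
the nuclear boundary is built on the Euclidean distance transform, and the
mislocalized fraction is the number of foci in that band divided by all
foci inside the nucleus (normalizing out nuclear size). NPCs normally sit
at the nuclear envelope, so foci displaced into this interior band mark
mislocalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import (
    BinaryMask,
    ChannelImage,
    DegenerateInputWarning,
    LabeledRegions,
    PointSet,
    boundary_distance,
    label_regions,
    local_maxima,
    threshold_global,
)

__all__ = [
    "NucleusRecord",
    "segment_nuclei",
    "nuclear_annulus",
    "detect_npc_foci",
    "mislocalization_fraction",
]


@dataclass
class NucleusRecord:
    """Per-nucleus foci bookkeeping.

    ``mislocalized_fraction`` is NaN (and ``fraction_defined`` False) when
    the nucleus contains no foci; such nuclei are excluded from summaries.
    """

    nucleus_id: int
    total_foci_in_nucleus: int
    foci_in_annulus: int
    mislocalized_fraction: float
    fraction_defined: bool
    annulus_empty: bool = False


def segment_nuclei(
    dapi: ChannelImage,
    median_radius_um: float = 0.2,
    min_area_um2: float = 5.0,
    method="otsu",
) -> LabeledRegions:
    """Segment nuclei from DAPI: median filter, threshold, fill, size-filter."""
    radius_px = max(1, int(round(median_radius_um / dapi.pixel_size)))
    filtered = ndimage.median_filter(dapi.pixels, size=2 * radius_px + 1)
    res = threshold_global(
        ChannelImage(filtered, dapi.pixel_size, dapi.channel_name), method
    )
    if res.degenerate:
        return LabeledRegions(np.zeros(dapi.shape, int), dapi.pixel_size, [])
    filled = ndimage.binary_fill_holes(res.mask.pixels)
    regs = label_regions(BinaryMask(filled, dapi.pixel_size))
    keep = [r.label for r in regs.regions if r.area_um2 >= min_area_um2]
    if len(keep) == len(regs.regions):
        return regs
    # relabel consecutively after dropping sub-minimum regions
    kept_px = np.isin(regs.labels, keep)
    return label_regions(BinaryMask(kept_px, dapi.pixel_size))


def nuclear_annulus(
    nucleus_mask: BinaryMask,
    inner_um: float = 0.7,
    outer_um: float = 1.2,
    direction: str = "inward",
) -> tuple[BinaryMask, bool]:
    """Band of pixels [inner, outer) um from the nuclear boundary.

    ``direction="inward"`` (default) takes the band inside the nucleus;
    ``"outward"`` takes it in the background just outside. Returns the
    annulus mask and a flag that is True when the nucleus is too small for
    any pixel to reach the inner depth (empty annulus).
    """
    if not 0 <= inner_um < outer_um:
        raise ValueError("require 0 <= inner_um < outer_um")
    if direction not in ("inward", "outward"):
        raise ValueError("direction must be 'inward' or 'outward'")
    if not nucleus_mask.pixels.any():
        raise ValueError("nucleus mask is empty")
    if direction == "inward":
        dist = boundary_distance(nucleus_mask)
    else:
        inverted = BinaryMask(~nucleus_mask.pixels, nucleus_mask.pixel_size)
        dist = boundary_distance(inverted)
    band = nucleus_mask.pixels & (dist >= inner_um) & (dist < outer_um)
    empty = not band.any()
    if empty:
        warnings.warn(
            "nucleus too small for the requested annulus depth",
            DegenerateInputWarning,
            stacklevel=2,
        )
    return BinaryMask(band, nucleus_mask.pixel_size), empty


def detect_npc_foci(
    mab414: ChannelImage,
    min_distance_um: float = 0.2,
    min_prominence: float = 10.0,
) -> PointSet:
    """Detect Mab414 foci as local maxima (see imaging_core.local_maxima)."""
    return local_maxima(mab414, min_distance_um, min_prominence)


def mislocalization_fraction(
    foci: PointSet,
    nuclei: LabeledRegions,
    inner_um: float = 0.7,
    outer_um: float = 1.2,
) -> list[NucleusRecord]:
    """Per-nucleus mislocalized-NPC fraction.

    Each focus is assigned to the nucleus whose label covers its nearest
    pixel (a focus outside every nucleus is ignored). Within a nucleus, a
    focus is mislocalized when its boundary depth lies in
    ``[inner_um, outer_um)``; foci deeper than ``outer_um`` count in the
    total but not the annulus. Nuclei without foci are flagged; their
    fraction is NaN.
    """
    if not 0 <= inner_um < outer_um:
        raise ValueError("require 0 <= inner_um < outer_um")
    labels = nuclei.labels
    px = nuclei.pixel_size
    records: list[NucleusRecord] = []
    # foci pixel coordinates, clipped into bounds
    if len(foci):
        rc = np.clip(
            np.round(foci.points).astype(int),
            0,
            np.array(labels.shape) - 1,
        )
        foci_labels = labels[rc[:, 0], rc[:, 1]]
    else:
        rc = np.empty((0, 2), int)
        foci_labels = np.empty(0, int)
    for reg in nuclei.regions:
        lab = reg.label
        sel = foci_labels == lab
        total = int(np.count_nonzero(sel))
        if total == 0:
            records.append(
                NucleusRecord(lab, 0, 0, float("nan"), False)
            )
            continue
        nuc_mask = BinaryMask(labels == lab, px)
        dist = boundary_distance(nuc_mask)
        depths = dist[rc[sel, 0], rc[sel, 1]]
        in_band = int(np.count_nonzero((depths >= inner_um) & (depths < outer_um)))
        records.append(
            NucleusRecord(lab, total, in_band, in_band / total, True)
        )
    return records
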