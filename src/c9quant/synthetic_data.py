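"""Synthetic ground-truth generators for every assay input.

Each generator is a pure function of ``(seed, parameters)``: regeneration
with the same arguments is bit-identical. A top-level seed fans out to
independent per-dataset streams via ``numpy.random.SeedSequence(seed,
spawn_key=(stream,))`` with a fixed stream index per generator, so the
datasets are statistically independent but jointly reproducible.

The returned :class:`GroundTruth` carries the planted parameters needed to
compute the expected pipeline output analytically or by brute force
(planted masks, lengths, depths, kinetic parameters, per-gene labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging_core import BinaryMask, ChannelImage

__all__ = [
    "GroundTruth",
    "gen_neurite_field",
    "gen_npc_nuclei",
    "gen_pi_timeseries",
    "gen_pi_frame",
    "gen_de_tables",
    "gen_expression_matrix",
    "gen_survival_fields",
    "gen_sting_field",
]

_STREAMS = {
    "neurite": 1,
    "npc": 2,
    "pi": 3,
    "de": 4,
    "survival": 5,
    "expression": 6,
    "sting": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class GroundTruth:
    """Planted parameters of one generated dataset.

    ``params`` holds JSON-serializable scalars/lists; ``arrays`` holds
    planted masks/grids used by oracle tests (excluded from JSON, noted by
    name so the dataset remains regenerable from ``(seed, params)``).
    """

    dataset: str
    seed: int
    params: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "dataset": self.dataset,
            "seed": self.seed,
            "params": self.params,
            "arrays_omitted": sorted(self.arrays),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# TUJ1 / NeuN neurite fields
# ---------------------------------------------------------------------------

_DIRS8 = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)
_STEP_LEN = np.array([1, np.sqrt(2), 1, np.sqrt(2), 1, np.sqrt(2), 1, np.sqrt(2)])


def _walk_filament(
    rng: np.random.Generator,
    bounds: tuple[int, int, int, int],
    target_len_px: float,
    occupied: set[tuple[int, int]],
    turn_prob: float = 0.05,
) -> tuple[list[tuple[int, int]], float]:
    """Persistent self-avoiding lattice walk within ``bounds`` (r0, r1, c0, c1).

    Heading changes are limited to +/-45 degrees per step, and a step may
    neither revisit nor come 8-adjacent to any previously planted pixel
    (``occupied``, shared across filaments) other than the walk head. The
    planted chains are therefore clean 1-px curves with no mutual contact,
    and their edge-weighted skeleton length equals the summed step lengths.
    The walk ends early if it boxes itself in.
    """
    r0, r1, c0, c1 = bounds

    def blocked(nr, nc, cur):
        if not (r0 <= nr < r1 and c0 <= nc < c1):
            return True
        if (nr, nc) in occupied:
            return True
        return any(
            (nr + er, nc + ec) in occupied
            for er, ec in _DIRS8
            if (nr + er, nc + ec) != cur
        )

    for _ in range(40):  # find a clear starting pixel
        r = int(rng.integers(r0, r1))
        c = int(rng.integers(c0, c1))
        if not blocked(r, c, (r, c)):
            break
    else:
        return [], 0.0
    heading = int(rng.integers(0, 8))
    path = [(r, c)]
    occupied.add((r, c))
    length = 0.0
    stuck = 0
    while length < target_len_px and stuck < 16:
        if rng.random() < turn_prob:
            heading = (heading + int(rng.choice([-1, 1]))) % 8
        dr, dc = _DIRS8[heading]
        nr, nc = r + dr, c + dc
        if blocked(nr, nc, (r, c)):
            heading = (heading + int(rng.choice([-1, 1]))) % 8
            stuck += 1
            continue
        stuck = 0
        length += _STEP_LEN[heading]
        r, c = nr, nc
        path.append((r, c))
        occupied.add((r, c))
    return path, length


def gen_neurite_field(
    seed: int,
    n_filaments: int = 8,
    total_length_um: float = 400.0,
    blob_fraction: float = 0.3,
    snr: float = 10.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1,
    n_nuclei: int = 8,
    background: float = 10.0,
    filament_amp: float = 40.0,
    blob_amp: float = 120.0,
    nucleus_radius_um: tuple[float, float] = (2.0, 3.0),
) -> tuple[ChannelImage, ChannelImage, GroundTruth]:
    """Generate a TUJ1/NeuN field with planted filaments, blobs and nuclei.

    Dim 1-px-wide persistent-walk filaments emulate polymerized
    microtubules; bright discs emulate depolymerized aggregates, sized so
    that planted blob pixels / total signal pixels equals ``blob_fraction``
    within +/-0.01. Filaments are confined to disjoint tiles (no crossing),
    and blobs avoid filaments. Noise is Poisson shot noise plus Gaussian
    read noise with sigma = filament_amp / snr.
    """
    if not 0.0 <= blob_fraction < 1.0:
        raise ValueError("blob_fraction must lie in [0, 1)")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = _rng(seed, "neurite")
    h, w = shape
    margin = 8
    total_len_px = total_length_um / pixel_size
    cap = 0.25 * (h - 2 * margin) * (w - 2 * margin)
    if total_len_px > cap:
        raise ValueError("requested filament length exceeds field capacity")

    bounds = (margin, h - margin, margin, w - margin)
    filament_mask = np.zeros(shape, dtype=bool)
    occupied: set[tuple[int, int]] = set()
    planted_length_px = 0.0
    n_planted = 0
    per_fil = total_len_px / n_filaments
    # top up with extra (shorter) filaments if walks box themselves in early
    while planted_length_px < 0.98 * total_len_px and n_planted < 6 * n_filaments:
        remaining = total_len_px - planted_length_px
        path, length = _walk_filament(rng, bounds, min(per_fil, remaining), occupied)
        if not path:
            continue
        for r, c in path:
            filament_mask[r, c] = True
        planted_length_px += length
        n_planted += 1
    if planted_length_px < 0.9 * total_len_px:
        raise ValueError("requested filament length exceeds field capacity")
    planted_length_um = planted_length_px * pixel_size

    fil_px = int(np.count_nonzero(filament_mask))
    blob_mask = np.zeros(shape, dtype=bool)
    if blob_fraction > 0 and fil_px > 0:
        target_blob_px = blob_fraction / (1.0 - blob_fraction) * fil_px
        # keep blobs away from filaments so subtraction cannot nibble them
        from scipy import ndimage

        forbidden = ndimage.binary_dilation(filament_mask, iterations=4)
        blob_px = 0
        attempts = 0
        while blob_px < target_blob_px * 0.99 and attempts < 4000:
            attempts += 1
            deficit = target_blob_px - blob_px
            radius = int(np.clip(np.sqrt(deficit / np.pi), 2, 7))
            r = int(rng.integers(margin + radius, h - margin - radius))
            c = int(rng.integers(margin + radius, w - margin - radius))
            rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
            stamp = rr**2 + cc**2 <= radius**2
            window = np.s_[r - radius : r + radius + 1, c - radius : c + radius + 1]
            if forbidden[window][stamp].any() or blob_mask[window][stamp].any():
                continue
            blob_mask[window] |= stamp
            forbidden[window] |= ndimage.binary_dilation(stamp, iterations=2)
            blob_px = int(np.count_nonzero(blob_mask))

    signal_px = fil_px + int(np.count_nonzero(blob_mask))
    planted_fraction = (
        np.count_nonzero(blob_mask) / signal_px if signal_px else 0.0
    )

    tuj1 = np.full(shape, background, dtype=float)
    tuj1[filament_mask] += filament_amp
    tuj1[blob_mask] = background + blob_amp  # blobs never overlap filaments

    # NeuN: non-overlapping bright nuclei
    neun = np.full(shape, background, dtype=float)
    nucleus_mask = np.zeros(shape, dtype=bool)
    centers = []
    tries = 0
    while len(centers) < n_nuclei and tries < 2000:
        tries += 1
        rad_um = rng.uniform(*nucleus_radius_um)
        rad = int(round(rad_um / pixel_size))
        r = int(rng.integers(margin + rad, h - margin - rad))
        c = int(rng.integers(margin + rad, w - margin - rad))
        if any((r - rr) ** 2 + (c - cc) ** 2 < (rad + rr2 + 4) ** 2
               for rr, cc, rr2 in centers):
            continue
        yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        stamp = yy**2 + xx**2 <= rad**2
        neun[r - rad : r + rad + 1, c - rad : c + rad + 1][stamp] = (
            background + blob_amp
        )
        nucleus_mask[r - rad : r + rad + 1, c - rad : c + rad + 1] |= stamp
        centers.append((r, c, rad))
    if len(centers) < n_nuclei:
        raise ValueError("could not place the requested number of nuclei")

    if np.isfinite(snr):
        sigma = filament_amp / snr
        tuj1 = rng.poisson(tuj1).astype(float) + rng.normal(0, sigma, shape)
        neun = rng.poisson(neun).astype(float) + rng.normal(0, sigma, shape)
    tuj1 = np.clip(tuj1, 0, None)
    neun = np.clip(neun, 0, None)

    truth = GroundTruth(
        dataset="neurite_field",
        seed=seed,
        params={
            "n_filaments": n_filaments,
            "total_length_um": total_length_um,
            "blob_fraction_requested": blob_fraction,
            "blob_fraction_planted": planted_fraction,
            "planted_filament_length_um": planted_length_um,
            "n_nuclei": n_nuclei,
            "snr": snr,
            "pixel_size": pixel_size,
            "background": background,
            "filament_amp": filament_amp,
            "blob_amp": blob_amp,
            "nucleus_centers": [(int(r), int(c), int(a)) for r, c, a in centers],
        },
        arrays={
            "filament_mask": filament_mask,
            "blob_mask": blob_mask,
            "nucleus_mask": nucleus_mask,
        },
    )
    return (
        ChannelImage(tuj1, pixel_size, "TUJ1"),
        ChannelImage(neun, pixel_size, "NeuN"),
        truth,
    )


# ---------------------------------------------------------------------------
# DAPI / NPC STED fields
# ---------------------------------------------------------------------------


def gen_npc_nuclei(
    seed: int,
    n_nuclei: int = 1,
    radius_range_um: tuple[float, float] = (3.0, 4.0),
    foci_per_nucleus: int = 20,
    depth_distribution: tuple[tuple[float, float], ...] = ((0.2, 0.7), (0.9, 0.3)),
    pixel_size: float = 0.02,
    shape: tuple[int, int] = (512, 512),
    noise_sigma: float = 0.0,
    background: float = 5.0,
    nucleus_amp: float = 100.0,
    focus_amp: float = 150.0,
    focus_sigma_px: float = 2.0,
    min_focus_spacing_um: float = 0.3,
) -> tuple[ChannelImage, ChannelImage, GroundTruth]:
    """Generate a DAPI/NPC field with foci at exactly recorded depths.

    ``depth_distribution`` is a sequence of ``(depth_um, fraction)`` pairs;
    each focus is placed on a pixel whose Euclidean boundary depth (the
    same distance-transform convention the pipeline uses) is as close as
    possible to the requested depth, and the *achieved* depth is recorded,
    so planted fractions are recovered exactly in the noiseless case.
    """
    fracs = [f for _, f in depth_distribution]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("depth_distribution fractions must sum to 1")
    rng = _rng(seed, "npc")
    h, w = shape
    margin = 6
    max_rad_px = radius_range_um[1] / pixel_size
    if 2 * max_rad_px + 2 * margin > min(h, w) and n_nuclei > 0:
        raise ValueError("nuclei do not fit the field")

    from scipy import ndimage

    dapi = np.full(shape, background, dtype=float)
    npc = np.full(shape, background, dtype=float)
    labels = np.zeros(shape, dtype=int)
    centers = []
    tries = 0
    while len(centers) < n_nuclei and tries < 3000:
        tries += 1
        rad_um = rng.uniform(*radius_range_um)
        rad = int(round(rad_um / pixel_size))
        r = int(rng.integers(margin + rad, h - margin - rad))
        c = int(rng.integers(margin + rad, w - margin - rad))
        if any((r - rr) ** 2 + (c - cc) ** 2 < (rad + pr + 6) ** 2
               for rr, cc, pr in centers):
            continue
        yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        stamp = yy**2 + xx**2 <= rad**2
        win = np.s_[r - rad : r + rad + 1, c - rad : c + rad + 1]
        dapi[win][stamp] = background + nucleus_amp
        labels[win][stamp] = len(centers) + 1
        centers.append((r, c, rad))
    if len(centers) < n_nuclei:
        raise ValueError("could not place the requested number of nuclei")

    spacing_px = min_focus_spacing_um / pixel_size
    foci_rows, foci_cols, foci_depths, foci_nucleus = [], [], [], []
    for idx, (r, c, rad) in enumerate(centers, start=1):
        nuc = labels == idx
        dist_um = ndimage.distance_transform_edt(nuc) * pixel_size
        max_depth = dist_um.max()
        n_per = [int(round(foci_per_nucleus * f)) for _, f in depth_distribution]
        while sum(n_per) < foci_per_nucleus:
            n_per[0] += 1
        while sum(n_per) > foci_per_nucleus:
            n_per[np.argmax(n_per)] -= 1
        placed: list[tuple[int, int]] = []
        for (depth_um, _), n_want in zip(depth_distribution, n_per):
            if depth_um > max_depth:
                raise ValueError(
                    f"depth {depth_um} um exceeds nucleus depth {max_depth:.2f} um"
                )
            err = np.abs(dist_um - depth_um)
            err[~nuc] = np.inf
            order = np.argsort(err, axis=None)
            got = 0
            for flat in order:
                if got >= n_want or err.flat[flat] > 0.1:
                    break
                rr, cc = np.unravel_index(flat, shape)
                if any((rr - pr) ** 2 + (cc - pc) ** 2 < spacing_px**2
                       for pr, pc in placed):
                    continue
                placed.append((rr, cc))
                foci_rows.append(int(rr))
                foci_cols.append(int(cc))
                foci_depths.append(float(dist_um[rr, cc]))
                foci_nucleus.append(idx)
                got += 1
            if got < n_want:
                raise ValueError(
                    "could not place requested foci at depth "
                    f"{depth_um} um with spacing {min_focus_spacing_um} um"
                )

    # render foci as Gaussian spots peaking exactly at the chosen pixel
    if foci_rows:
        half = int(np.ceil(4 * focus_sigma_px))
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(yy**2 + xx**2) / (2 * focus_sigma_px**2))
        for rr, cc in zip(foci_rows, foci_cols):
            r0, r1 = max(0, rr - half), min(h, rr + half + 1)
            c0, c1 = max(0, cc - half), min(w, cc + half + 1)
            npc[r0:r1, c0:c1] += (
                focus_amp
                * kernel[
                    r0 - rr + half : r1 - rr + half, c0 - cc + half : c1 - cc + half
                ]
            )

    if noise_sigma > 0:
        dapi = np.clip(dapi + rng.normal(0, noise_sigma, shape), 0, None)
        npc = np.clip(npc + rng.normal(0, noise_sigma, shape), 0, None)

    truth = GroundTruth(
        dataset="npc_nuclei",
        seed=seed,
        params={
            "n_nuclei": n_nuclei,
            "foci_per_nucleus": foci_per_nucleus,
            "depth_distribution": [list(d) for d in depth_distribution],
            "pixel_size": pixel_size,
            "noise_sigma": noise_sigma,
            "nucleus_centers": [(int(r), int(c), int(a)) for r, c, a in centers],
            "foci": [
                {"row": r, "col": c, "depth_um": d, "nucleus": n}
                for r, c, d, n in zip(
                    foci_rows, foci_cols, foci_depths, foci_nucleus
                )
            ],
        },
        arrays={"labels": labels},
    )
    return (
        ChannelImage(dapi, pixel_size, "DAPI"),
        ChannelImage(npc, pixel_size, "Mab414"),
        truth,
    )


# ---------------------------------------------------------------------------
# PI uptake
# ---------------------------------------------------------------------------


def _logistic_fraction(t, baseline_frac, plateau_frac, rate_per_h, t50_h):
    return baseline_frac + (plateau_frac - baseline_frac) / (
        1.0 + np.exp(-rate_per_h * (np.asarray(t, float) - t50_h))
    )


def _logistic_fraction_integral(t, baseline_frac, plateau_frac, rate_per_h, t50_h):
    """Antiderivative of the logistic uptake fraction (softplus form)."""
    t = np.asarray(t, float)
    softplus = np.logaddexp(0.0, rate_per_h * (t - t50_h)) / rate_per_h
    return baseline_frac * t + (plateau_frac - baseline_frac) * softplus


def gen_pi_timeseries(
    seed: int,
    n_cells: int = 1000,
    baseline_frac: float = 0.05,
    plateau_frac: float = 0.6,
    rate_per_h: float = 0.06,
    t50_h: float = 84.0,
    timestamps_h=None,
    noiseless: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a PI-uptake count table from a logistic uptake curve.

    The expected PI-positive count is ``n_cells *
    logistic(t; baseline, plateau, rate, t50)``; observed counts are
    Poisson draws (or the rounded expectation when ``noiseless``). The
    final lysis frame counts all ``n_cells``. The ground truth records both
    the closed-form AUC of the noiseless normalized, baseline-subtracted
    curve over the sampled window and the trapezoid of the sampled counts.
    """
    if timestamps_h is None:
        timestamps_h = np.arange(0.0, 169.0, 12.0)
    t = np.asarray(timestamps_h, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    rng = _rng(seed, "pi")
    expected = n_cells * _logistic_fraction(
        t, baseline_frac, plateau_frac, rate_per_h, t50_h
    )
    if noiseless:
        counts = np.round(expected).astype(int)
    else:
        counts = rng.poisson(expected)

    # closed-form AUC of the noiseless normalized baseline-subtracted curve
    F = _logistic_fraction_integral(
        [t[0], t[-1]], baseline_frac, plateau_frac, rate_per_h, t50_h
    )
    f0 = _logistic_fraction(t[0], baseline_frac, plateau_frac, rate_per_h, t50_h)
    auc_closed = 100.0 * float(F[1] - F[0] - f0 * (t[-1] - t[0]))
    # trapezoid of the sampled (possibly rounded) normalized curve,
    # accumulated by an explicit interval loop (independent of numpy.trapezoid)
    norm = 100.0 * counts / n_cells
    norm = norm - norm[0]
    auc_sampled = 0.0
    for i in range(len(t) - 1):
        auc_sampled += 0.5 * (norm[i] + norm[i + 1]) * (t[i + 1] - t[i])

    table = pd.DataFrame(
        {"time_h": t, "pi_count": counts, "max_count": n_cells}
    )
    truth = GroundTruth(
        dataset="pi_timeseries",
        seed=seed,
        params={
            "n_cells": n_cells,
            "baseline_frac": baseline_frac,
            "plateau_frac": plateau_frac,
            "rate_per_h": rate_per_h,
            "t50_h": t50_h,
            "timestamps_h": list(map(float, t)),
            "noiseless": noiseless,
            "auc_closed_form_pct_h": auc_closed,
            "auc_sampled_pct_h": float(auc_sampled),
        },
    )
    return table, truth


def gen_pi_frame(
    seed: int,
    n_positive: int = 30,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    background: float = 2.0,
    rcu_amplitude: float = 1.0,
    cell_radius_um: float = 5.0,
    noise_sigma: float = 0.0,
) -> tuple[ChannelImage, GroundTruth]:
    """One PI frame with ``n_positive`` planted cells ``rcu_amplitude``
    above a flat background (amplitudes survive top-hat subtraction)."""
    rng = _rng(seed, "pi")
    h, w = shape
    rad = max(2, int(round(cell_radius_um / pixel_size)))
    img = np.full(shape, background, dtype=float)
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_positive and tries < 5000:
        tries += 1
        r = int(rng.integers(rad + 2, h - rad - 2))
        c = int(rng.integers(rad + 2, w - rad - 2))
        if any((r - rr) ** 2 + (c - cc) ** 2 < (4 * rad) ** 2 for rr, cc in centers):
            continue
        yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        stamp = yy**2 + xx**2 <= rad**2
        img[r - rad : r + rad + 1, c - rad : c + rad + 1][stamp] = (
            background + rcu_amplitude
        )
        centers.append((r, c))
    if len(centers) < n_positive:
        raise ValueError("could not place the requested number of cells")
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, shape), 0, None)
    truth = GroundTruth(
        dataset="pi_frame",
        seed=seed,
        params={
            "n_positive": n_positive,
            "rcu_amplitude": rcu_amplitude,
            "background": background,
            "pixel_size": pixel_size,
            "centers": [(int(r), int(c)) for r, c in centers],
        },
    )
    return ChannelImage(img, pixel_size, "PI"), truth


# ---------------------------------------------------------------------------
# DE tables with planted rescue structure
# ---------------------------------------------------------------------------


def gen_de_tables(
    seed: int,
    n_genes: int = 5000,
    n_affected: int = 200,
    rescue_fraction: float = 0.5,
    effect_size: float = 2.0,
    lfc_min: float = 0.5,
    padj_max: float = 0.05,
    null_padj_model: str = "uniform",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Three contrast tables with planted DE and rescue labels.

    Affected genes carry ``|log2fc| >= effect_size`` and tiny padj in
    control-vs-CUG. Each affected gene is independently rescued with
    probability ``rescue_fraction``; rescued genes satisfy at least one
    rescue clause by construction (a planted clause choice decides which),
    non-rescued genes satisfy neither. Unaffected genes draw small fold
    changes and null padj values. ``effect_size`` must exceed ``lfc_min``
    or labels would be ambiguous.
    """
    if n_affected > n_genes:
        raise ValueError("n_affected cannot exceed n_genes")
    if not 0.0 <= rescue_fraction <= 1.0:
        raise ValueError("rescue_fraction must lie in [0, 1]")
    if effect_size <= lfc_min:
        raise ValueError("effect_size must exceed the DE fold-change threshold")
    if null_padj_model != "uniform":
        raise ValueError("only the uniform null padj model is implemented")
    rng = _rng(seed, "de")
    genes = pd.Index([f"GENE{i:05d}" for i in range(n_genes)], name="gene_id")
    affected = rng.choice(n_genes, size=n_affected, replace=False)
    is_affected = np.zeros(n_genes, bool)
    is_affected[affected] = True
    rescued = np.zeros(n_genes, bool)
    rescued[affected] = rng.random(n_affected) < rescue_fraction
    # which clause makes a rescued gene pass (0 -> CUG-vs-CCG change,
    # 1 -> CCG indistinguishable from control)
    clause = np.where(rng.random(n_genes) < 0.5, 0, 1)

    def tiny_padj(n):
        return 10.0 ** rng.uniform(-8, -3, n)

    def null_padj(n):
        return rng.uniform(padj_max * 2, 1.0, n)

    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    small = rng.uniform(0, lfc_min * 0.5, n_genes) * sign

    # control vs CUG (the disease contrast)
    a_lfc = np.where(
        is_affected, sign * effect_size * rng.uniform(1.0, 1.5, n_genes), small
    )
    a_padj = np.where(is_affected, tiny_padj(n_genes), rng.uniform(0, 1, n_genes))

    # CUG vs CCG (the editing contrast)
    b_lfc = np.where(
        rescued & (clause == 0),
        -a_lfc * rng.uniform(0.8, 1.2, n_genes),
        small,
    )
    b_padj = np.where(rescued & (clause == 0), tiny_padj(n_genes), null_padj(n_genes))

    # control vs CCG (residual-disease contrast)
    c_lfc = np.where(rescued, small, a_lfc)
    c_padj = np.where(
        rescued & (clause == 1),
        null_padj(n_genes),
        np.where(is_affected, tiny_padj(n_genes), rng.uniform(0, 1, n_genes)),
    )

    def table(lfc, padj):
        return pd.DataFrame({"log2fc": lfc, "padj": padj}, index=genes)

    truth = GroundTruth(
        dataset="de_tables",
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_affected": n_affected,
            "rescue_fraction": rescue_fraction,
            "effect_size": effect_size,
            "n_rescued_planted": int(rescued.sum()),
            "affected_genes": [genes[i] for i in sorted(affected)],
            "rescued_genes": list(genes[rescued]),
        },
    )
    return table(a_lfc, a_padj), table(b_lfc, b_padj), table(c_lfc, c_padj), truth


def gen_expression_matrix(
    seed: int,
    n_genes: int = 2000,
    n_samples: int = 6,
    expressed_fraction: float = 0.6,
    expressed_log10_tpm: tuple[float, float] = (2.0, 0.5),
    silent_log10_tpm: tuple[float, float] = (-2.0, 0.5),
    mean_length_kb: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Counts + gene lengths whose TPM distribution is a two-mode mixture.

    Used to exercise TPM normalization and the bimodal expressed-gene
    cutoff; the planted component label of each gene is recorded.
    """
    rng = _rng(seed, "expression")
    genes = pd.Index([f"GENE{i:05d}" for i in range(n_genes)], name="gene_id")
    expressed = rng.random(n_genes) < expressed_fraction
    mu = np.where(expressed, expressed_log10_tpm[0], silent_log10_tpm[0])
    sd = np.where(expressed, expressed_log10_tpm[1], silent_log10_tpm[1])
    base_tpm = 10.0 ** rng.normal(mu, sd)
    lengths = pd.Series(
        rng.gamma(4.0, mean_length_kb / 4.0, n_genes) + 0.2, index=genes,
        name="length_kb",
    )
    # counts proportional to tpm * length per sample, Poisson-sampled
    depth = 3e6
    lam = base_tpm * lengths.to_numpy() / (base_tpm * lengths.to_numpy()).sum()
    counts = pd.DataFrame(
        rng.poisson(np.outer(lam, np.full(n_samples, depth))),
        index=genes,
        columns=[f"S{j}" for j in range(n_samples)],
    )
    truth = GroundTruth(
        dataset="expression_matrix",
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_samples": n_samples,
            "expressed_fraction": expressed_fraction,
            "n_expressed_planted": int(expressed.sum()),
            "expressed_genes": list(genes[expressed]),
        },
    )
    return counts, lengths, truth


# ---------------------------------------------------------------------------
# BFP+ survival and STING fields
# ---------------------------------------------------------------------------


def gen_survival_fields(
    seed: int,
    counts_by_day: dict[int, int] | None = None,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.65,
    nucleus_radius_um: float = 3.0,
    background: float = 5.0,
    amp: float = 100.0,
    noise_sigma: float = 0.0,
) -> tuple[dict[int, ChannelImage], GroundTruth]:
    """Per-day fields with exactly the requested number of BFP+ nuclei."""
    if counts_by_day is None:
        counts_by_day = {4: 100, 7: 80, 11: 50}
    if any(c < 0 for c in counts_by_day.values()):
        raise ValueError("counts must be non-negative")
    rng = _rng(seed, "survival")
    h, w = shape
    rad = max(2, int(round(nucleus_radius_um / pixel_size)))
    capacity = (h - 4 * rad) * (w - 4 * rad) / (4 * rad) ** 2 / 4
    if max(counts_by_day.values(), default=0) > capacity:
        raise ValueError("requested count exceeds packing capacity")
    fields: dict[int, ChannelImage] = {}
    centers_by_day: dict[int, list[tuple[int, int]]] = {}
    for day in sorted(counts_by_day):
        n = counts_by_day[day]
        img = np.full(shape, background, dtype=float)
        centers: list[tuple[int, int]] = []
        tries = 0
        while len(centers) < n and tries < 20000:
            tries += 1
            r = int(rng.integers(rad + 2, h - rad - 2))
            c = int(rng.integers(rad + 2, w - rad - 2))
            if any((r - rr) ** 2 + (c - cc) ** 2 < (2 * rad + 3) ** 2
                   for rr, cc in centers):
                continue
            yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
            stamp = yy**2 + xx**2 <= rad**2
            img[r - rad : r + rad + 1, c - rad : c + rad + 1][stamp] = (
                background + amp
            )
            centers.append((r, c))
        if len(centers) < n:
            raise ValueError("could not place the requested number of nuclei")
        if noise_sigma > 0:
            img = np.clip(img + rng.normal(0, noise_sigma, shape), 0, None)
        fields[day] = ChannelImage(img, pixel_size, "BFP")
        centers_by_day[day] = centers
    truth = GroundTruth(
        dataset="survival_fields",
        seed=seed,
        params={
            "counts_by_day": {int(d): int(c) for d, c in counts_by_day.items()},
            "pixel_size": pixel_size,
            "nucleus_radius_um": nucleus_radius_um,
            "centers_by_day": {
                int(d): [(int(r), int(c)) for r, c in v]
                for d, v in centers_by_day.items()
            },
        },
    )
    return fields, truth


def gen_sting_field(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.3,
    sting_level: float = 50.0,
    background: float = 5.0,
    mask_fraction: float = 0.3,
    noise_sigma: float = 0.0,
) -> tuple[ChannelImage, BinaryMask, GroundTruth]:
    """A STING image with known mean level inside a planted TUJ1 mask."""
    rng = _rng(seed, "sting")
    h, w = shape
    mask = np.zeros(shape, bool)
    target = mask_fraction * h * w
    tries = 0
    while mask.sum() < target and tries < 500:
        tries += 1
        rad = int(rng.integers(8, 20))
        r = int(rng.integers(rad, h - rad))
        c = int(rng.integers(rad, w - rad))
        yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
        mask[r - rad : r + rad + 1, c - rad : c + rad + 1] |= (
            yy**2 + xx**2 <= rad**2
        )
    img = np.full(shape, background, dtype=float)
    img[mask] = sting_level
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0, noise_sigma, shape), 0, None)
    truth = GroundTruth(
        dataset="sting_field",
        seed=seed,
        params={
            "sting_level": sting_level,
            "background": background,
            "mask_pixels": int(mask.sum()),
            "pixel_size": pixel_size,
        },
    )
    return (
        ChannelImage(img, pixel_size, "STING"),
        BinaryMask(mask, pixel_size),
        truth,
    )
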