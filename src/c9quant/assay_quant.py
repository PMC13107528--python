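"""Scalar viability / survival / intensity / behavioral assays.

Covers:

* propidium-iodide (PI) uptake time series: per-frame PI-positive counting
  after top-hat background subtraction, normalization to the post-lysis
  maximal count, baseline subtraction, and trapezoidal AUC over 168 h;
* BFP-positive motor-neuron survival counts normalized to day 4;
* STING intensity within the TUJ1-positive mask, fold change vs control;
* the inverted-grid holding impulse (body weight x g-force x hang time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging_core import BinaryMask, ChannelImage, threshold_global, label_regions, tophat_subtract

__all__ = [
    "PISeries",
    "SurvivalSeries",
    "StingResult",
    "count_pi_positive",
    "normalize_to_lysis_max",
    "baseline_subtract",
    "auc",
    "count_bfp_nuclei",
    "survival_normalize",
    "sting_intensity",
    "normalize_to_control",
    "holding_impulse",
    "GRAVITY_N_PER_G",
]

#: gravitational force per gram of body weight, N/g
GRAVITY_N_PER_G = 0.00980665


def count_pi_positive(
    frame: ChannelImage,
    background: float | None = None,
    threshold_rcu: float = 0.5,
    tophat_radius_um: float = 10.0,
) -> int:
    """Count PI-positive cells in one frame.

    The frame undergoes top-hat background subtraction with a disc of the
    given physical radius; objects are connected components whose intensity
    is at least ``threshold_rcu`` red calibrated units above background.
    ``background`` defaults to the per-frame median after top-hat (the
    residual background level).
    """
    flat = tophat_subtract(frame, tophat_radius_um)
    if background is None:
        background = float(np.median(flat.pixels))
    positive = flat.pixels >= background + threshold_rcu
    if not positive.any():
        return 0
    return label_regions(BinaryMask(positive, frame.pixel_size)).n_regions


def normalize_to_lysis_max(counts, max_count: int) -> np.ndarray:
    """Express counts as percentages of the post-lysis maximal count."""
    counts = np.asarray(counts, dtype=float)
    if max_count <= 0:
        raise ValueError("lysis maximal count must be > 0")
    if np.any(counts > max_count):
        warnings.warn(
            "count exceeds the lysis maximum; values above 100% retained",
            UserWarning,
            stacklevel=2,
        )
    return 100.0 * counts / max_count


def baseline_subtract(series, clip_negative: bool = False) -> np.ndarray:
    """Subtract the first (baseline) value from every point in the series.

    Negative values are retained by default (literal subtraction); set
    ``clip_negative`` to floor them at zero.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series is empty")
    out = series - series[0]
    if np.any(out < 0):
        if clip_negative:
            out = np.clip(out, 0.0, None)
        else:
            warnings.warn(
                "baseline subtraction produced negative values (retained)",
                UserWarning,
                stacklevel=2,
            )
    return out


@dataclass
class PISeries:
    """A per-well PI-uptake time series.

    ``timestamps_h`` must be strictly increasing with the first point the
    pre-treatment baseline; ``pi_counts`` are the per-timestamp PI-positive
    counts and ``max_count`` the count from the post-lysis (Triton) frame.
    """

    timestamps_h: np.ndarray
    pi_counts: np.ndarray
    max_count: int
    well: str = ""
    clip_negative: bool = False
    normalized_pct: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.timestamps_h = np.asarray(self.timestamps_h, dtype=float)
        self.pi_counts = np.asarray(self.pi_counts, dtype=float)
        if self.timestamps_h.ndim != 1 or self.timestamps_h.size < 1:
            raise ValueError("timestamps must be a non-empty 1D sequence")
        if np.any(np.diff(self.timestamps_h) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pi_counts.shape != self.timestamps_h.shape:
            raise ValueError("counts and timestamps lengths differ")
        if np.any(self.pi_counts < 0):
            raise ValueError("PI counts must be non-negative")
        self.normalized_pct = baseline_subtract(
            normalize_to_lysis_max(self.pi_counts, self.max_count),
            clip_negative=self.clip_negative,
        )

    def auc(self, t_end_h: float = 168.0) -> float:
        return auc(self, t_end_h)


def auc(series: PISeries, t_end_h: float = 168.0) -> float:
    """Trapezoidal AUC (% * h) of the normalized, baseline-subtracted curve.

    Integration runs from the baseline timestamp to the last available
    timestamp <= ``t_end_h``. Actual recorded timestamps are used; at least
    two points are required.
    """
    t = series.timestamps_h
    use = t <= t_end_h
    if np.count_nonzero(use) < 2:
        raise ValueError("need at least two timestamps within [t0, t_end]")
    return float(np.trapezoid(series.normalized_pct[use], t[use]))


def count_bfp_nuclei(
    frame: ChannelImage, min_area_um2: float = 10.0, method="otsu"
) -> int:
    """Count BFP-positive nuclei: bright regions of area >= min_area."""
    res = threshold_global(frame, method)
    if res.degenerate:
        return 0
    regs = label_regions(res.mask)
    return sum(1 for r in regs.regions if r.area_um2 >= min_area_um2)


@dataclass
class SurvivalSeries:
    """BFP+ counts by day with fractions relative to the baseline day."""

    counts_by_day: dict[int, int]
    baseline_day: int
    fractions: dict[int, float]


def survival_normalize(
    counts_by_day: dict[int, int], baseline_day: int = 4
) -> SurvivalSeries:
    """Normalize per-day survival counts to the baseline day (fraction 1.0)."""
    if baseline_day not in counts_by_day:
        raise ValueError(f"baseline day {baseline_day} missing from counts")
    base = counts_by_day[baseline_day]
    if base <= 0:
        raise ValueError("baseline count must be > 0")
    if any(c < 0 for c in counts_by_day.values()):
        raise ValueError("counts must be non-negative")
    fractions = {d: c / base for d, c in sorted(counts_by_day.items())}
    return SurvivalSeries(dict(sorted(counts_by_day.items())), baseline_day, fractions)


@dataclass
class StingResult:
    well: str
    mean_intensity: float
    fold_change: float


def sting_intensity(sting: ChannelImage, tuj1_mask: BinaryMask) -> float:
    """Mean STING intensity over the TUJ1-positive pixels."""
    if sting.shape != tuj1_mask.shape:
        raise ValueError("STING image and TUJ1 mask shapes differ")
    if not tuj1_mask.pixels.any():
        raise ValueError("TUJ1 mask is empty")
    return float(sting.pixels[tuj1_mask.pixels].mean())


def normalize_to_control(values, control_mean: float) -> np.ndarray:
    """Fold change of each well value relative to the control-line mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(values, dtype=float) / control_mean


def holding_impulse(body_weight_g: float, hang_time_s: float) -> float:
    """Inverted-grid holding impulse: weight (g) x 0.00980665 (N/g) x time (s)."""
    if body_weight_g < 0 or hang_time_s < 0:
        raise ValueError("weight and time must be non-negative")
    return body_weight_g * GRAVITY_N_PER_G * hang_time_s
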