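"""YAML run configuration with schema validation.

Every assay has a documented set of allowed keys with defaults; unknown
keys are rejected by name and all violations are reported together.
Physical quantities carry their unit in the key suffix (``_um``, ``_h``,
``_g``, ``_s``) to prevent unit confusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "SCHEMAS"]


class ConfigError(ValueError):
    """Configuration failed validation; message lists every violation."""


def _positive(v) -> bool:
    return v > 0


def _non_negative(v) -> bool:
    return v >= 0


def _fraction(v) -> bool:
    return 0 <= v <= 1


# key -> (type, default, constraint or None, description)
_COMMON_IMAGING = {
    "pixel_size_um": ((int, float), None, _positive, "pixel edge length"),
}

SCHEMAS: dict[str, dict] = {
    "mtquant": {
        **_COMMON_IMAGING,
        "low_method": (str, "mad:5", None, "low (all-structure) threshold"),
        "high_method": (str, "otsu_foreground", None, "high (aggregate) threshold"),
        "min_circ": ((int, float), 0.5, _fraction, "circularity cutoff"),
        "smooth_sigma_px": ((int, float), 0.0, _non_negative, "pre-smoothing sigma"),
        "depoly_min_area_um2": ((int, float), 0.1, _positive, "aggregate size filter"),
        "neun_min_area_um2": ((int, float), 10.0, _positive, "NeuN size filter"),
        "close_radius_px": (int, 1, _non_negative, "gap closing before skeleton"),
    },
    "npcquant": {
        **_COMMON_IMAGING,
        "inner_um": ((int, float), 0.7, _non_negative, "annulus inner depth"),
        "outer_um": ((int, float), 1.2, _positive, "annulus outer depth"),
        "median_radius_um": ((int, float), 0.2, _positive, "DAPI median filter"),
        "min_area_um2": ((int, float), 5.0, _positive, "nucleus size filter"),
        "min_distance_um": ((int, float), 0.2, _non_negative, "foci separation"),
        "min_prominence": ((int, float), 10.0, _non_negative, "foci prominence"),
    },
    "piuptake": {
        "threshold_rcu": ((int, float), 0.5, _positive, "positivity cut above bg"),
        "tophat_radius_um": ((int, float), 10.0, _positive, "top-hat disc radius"),
        "t_end_h": ((int, float), 168.0, _positive, "AUC upper limit"),
        "clip_negative": (bool, False, None, "clip baseline-subtracted values"),
        "pixel_size_um": ((int, float), 0.65, _positive, "pixel edge length"),
    },
    "survival": {
        "baseline_day": (int, 4, _positive, "normalization day"),
        "min_area_um2": ((int, float), 10.0, _positive, "BFP nucleus size filter"),
        "pixel_size_um": ((int, float), 0.65, _positive, "pixel edge length"),
    },
    "sting": {
        **_COMMON_IMAGING,
        "control_group": (str, "control", None, "group defining fold = 1"),
        "tuj1_method": (str, "otsu", None, "TUJ1 mask threshold"),
    },
    "impulse": {},
    "rescue": {
        "lfc_min": ((int, float), 0.5, _positive, "log2fc threshold"),
        "padj_max": ((int, float), 0.05, _positive, "adjusted-p threshold"),
        "require_opposite_direction": (bool, False, None, "clause-1 sign rule"),
    },
    "simulate": {
        "dataset": (str, None, None, "which generator to run"),
        "seed": (int, 0, None, "top-level seed"),
        "params": (dict, {}, None, "generator keyword overrides"),
    },
}

_CROSS_CHECKS = {
    "npcquant": [
        (
            lambda c: c["inner_um"] < c["outer_um"],
            "inner_um must be smaller than outer_um",
        )
    ],
}


@dataclass
class RunConfig:
    """A validated, fully defaulted assay configuration."""

    assay: str
    options: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.options[key]


def validate_options(assay: str, options: dict) -> RunConfig:
    """Apply defaults and schema-check an option mapping for one assay."""
    if assay not in SCHEMAS:
        raise ConfigError(f"unknown assay {assay!r}; valid: {sorted(SCHEMAS)}")
    schema = SCHEMAS[assay]
    errors = []
    unknown = sorted(set(options) - set(schema))
    for key in unknown:
        errors.append(f"unknown key {key!r} for assay {assay!r}")
    merged = {}
    for key, (typ, default, constraint, desc) in schema.items():
        if key in options:
            value = options[key]
        else:
            value = default
            if value is None:
                errors.append(f"missing required key {key!r} ({desc})")
                continue
        if typ is int and isinstance(value, bool):
            errors.append(f"{key!r}: expected int, got bool")
            continue
        if not isinstance(value, typ):
            tname = typ.__name__ if isinstance(typ, type) else "number"
            errors.append(f"{key!r}: expected {tname}, got {type(value).__name__}")
            continue
        if constraint is not None and not constraint(value):
            errors.append(f"{key!r}: value {value!r} violates its constraint ({desc})")
            continue
        merged[key] = value
    if not errors:
        for check, msg in _CROSS_CHECKS.get(assay, []):
            if not check(merged):
                errors.append(msg)
    if errors:
        raise ConfigError(
            f"invalid configuration for {assay!r}:\n  - " + "\n  - ".join(errors)
        )
    return RunConfig(assay=assay, options=merged)


def validate_config(path: str | Path, assay: str | None = None) -> RunConfig:
    """Load a YAML config file and validate it for its assay.

    The file either nests options under the assay name or carries an
    ``assay`` key next to flat options; ``assay`` overrides the file.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    if assay is None:
        assay = raw.pop("assay", None)
        if assay is None:
            raise ConfigError("config must name an assay (key 'assay')")
    elif isinstance(raw.get(assay), dict):
        raw = raw[assay]
    else:
        raw.pop("assay", None)
    return validate_options(assay, raw)
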