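"""Thresholds, alert weights and machine geometry defaults.

Every number a check depends on lives here so that a clinic can re-tune the
tool from a single config file without touching code.  The defaults are the
values the checks were designed around: a 30 % volume-difference threshold,
a 10-percentage-point target-chain spread, 1 cm² / 5 MU segment limits, and
the alert weights that drive the traffic light.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class MLCGeometryConfig:
    """Double-stack MLC description.

    ``n_pairs`` leaf pairs per stack, ``leaf_width`` mm at isocenter, and the
    transverse offset of stack B relative to stack A (half a leaf width for
    the half-leaf-shifted double stack).
    """

    n_pairs: int = 34
    leaf_width: float = 8.3
    stack_offset: float = 4.15

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.leaf_width <= 0:
            raise ValueError("leaf_width must be positive")
        if not (0 <= self.stack_offset < self.leaf_width):
            raise ValueError("stack_offset must lie in [0, leaf_width)")


#: Fixed (non-formula) alert weights.  MU_DIFF and SMALL_SEGMENTS carry
#: arithmetic weights computed at alert time; see :mod:`apart.alerting`.
DEFAULT_WEIGHTS: dict[str, float] = {
    "WRONG_PATIENT": 10.0,
    "WRONG_PLAN": 10.0,
    "STRUCTURE_DELETED": 5.0,
    "VOLUME_DIFF": 3.0,
    "TARGET_INCONSISTENT": 2.0,
    "LOW_MU_SEGMENTS": 1.0,
    "STRUCTURE_GAP": 5.0,
}

#: Regexes matched case-insensitively against structure names; the capture
#: group is the chain suffix, so GTV2/CTV2/PTV2 group into one chain.
DEFAULT_TARGET_PATTERNS: dict[str, str] = {
    "gtv": r"^gtv(.*)$",
    "ctv": r"^ctv(.*)$",
    "ptv": r"^ptv(.*)$",
}


@dataclass(frozen=True)
class CheckConfig:
    # contour checks
    volume_diff_percent: float = 30.0      # |ΔV%| above this raises VOLUME_DIFF
    gap_factor: float = 1.5                # z-step > factor × nominal spacing = gap
    default_slice_spacing_mm: float = 3.0  # fallback when a structure has one slice
    density_plausible: tuple[float, float] = (0.0, 3.0)  # rel. electron density band

    # target-chain checks
    target_spread_points: float = 10.0     # max Δ%-spread between chain members
    target_zero_tol_points: float = 0.5    # |Δ%| below this counts as "no change"
    target_patterns: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_PATTERNS)
    )

    # MLC complexity
    small_area_cm2: float = 1.0
    small_area_frac_percent: float = 10.0
    low_mu: float = 5.0
    low_mu_frac_percent: float = 5.0
    mu_diff_percent: float = 10.0

    # alerting
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    orange_max: float = 9.0                # total > orange_max -> red

    # machine
    mlc: MLCGeometryConfig = field(default_factory=MLCGeometryConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["density_plausible"] = list(self.density_plausible)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CheckConfig":
        d = dict(d)
        if "mlc" in d and isinstance(d["mlc"], dict):
            d["mlc"] = MLCGeometryConfig(**d["mlc"])
        if "density_plausible" in d:
            d["density_plausible"] = tuple(d["density_plausible"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "CheckConfig":
        """Load overrides from a JSON or YAML file (keys as in to_dict)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
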