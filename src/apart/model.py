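"""Domain model shared by all checks.

Everything is in the DICOM patient coordinate system, millimetres.  A
structure is a stack of closed planar polygons (one or more per slice); a
plan is a list of beams, each a list of step-and-shoot MLC segments with
their monitor units and the leaf openings of both stacks of the double-stack
MLC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .config import MLCGeometryConfig

MLCGeometry = MLCGeometryConfig  # machine description doubles as config entry


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValueError):
    """File is not the expected DICOM object."""


def _normalize_ws(s: str) -> str:
    return " ".join(str(s).split())


@dataclass(frozen=True)
class PlanIdentity:
    """Patient and plan identity used for the wrong-patient/wrong-plan check."""

    patient_name: str
    patient_id: str
    plan_name: str

    def __post_init__(self) -> None:
        for f in ("patient_name", "patient_id", "plan_name"):
            if not _normalize_ws(getattr(self, f)):
                raise ValidationError(f"identity field {f!r} is empty")

    def normalized(self) -> "PlanIdentity":
        return PlanIdentity(
            _normalize_ws(self.patient_name),
            _normalize_ws(self.patient_id),
            _normalize_ws(self.plan_name),
        )


@dataclass
class Contour:
    """One closed planar polygon at axial position ``z`` (mm).

    Vertices are (x, y) pairs; the polygon is implicitly closed and must be
    simple (non-self-intersecting).
    """

    z: float
    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError("contour vertices must be an (n, 2) array")
        if v.shape[0] < 3:
            raise ValidationError("contour needs at least 3 vertices")
        self.vertices = v
        if not self.polygon().is_valid:
            raise ValidationError(f"self-intersecting contour at z={self.z}")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def area(self) -> float:
        """Unsigned shoelace area in mm²."""
        return self.polygon().area


@dataclass
class Structure:
    """A named ROI: contours sorted by z plus an optional density override."""

    name: str
    roi_number: int
    contours: list[Contour]
    density_override: Optional[tuple[float, int]] = None  # (rel. e-density, priority)

    def __post_init__(self) -> None:
        self.contours = sorted(self.contours, key=lambda c: c.z)

    @property
    def z_positions(self) -> list[float]:
        """Distinct contoured slice positions, ascending (1e-6 mm dedup)."""
        out: list[float] = []
        for c in self.contours:
            if not out or abs(c.z - out[-1]) > 1e-6:
                out.append(c.z)
        return out

    def contours_at(self, z: float, tol: float = 1e-6) -> list[Contour]:
        return [c for c in self.contours if abs(c.z - z) <= tol]


@dataclass
class StructureSet:
    identity: PlanIdentity
    structures: list[Structure]
    slice_spacing_hint: Optional[float] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.structures:
            key = s.name.strip().lower()
            if key in seen:
                raise ValidationError(f"duplicate structure name {s.name!r}")
            seen.add(key)

    def get(self, name: str) -> Optional[Structure]:
        key = name.strip().lower()
        for s in self.structures:
            if s.name.strip().lower() == key:
                return s
        return None


LeafPairs = Sequence[tuple[float, float]]  # (left, right) mm per leaf pair


@dataclass
class MLCSegment:
    """One static aperture of the double-stack MLC with its monitor units."""

    mu: float
    stack_a: list[tuple[float, float]]
    stack_b: list[tuple[float, float]]
    geometry: MLCGeometry = field(default_factory=MLCGeometry)

    def __post_init__(self) -> None:
        if self.mu < 0 or not math.isfinite(self.mu):
            raise ValidationError("segment MU must be finite and >= 0")
        for label, stack in (("A", self.stack_a), ("B", self.stack_b)):
            if len(stack) != self.geometry.n_pairs:
                raise ValidationError(
                    f"stack {label} has {len(stack)} pairs, "
                    f"geometry defines {self.geometry.n_pairs}"
                )
            for i, (left, right) in enumerate(stack):
                if left > right + 1e-9:
                    raise ValidationError(
                        f"stack {label} pair {i}: left {left} > right {right}"
                    )


@dataclass
class Beam:
    beam_id: str
    segments: list[MLCSegment]

    @property
    def mu(self) -> float:
        return float(sum(s.mu for s in self.segments))


@dataclass
class Plan:
    identity: PlanIdentity
    beams: list[Beam]
    total_mu: float

    def __post_init__(self) -> None:
        seg_sum = sum(b.mu for b in self.beams)
        if seg_sum > 0 and abs(seg_sum - self.total_mu) > 1e-6 * max(seg_sum, 1.0):
            raise ValidationError(
                f"plan total MU {self.total_mu} != sum of segment MUs {seg_sum}"
            )

    @property
    def n_segments(self) -> int:
        return sum(len(b.segments) for b in self.beams)

    def all_segments(self) -> list[MLCSegment]:
        return [s for b in self.beams for s in b.segments]
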