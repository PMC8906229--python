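"""MLC aperture geometry and modulation-complexity metrics.

The double-stack MLC (two leaf banks offset by half a leaf width) is
converted into an artificial single-stack aperture: the field is partitioned
into rows at half-leaf pitch, each row is covered by exactly one leaf pair
of each stack, and the row opening is the intersection of the two pairs'
open intervals.  On these apertures the module computes segment areas,
connected subsegments, the per-beam union area, the effective MU

    effMU_i = Σ_j MU_ij · AA_ij / U(AA_ij)

(MU-weighted mean segment area over the union area of beam i — the MU an
open field of the same union would need for the same modulation-weighted
fluence), and the small-segment / low-MU statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alerting import Alert, AlertCode, make_alert
from .config import CheckConfig
from .model import Beam, MLCSegment, Plan, ValidationError


@dataclass(frozen=True)
class ApertureRow:
    y_low: float
    y_high: float
    x_left: float
    x_right: float

    @property
    def open(self) -> bool:
        return self.x_right > self.x_left

    @property
    def width(self) -> float:
        return max(0.0, self.x_right - self.x_left)

    @property
    def height(self) -> float:
        return self.y_high - self.y_low


@dataclass
class Aperture:
    """Single-stack equivalent opening of one double-stack segment."""

    rows: list[ApertureRow]
    mu: float = 0.0


def _row_edges(seg: MLCSegment) -> list[float]:
    """y-boundaries of the half-leaf-pitch rows covered by both stacks."""
    g = seg.geometry
    a0 = -g.n_pairs * g.leaf_width / 2.0
    edges_a = [a0 + k * g.leaf_width for k in range(g.n_pairs + 1)]
    edges_b = [e + g.stack_offset for e in edges_a]
    merged = sorted(set(round(e, 9) for e in edges_a + edges_b))
    # keep only rows covered by both stacks (edge half-rows are blocked by
    # the other bank's carriage)
    lo = max(edges_a[0], edges_b[0])
    hi = min(edges_a[-1], edges_b[-1])
    return [e for e in merged if lo - 1e-9 <= e <= hi + 1e-9]


def _pair_index(y: float, first_edge: float, leaf_width: float, n: int) -> Optional[int]:
    idx = int(math.floor((y - first_edge) / leaf_width))
    return idx if 0 <= idx < n else None


def combine_stacks(seg: MLCSegment) -> Aperture:
    """Minimum united opening of both stacks, per half-leaf-pitch row."""
    g = seg.geometry
    a0 = -g.n_pairs * g.leaf_width / 2.0
    b0 = a0 + g.stack_offset
    edges = _row_edges(seg)
    rows: list[ApertureRow] = []
    for y_low, y_high in zip(edges, edges[1:]):
        if y_high - y_low < 1e-9:
            continue
        mid = 0.5 * (y_low + y_high)
        ia = _pair_index(mid, a0, g.leaf_width, g.n_pairs)
        ib = _pair_index(mid, b0, g.leaf_width, g.n_pairs)
        if ia is None or ib is None:
            left, right = 0.0, 0.0
        else:
            la, ra = seg.stack_a[ia]
            lb, rb = seg.stack_b[ib]
            left, right = max(la, lb), min(ra, rb)
        if right <= left:
            left = right = 0.0
        rows.append(ApertureRow(y_low, y_high, left, right))
    return Aperture(rows=rows, mu=seg.mu)


def aperture_area(aperture: Aperture) -> float:
    """Open area in cm²."""
    mm2 = sum(r.width * r.height for r in aperture.rows if r.open)
    return mm2 / 100.0


def count_subsegments(aperture: Aperture) -> int:
    """Connected open regions: adjacent rows connect iff their x-intervals
    overlap with positive length (union-find over rows)."""
    rows = aperture.rows
    parent = list(range(len(rows)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(rows) - 1):
        a, b = rows[i], rows[i + 1]
        if a.open and b.open and min(a.x_right, b.x_right) > max(a.x_left, b.x_left):
            union(i, i + 1)
    return len({find(i) for i, r in enumerate(rows) if r.open})


def _merge_intervals(
    intervals: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def union_area(apertures: Sequence[Aperture]) -> float:
    """Area (cm²) of the union of the apertures, row by row."""
    if not apertures:
        raise ValidationError("union_area needs at least one aperture")
    n_rows = len(apertures[0].rows)
    if any(len(a.rows) != n_rows for a in apertures):
        raise ValidationError("apertures have mismatching row partitions")
    mm2 = 0.0
    for i in range(n_rows):
        height = apertures[0].rows[i].height
        intervals = [
            (a.rows[i].x_left, a.rows[i].x_right)
            for a in apertures
            if a.rows[i].open
        ]
        mm2 += height * sum(hi - lo for lo, hi in _merge_intervals(intervals))
    return mm2 / 100.0


def effective_mu(beam: Beam) -> Optional[float]:
    """effMU of one beam; None (undefined) when every segment is closed."""
    apertures = [combine_stacks(s) for s in beam.segments]
    u = union_area(apertures)
    if u <= 0:
        return None
    weighted = sum(a.mu * aperture_area(a) for a in apertures)
    return weighted / u


@dataclass
class BeamComplexity:
    beam_id: str
    eff_mu: Optional[float]   # MU; None if the beam never opens
    union_area: float         # cm²
    mu: float

    def to_dict(self) -> dict:
        return {
            "beam_id": self.beam_id,
            "eff_mu": self.eff_mu,
            "union_area_cm2": self.union_area,
            "mu": self.mu,
        }


@dataclass
class ComplexityReport:
    """Per-plan modulation summary."""

    beams: list[BeamComplexity]
    n_segments: int
    n_subsegments: int
    min_area_segment: Optional[tuple[float, float]]  # (cm², its MU)
    min_mu_segment: Optional[tuple[float, float]]    # (MU, its cm²)
    frac_small_area: float  # % of segments below the area threshold
    frac_low_mu: float      # % of segments below the MU threshold
    mu_total: float

    def to_dict(self) -> dict:
        return {
            "beams": [b.to_dict() for b in self.beams],
            "n_segments": self.n_segments,
            "n_subsegments": self.n_subsegments,
            "min_area_segment": list(self.min_area_segment)
            if self.min_area_segment
            else None,
            "min_mu_segment": list(self.min_mu_segment)
            if self.min_mu_segment
            else None,
            "frac_small_area_percent": self.frac_small_area,
            "frac_low_mu_percent": self.frac_low_mu,
            "mu_total": self.mu_total,
        }


def analyze_plan(plan: Plan, config: CheckConfig | None = None) -> ComplexityReport:
    """Compute the full complexity summary of one plan (no alerts)."""
    config = config or CheckConfig()
    beams: list[BeamComplexity] = []
    areas_mus: list[tuple[float, float]] = []  # (area cm², mu) per segment
    n_sub = 0
    for beam in plan.beams:
        apertures = [combine_stacks(s) for s in beam.segments]
        for a in apertures:
            areas_mus.append((aperture_area(a), a.mu))
            n_sub += count_subsegments(a)
        beams.append(
            BeamComplexity(
                beam_id=beam.beam_id,
                eff_mu=effective_mu(beam),
                union_area=union_area(apertures) if apertures else 0.0,
                mu=beam.mu,
            )
        )
    n = len(areas_mus)
    if n == 0:
        raise ValidationError("plan has no segments")
    frac_small = 100.0 * sum(1 for a, _ in areas_mus if a < config.small_area_cm2) / n
    frac_low = 100.0 * sum(1 for _, m in areas_mus if m < config.low_mu) / n
    min_area = min(areas_mus, key=lambda t: t[0])
    min_mu = min(areas_mus, key=lambda t: t[1])
    return ComplexityReport(
        beams=beams,
        n_segments=n,
        n_subsegments=n_sub,
        min_area_segment=(min_area[0], min_area[1]),
        min_mu_segment=(min_mu[1], min_mu[0]),
        frac_small_area=frac_small,
        frac_low_mu=frac_low,
        mu_total=plan.total_mu,
    )


def segment_stats(
    plan: Plan, config: CheckConfig | None = None
) -> tuple[ComplexityReport, list[Alert]]:
    """Complexity report plus small-segment / low-MU alerts.

    SMALL_SEGMENTS carries the formula weight (small fraction % − 10) when
    more than 10 % of segments are below 1 cm²; LOW_MU_SEGMENTS weight 1
    when more than 5 % deliver less than 5 MU.
    """
    config = config or CheckConfig()
    report = analyze_plan(plan, config)
    alerts: list[Alert] = []
    if report.frac_small_area > config.small_area_frac_percent:
        alerts.append(
            make_alert(
                AlertCode.SMALL_SEGMENTS,
                f"{report.frac_small_area:.1f}% of segments smaller than "
                f"{config.small_area_cm2:g} cm²",
                config=config,
                measured=report.frac_small_area - config.small_area_frac_percent,
            )
        )
    if report.frac_low_mu > config.low_mu_frac_percent:
        alerts.append(
            make_alert(
                AlertCode.LOW_MU_SEGMENTS,
                f"{report.frac_low_mu:.1f}% of segments deliver less than "
                f"{config.low_mu:g} MU",
                config=config,
            )
        )
    return report, alerts


def mu_comparison(
    orig: Plan, adapted: Plan, config: CheckConfig | None = None
) -> tuple[float, list[Alert]]:
    """Total-MU change in percent plus the MU-difference alert.

    The alert weight is |Δ%| − 10 once |Δ%| exceeds 10 (absolute value: an
    MU decrease is as suspicious as an increase).
    """
    config = config or CheckConfig()
    if orig.total_mu <= 0:
        raise ValidationError("original plan has zero total MU")
    delta = 100.0 * (adapted.total_mu - orig.total_mu) / orig.total_mu
    alerts: list[Alert] = []
    if abs(delta) > config.mu_diff_percent:
        alerts.append(
            make_alert(
                AlertCode.MU_DIFF,
                f"total MU changed {delta:+.1f}% "
                f"({orig.total_mu:.1f} -> {adapted.total_mu:.1f})",
                config=config,
                measured=abs(delta) - config.mu_diff_percent,
            )
        )
    return delta, alerts
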