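"""Contour-level checks: volumes, volume differences, gaps, density overrides.

Volume is computed by slice-prism summation: on every contoured slice the
polygon areas are combined with even-odd nesting (a polygon contained in an
odd number of others is a hole) and the slice area is multiplied by the
slice spacing.  No end-cap correction is applied; the same convention is
used for both plans so differences are unaffected.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from shapely.geometry import Point

from .alerting import Alert, AlertCode, make_alert
from .config import CheckConfig
from .model import Structure, StructureSet

log = logging.getLogger(__name__)


@dataclass
class VolumeEntry:
    """Original/adapted volume of one matched structure and its change."""

    name: str
    volume_original: float  # cc
    volume_adapted: float   # cc
    delta_cc: float = field(init=False)
    delta_percent: Optional[float] = field(init=False)  # None when V_or == 0
    undefined: bool = field(init=False)

    def __post_init__(self) -> None:
        self.delta_cc = self.volume_adapted - self.volume_original
        if self.volume_original > 0:
            self.delta_percent = 100.0 * self.delta_cc / self.volume_original
            self.undefined = False
        else:
            self.delta_percent = None
            self.undefined = True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "volume_original_cc": self.volume_original,
            "volume_adapted_cc": self.volume_adapted,
            "delta_cc": self.delta_cc,
            "delta_percent": self.delta_percent,
            "undefined": self.undefined,
        }


@dataclass
class GapReport:
    structure_name: str
    nominal_spacing: float          # mm, mode of consecutive z-differences
    missing_z: list[float]          # mm, strictly inside the contoured range

    @property
    def has_gap(self) -> bool:
        return bool(self.missing_z)

    def to_dict(self) -> dict:
        return {
            "structure_name": self.structure_name,
            "nominal_spacing_mm": self.nominal_spacing,
            "missing_z_mm": list(self.missing_z),
        }


def slice_area(structure: Structure, z: float) -> float:
    """Net polygon area (mm²) of one slice, holes subtracted (even-odd)."""
    polys = [c.polygon() for c in structure.contours_at(z)]
    total = 0.0
    for i, p in enumerate(polys):
        depth = 0
        rep = Point(p.representative_point())
        for j, q in enumerate(polys):
            if i != j and q.contains(rep) and q.area > p.area:
                depth += 1
        total += p.area if depth % 2 == 0 else -p.area
    return max(total, 0.0)


def structure_volume(structure: Structure, spacing: float) -> float:
    """Slice-prism volume in cc: Σ slice-area × spacing, mm³/1000."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total_mm3 = sum(slice_area(structure, z) for z in structure.z_positions) * spacing
    if total_mm3 == 0:
        log.warning("structure %s has zero total area", structure.name)
    return total_mm3 / 1000.0


def nominal_spacing(structure: Structure, default: float = 3.0) -> float:
    """Mode of consecutive z-differences (ties -> smallest); *default* if <2 slices."""
    zs = structure.z_positions
    if len(zs) < 2:
        return default
    diffs = [round(b - a, 6) for a, b in zip(zs, zs[1:])]
    counts = Counter(diffs)
    best = max(counts.values())
    return float(min(d for d, c in counts.items() if c == best))


def match_structures(
    orig: StructureSet, adapted: StructureSet
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Match by case-insensitive name; return (matched pairs, deleted, new)."""
    omap = {s.name.strip().lower(): s.name for s in orig.structures}
    amap = {s.name.strip().lower(): s.name for s in adapted.structures}
    matched = [(omap[k], amap[k]) for k in omap if k in amap]
    deleted = [omap[k] for k in omap if k not in amap]
    new = [amap[k] for k in amap if k not in omap]
    return matched, deleted, new


def volume_diff_table(
    orig: StructureSet,
    adapted: StructureSet,
    matched: list[tuple[str, str]],
    config: CheckConfig | None = None,
) -> tuple[list[VolumeEntry], list[Alert]]:
    """Volume table for the matched structures plus volume-difference alerts.

    One alert (weight 3 by default) per structure whose |Δ%| exceeds the
    threshold; a structure with zero original volume is flagged undefined
    and alerted as well.
    """
    config = config or CheckConfig()
    entries: list[VolumeEntry] = []
    alerts: list[Alert] = []
    for oname, aname in matched:
        so, sa = orig.get(oname), adapted.get(aname)
        assert so is not None and sa is not None
        sp_o = nominal_spacing(so, config.default_slice_spacing_mm)
        sp_a = nominal_spacing(sa, config.default_slice_spacing_mm)
        entry = VolumeEntry(
            name=oname,
            volume_original=structure_volume(so, sp_o),
            volume_adapted=structure_volume(sa, sp_a),
        )
        entries.append(entry)
        if entry.undefined:
            alerts.append(
                make_alert(
                    AlertCode.VOLUME_DIFF,
                    f"{oname}: original volume is zero, change undefined",
                    subject=oname,
                    config=config,
                )
            )
        elif abs(entry.delta_percent) > config.volume_diff_percent:
            alerts.append(
                make_alert(
                    AlertCode.VOLUME_DIFF,
                    f"{oname}: volume changed {entry.delta_percent:+.1f}% "
                    f"({entry.volume_original:.2f} -> {entry.volume_adapted:.2f} cc)",
                    subject=oname,
                    config=config,
                )
            )
    return entries, alerts


def detect_gaps(structure: Structure, config: CheckConfig | None = None) -> GapReport:
    """Missing-slice detection.

    A consecutive z-step larger than gap_factor × the structure's nominal
    spacing reports the intermediate grid positions as missing.  Fewer than
    two slices -> empty report (no spacing determinable).
    """
    config = config or CheckConfig()
    zs = structure.z_positions
    if len(zs) < 2:
        return GapReport(structure.name, 0.0, [])
    nominal = nominal_spacing(structure, config.default_slice_spacing_mm)
    missing: list[float] = []
    for a, b in zip(zs, zs[1:]):
        step = b - a
        if step > config.gap_factor * nominal:
            n_missing = round(step / nominal) - 1
            missing.extend(a + k * nominal for k in range(1, n_missing + 1))
    return GapReport(structure.name, nominal, missing)


def gap_alerts(
    ss: StructureSet, config: CheckConfig | None = None
) -> tuple[list[GapReport], list[Alert]]:
    """Run gap detection over a structure set; one alert per gapped structure."""
    config = config or CheckConfig()
    reports = [detect_gaps(s, config) for s in ss.structures]
    alerts = [
        make_alert(
            AlertCode.STRUCTURE_GAP,
            f"{r.structure_name}: missing slice(s) at z = "
            + ", ".join(f"{z:g}" for z in r.missing_z),
            subject=r.structure_name,
            config=config,
        )
        for r in reports
        if r.has_gap
    ]
    return reports, alerts


def density_override_report(
    ss: StructureSet, config: CheckConfig | None = None
) -> list[dict]:
    """All density overrides, priority-descending; informational only.

    Values outside the plausible relative-electron-density band are flagged
    as extreme in the detailed report but carry no weight.
    """
    config = config or CheckConfig()
    lo, hi = config.density_plausible
    rows = [
        {
            "name": s.name,
            "density": s.density_override[0],
            "priority": s.density_override[1],
            "extreme": not (lo < s.density_override[0] <= hi),
        }
        for s in ss.structures
        if s.density_override is not None
    ]
    rows.sort(key=lambda r: (-r["priority"], r["name"]))
    return rows
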