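"""Synthetic paired DICOM fixtures with injectable faults.

Generates a valid "original" and "adapted" RT Plan + RT Structure Set pair
from an analytic description (spheres, cylinders, boxes; rectangular MLC
segments) so that every check is testable without clinical data.  The
adapted pair is the original with benign recontouring noise (small in-plane
volume scaling, same factor for all members of a target chain) plus the
requested faults; each fault kind maps to exactly one expected alert code
(:data:`FAULT_ALERT_MAP`).

All geometry is analytic, so the generator carries its own ground truth:
exact contour stacks, leaf openings, per-segment MU and expected alerts,
independent of the checking code.  Output is deterministic per seed, down
to the DICOM UIDs.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .model import (
    Beam,
    Contour,
    MLCGeometry,
    MLCSegment,
    Plan,
    PlanIdentity,
    Structure,
    StructureSet,
    ValidationError,
)

MIN_SLICE_RADIUS = 0.3  # mm; thinner sphere caps are not contoured

#: fault kind -> the alert code the fault is constructed to raise
FAULT_ALERT_MAP: dict[str, str] = {
    "delete_slice": "STRUCTURE_GAP",
    "delete_structure": "STRUCTURE_DELETED",
    "wrong_margin": "TARGET_INCONSISTENT",
    "skip_margin_expansion": "TARGET_INCONSISTENT",
    "inflate_wrong_ptv": "TARGET_INCONSISTENT",
    "scale_volume": "VOLUME_DIFF",
    "rename_patient": "WRONG_PATIENT",
    "rename_plan": "WRONG_PLAN",
    "add_small_segment": "SMALL_SEGMENTS",
    "add_low_mu_segment": "LOW_MU_SEGMENTS",
    "scale_total_mu": "MU_DIFF",
}


# ---------------------------------------------------------------------------
# specs


@dataclass
class StructureSpec:
    """One OAR-like structure: sphere (radius), cylinder (radius, height)
    or box (wx, wy, wz), sliced at ``slice_spacing``."""

    name: str
    shape: str = "sphere"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    size: tuple[float, ...] = (10.0,)
    slice_spacing: float = 1.0
    n_vertices: int = 72
    density_override: Optional[tuple[float, int]] = None


@dataclass
class ChainSpec:
    """A GTV -> CTV -> PTV family built from concentric spheres."""

    suffix: str = ""
    gtv_radius: float = 8.0
    ctv_margin: float = 3.0
    ptv_margin: float = 5.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_spacing: float = 1.0
    n_vertices: int = 72


@dataclass
class SegmentSpec:
    """A rectangular MLC opening: both stacks set to the same x-interval
    over the leaf pairs whose span intersects the y-range."""

    mu: float
    x_half: float = 20.0
    y_half: float = 15.0
    x_center: float = 0.0
    y_center: float = 0.0


@dataclass
class BeamSpec:
    beam_id: str
    segments: list[SegmentSpec]


@dataclass
class FaultSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FAULT_ALERT_MAP:
            raise ValidationError(f"unknown fault kind {self.kind!r}")


def _default_beams() -> list[BeamSpec]:
    return [
        BeamSpec(
            "B1",
            [
                SegmentSpec(mu=40.0, x_half=20.0, y_half=15.0),
                SegmentSpec(mu=60.0, x_half=25.0, y_half=20.0),
                SegmentSpec(mu=50.0, x_half=15.0, y_half=10.0, x_center=5.0),
                SegmentSpec(mu=50.0, x_half=18.0, y_half=12.0, y_center=4.0),
            ],
        )
    ]


@dataclass
class FixtureSpec:
    seed: int = 0
    name: str = "fixture"
    patient_name: str = "DOE^JANE"
    patient_id: str = "PAT0001"
    plan_name: str = "ABD_SBRT_A"
    structures: list[StructureSpec] = field(default_factory=list)
    chains: list[ChainSpec] = field(default_factory=list)
    beams: list[BeamSpec] = field(default_factory=_default_beams)
    faults: list[FaultSpec] = field(default_factory=list)
    noise_percent: float = 2.0  # benign |volume change| upper bound
    geometry: MLCGeometry = field(default_factory=MLCGeometry)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        d = copy.deepcopy(d)
        d["structures"] = [StructureSpec(**s) for s in d.get("structures", [])]
        d["chains"] = [ChainSpec(**c) for c in d.get("chains", [])]
        d["beams"] = [
            BeamSpec(b["beam_id"], [SegmentSpec(**s) for s in b["segments"]])
            for b in d.get("beams", [])
        ]
        d["faults"] = [FaultSpec(**f) for f in d.get("faults", [])]
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = MLCGeometry(**d["geometry"])
        for spec in d["structures"]:
            spec.center = tuple(spec.center)
            spec.size = tuple(spec.size)
        for chain in d["chains"]:
            chain.center = tuple(chain.center)
        return cls(**d)


# ---------------------------------------------------------------------------
# analytic geometry -> contours


def _round6(x: float) -> float:
    return float(f"{x:.6f}")


def _ngon(cx: float, cy: float, r: float, n: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return np.round(pts, 6)


def _rect(cx: float, cy: float, hx: float, hy: float) -> np.ndarray:
    return np.round(
        np.array(
            [[cx - hx, cy - hy], [cx + hx, cy - hy], [cx + hx, cy + hy], [cx - hx, cy + hy]]
        ),
        6,
    )


def _slice_grid(cz: float, half_extent: float, spacing: float) -> list[float]:
    k_min = math.ceil((-half_extent + 1e-9) / spacing)
    k_max = math.floor((half_extent - 1e-9) / spacing)
    return [cz + k * spacing for k in range(k_min, k_max + 1)]


def make_sphere(
    name: str, roi: int, center: tuple, radius: float, spacing: float, n: int,
    density_override=None,
) -> Structure:
    if radius <= spacing:
        raise ValidationError(f"{name}: sphere radius {radius} too small for "
                              f"spacing {spacing} (needs >= 2 slices)")
    cx, cy, cz = center
    contours = []
    for z in _slice_grid(cz, radius, spacing):
        r = math.sqrt(max(0.0, radius**2 - (z - cz) ** 2))
        if r < MIN_SLICE_RADIUS:
            continue
        contours.append(Contour(z=_round6(z), vertices=_ngon(cx, cy, r, n)))
    return Structure(name, roi, contours, density_override)


def make_structure(spec: StructureSpec, roi: int) -> Structure:
    cx, cy, cz = spec.center
    if spec.shape == "sphere":
        return make_sphere(
            spec.name, roi, spec.center, spec.size[0], spec.slice_spacing,
            spec.n_vertices, spec.density_override,
        )
    if spec.shape == "cylinder":
        radius, height = spec.size
        contours = [
            Contour(z=_round6(z), vertices=_ngon(cx, cy, radius, spec.n_vertices))
            for z in _slice_grid(cz, height / 2.0, spec.slice_spacing)
        ]
    elif spec.shape == "box":
        wx, wy, wz = spec.size
        contours = [
            Contour(z=_round6(z), vertices=_rect(cx, cy, wx / 2.0, wy / 2.0))
            for z in _slice_grid(cz, wz / 2.0, spec.slice_spacing)
        ]
    else:
        raise ValidationError(f"unknown shape {spec.shape!r}")
    if len(contours) < 2:
        raise ValidationError(f"{spec.name}: shape produces fewer than 2 slices")
    return Structure(spec.name, roi, contours, spec.density_override)


def scale_structure(s: Structure, volume_factor: float, center_xy: tuple[float, float]) -> Structure:
    """In-plane scaling about the given center: volume scales exactly by the
    factor (slice set is unchanged)."""
    if volume_factor <= 0:
        raise ValidationError("volume factor must be positive")
    k = math.sqrt(volume_factor)
    cx, cy = center_xy
    contours = [
        Contour(
            z=c.z,
            vertices=np.round(
                (c.vertices - [cx, cy]) * k + [cx, cy], 6
            ),
        )
        for c in s.contours
    ]
    return Structure(s.name, s.roi_number, contours, s.density_override)


def shoelace_volume_cc(s: Structure, spacing: float) -> float:
    """Ground-truth volume: plain shoelace area per slice × spacing."""
    total = 0.0
    for c in s.contours:
        v = c.vertices
        x, y = v[:, 0], v[:, 1]
        total += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return total * spacing / 1000.0


# ---------------------------------------------------------------------------
# analytic MLC segments


def _stack_edges(geometry: MLCGeometry) -> tuple[np.ndarray, np.ndarray]:
    a0 = -geometry.n_pairs * geometry.leaf_width / 2.0
    edges_a = a0 + geometry.leaf_width * np.arange(geometry.n_pairs + 1)
    return edges_a, edges_a + geometry.stack_offset


def rect_segment(spec: SegmentSpec, geometry: MLCGeometry) -> MLCSegment:
    """Both stacks open to the same x-interval over every leaf pair whose
    span overlaps the requested y-range with positive length."""
    y_lo, y_hi = spec.y_center - spec.y_half, spec.y_center + spec.y_half
    x = (_round6(spec.x_center - spec.x_half), _round6(spec.x_center + spec.x_half))
    edges_a, edges_b = _stack_edges(geometry)
    stacks = []
    for edges in (edges_a, edges_b):
        pairs = []
        for k in range(geometry.n_pairs):
            overlap = min(edges[k + 1], y_hi) - max(edges[k], y_lo)
            pairs.append(x if overlap > 1e-9 else (0.0, 0.0))
        stacks.append(pairs)
    return MLCSegment(mu=spec.mu, stack_a=stacks[0], stack_b=stacks[1], geometry=geometry)


def rect_segment_open_area_cm2(spec: SegmentSpec, geometry: MLCGeometry) -> float:
    """Expected single-stack area of a rectangular segment.

    The opening is the x-width times the overlap of the two stacks' opened
    leaf spans (leaf quantization widens the requested y-range).
    """
    y_lo, y_hi = spec.y_center - spec.y_half, spec.y_center + spec.y_half
    spans = []
    for edges in _stack_edges(geometry):
        opened = [
            (edges[k], edges[k + 1])
            for k in range(geometry.n_pairs)
            if min(edges[k + 1], y_hi) - max(edges[k], y_lo) > 1e-9
        ]
        if not opened:
            return 0.0
        spans.append((opened[0][0], opened[-1][1]))
    height = min(spans[0][1], spans[1][1]) - max(spans[0][0], spans[1][0])
    return max(0.0, height) * 2.0 * spec.x_half / 100.0


def small_segment_spec(area_cm2: float, mu: float, geometry: MLCGeometry) -> SegmentSpec:
    """A one-row segment with exactly the requested open area."""
    # y-range inside a single half-leaf row of the combined stack
    y0 = geometry.stack_offset / 8.0
    y1 = geometry.stack_offset * 7.0 / 8.0
    width = area_cm2 * 100.0 / geometry.stack_offset
    return SegmentSpec(
        mu=mu,
        x_half=_round6(width / 2.0),
        y_half=(y1 - y0) / 2.0,
        y_center=(y0 + y1) / 2.0,
    )


# ---------------------------------------------------------------------------
# ground truth + pair generation


@dataclass
class GroundTruth:
    """What the written files encode, plus what the checks should find."""

    orig_structures: StructureSet
    orig_plan: Plan
    adapted_structures: StructureSet
    adapted_plan: Plan
    volumes_original: dict[str, float]       # cc, shoelace ground truth
    volumes_adapted: dict[str, float]
    segment_areas_original: list[float]      # cm², analytic per segment
    segment_areas_adapted: list[float]
    expected_alert_codes: set[str]
    spacing: dict[str, float]                # per structure


@dataclass
class FixturePair:
    orig_plan_path: Path
    orig_rs_path: Path
    adapted_plan_path: Path
    adapted_rs_path: Path
    ground_truth: GroundTruth

    @property
    def paths(self) -> tuple[Path, Path, Path, Path]:
        return (
            self.orig_plan_path,
            self.orig_rs_path,
            self.adapted_plan_path,
            self.adapted_rs_path,
        )


def _chain_structures(chain: ChainSpec) -> list[tuple[str, float]]:
    if chain.ptv_margin < 0 or chain.ctv_margin < 0:
        raise ValidationError("margins must be >= 0")
    r = chain.gtv_radius
    return [
        (f"GTV{chain.suffix}", r),
        (f"CTV{chain.suffix}", r + chain.ctv_margin),
        (f"PTV{chain.suffix}", r + chain.ctv_margin + chain.ptv_margin),
    ]


def _build_original(spec: FixtureSpec) -> tuple[dict[str, Structure], dict[str, float], dict[str, tuple[float, float]]]:
    structures: dict[str, Structure] = {}
    spacing: dict[str, float] = {}
    centers: dict[str, tuple[float, float]] = {}
    roi = 1
    for chain in spec.chains:
        for name, radius in _chain_structures(chain):
            structures[name] = make_sphere(
                name, roi, chain.center, radius, chain.slice_spacing, chain.n_vertices
            )
            spacing[name] = chain.slice_spacing
            centers[name] = chain.center[:2]
            roi += 1
    for sspec in spec.structures:
        structures[sspec.name] = make_structure(sspec, roi)
        spacing[sspec.name] = sspec.slice_spacing
        centers[sspec.name] = sspec.center[:2]
        roi += 1
    if not structures:
        raise ValidationError("fixture needs at least one structure or chain")
    return structures, spacing, centers


def _apply_faults(
    spec: FixtureSpec,
    adapted: dict[str, Structure],
    original: dict[str, Structure],
    centers: dict[str, tuple[float, float]],
    beam_specs: list[BeamSpec],
    identity: dict[str, str],
    pinned: set[tuple[int, int]],
    mu_target: list[Optional[float]],
) -> set[str]:
    expected: set[str] = set()
    for fault in spec.faults:
        p = fault.params
        if fault.kind == "delete_slice":
            s = adapted[p["name"]]
            zs = s.z_positions
            if len(zs) < 3:
                raise ValidationError(f"{s.name}: too few slices to delete one")
            z_gone = zs[p.get("index", len(zs) // 2)]
            if z_gone in (zs[0], zs[-1]):
                raise ValidationError("deleted slice must be interior")
            adapted[s.name] = Structure(
                s.name, s.roi_number,
                [c for c in s.contours if abs(c.z - z_gone) > 1e-9],
                s.density_override,
            )
            expected.add("STRUCTURE_GAP")
        elif fault.kind == "delete_structure":
            del adapted[p["name"]]
            expected.add("STRUCTURE_DELETED")
        elif fault.kind == "scale_volume":
            name, factor = p["name"], p["factor"]
            adapted[name] = scale_structure(original[name], factor, centers[name])
        elif fault.kind == "wrong_margin":
            chain = _find_chain(spec, p.get("suffix", ""))
            gtv_scale = p.get("gtv_scale", 1.2)
            r_g = chain.gtv_radius * gtv_scale ** (1.0 / 3.0)
            radii = {
                f"GTV{chain.suffix}": r_g,
                f"CTV{chain.suffix}": r_g + chain.ctv_margin,
                f"PTV{chain.suffix}": r_g + chain.ctv_margin + p["ptv_margin"],
            }
            for name, radius in radii.items():
                adapted[name] = make_sphere(
                    name, original[name].roi_number, chain.center, radius,
                    chain.slice_spacing, chain.n_vertices,
                )
            expected.add("TARGET_INCONSISTENT")
        elif fault.kind == "skip_margin_expansion":
            chain = _find_chain(spec, p.get("suffix", ""))
            name = f"PTV{chain.suffix}"
            adapted[name] = original[name]
            expected.add("TARGET_INCONSISTENT")
        elif fault.kind == "inflate_wrong_ptv":
            chain = _find_chain(spec, p.get("suffix", ""))
            wrong = _find_chain(spec, p["wrong_suffix"])
            edited = f"PTV{chain.suffix}"
            adapted[edited] = original[edited]
            victim = f"PTV{wrong.suffix}"
            adapted[victim] = scale_structure(
                original[victim], p.get("factor", 1.25), centers[victim]
            )
            expected.add("TARGET_INCONSISTENT")
        elif fault.kind == "rename_patient":
            identity["patient_name"] = p.get("new_name", "WRONG^PATIENT")
            expected.add("WRONG_PATIENT")
        elif fault.kind == "rename_plan":
            identity["plan_name"] = p.get("new_name", identity["plan_name"] + "_X")
            expected.add("WRONG_PLAN")
        elif fault.kind == "add_small_segment":
            bi = p.get("beam", 0)
            seg = small_segment_spec(
                p.get("area_cm2", 0.5), p.get("mu", 20.0), spec.geometry
            )
            beam_specs[bi].segments.append(seg)
            pinned.add((bi, len(beam_specs[bi].segments) - 1))
            expected.add("SMALL_SEGMENTS")
        elif fault.kind == "add_low_mu_segment":
            bi = p.get("beam", 0)
            seg = SegmentSpec(
                mu=p.get("mu", 3.0), x_half=p.get("x_half", 15.0),
                y_half=p.get("y_half", 12.0),
            )
            beam_specs[bi].segments.append(seg)
            pinned.add((bi, len(beam_specs[bi].segments) - 1))
            expected.add("LOW_MU_SEGMENTS")
        elif fault.kind == "scale_total_mu":
            mu_target[0] = p["factor"]
            if abs(p["factor"] - 1.0) > 0.10:
                expected.add("MU_DIFF")
    return expected


def _volume_expected_codes(
    spec: FixtureSpec,
    vol_orig: dict[str, float],
    vol_adapted: dict[str, float],
) -> set[str]:
    """Alert codes the generated volumes imply, from the generator's own
    shoelace bookkeeping and the default thresholds (30 % volume change;
    chain rules: sign mismatch, 10-point spread, frozen PTV at 0.5-point
    tolerance)."""
    expected: set[str] = set()
    deltas: dict[str, float] = {}
    for name, v0 in vol_orig.items():
        if name not in vol_adapted or v0 <= 0:
            continue
        d = 100.0 * (vol_adapted[name] - v0) / v0
        deltas[name] = d
        if abs(d) > 30.0:
            expected.add("VOLUME_DIFF")
    for chain in spec.chains:
        members = {
            role: deltas[f"{role.upper()}{chain.suffix}"]
            for role in ("gtv", "ctv", "ptv")
            if f"{role.upper()}{chain.suffix}" in deltas
        }
        if len(members) < 2:
            continue
        ptv = members.get("ptv")
        inconsistent = any(
            abs(a - b) > 10.0
            for i, a in enumerate(members.values())
            for b in list(members.values())[i + 1 :]
        )
        if ptv is not None:
            for role in ("gtv", "ctv"):
                d = members.get(role)
                if d is None:
                    continue
                if abs(d) > 0.5 and abs(ptv) > 0.5 and d * ptv < 0:
                    inconsistent = True
                if abs(ptv) <= 0.5 and abs(d) > 0.5:
                    inconsistent = True
        if inconsistent:
            expected.add("TARGET_INCONSISTENT")
    return expected


def _find_chain(spec: FixtureSpec, suffix: str) -> ChainSpec:
    for chain in spec.chains:
        if chain.suffix == suffix:
            return chain
    raise ValidationError(f"no target chain with suffix {suffix!r}")


def _build_plan(
    beam_specs: list[BeamSpec], identity: PlanIdentity, geometry: MLCGeometry,
    mu_scale: dict[tuple[int, int], float],
) -> tuple[Plan, list[float]]:
    """Build a plan with DICOM-rounded MU bookkeeping (what the file encodes)."""
    beams = []
    areas: list[float] = []
    for bi, bspec in enumerate(beam_specs):
        mus = [
            s.mu * mu_scale.get((bi, si), 1.0) for si, s in enumerate(bspec.segments)
        ]
        meterset = _round6(sum(mus))
        cumulative = np.concatenate([[0.0], np.cumsum(mus)]) / sum(mus)
        weights = [float(f"{w:.8f}") for w in cumulative]
        segments = []
        for si, sspec in enumerate(bspec.segments):
            mu = (weights[si + 1] - weights[si]) * meterset
            sspec_scaled = dataclasses.replace(sspec, mu=mu)
            segments.append(rect_segment(sspec_scaled, geometry))
            areas.append(rect_segment_open_area_cm2(sspec, geometry))
        beams.append(Beam(beam_id=bspec.beam_id, segments=segments))
    total = sum(b.mu for b in beams)
    return Plan(identity=identity, beams=beams, total_mu=total), areas


def generate_pair(spec: FixtureSpec, outdir: str | Path) -> FixturePair:
    """Write the four DICOM files and return them with their ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    original, spacing, centers = _build_original(spec)

    # benign recontouring noise: one volume factor per chain (members move
    # together) and one per free structure
    forced_chains = {
        f.params.get("suffix", "")
        for f in spec.faults
        if f.kind in ("skip_margin_expansion", "inflate_wrong_ptv")
    }
    adapted: dict[str, Structure] = {}
    for chain in spec.chains:
        dv = rng.uniform(-spec.noise_percent, spec.noise_percent)
        if chain.suffix in forced_chains:
            # the edited-chain faults need a visible recontouring change
            dv = math.copysign(max(abs(dv), 1.5), dv if dv != 0 else 1.0)
        for name, _ in _chain_structures(chain):
            adapted[name] = scale_structure(original[name], 1.0 + dv / 100.0, centers[name])
    for sspec in spec.structures:
        dv = rng.uniform(-spec.noise_percent, spec.noise_percent)
        adapted[sspec.name] = scale_structure(
            original[sspec.name], 1.0 + dv / 100.0, centers[sspec.name]
        )

    identity = {
        "patient_name": spec.patient_name,
        "patient_id": spec.patient_id,
        "plan_name": spec.plan_name,
    }
    adapted_beam_specs = [
        BeamSpec(b.beam_id, [dataclasses.replace(s) for s in b.segments])
        for b in spec.beams
    ]
    pinned: set[tuple[int, int]] = set()
    mu_target: list[Optional[float]] = [None]
    expected = _apply_faults(
        spec, adapted, original, centers, adapted_beam_specs, identity,
        pinned, mu_target,
    )

    orig_identity = PlanIdentity(spec.patient_name, spec.patient_id, spec.plan_name)
    adapted_identity = PlanIdentity(
        identity["patient_name"], identity["patient_id"], identity["plan_name"]
    )

    orig_plan, orig_areas = _build_plan(spec.beams, orig_identity, spec.geometry, {})

    # adapted MU bookkeeping: pinned (fault-added) segments keep their MU;
    # a total-MU fault rescales the remaining segments to hit the target
    mu_scale: dict[tuple[int, int], float] = {}
    if mu_target[0] is not None:
        orig_total = sum(s.mu for b in spec.beams for s in b.segments)
        pinned_mu = sum(
            adapted_beam_specs[bi].segments[si].mu for bi, si in pinned
        )
        free_mu = sum(
            s.mu
            for bi, b in enumerate(adapted_beam_specs)
            for si, s in enumerate(b.segments)
            if (bi, si) not in pinned
        )
        target_total = orig_total * mu_target[0]
        if target_total <= pinned_mu or free_mu <= 0:
            raise ValidationError("total-MU fault target infeasible")
        k = (target_total - pinned_mu) / free_mu
        for bi, b in enumerate(adapted_beam_specs):
            for si in range(len(b.segments)):
                if (bi, si) not in pinned:
                    mu_scale[(bi, si)] = k
    adapted_plan, adapted_areas = _build_plan(
        adapted_beam_specs, adapted_identity, spec.geometry, mu_scale
    )

    orig_ss = StructureSet(
        identity=PlanIdentity(spec.patient_name, spec.patient_id, spec.plan_name),
        structures=list(original.values()),
    )
    adapted_ss = StructureSet(
        identity=PlanIdentity(
            identity["patient_name"], identity["patient_id"], identity["plan_name"]
        ),
        structures=list(adapted.values()),
    )

    paths = (
        outdir / "orig_plan.dcm",
        outdir / "orig_rs.dcm",
        outdir / "adapted_plan.dcm",
        outdir / "adapted_rs.dcm",
    )
    write_plan(paths[0], orig_plan, spec.seed, "orig_plan")
    write_structure_set(paths[1], orig_ss, spec.seed, "orig_rs")
    write_plan(paths[2], adapted_plan, spec.seed, "adapted_plan")
    write_structure_set(paths[3], adapted_ss, spec.seed, "adapted_rs")

    volumes_original = {
        n: shoelace_volume_cc(s, spacing[n]) for n, s in original.items()
    }
    volumes_adapted = {
        n: shoelace_volume_cc(s, spacing[n]) for n, s in adapted.items()
    }
    expected |= _volume_expected_codes(spec, volumes_original, volumes_adapted)

    gt = GroundTruth(
        orig_structures=orig_ss,
        orig_plan=orig_plan,
        adapted_structures=adapted_ss,
        adapted_plan=adapted_plan,
        volumes_original=volumes_original,
        volumes_adapted=volumes_adapted,
        segment_areas_original=orig_areas,
        segment_areas_adapted=adapted_areas,
        expected_alert_codes=expected,
        spacing=spacing,
    )
    return FixturePair(*paths, ground_truth=gt)


# ---------------------------------------------------------------------------
# DICOM writing

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


def _uid(seed: int, tag: str) -> str:
    digest = hashlib.sha256(f"apart-fixture-{seed}-{tag}".encode()).digest()
    return f"2.25.{int.from_bytes(digest[:12], 'big')}"


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _file_dataset(path: Path, sop_class: str, seed: int, tag: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = _uid(seed, tag)
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _uid(seed, "impl")
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.SeriesInstanceUID = _uid(seed, f"series-{tag}")
    ds.InstanceCreationDate = "20200101"
    ds.InstanceCreationTime = "120000"
    return ds


def write_structure_set(path: str | Path, ss: StructureSet, seed: int, tag: str) -> None:
    path = Path(path)
    ds = _file_dataset(path, RTSTRUCT_SOP_CLASS, seed, tag)
    ds.Modality = "RTSTRUCT"
    ds.PatientName = ss.identity.patient_name
    ds.PatientID = ss.identity.patient_id
    ds.StructureSetLabel = ss.identity.plan_name
    ds.StructureSetDate = "20200101"
    ds.StructureSetTime = "120000"

    roi_seq, contour_seq, obs_seq = [], [], []
    frame_uid = _uid(seed, "frame")
    for i, s in enumerate(ss.structures):
        roi = Dataset()
        roi.ROINumber = s.roi_number
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIName = s.name
        roi.ROIGenerationAlgorithm = "MANUAL"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = s.roi_number
        items = []
        for c in s.contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(c.vertices)
            item.ContourData = [
                _fmt(v)
                for xy in c.vertices
                for v in (xy[0], xy[1], c.z)
            ]
            items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)

        obs = Dataset()
        obs.ObservationNumber = i + 1
        obs.ReferencedROINumber = s.roi_number
        obs.RTROIInterpretedType = "ORGAN"
        if s.density_override is not None:
            density, priority = s.density_override
            obs.ROIObservationDescription = f"DENSITY_PRIORITY={priority}"
            prop = Dataset()
            prop.ROIPhysicalProperty = "REL_ELEC_DENSITY"
            prop.ROIPhysicalPropertyValue = _fmt(density)
            obs.ROIPhysicalPropertiesSequence = [prop]
        obs_seq.append(obs)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(str(path), enforce_file_format=True)


def write_plan(path: str | Path, plan: Plan, seed: int, tag: str) -> None:
    path = Path(path)
    ds = _file_dataset(path, RTPLAN_SOP_CLASS, seed, tag)
    ds.Modality = "RTPLAN"
    ds.PatientName = plan.identity.patient_name
    ds.PatientID = plan.identity.patient_id
    ds.RTPlanLabel = plan.identity.plan_name
    ds.RTPlanName = plan.identity.plan_name
    ds.RTPlanDate = "20200101"
    ds.RTPlanTime = "120000"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    rb_seq = []
    for bi, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = _fmt(beam.mu)
        rb_seq.append(rb)
    fg.ReferencedBeamSequence = rb_seq
    ds.FractionGroupSequence = [fg]

    beam_seq = []
    for bi, beam in enumerate(plan.beams, start=1):
        geometry = beam.segments[0].geometry
        b = Dataset()
        b.BeamNumber = bi
        b.BeamName = beam.beam_id
        b.TreatmentMachineName = "MRL1"
        b.RadiationType = "PHOTON"
        b.BeamType = "STATIC"
        b.TreatmentDeliveryType = "TREATMENT"
        b.FinalCumulativeMetersetWeight = "1.00000000"
        b.NumberOfControlPoints = len(beam.segments) + 1

        edges_a, edges_b = _stack_edges(geometry)
        bld_seq = []
        for dev, edges in (("MLCX1", edges_a), ("MLCX2", edges_b)):
            item = Dataset()
            item.RTBeamLimitingDeviceType = dev
            item.NumberOfLeafJawPairs = geometry.n_pairs
            item.LeafPositionBoundaries = [_fmt(e) for e in edges]
            bld_seq.append(item)
        b.BeamLimitingDeviceSequence = bld_seq

        total = beam.mu
        cumulative = [0.0]
        for seg in beam.segments:
            cumulative.append(cumulative[-1] + seg.mu / total)
        cps = []
        for j in range(len(beam.segments) + 1):
            cp = Dataset()
            cp.ControlPointIndex = j
            cp.CumulativeMetersetWeight = f"{min(cumulative[j], 1.0):.8f}"
            if j < len(beam.segments):
                seg = beam.segments[j]
                pos_seq = []
                for dev, stack in (("MLCX1", seg.stack_a), ("MLCX2", seg.stack_b)):
                    item = Dataset()
                    item.RTBeamLimitingDeviceType = dev
                    item.LeafJawPositions = [
                        _fmt(v) for v in [p[0] for p in stack] + [p[1] for p in stack]
                    ]
                    pos_seq.append(item)
                cp.BeamLimitingDevicePositionSequence = pos_seq
            cps.append(cp)
        b.ControlPointSequence = cps
        beam_seq.append(b)
    ds.BeamSequence = beam_seq
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# incident suite


def incident_suite() -> list[FixtureSpec]:
    """Nine fixtures reproducing the incident patterns this kind of check
    exists to catch: four target/margin irregularities, four accidental
    missing slices, one over-modulated plan (small segment + MU jump)."""
    specs: list[FixtureSpec] = []

    def chain(**kw) -> ChainSpec:
        base = dict(gtv_radius=8.0, ctv_margin=3.0, ptv_margin=5.0)
        base.update(kw)
        return ChainSpec(**base)

    oar = StructureSpec("Liver", shape="sphere", center=(40.0, 0.0, 0.0),
                        size=(25.0,), slice_spacing=1.0)

    # 1) larger tracking margins forgotten: PTV -21% while GTV +32%, CTV +16%
    specs.append(
        FixtureSpec(
            seed=101, name="target_margin_forgotten",
            chains=[chain()], structures=[oar],
            faults=[
                FaultSpec("scale_volume", {"name": "GTV", "factor": 1.32}),
                FaultSpec("scale_volume", {"name": "CTV", "factor": 1.16}),
                FaultSpec("scale_volume", {"name": "PTV", "factor": 0.79}),
            ],
        )
    )
    # 2) margin 3 mm instead of 5 mm: PTV about -55% while GTV/CTV grow ~20%
    specs.append(
        FixtureSpec(
            seed=102, name="target_margin_too_small",
            chains=[chain(gtv_radius=2.0, ctv_margin=1.0, ptv_margin=5.0)],
            structures=[oar],
            faults=[FaultSpec("wrong_margin", {"suffix": "", "ptv_margin": 3.0,
                                               "gtv_scale": 1.2})],
        )
    )
    # 3) wrong PTV inflated: edited chain's GTV/CTV +19%/+10% with PTV at 0%
    specs.append(
        FixtureSpec(
            seed=103, name="target_wrong_ptv_inflated",
            chains=[chain(suffix="1"),
                    chain(suffix="2", center=(0.0, 40.0, 0.0))],
            structures=[oar],
            faults=[
                FaultSpec("scale_volume", {"name": "GTV1", "factor": 1.19}),
                FaultSpec("scale_volume", {"name": "CTV1", "factor": 1.10}),
                FaultSpec("scale_volume", {"name": "PTV1", "factor": 1.0}),
                FaultSpec("scale_volume", {"name": "PTV2", "factor": 1.25}),
            ],
        )
    )
    # 4) wrong GTV edited, old PTV reused: PTV 0% while GTV/CTV -1%/-2%
    specs.append(
        FixtureSpec(
            seed=104, name="target_not_edited",
            chains=[chain()], structures=[oar],
            faults=[
                FaultSpec("scale_volume", {"name": "GTV", "factor": 0.99}),
                FaultSpec("scale_volume", {"name": "CTV", "factor": 0.98}),
                FaultSpec("scale_volume", {"name": "PTV", "factor": 1.0}),
            ],
        )
    )
    # 5-7) accidentally deleted slices within CTV/GTV contours
    for seed, name, target in (
        (105, "gap_ctv_a", "CTV"),
        (106, "gap_ctv_b", "CTV"),
        (107, "gap_gtv", "GTV"),
    ):
        specs.append(
            FixtureSpec(
                seed=seed, name=name, chains=[chain()], structures=[oar],
                faults=[FaultSpec("delete_slice", {"name": target})],
            )
        )
    # 8) accidentally deleted slice in the bowel
    specs.append(
        FixtureSpec(
            seed=108, name="gap_bowel",
            chains=[chain()],
            structures=[
                StructureSpec("Bowel", shape="cylinder", center=(-40.0, 0.0, 0.0),
                              size=(15.0, 60.0), slice_spacing=3.0)
            ],
            faults=[FaultSpec("delete_slice", {"name": "Bowel"})],
        )
    )
    # 9) over-modulated adapted plan: MU +10.1% with a 0.66 cm² / 302.6 MU
    # segment among five
    specs.append(
        FixtureSpec(
            seed=109, name="mu_small_segment",
            chains=[chain()], structures=[oar],
            beams=[
                BeamSpec(
                    "B1",
                    [
                        SegmentSpec(mu=120.0, x_half=20.0, y_half=15.0),
                        SegmentSpec(mu=140.0, x_half=25.0, y_half=20.0),
                        SegmentSpec(mu=110.0, x_half=15.0, y_half=10.0),
                        SegmentSpec(mu=130.0, x_half=18.0, y_half=12.0),
                    ],
                )
            ],
            faults=[
                FaultSpec("add_small_segment", {"area_cm2": 0.66, "mu": 302.6}),
                FaultSpec("scale_total_mu", {"factor": 1.101}),
            ],
        )
    )
    return specs
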