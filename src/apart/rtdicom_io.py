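"""Read DICOM RT Plan and RT Structure Set files into the domain model.

No check logic lives here.  Coordinates are taken verbatim from ContourData
(patient coordinate system, mm); per-segment monitor units are derived from
cumulative meterset weight differences under a step-and-shoot assumption,
with leaf positions taken at the start control point of each segment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom

from .model import (
    Beam,
    Contour,
    FormatError,
    MLCGeometry,
    MLCSegment,
    Plan,
    PlanIdentity,
    Structure,
    StructureSet,
    ValidationError,
)

log = logging.getLogger(__name__)

RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

_PRIORITY_RE = re.compile(r"DENSITY_PRIORITY\s*=\s*(\d+)")


@dataclass
class ReadReport:
    """Non-fatal issues encountered while reading (degenerate contours etc.)."""

    skipped_contours: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _read_dataset(path: str | Path, sop_class: str, kind: str) -> pydicom.Dataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ds = pydicom.dcmread(str(path), force=False)
    except Exception as exc:  # not DICOM at all
        raise FormatError(f"{path} is not readable DICOM: {exc}") from exc
    if str(getattr(ds, "SOPClassUID", "")) != sop_class:
        raise FormatError(
            f"{path} is not an RT {kind} (SOP class "
            f"{getattr(ds, 'SOPClassUID', 'missing')})"
        )
    return ds


def _identity(ds: pydicom.Dataset, plan_name: str) -> PlanIdentity:
    return PlanIdentity(
        patient_name=str(getattr(ds, "PatientName", "")),
        patient_id=str(getattr(ds, "PatientID", "")),
        plan_name=plan_name,
    )


def read_structure_set(
    path: str | Path, report: ReadReport | None = None
) -> StructureSet:
    """Parse an RT Structure Set into a :class:`StructureSet`.

    Degenerate contours (<3 points) are skipped with a warning and recorded
    in *report*; a duplicate ROI name or a wrong SOP class is an error.
    """
    report = report if report is not None else ReadReport()
    ds = _read_dataset(path, RTSTRUCT_SOP_CLASS, "Structure Set")

    names: dict[int, str] = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    # density overrides + priority from RT ROI observations
    overrides: dict[int, tuple[float, int]] = {}
    for i, obs in enumerate(getattr(ds, "RTROIObservationsSequence", [])):
        roi_num = int(obs.ReferencedROINumber)
        priority = i
        m = _PRIORITY_RE.search(str(getattr(obs, "ROIObservationDescription", "")))
        if m:
            priority = int(m.group(1))
        for prop in getattr(obs, "ROIPhysicalPropertiesSequence", []):
            if str(getattr(prop, "ROIPhysicalProperty", "")) == "REL_ELEC_DENSITY":
                overrides[roi_num] = (float(prop.ROIPhysicalPropertyValue), priority)

    structures: list[Structure] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        roi_num = int(rc.ReferencedROINumber)
        name = names.get(roi_num, f"ROI_{roi_num}")
        contours: list[Contour] = []
        for item in getattr(rc, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                msg = f"{name}: degenerate contour ({data.shape[0]} points) skipped"
                log.warning(msg)
                report.skipped_contours.append(msg)
                continue
            contours.append(Contour(z=float(data[0, 2]), vertices=data[:, :2]))
        if contours:
            structures.append(
                Structure(
                    name=name,
                    roi_number=roi_num,
                    contours=contours,
                    density_override=overrides.get(roi_num),
                )
            )

    identity = _identity(ds, str(getattr(ds, "StructureSetLabel", "")) or "UNKNOWN")
    hint = getattr(ds, "SliceThickness", None)
    return StructureSet(
        identity=identity,
        structures=structures,
        slice_spacing_hint=float(hint) if hint else None,
    )


def _geometry_from_beam(beam: pydicom.Dataset) -> tuple[MLCGeometry, list[str]]:
    """Derive the double-stack geometry and the stack-A/B device-type order.

    Any beam-limiting device whose type starts with "MLC" is a stack; the one
    with the smaller first leaf boundary is stack A.
    """
    mlcs = [
        d
        for d in getattr(beam, "BeamLimitingDeviceSequence", [])
        if str(d.RTBeamLimitingDeviceType).upper().startswith("MLC")
    ]
    if len(mlcs) != 2:
        raise ValidationError(
            f"beam {getattr(beam, 'BeamNumber', '?')}: expected 2 MLC stacks, "
            f"found {len(mlcs)}"
        )
    mlcs.sort(key=lambda d: float(d.LeafPositionBoundaries[0]))
    bound_a = np.asarray(mlcs[0].LeafPositionBoundaries, dtype=float)
    bound_b = np.asarray(mlcs[1].LeafPositionBoundaries, dtype=float)
    n_pairs = int(mlcs[0].NumberOfLeafJawPairs)
    if int(mlcs[1].NumberOfLeafJawPairs) != n_pairs:
        raise ValidationError("MLC stacks differ in leaf-pair count")
    leaf_width = float(np.mean(np.diff(bound_a)))
    geometry = MLCGeometry(
        n_pairs=n_pairs,
        leaf_width=leaf_width,
        stack_offset=float(bound_b[0] - bound_a[0]),
    )
    return geometry, [str(d.RTBeamLimitingDeviceType) for d in mlcs]


def _leaf_pairs(cp: pydicom.Dataset, device_type: str, n: int):
    for item in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        if str(item.RTBeamLimitingDeviceType) == device_type:
            pos = np.asarray(item.LeafJawPositions, dtype=float)
            if pos.size != 2 * n:
                raise ValidationError(
                    f"device {device_type}: {pos.size} leaf positions, expected {2 * n}"
                )
            return list(zip(pos[:n].tolist(), pos[n:].tolist()))
    return None


def read_plan(path: str | Path) -> Plan:
    """Parse an RT Plan into a :class:`Plan`.

    Segment j of a beam spans control points (j, j+1): its MU is the
    cumulative-weight difference scaled by the beam meterset, its leaf
    positions are those in force at control point j.
    """
    ds = _read_dataset(path, RTPLAN_SOP_CLASS, "Plan")

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[Beam] = []
    for beam in getattr(ds, "BeamSequence", []):
        beam_number = int(beam.BeamNumber)
        beam_name = str(getattr(beam, "BeamName", "")) or f"Beam{beam_number}"
        geometry, device_types = _geometry_from_beam(beam)
        cps = list(getattr(beam, "ControlPointSequence", []))
        if len(cps) < 2:
            raise ValidationError(f"beam {beam_name}: fewer than 2 control points")
        weights = [float(cp.CumulativeMetersetWeight) for cp in cps]
        if any(w1 - w0 < -1e-9 for w0, w1 in zip(weights, weights[1:])):
            raise ValidationError(
                f"beam {beam_name}: cumulative meterset weights not monotone"
            )
        final = float(getattr(beam, "FinalCumulativeMetersetWeight", weights[-1]))
        if final <= 0:
            raise ValidationError(f"beam {beam_name}: final cumulative weight <= 0")
        meterset = metersets.get(beam_number)
        if meterset is None:
            raise ValidationError(f"beam {beam_name}: no BeamMeterset referenced")

        segments: list[MLCSegment] = []
        current: dict[str, list[tuple[float, float]]] = {}
        for j in range(len(cps) - 1):
            for dev in device_types:
                pairs = _leaf_pairs(cps[j], dev, geometry.n_pairs)
                if pairs is not None:
                    current[dev] = pairs
            if len(current) != 2:
                raise ValidationError(
                    f"beam {beam_name}: missing MLC positions at control point {j}"
                )
            mu = (weights[j + 1] - weights[j]) / final * meterset
            segments.append(
                MLCSegment(
                    mu=mu,
                    stack_a=list(current[device_types[0]]),
                    stack_b=list(current[device_types[1]]),
                    geometry=geometry,
                )
            )
        beams.append(Beam(beam_id=beam_name, segments=segments))

    identity = _identity(
        ds, str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "RTPlanName", ""))
    )
    total = sum(b.mu for b in beams)
    return Plan(identity=identity, beams=beams, total_mu=total)
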