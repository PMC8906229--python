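"""Assemble the per-fraction report and serialize it to JSON or text.

``run_check`` executes every check in a fixed order (identity -> structures
-> targets -> gaps -> overrides -> complexity -> score) and returns a
:class:`FractionReport`; ``render`` turns it into a JSON document (validating
against the shipped schema) or a human-readable text summary.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

from . import rtdicom_io
from .alerting import Alert, TrafficLight, compare_identity, score
from .config import CheckConfig
from .contour_checks import (
    VolumeEntry,
    density_override_report,
    gap_alerts,
    match_structures,
    volume_diff_table,
)
from .mlc_complexity import ComplexityReport, mu_comparison, segment_stats
from .model import Plan, PlanIdentity, StructureSet
from .schema import validate
from .target_consistency import ChainFinding, check_all_chains


class CheckAborted(RuntimeError):
    """A required input file could not be read."""


@dataclass
class FractionReport:
    identity_original: PlanIdentity
    identity_adapted: PlanIdentity
    matched: list[tuple[str, str]]
    deleted: list[str]
    new: list[str]
    volume_table: list[VolumeEntry]
    chain_findings: list[ChainFinding]
    gap_reports: dict[str, list]          # "original"/"adapted" -> [GapReport]
    density_overrides: dict[str, list]    # "original"/"adapted" -> [dict]
    complexity: dict[str, ComplexityReport]  # "original"/"adapted"
    mu_delta_percent: float
    alerts: list[Alert]
    light: TrafficLight
    config_used: dict
    timestamps: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def ident(i: PlanIdentity) -> dict:
            return {
                "patient_name": i.patient_name,
                "patient_id": i.patient_id,
                "plan_name": i.plan_name,
            }

        return {
            "identity": {
                "original": ident(self.identity_original),
                "adapted": ident(self.identity_adapted),
            },
            "structures": {
                "matched": [list(p) for p in self.matched],
                "deleted": list(self.deleted),
                "new": list(self.new),
                "count_original": len(self.matched) + len(self.deleted),
                "count_adapted": len(self.matched) + len(self.new),
            },
            "volume_table": [v.to_dict() for v in self.volume_table],
            "chain_findings": [c.to_dict() for c in self.chain_findings],
            "gap_reports": {
                k: [g.to_dict() for g in v] for k, v in self.gap_reports.items()
            },
            "density_overrides": self.density_overrides,
            "complexity": {
                k: v.to_dict() for k, v in self.complexity.items()
            },
            "mu_delta_percent": self.mu_delta_percent,
            "alerts": [a.to_dict() for a in self.alerts],
            "light": {
                "value": self.light.value,
                "total_weight": self.light.total_weight,
            },
            "config_used": self.config_used,
            "timestamps": dict(self.timestamps),
        }


def check_models(
    orig_plan: Plan,
    orig_rs: StructureSet,
    adapted_plan: Plan,
    adapted_rs: StructureSet,
    config: CheckConfig | None = None,
) -> FractionReport:
    """Run every check on already-parsed domain objects."""
    config = config or CheckConfig()
    alerts: list[Alert] = []

    # identity
    alerts.extend(compare_identity(orig_plan.identity, adapted_plan.identity, config))

    # structures: matching, deletions, volumes
    matched, deleted, new = match_structures(orig_rs, adapted_rs)
    from .alerting import AlertCode, make_alert

    for name in deleted:
        alerts.append(
            make_alert(
                AlertCode.STRUCTURE_DELETED,
                f"structure {name!r} missing from the adapted plan",
                subject=name,
                config=config,
            )
        )
    volume_table, vol_alerts = volume_diff_table(orig_rs, adapted_rs, matched, config)
    alerts.extend(vol_alerts)

    # target chains
    chain_findings, chain_alerts = check_all_chains(volume_table, config)
    alerts.extend(chain_alerts)

    # gaps: the adapted set raises alerts (slices are deleted while
    # recontouring); the original's reports are kept for reference
    gaps_orig, _ = gap_alerts(orig_rs, config)
    gaps_adapted, g_alerts = gap_alerts(adapted_rs, config)
    alerts.extend(g_alerts)

    # density overrides (informational)
    overrides = {
        "original": density_override_report(orig_rs, config),
        "adapted": density_override_report(adapted_rs, config),
    }

    # MLC complexity; segment alerts evaluated on the deliverable plan
    complexity_orig, _ = segment_stats(orig_plan, config)
    complexity_adapted, seg_alerts = segment_stats(adapted_plan, config)
    alerts.extend(seg_alerts)
    mu_delta, mu_alerts = mu_comparison(orig_plan, adapted_plan, config)
    alerts.extend(mu_alerts)

    light = score(alerts, config)
    return FractionReport(
        identity_original=orig_plan.identity,
        identity_adapted=adapted_plan.identity,
        matched=matched,
        deleted=deleted,
        new=new,
        volume_table=volume_table,
        chain_findings=chain_findings,
        gap_reports={"original": gaps_orig, "adapted": gaps_adapted},
        density_overrides=overrides,
        complexity={"original": complexity_orig, "adapted": complexity_adapted},
        mu_delta_percent=mu_delta,
        alerts=alerts,
        light=light,
        config_used=config.to_dict(),
        timestamps={
            "generated": datetime.datetime.now(datetime.timezone.utc).isoformat()
        },
    )


def run_check(
    orig_plan_path: str | Path,
    orig_rs_path: str | Path,
    adapted_plan_path: str | Path,
    adapted_rs_path: str | Path,
    config: CheckConfig | None = None,
) -> FractionReport:
    """Read the four DICOM files and run the full per-fraction check."""
    inputs = [
        ("original plan", orig_plan_path, rtdicom_io.read_plan),
        ("original structure set", orig_rs_path, rtdicom_io.read_structure_set),
        ("adapted plan", adapted_plan_path, rtdicom_io.read_plan),
        ("adapted structure set", adapted_rs_path, rtdicom_io.read_structure_set),
    ]
    parsed = []
    for label, path, reader in inputs:
        try:
            parsed.append(reader(path))
        except Exception as exc:
            raise CheckAborted(f"cannot read {label} ({path}): {exc}") from exc
    orig_plan, orig_rs, adapted_plan, adapted_rs = parsed
    return check_models(orig_plan, orig_rs, adapted_plan, adapted_rs, config)


def load_schema() -> dict:
    with resources.files("apart").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def render(report: FractionReport, format: str = "json") -> str:
    """Serialize a report; 'json' validates against the shipped schema."""
    if format == "json":
        d = report.to_dict()
        validate(d, load_schema())
        return json.dumps(d, indent=2, sort_keys=True)
    if format == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {format!r} (expected 'json' or 'text')")


def _render_text(report: FractionReport) -> str:
    lines: list[str] = []
    add = lines.append
    add(f"TRAFFIC LIGHT: {report.light.value.upper()} "
        f"(total weight {report.light.total_weight:g})")
    add("")
    add(f"Patient: {report.identity_adapted.patient_name} "
        f"({report.identity_adapted.patient_id})  "
        f"Plan: {report.identity_adapted.plan_name}")
    add(f"Total MU: {report.complexity['original'].mu_total:.1f} -> "
        f"{report.complexity['adapted'].mu_total:.1f} "
        f"({report.mu_delta_percent:+.1f}%)")
    add("")
    add(f"Alerts ({len(report.alerts)}):")
    if not report.alerts:
        add("  none")
    for a in report.alerts:
        add(f"  [{a.code.value}] weight {a.weight:g}: {a.message}")
    add("")
    add("Volume table (cc):")
    add(f"  {'structure':<24}{'original':>10}{'adapted':>10}{'delta %':>10}")
    for v in report.volume_table:
        delta = "undef" if v.delta_percent is None else f"{v.delta_percent:+.1f}"
        add(f"  {v.name:<24}{v.volume_original:>10.2f}{v.volume_adapted:>10.2f}{delta:>10}")
    if report.deleted:
        add(f"  deleted: {', '.join(report.deleted)}")
    if report.new:
        add(f"  new: {', '.join(report.new)}")
    add("")
    for label in ("original", "adapted"):
        c = report.complexity[label]
        add(f"Complexity ({label}): {c.n_segments} segments, "
            f"{c.n_subsegments} subsegments")
        if c.min_area_segment:
            add(f"  smallest segment: {c.min_area_segment[0]:.2f} cm² "
                f"at {c.min_area_segment[1]:.1f} MU")
        if c.min_mu_segment:
            add(f"  lowest-MU segment: {c.min_mu_segment[0]:.1f} MU "
                f"at {c.min_mu_segment[1]:.2f} cm²")
        for b in c.beams:
            eff = "undefined" if b.eff_mu is None else f"{b.eff_mu:.1f}"
            add(f"  beam {b.beam_id}: effMU {eff}, union {b.union_area:.2f} cm², "
                f"MU {b.mu:.1f}")
    add("")
    add("Target chains:")
    if not report.chain_findings:
        add("  none")
    for c in report.chain_findings:
        label = c.chain.label or "(unsuffixed)"
        status = "consistent" if c.consistent else "INCONSISTENT"
        if not c.checked:
            status = "not checkable (single member)"
        margins = ""
        if c.sphere_margin_original is not None:
            margins = (f"; sphere margin {c.sphere_margin_original:.2f} -> "
                       f"{c.sphere_margin_adapted:.2f} mm")
        add(f"  chain {label}: {status}{margins}")
        for r in c.reasons:
            add(f"    - {r}")
    for label in ("original", "adapted"):
        rows = report.density_overrides[label]
        if rows:
            add("")
            add(f"Density overrides ({label}):")
            for r in rows:
                extreme = "  (EXTREME VALUE)" if r["extreme"] else ""
                add(f"  {r['name']}: rel. density {r['density']:g}, "
                    f"priority {r['priority']}{extreme}")
    gapped = [g for g in report.gap_reports["adapted"] if g.has_gap]
    if gapped:
        add("")
        add("Structure gaps (adapted):")
        for g in gapped:
            add(f"  {g.structure_name}: missing z = "
                + ", ".join(f"{z:g}" for z in g.missing_z))
    return "\n".join(lines) + "\n"
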