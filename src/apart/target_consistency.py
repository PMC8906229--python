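"""Target-chain consistency: GTV -> CTV -> PTV margin-expansion checks.

Targets are recontoured at every adapted fraction and the margins re-applied,
so the members of one chain should change volume together.  Three rules flag
an inconsistent chain:

(a) sign mismatch — the PTV shrinks while GTV/CTV grow or vice versa;
(b) spread — the percentage changes of two chain members differ by more
    than 10 percentage points;
(c) frozen PTV — GTV or CTV changed but the PTV did not (margin expansion
    skipped, or the wrong PTV edited).

Changes within a 0.5-percentage-point tolerance count as "no change".  For
reassurance the equivalent-sphere expansion radius of each plan's chain is
reported: the margin the outer volume would imply if both were spheres.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional

from .alerting import Alert, AlertCode, make_alert
from .config import CheckConfig
from .contour_checks import VolumeEntry

TARGET_ROLES = ("gtv", "ctv", "ptv")


@dataclass
class TargetChain:
    """A GTV/CTV/PTV family sharing one name suffix (e.g. '1' or '_boost')."""

    label: str
    members: dict[str, VolumeEntry] = field(default_factory=dict)  # role -> entry

    def get(self, role: str) -> Optional[VolumeEntry]:
        return self.members.get(role)

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ChainFinding:
    chain: TargetChain
    sphere_margin_original: Optional[float]  # mm, innermost -> PTV, original plan
    sphere_margin_adapted: Optional[float]
    consistent: bool
    reasons: list[str]
    checked: bool = True  # False for single-member chains

    def to_dict(self) -> dict:
        return {
            "label": self.chain.label,
            "members": {r: e.to_dict() for r, e in self.chain.members.items()},
            "sphere_margin_original_mm": self.sphere_margin_original,
            "sphere_margin_adapted_mm": self.sphere_margin_adapted,
            "consistent": self.consistent,
            "reasons": list(self.reasons),
            "checked": self.checked,
        }


def build_chains(
    entries: list[VolumeEntry], config: CheckConfig | None = None
) -> list[TargetChain]:
    """Group target volume entries into chains by role pattern and suffix."""
    config = config or CheckConfig()
    patterns = {
        role: re.compile(pat, re.IGNORECASE)
        for role, pat in config.target_patterns.items()
    }
    chains: dict[str, TargetChain] = {}
    for entry in entries:
        for role, pat in patterns.items():
            m = pat.match(entry.name.strip())
            if m:
                suffix = (m.group(1) if m.groups() else "").strip().lower()
                chain = chains.setdefault(suffix, TargetChain(label=suffix))
                chain.members[role] = entry
                break
    return [chains[k] for k in sorted(chains)]


def sphere_equivalent_margin(v_inner_cc: float, v_outer_cc: float) -> float:
    """Radius difference (mm) of spheres with these volumes; may be negative."""
    if v_inner_cc < 0 or v_outer_cc < 0:
        raise ValueError("volumes must be >= 0")

    def radius(v_cc: float) -> float:
        return (3.0 * v_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    return radius(v_outer_cc) - radius(v_inner_cc)


def _chain_sphere_margins(
    chain: TargetChain,
) -> tuple[Optional[float], Optional[float]]:
    """Innermost-member -> PTV equivalent-sphere margins for both plans."""
    ptv = chain.get("ptv")
    inner = chain.get("ctv") or chain.get("gtv")
    if ptv is None or inner is None:
        return None, None
    return (
        sphere_equivalent_margin(inner.volume_original, ptv.volume_original),
        sphere_equivalent_margin(inner.volume_adapted, ptv.volume_adapted),
    )


def check_chain(
    chain: TargetChain, config: CheckConfig | None = None
) -> tuple[ChainFinding, list[Alert]]:
    """Apply the consistency rules to one chain; alert if it fails any."""
    config = config or CheckConfig()
    tol = config.target_zero_tol_points
    margins = _chain_sphere_margins(chain)

    deltas = {
        role: e.delta_percent
        for role, e in chain.members.items()
        if e.delta_percent is not None
    }
    if chain.n_members < 2 or len(deltas) < 2:
        # noted via checked=False; reasons stay empty so consistent<->no reasons holds
        return (
            ChainFinding(chain, *margins, consistent=True, reasons=[], checked=False),
            [],
        )

    reasons: list[str] = []

    # (a) sign mismatch between PTV and GTV/CTV, either direction
    ptv_delta = deltas.get("ptv")
    if ptv_delta is not None:
        for role in ("gtv", "ctv"):
            d = deltas.get(role)
            if d is None:
                continue
            if abs(d) > tol and abs(ptv_delta) > tol and d * ptv_delta < 0:
                reasons.append(
                    f"sign mismatch: {role.upper()} {d:+.1f}% vs PTV {ptv_delta:+.1f}%"
                )

    # (b) pairwise percentage-point spread
    roles = list(deltas)
    for i, r1 in enumerate(roles):
        for r2 in roles[i + 1 :]:
            spread = abs(deltas[r1] - deltas[r2])
            if spread > config.target_spread_points:
                reasons.append(
                    f"change spread {spread:.1f} points between "
                    f"{r1.upper()} ({deltas[r1]:+.1f}%) and {r2.upper()} ({deltas[r2]:+.1f}%)"
                )

    # (c) GTV/CTV changed while the PTV stayed frozen
    if ptv_delta is not None and abs(ptv_delta) <= tol:
        changed = [
            role for role in ("gtv", "ctv") if abs(deltas.get(role, 0.0)) > tol
        ]
        if changed:
            reasons.append(
                "PTV unchanged while "
                + "/".join(r.upper() for r in changed)
                + " changed ("
                + ", ".join(f"{deltas[r]:+.1f}%" for r in changed)
                + ")"
            )

    finding = ChainFinding(
        chain, *margins, consistent=not reasons, reasons=reasons
    )
    alerts: list[Alert] = []
    if reasons:
        label = chain.label or "(unsuffixed)"
        alerts.append(
            make_alert(
                AlertCode.TARGET_INCONSISTENT,
                f"target chain {label}: " + "; ".join(reasons),
                subject=label,
                config=config,
            )
        )
    return finding, alerts


def check_all_chains(
    entries: list[VolumeEntry], config: CheckConfig | None = None
) -> tuple[list[ChainFinding], list[Alert]]:
    config = config or CheckConfig()
    findings: list[ChainFinding] = []
    alerts: list[Alert] = []
    for chain in build_chains(entries, config):
        finding, chain_alerts = check_chain(chain, config)
        findings.append(finding)
        alerts.extend(chain_alerts)
    return findings, alerts
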