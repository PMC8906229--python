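"""Weighted alerts and the traffic-light verdict.

Each irregularity a check finds becomes an :class:`Alert` with a severity
weight; the weights are summed and mapped to a traffic light: zero -> green,
up to 9 -> orange, above 9 -> red.  Any positive total — including fractional
totals below 1, reachable through the formula-weighted MU-difference alert —
shows at least orange, so no raised alert is ever invisible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .config import CheckConfig
from .model import PlanIdentity, ValidationError


class AlertCode(str, enum.Enum):
    WRONG_PATIENT = "WRONG_PATIENT"
    WRONG_PLAN = "WRONG_PLAN"
    MU_DIFF = "MU_DIFF"
    STRUCTURE_DELETED = "STRUCTURE_DELETED"
    VOLUME_DIFF = "VOLUME_DIFF"
    TARGET_INCONSISTENT = "TARGET_INCONSISTENT"
    SMALL_SEGMENTS = "SMALL_SEGMENTS"
    LOW_MU_SEGMENTS = "LOW_MU_SEGMENTS"
    STRUCTURE_GAP = "STRUCTURE_GAP"


#: Codes whose weight is an arithmetic expression of the measured quantity
#: rather than a fixed number.
FORMULA_CODES = {AlertCode.MU_DIFF, AlertCode.SMALL_SEGMENTS}


@dataclass(frozen=True)
class Alert:
    code: AlertCode
    weight: float
    message: str
    subject: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError(f"alert weight must be >= 0, got {self.weight}")

    def to_dict(self) -> dict:
        return {
            "code": self.code.value,
            "weight": self.weight,
            "message": self.message,
            "subject": self.subject,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Alert":
        return cls(AlertCode(d["code"]), float(d["weight"]), d["message"], d.get("subject", ""))


def make_alert(
    code: AlertCode, message: str, subject: str = "", *,
    config: CheckConfig | None = None, measured: float | None = None,
) -> Alert:
    """Build an alert with the configured weight for its code.

    For the formula-weighted codes *measured* is the quantity the weight is
    derived from: the excess over the threshold (|ΔMU%| − 10 for MU_DIFF,
    small-segment fraction % − 10 for SMALL_SEGMENTS).
    """
    config = config or CheckConfig()
    if code in FORMULA_CODES:
        if measured is None:
            raise ValidationError(f"{code.value} requires a measured weight")
        weight = max(0.0, measured)
    else:
        weight = config.weights[code.value]
    return Alert(code=code, weight=weight, message=message, subject=subject)


@dataclass(frozen=True)
class TrafficLight:
    value: str  # green | orange | red
    total_weight: float


def compare_identity(
    orig: PlanIdentity, adapted: PlanIdentity, config: CheckConfig | None = None
) -> list[Alert]:
    """Wrong-patient / wrong-plan check.

    Comparison is case-sensitive after whitespace normalization; a mismatch
    in patient name *or* patient ID raises a single wrong-patient alert.
    """
    config = config or CheckConfig()
    o, a = orig.normalized(), adapted.normalized()
    alerts: list[Alert] = []
    if o.patient_name != a.patient_name or o.patient_id != a.patient_id:
        alerts.append(
            make_alert(
                AlertCode.WRONG_PATIENT,
                f"patient mismatch: {o.patient_name!r}/{o.patient_id!r} vs "
                f"{a.patient_name!r}/{a.patient_id!r}",
                config=config,
            )
        )
    if o.plan_name != a.plan_name:
        alerts.append(
            make_alert(
                AlertCode.WRONG_PLAN,
                f"plan name mismatch: {o.plan_name!r} vs {a.plan_name!r}",
                config=config,
            )
        )
    return alerts


def score(alerts: Iterable[Alert], config: CheckConfig | None = None) -> TrafficLight:
    """Sum alert weights and map the total to green/orange/red."""
    config = config or CheckConfig()
    total = 0.0
    for a in alerts:
        if a.weight < 0:
            raise ValidationError("negative alert weight")
        total += a.weight
    if total == 0:
        value = "green"
    elif total <= config.orange_max:
        value = "orange"
    else:
        value = "red"
    return TrafficLight(value=value, total_weight=total)
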