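"""Diagnosis engine: weight-sum scoring, classification, notifications.

The score for one patient x condition is 100 times the sum of the AHP
priority weights of the activated risk factors, so it lies in [0, 100].
Classification is positive when the score reaches the profile's
diagnosis threshold (inclusive); a score at or above the critical
threshold additionally raises a critical notification event.  Scores
are computed from the unrounded weights — the integer-percentage view
is presentation only and never changes a classification.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from . import ahp
from .errors import AhpdxError, ProfileInconsistencyError
from .risk import ActivationMap, ConditionProfile, activation_map

__all__ = [
    "DiagnosisResult",
    "NotificationEvent",
    "score",
    "classify",
    "diagnose",
    "batch_diagnose",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class DiagnosisResult:
    """Outcome of evaluating one condition profile on one lab panel."""

    patient_id: str
    condition: str
    panel_date: dt.date
    per_factor: dict  # factor_id -> (weight_percent, active)
    score: float
    classification: str
    critical: bool

    def __post_init__(self):
        if not 0.0 <= self.score <= 100.0 + 1e-9:
            raise ProfileInconsistencyError(f"score out of range: {self.score}")
        if self.critical and self.classification != POSITIVE:
            raise ProfileInconsistencyError("a critical result must be positive")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "condition": self.condition,
            "panel_date": self.panel_date.isoformat(),
            "per_factor": {
                f: {"weight_percent": wp, "active": act}
                for f, (wp, act) in self.per_factor.items()
            },
            "score": round(self.score, 2),
            "classification": self.classification,
            "critical": self.critical,
        }


@dataclass(frozen=True)
class NotificationEvent:
    """A machine-consumable event: new result, diagnosis, or critical case."""

    kind: str  # new_result | diagnosis | critical
    patient_id: str
    reference: str  # condition or panel id
    timestamp: dt.datetime
    summary: str

    def guid(self) -> str:
        ts = self.timestamp.strftime("%Y%m%dT%H%M%SZ")
        return f"ahpdx:{self.kind}:{self.patient_id}:{self.reference}:{ts}"


def score(weights: ahp.WeightVector, activation: ActivationMap) -> float:
    """Percentage score: 100 x sum of weights over active factors."""
    if set(weights.factors) != set(activation.factor_ids):
        raise ProfileInconsistencyError(
            "weight vector and activation map cover different factor sets: "
            f"{sorted(weights.factors)} vs {sorted(activation.factor_ids)}"
        )
    total = sum(
        w for f, w in zip(weights.factors, weights.weights) if activation[f].active
    )
    return 100.0 * float(total)


def classify(score_pct: float, threshold: float) -> str:
    """Positive iff the score reaches the threshold (inclusive)."""
    if not 0 <= score_pct <= 100 + 1e-9:
        raise ProfileInconsistencyError(f"score must be in [0, 100], got {score_pct}")
    if not 0 < threshold <= 100:
        raise ProfileInconsistencyError(f"threshold must be in (0, 100], got {threshold}")
    return POSITIVE if score_pct >= threshold else NEGATIVE


def diagnose(
    profile: ConditionProfile,
    patient,
    panel,
    threshold: float | None = None,
    notify=None,
) -> DiagnosisResult:
    """Run the full pipeline for one patient and panel.

    Computes weights, activates rows against reference ranges, scores,
    classifies against ``threshold`` (default: the profile's diagnosis
    threshold), and — when the score reaches the profile's critical
    threshold — passes a critical :class:`NotificationEvent` to the
    ``notify`` callback.  Pure function of its inputs apart from that
    callback.
    """
    try:
        weights = profile.priority_weights()
        act = activation_map(profile, panel, patient)
        s = score(weights, act)
        thr = profile.diagnosis_threshold if threshold is None else threshold
        cls = classify(s, thr)
        critical = s >= profile.critical_threshold and cls == POSITIVE
    except AhpdxError as exc:
        raise type(exc)(
            f"{exc} [condition={profile.condition!r}, patient={patient.patient_id!r}]"
        ) from exc

    percents = ahp.to_percentages(weights)
    result = DiagnosisResult(
        patient_id=patient.patient_id,
        condition=profile.condition,
        panel_date=panel.collected,
        per_factor={f: (percents[f], act[f].active) for f in weights.factors},
        score=s,
        classification=cls,
        critical=critical,
    )
    if critical and notify is not None:
        notify(critical_event(result))
    return result


def critical_event(result: DiagnosisResult) -> NotificationEvent:
    if not result.critical:
        raise ProfileInconsistencyError("event requires a critical result")
    return NotificationEvent(
        kind="critical",
        patient_id=result.patient_id,
        reference=result.condition,
        timestamp=dt.datetime.combine(
            result.panel_date, dt.time(0, 0), tzinfo=dt.timezone.utc
        ),
        summary="Critical result — please contact your doctor",
    )


def batch_diagnose(profile: ConditionProfile, records):
    """Diagnose a list of (patient, panel) records.

    Returns ``(results, events, errors)``: results in input order for the
    records that succeeded, critical notification events, and a list of
    (index, error) pairs for records that failed — a bad record never
    aborts the batch.  Weights are computed once per profile (cached on
    the profile), not per record.
    """
    results: list[DiagnosisResult] = []
    events: list[NotificationEvent] = []
    errors: list[tuple[int, AhpdxError]] = []
    profile.priority_weights()  # warm the cache once
    for i, (patient, panel) in enumerate(records):
        try:
            results.append(diagnose(profile, patient, panel, notify=events.append))
        except AhpdxError as exc:
            errors.append((i, exc))
    return results, events, errors
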