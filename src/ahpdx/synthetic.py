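"""Synthetic patient cohorts with controlled ground truth.

The generator produces (patient, panel, truth-label) records for a
condition profile: a fixed count of truth-positive records whose recipe
factors are forced strictly beyond their reference bounds, and
truth-negative records sampled strictly inside every range.  Because
activation is strict and out-of-range forcing overshoots the bound by a
margin, a noise-free cohort is perfectly separable by construction —
which is exactly what makes it a sharp end-to-end test bed for the
engine.  It does not emulate real biochemistry: analytes are sampled
independently and uniformly, with no measurement error model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .engine import NEGATIVE, POSITIVE, batch_diagnose
from .errors import ConfigError
from .risk import ConditionProfile, resolve_range
from .store import LabPanel, Analyte, Patient

__all__ = ["CohortSpec", "ConfusionSummary", "generate_cohort", "evaluate"]

#: relative overshoot past a bound when forcing a factor out of range
DEFAULT_MARGIN = 0.10


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``positive_recipe`` names the factors forced out of range in
    truth-positive records; their combined profile weight should reach
    the diagnosis threshold so generated positives are detectable.
    ``sampling_intervals`` optionally overrides the in-range sampling
    interval per factor; by default it is derived from the reference
    range (see :func:`in_range_interval`).
    """

    n_patients: int
    prevalence: float
    positive_recipe: tuple[str, ...]
    seed: int
    sampling_intervals: dict = field(default_factory=dict)
    margin: float = DEFAULT_MARGIN
    age_range: tuple[int, int] = (20, 44)
    collected: dt.date = dt.date(2012, 6, 1)

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be at least 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must be in [0, 1]")
        object.__setattr__(self, "positive_recipe", tuple(self.positive_recipe))

    @property
    def n_positive(self) -> int:
        # exact count, not Bernoulli draws: cohort composition is sharp
        return round(self.n_patients * self.prevalence)


@dataclass(frozen=True)
class ConfusionSummary:
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    @property
    def n(self) -> int:
        return (self.true_positive + self.false_positive
                + self.true_negative + self.false_negative)

    @property
    def sensitivity(self) -> float | None:
        denom = self.true_positive + self.false_negative
        return None if denom == 0 else self.true_positive / denom

    @property
    def specificity(self) -> float | None:
        denom = self.true_negative + self.false_positive
        return None if denom == 0 else self.true_negative / denom

    def to_dict(self) -> dict:
        return {
            "true_positive": self.true_positive,
            "false_positive": self.false_positive,
            "true_negative": self.true_negative,
            "false_negative": self.false_negative,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def in_range_interval(rng) -> tuple[float, float]:
    """The open interval a truth-negative value is sampled from.

    Both bounds present: the range itself.  Only a high bound: from half
    the bound up to it.  Only a low bound: from the bound up to twice it
    (bounds are positive analyte concentrations in practice).
    """
    if rng.low is not None and rng.high is not None:
        return rng.low, rng.high
    if rng.high is not None:
        return rng.high / 2.0, rng.high
    return rng.low, rng.low + abs(rng.low)


def out_of_range_value(rng, margin: float) -> float:
    """A value strictly beyond a bound: past high when a high bound
    exists, else below low, overshooting by ``margin`` x |bound| so the
    strict-activation boundary is never ambiguous."""
    if rng.high is not None:
        return rng.high + margin * abs(rng.high) + (margin if rng.high == 0 else 0.0)
    return rng.low - margin * abs(rng.low) - (margin if rng.low == 0 else 0.0)


def _sample_inside(rng_np, lo: float, hi: float) -> float:
    # strictly inside (lo, hi): shrink by 1% on each side
    pad = 0.01 * (hi - lo)
    return float(rng_np.uniform(lo + pad, hi - pad))


def generate_cohort(profile: ConditionProfile, spec: CohortSpec):
    """Deterministically generate ``spec.n_patients`` records.

    Returns a list of ``(Patient, LabPanel, truth)`` with ``truth`` in
    {"positive", "negative"}.  Exactly ``round(n x prevalence)`` records
    are positive; which patients they are is a seeded shuffle.  Sexes
    are sampled uniformly; ages uniformly over ``spec.age_range`` (which
    should sit inside any demographic factor's range unless that factor
    is in the recipe).
    """
    known = set(profile.factor_ids)
    for f in spec.positive_recipe:
        if f not in known:
            raise ConfigError(f"positive recipe references unknown factor {f!r}")

    rng_np = np.random.default_rng(spec.seed)
    labels = np.array([True] * spec.n_positive
                      + [False] * (spec.n_patients - spec.n_positive))
    rng_np.shuffle(labels)

    records = []
    for i, positive in enumerate(labels):
        sex = "male" if rng_np.integers(0, 2) == 0 else "female"
        lo_age, hi_age = spec.age_range
        age = int(rng_np.integers(lo_age, hi_age + 1))
        birth = dt.date(spec.collected.year - age, 6, 15)
        # keep the completed-years age exact regardless of month arithmetic
        if (spec.collected.month, spec.collected.day) < (birth.month, birth.day):
            birth = birth.replace(month=1, day=15)
        patient = Patient(f"syn-{i:04d}", sex, birth, spec.collected)

        analytes = []
        for factor in profile.factors:
            rng = resolve_range(factor.id, sex, age, profile.ranges_for(factor.id))
            force_out = positive and factor.id in spec.positive_recipe
            if factor.source == "demographic":
                # demographic recipe factors would need age resampling;
                # the shipped profiles keep recipes on lab analytes
                continue
            if factor.source == "clinical_observation":
                continue
            if force_out:
                value = out_of_range_value(rng, spec.margin)
            else:
                lo, hi = spec.sampling_intervals.get(factor.id) or in_range_interval(rng)
                value = _sample_inside(rng_np, lo, hi)
            analytes.append(Analyte(factor.id, round(value, 2), factor.units))

        panel = LabPanel(
            panel_id=f"panel-{i:04d}",
            patient_id=patient.patient_id,
            collected=spec.collected,
            analytes=tuple(analytes),
        )
        records.append((patient, panel, POSITIVE if positive else NEGATIVE))
    return records


def evaluate(profile: ConditionProfile, cohort) -> ConfusionSummary:
    """Run the diagnosis engine over a cohort and tabulate the confusion
    counts against the generator's truth labels."""
    results, _events, errors = batch_diagnose(
        profile, [(p, panel) for p, panel, _ in cohort]
    )
    if errors:
        raise ConfigError(f"{len(errors)} cohort records failed to diagnose: {errors[0]}")
    tp = fp = tn = fn = 0
    for (_, _, truth), result in zip(cohort, results):
        predicted = result.classification
        if truth == POSITIVE and predicted == POSITIVE:
            tp += 1
        elif truth == POSITIVE:
            fn += 1
        elif predicted == POSITIVE:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp, fp, tn, fn)
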