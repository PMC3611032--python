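"""Condition profiles, reference ranges and per-factor activation.

A condition profile lists the risk factors contributing to an illness,
the pairwise importance judgments (or precomputed weights) among them,
sex/age-stratified reference ranges, and the positivity/critical
thresholds.  A factor "activates" for a patient when its observed value
lies strictly beyond a bound of the applicable reference range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import ahp
from .errors import ConfigError, InvalidProfileError, MissingRangeError, UnitMismatchError

__all__ = [
    "RiskFactor",
    "ReferenceRange",
    "ConditionProfile",
    "FactorActivation",
    "ActivationMap",
    "resolve_range",
    "evaluate_activation",
    "activation_map",
    "load_profile",
    "bundled_profile_path",
]

CATEGORIES = ("elementary", "secondary")
SOURCES = ("lab_analyte", "demographic", "clinical_observation")
SEXES = ("male", "female", "any")


@dataclass(frozen=True)
class RiskFactor:
    """A variable contributing to a diagnosis.

    Elementary factors are lab analytes; secondary factors are
    demographic attributes (e.g. age) or clinical observations
    (symptoms recorded as present/absent).
    """

    id: str
    name: str = ""
    category: str = "elementary"
    source: str = "lab_analyte"
    units: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidProfileError(f"unknown factor category {self.category!r}")
        if self.source not in SOURCES:
            raise InvalidProfileError(f"unknown factor source {self.source!r}")
        if self.category == "elementary" and self.source != "lab_analyte":
            raise InvalidProfileError(
                f"elementary factor {self.id!r} must have source lab_analyte"
            )
        if self.category == "secondary" and self.source == "lab_analyte":
            raise InvalidProfileError(
                f"secondary factor {self.id!r} must be demographic or clinical_observation"
            )
        if not self.name:
            object.__setattr__(self, "name", self.id)


@dataclass(frozen=True)
class ReferenceRange:
    """Low/high bounds for a factor, optionally sex- and age-stratified.

    A missing bound means that side is unbounded.  ``sex="any"`` matches
    both sexes; absent age bounds match every age.
    """

    factor_id: str
    sex: str = "any"
    age_min: float | None = None
    age_max: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise InvalidProfileError(f"range sex must be one of {SEXES}, got {self.sex!r}")
        if self.low is None and self.high is None:
            raise InvalidProfileError(
                f"range for {self.factor_id!r} needs at least one of low/high"
            )
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise InvalidProfileError(f"range for {self.factor_id!r}: low must be < high")
        if (
            self.age_min is not None
            and self.age_max is not None
            and self.age_min > self.age_max
        ):
            raise InvalidProfileError(f"range for {self.factor_id!r}: age_min > age_max")

    def matches(self, sex: str, age: float | None) -> bool:
        if self.sex != "any" and self.sex != sex:
            return False
        if self.age_min is not None or self.age_max is not None:
            if age is None:
                return False
            if self.age_min is not None and age < self.age_min:
                return False
            if self.age_max is not None and age > self.age_max:
                return False
        return True

    @property
    def _age_span(self) -> float:
        lo = self.age_min if self.age_min is not None else -math.inf
        hi = self.age_max if self.age_max is not None else math.inf
        return hi - lo


@dataclass(frozen=True)
class FactorActivation:
    """Activation outcome for one factor: active flag, observed value
    (absent for unobserved factors) and the range that was applied."""

    factor_id: str
    active: bool
    observed_value: float | None = None
    range_used: ReferenceRange | None = None
    observed: bool = True


@dataclass(frozen=True)
class ActivationMap:
    """Per-factor activation results for one patient x condition."""

    entries: dict[str, FactorActivation]

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def active_factors(self) -> tuple[str, ...]:
        return tuple(f for f, e in self.entries.items() if e.active)

    def __getitem__(self, factor_id: str) -> FactorActivation:
        return self.entries[factor_id]


@dataclass(frozen=True)
class ConditionProfile:
    """An illness's risk factors, judgments/weights, ranges and thresholds."""

    condition: str
    factors: tuple[RiskFactor, ...]
    judgments: tuple = ()
    weights: ahp.WeightVector | None = None
    ranges: tuple[ReferenceRange, ...] = ()
    diagnosis_threshold: float = 80.0
    critical_threshold: float = 95.0
    _weight_cache: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "ranges", tuple(self.ranges))
        object.__setattr__(self, "judgments", tuple(tuple(j) for j in self.judgments))
        ids = [f.id for f in self.factors]
        if len(set(ids)) != len(ids):
            raise InvalidProfileError("factor ids must be unique")
        if not self.judgments and self.weights is None:
            raise InvalidProfileError("profile needs judgments or precomputed weights")
        if self.weights is not None and tuple(self.weights.factors) != tuple(ids):
            raise InvalidProfileError("weight vector factors must match profile factors")
        if not 0 < self.diagnosis_threshold <= self.critical_threshold <= 100:
            raise InvalidProfileError(
                "thresholds must satisfy 0 < diagnosis <= critical <= 100"
            )
        ranged = {r.factor_id for r in self.ranges}
        for f in self.factors:
            if f.source == "clinical_observation":
                continue  # symptoms activate via an explicit boolean observation
            if f.id not in ranged:
                raise InvalidProfileError(f"factor {f.id!r} has no reference range")
        for r in self.ranges:
            if r.factor_id not in set(ids):
                raise InvalidProfileError(f"range references unknown factor {r.factor_id!r}")

    @property
    def factor_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.factors)

    def factor(self, factor_id: str) -> RiskFactor:
        for f in self.factors:
            if f.id == factor_id:
                return f
        raise KeyError(factor_id)

    def ranges_for(self, factor_id: str) -> tuple[ReferenceRange, ...]:
        return tuple(r for r in self.ranges if r.factor_id == factor_id)

    def priority_weights(self, tol: float = 1e-6, max_iter: int = 20) -> ahp.WeightVector:
        """Weights from the profile: precomputed if given, else derived
        from the judgments (cached, so batch use computes them once)."""
        if self.weights is not None:
            return self.weights
        if not self._weight_cache:
            matrix = ahp.build_matrix(self.factor_ids, self.judgments)
            self._weight_cache.append(ahp.principal_weights(matrix, tol=tol, max_iter=max_iter))
        return self._weight_cache[0]


def resolve_range(
    factor_id: str, sex: str, age: float | None, ranges
) -> ReferenceRange:
    """Pick the most specific reference range for the given demographics.

    An exact-sex range beats ``sex="any"``; among equally sex-specific
    candidates a narrower age span wins; remaining ties go to the first
    range in declaration order, so the choice is deterministic.
    """
    candidates = [r for r in ranges if r.factor_id == factor_id and r.matches(sex, age)]
    if not candidates:
        raise MissingRangeError(
            f"no reference range for factor {factor_id!r} matches sex={sex}, age={age}"
        )
    return min(
        candidates,
        key=lambda r: (r.sex == "any", r._age_span),
    )


def evaluate_activation(value: float, range_: ReferenceRange) -> bool:
    """True iff ``value`` lies strictly beyond a bound of the range.

    Boundary values are inactive: activation requires value < low or
    value > high.
    """
    if not math.isfinite(value):
        raise InvalidProfileError(f"observed value must be finite, got {value!r}")
    if range_.low is not None and value < range_.low:
        return True
    if range_.high is not None and value > range_.high:
        return True
    return False


def _age_at(birth_date, on_date) -> int:
    """Completed years between birth_date and on_date."""
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def activation_map(profile: ConditionProfile, panel, patient) -> ActivationMap:
    """Evaluate every profile factor against a patient's lab panel.

    Elementary factors look up their analyte in the panel (name match is
    case-insensitive) and test the resolved reference range.  Demographic
    factors evaluate patient attributes — age is computed at the panel's
    collection date so results are reproducible.  Clinical-observation
    factors activate via an explicit boolean in the panel's observations.
    Factors absent from the panel are inactive and flagged unobserved.
    """
    if panel.patient_id != patient.patient_id:
        raise InvalidProfileError(
            f"panel {panel.panel_id!r} belongs to {panel.patient_id!r}, "
            f"not {patient.patient_id!r}"
        )
    age = _age_at(patient.birth_date, panel.collected)
    analytes = {a.name.lower(): a for a in panel.analytes}
    observations = {o.name.lower(): o.present for o in panel.observations}

    entries: dict[str, FactorActivation] = {}
    for f in profile.factors:
        if f.source == "clinical_observation":
            if f.id.lower() in observations:
                entries[f.id] = FactorActivation(f.id, observations[f.id.lower()])
            else:
                entries[f.id] = FactorActivation(f.id, False, observed=False)
            continue

        if f.source == "demographic":
            # age is currently the only supported demographic attribute
            value = float(age)
        else:
            analyte = analytes.get(f.id.lower())
            if analyte is None:
                entries[f.id] = FactorActivation(f.id, False, observed=False)
                continue
            if f.units and analyte.units and f.units.lower() != analyte.units.lower():
                raise UnitMismatchError(
                    f"factor {f.id!r} expects units {f.units!r} "
                    f"but panel reports {analyte.units!r}"
                )
            value = float(analyte.value)

        rng = resolve_range(f.id, patient.sex, age, profile.ranges_for(f.id))
        entries[f.id] = FactorActivation(
            f.id, evaluate_activation(value, rng), observed_value=value, range_used=rng
        )
    return ActivationMap(entries)


def _opt_float(mapping, key):
    v = mapping.get(key)
    return None if v is None else float(v)


def profile_from_dict(data: dict) -> ConditionProfile:
    """Build a :class:`ConditionProfile` from a parsed config mapping."""
    try:
        factors = tuple(
            RiskFactor(
                id=str(f["id"]),
                name=str(f.get("name", "")),
                category=str(f.get("category", "elementary")),
                source=str(f.get("source", "lab_analyte")),
                units=str(f.get("units", "")),
            )
            for f in data["factors"]
        )
        judgments = tuple(
            (str(j[0]), str(j[1]), ahp.parse_ratio(j[2])) for j in data.get("judgments", [])
        )
        ranges = tuple(
            ReferenceRange(
                factor_id=str(r["factor_id"]),
                sex=str(r.get("sex", "any")),
                age_min=_opt_float(r, "age_min"),
                age_max=_opt_float(r, "age_max"),
                low=_opt_float(r, "low"),
                high=_opt_float(r, "high"),
            )
            for r in data.get("ranges", [])
        )
        return ConditionProfile(
            condition=str(data["condition"]),
            factors=factors,
            judgments=judgments,
            ranges=ranges,
            diagnosis_threshold=float(data.get("diagnosis_threshold", 80)),
            critical_threshold=float(data.get("critical_threshold", 95)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid profile config: {exc}") from exc


def load_profile(path) -> ConditionProfile:
    """Load a condition profile from a YAML (or JSON) config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"profile file {path} does not contain a mapping")
    return profile_from_dict(data)


def bundled_profile_path(name: str = "hyperglycemia") -> Path:
    """Path to a profile shipped with the package."""
    p = Path(__file__).parent / "profiles" / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"no bundled profile named {name!r}")
    return p
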