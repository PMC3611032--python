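"""Patient/lab-panel data model, XML panel dialect, and keyed storage.

Panels travel as small XML documents in the ``ahpdx-panel-1`` dialect::

    <panel dialect="ahpdx-panel-1" patient="p001" id="panel-1"
           collected="2012-06-01">
      <analyte name="HDL" value="45" units="mg/dL"/>
      <observation name="polyuria" present="true"/>
      <notes>doctor's findings and/or reminders</notes>
    </panel>

Storage is a single-file, line-delimited JSON record store keyed by
(patient_id, panel_id): insert is idempotent for identical content and
rejects conflicting re-inserts; listing is chronological, newest first.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .errors import (
    ConflictError,
    InvalidProfileError,
    NotFoundError,
    PanelParseError,
    PanelSchemaError,
)

__all__ = [
    "Patient",
    "Analyte",
    "Observation",
    "LabPanel",
    "parse_panel_xml",
    "write_panel_xml",
    "RecordStore",
    "list_panels",
    "PANEL_DIALECT",
]

PANEL_DIALECT = "ahpdx-panel-1"


def _parse_date(text: str, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise PanelSchemaError(f"{what} is not an ISO date: {text!r}") from exc


@dataclass(frozen=True)
class Patient:
    """Demographics captured when a client registers."""

    patient_id: str
    sex: str
    birth_date: dt.date
    registered: dt.date

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise InvalidProfileError(f"patient sex must be male/female, got {self.sex!r}")
        if self.birth_date > self.registered:
            raise InvalidProfileError("birth_date must not be after registration date")


@dataclass(frozen=True)
class Analyte:
    name: str
    value: float
    units: str = ""

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise InvalidProfileError(f"analyte {self.name!r} value must be finite")


@dataclass(frozen=True)
class Observation:
    name: str
    present: bool


@dataclass(frozen=True)
class LabPanel:
    """One dated set of analyte measurements for one patient."""

    panel_id: str
    patient_id: str
    collected: dt.date
    analytes: tuple[Analyte, ...] = ()
    observations: tuple[Observation, ...] = ()
    notes: str = ""

    def __post_init__(self):
        object.__setattr__(self, "analytes", tuple(self.analytes))
        object.__setattr__(self, "observations", tuple(self.observations))
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            raise InvalidProfileError("analyte names must be unique within a panel")


def parse_panel_xml(document: str) -> LabPanel:
    """Parse a panel document in the ``ahpdx-panel-1`` dialect.

    Unknown child elements are ignored with a warning.  Malformed XML
    raises :class:`PanelParseError` with line information; dialect
    violations raise :class:`PanelSchemaError` naming the element.
    """
    try:
        root = etree.fromstring(document.encode())
    except etree.XMLSyntaxError as exc:
        raise PanelParseError(f"malformed panel XML: {exc}") from exc

    if root.tag != "panel":
        raise PanelSchemaError(f"root element must be <panel>, got <{root.tag}>")
    dialect = root.get("dialect")
    if dialect != PANEL_DIALECT:
        raise PanelSchemaError(f"unsupported panel dialect {dialect!r}")
    patient = root.get("patient")
    if not patient:
        raise PanelSchemaError("<panel> is missing the required 'patient' attribute")
    collected_raw = root.get("collected")
    if not collected_raw:
        raise PanelSchemaError("<panel> is missing the required 'collected' attribute")
    collected = _parse_date(collected_raw, "'collected' attribute")
    panel_id = root.get("id") or f"{patient}-{collected.isoformat()}"

    analytes: list[Analyte] = []
    seen: set[str] = set()
    observations: list[Observation] = []
    notes = ""
    for child in root:
        if child.tag is etree.Comment:
            continue
        if child.tag == "analyte":
            name = child.get("name")
            if not name:
                raise PanelSchemaError("<analyte> is missing the required 'name' attribute")
            if name in seen:
                raise PanelSchemaError(f"duplicate <analyte name={name!r}>")
            seen.add(name)
            raw = child.get("value")
            if raw is None:
                raise PanelSchemaError(f"<analyte name={name!r}> is missing 'value'")
            try:
                value = float(raw)
            except ValueError as exc:
                raise PanelSchemaError(
                    f"<analyte name={name!r}> value {raw!r} is not a number"
                ) from exc
            analytes.append(Analyte(name, value, child.get("units", "")))
        elif child.tag == "observation":
            name = child.get("name")
            if not name:
                raise PanelSchemaError("<observation> is missing 'name'")
            present = (child.get("present", "false").lower() == "true")
            observations.append(Observation(name, present))
        elif child.tag == "notes":
            notes = child.text or ""
        else:
            warnings.warn(f"ignoring unknown element <{child.tag}> in panel document",
                          stacklevel=2)
    return LabPanel(panel_id, patient, collected, tuple(analytes),
                    tuple(observations), notes)


def _fmt_value(v: float) -> str:
    return repr(float(v))


def write_panel_xml(panel: LabPanel) -> str:
    """Serialize a panel to the canonical dialect.

    Output is deterministic: analytes are sorted by name, observations
    by name, and text content is XML-escaped.
    """
    lines = [
        f'<panel dialect="{PANEL_DIALECT}" patient={quoteattr(panel.patient_id)} '
        f'id={quoteattr(panel.panel_id)} collected="{panel.collected.isoformat()}">'
    ]
    for a in sorted(panel.analytes, key=lambda a: a.name):
        lines.append(
            f"  <analyte name={quoteattr(a.name)} value=\"{_fmt_value(a.value)}\""
            f" units={quoteattr(a.units)}/>"
        )
    for o in sorted(panel.observations, key=lambda o: o.name):
        present = "true" if o.present else "false"
        lines.append(f'  <observation name={quoteattr(o.name)} present="{present}"/>')
    if panel.notes:
        lines.append(f"  <notes>{escape(panel.notes)}</notes>")
    lines.append("</panel>")
    return "\n".join(lines) + "\n"


def _panel_record(panel: LabPanel) -> dict:
    d = asdict(panel)
    d["collected"] = panel.collected.isoformat()
    return d


def _panel_from_record(d: dict) -> LabPanel:
    return LabPanel(
        panel_id=d["panel_id"],
        patient_id=d["patient_id"],
        collected=dt.date.fromisoformat(d["collected"]),
        analytes=tuple(Analyte(**a) for a in d["analytes"]),
        observations=tuple(Observation(**o) for o in d["observations"]),
        notes=d.get("notes", ""),
    )


class RecordStore:
    """Line-delimited JSON store of patients and panels.

    Each line is one record: ``{"kind": "patient"|"panel", ...}``.  Keys
    are ``patient_id`` for patients and ``(patient_id, panel_id)`` for
    panels.  Re-inserting identical content is a no-op; conflicting
    content for an existing key raises :class:`ConflictError`.
    """

    def __init__(self, path):
        self.path = Path(path)
        self._patients: dict[str, dict] = {}
        self._panels: dict[tuple[str, str], dict] = {}
        if self.path.exists():
            self._load()

    def _load(self):
        for line in self.path.read_text().splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            if rec["kind"] == "patient":
                self._patients[rec["patient_id"]] = rec
            elif rec["kind"] == "panel":
                self._panels[(rec["patient_id"], rec["panel_id"])] = rec

    def _append(self, rec: dict):
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    # -- patients ---------------------------------------------------------

    def add_patient(self, patient: Patient):
        rec = {
            "kind": "patient",
            "patient_id": patient.patient_id,
            "sex": patient.sex,
            "birth_date": patient.birth_date.isoformat(),
            "registered": patient.registered.isoformat(),
        }
        existing = self._patients.get(patient.patient_id)
        if existing is not None:
            if existing == rec:
                return
            raise ConflictError(f"patient {patient.patient_id!r} already exists "
                                "with different data")
        self._patients[patient.patient_id] = rec
        self._append(rec)

    def get_patient(self, patient_id: str) -> Patient:
        rec = self._patients.get(patient_id)
        if rec is None:
            raise NotFoundError(f"unknown patient {patient_id!r}")
        return Patient(
            patient_id=rec["patient_id"],
            sex=rec["sex"],
            birth_date=dt.date.fromisoformat(rec["birth_date"]),
            registered=dt.date.fromisoformat(rec["registered"]),
        )

    def has_patient(self, patient_id: str) -> bool:
        return patient_id in self._patients

    # -- panels -----------------------------------------------------------

    def add_panel(self, panel: LabPanel):
        rec = {"kind": "panel", **_panel_record(panel)}
        key = (panel.patient_id, panel.panel_id)
        existing = self._panels.get(key)
        if existing is not None:
            if existing == rec:
                return
            raise ConflictError(
                f"panel {panel.panel_id!r} for patient {panel.patient_id!r} "
                "already exists with different content"
            )
        self._panels[key] = rec
        self._append(rec)

    def get_panel(self, patient_id: str, panel_id: str) -> LabPanel:
        rec = self._panels.get((patient_id, panel_id))
        if rec is None:
            raise NotFoundError(f"unknown panel {panel_id!r} for patient {patient_id!r}")
        return _panel_from_record(rec)

    def list_panels(self, patient_id: str) -> list[LabPanel]:
        return list_panels(self, patient_id)


def list_panels(store: RecordStore, patient_id: str) -> list[LabPanel]:
    """All panels for a patient, newest collection date first, ties
    broken by ascending panel_id (a total order)."""
    if not store.has_patient(patient_id):
        raise NotFoundError(f"unknown patient {patient_id!r}")
    panels = [
        _panel_from_record(rec)
        for (pid, _), rec in store._panels.items()
        if pid == patient_id
    ]
    panels.sort(key=lambda p: (-p.collected.toordinal(), p.panel_id))
    return panels
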