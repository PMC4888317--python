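"""Template-driven clinical-record structured reports.

Per-patient clinical metadata (demographics, risk factors, diagnosis,
treatment, outcomes) is encoded as one structured report per patient,
following a declarative private template (a "Clinical Data Report" root
container with subordinate sections).  The clinical SR objects live in a
study *separate* from the imaging study, with both the study and series
description set to "Clinical Data", but share the patient-level composite
context so they bind to the imaging objects.

Input is the tab-delimited export of a clinical database, one row per
patient, mapped to record fields through a configurable column map.
Measurements made on images for clinical purposes are deliberately not
imported — only history, treatment and outcome fields.
"""

from __future__ import annotations

import csv
import importlib.resources
import random
import warnings
from dataclasses import dataclass, fields as dataclass_fields
from datetime import date, datetime
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .core import CompositeContext, TerminologyTable
from .errors import MetadataError, TemplateError
from .sr import NumValue, SRContentItem, SRDocument, parse_sr, serialize_sr

__all__ = [
    "ClinicalRecord",
    "TemplateRow",
    "TemplateDefinition",
    "load_default_template",
    "parse_clinical_table",
    "encode_clinical_sr",
    "decode_clinical_sr",
    "DEFAULT_COLUMN_MAP",
]

CLINICAL_DESCRIPTION = "Clinical Data"


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical history, treatment and outcome."""

    patient_id: str
    sex: str | None = None  # "M" / "F"
    age: float | None = None  # years at diagnosis
    smoking: str | None = None  # "yes" / "no"
    alcohol: str | None = None  # "yes" / "no"
    pathology: str | None = None
    stage: str | None = None
    primary_site: str | None = None
    nodal_sites: str | None = None
    surgery: str | None = None  # "yes" / "no"
    radiation_dose_gy: float | None = None
    chemotherapy: str | None = None  # "yes" / "no"
    followup_date: date | None = None
    status: str | None = None  # "alive" / "dead"
    death_date: date | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise MetadataError("clinical record requires a patient id")
        if self.status == "alive" and self.death_date is not None:
            raise MetadataError("a patient alive at follow-up cannot have a death date")
        if self.death_date is not None and self.followup_date is not None \
                and self.death_date < self.followup_date:
            raise MetadataError("death date precedes the recorded follow-up date")


@dataclass(frozen=True)
class TemplateRow:
    level: int
    value_type: str
    concept_role: str
    requirement: str  # M / U / C
    relationship: str | None = None
    field: str | None = None
    units_role: str | None = None
    value_map: Mapping[str, str] | None = None  # record value -> concept role


@dataclass(frozen=True)
class TemplateDefinition:
    template_id: str
    rows: tuple[TemplateRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise TemplateError("template has no rows")
        first = self.rows[0]
        if first.level != 0 or first.value_type != "CONTAINER":
            raise TemplateError("template row 1 must be a level-0 root CONTAINER")
        prev = 0
        for i, row in enumerate(self.rows[1:], start=2):
            if row.level < 1 or row.level > prev + 1:
                raise TemplateError(f"template row {i}: nesting level {row.level} ill-formed")
            prev = row.level

    @classmethod
    def from_file(cls, path) -> "TemplateDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        rows = tuple(TemplateRow(**r) for r in raw["rows"])
        return cls(template_id=str(raw.get("template_id", "PQI_2000")), rows=rows)


def load_default_template() -> TemplateDefinition:
    ref = importlib.resources.files("petqi").joinpath("data/clinical_template.yaml")
    with importlib.resources.as_file(ref) as path:
        return TemplateDefinition.from_file(path)


DEFAULT_COLUMN_MAP: dict[str, str] = {
    f.name: f.name for f in dataclass_fields(ClinicalRecord)
}

_DATE_FIELDS = ("followup_date", "death_date")
_FLOAT_FIELDS = ("age", "radiation_dose_gy")


def parse_clinical_table(path, column_map: Mapping[str, str] | None = None
                         ) -> list[ClinicalRecord]:
    """Parse a tab-delimited clinical export, one record per patient row.

    *column_map* maps record field names to file column names.  Columns not
    named by the map are rejected; optional fields may be blank.  Dates are
    ISO ``YYYY-MM-DD``.
    """
    column_map = dict(column_map or DEFAULT_COLUMN_MAP)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        known = set(column_map.values())
        unknown = [c for c in header if c not in known]
        if unknown:
            raise MetadataError(f"unknown columns in clinical table: {unknown}")
        if column_map["patient_id"] not in header:
            raise MetadataError(
                f"mandatory column {column_map['patient_id']!r} missing from clinical table"
            )
        records = []
        seen: set[str] = set()
        for line_no, row in enumerate(reader, start=2):
            kwargs: dict = {}
            for field_name, column in column_map.items():
                raw = (row.get(column) or "").strip()
                if raw == "":
                    continue
                if field_name in _DATE_FIELDS:
                    try:
                        kwargs[field_name] = datetime.strptime(raw, "%Y-%m-%d").date()
                    except ValueError:
                        raise MetadataError(
                            f"line {line_no}: malformed date {raw!r} in column {column!r}"
                        ) from None
                elif field_name in _FLOAT_FIELDS:
                    try:
                        kwargs[field_name] = float(raw)
                    except ValueError:
                        raise MetadataError(
                            f"line {line_no}: malformed number {raw!r} in column {column!r}"
                        ) from None
                else:
                    kwargs[field_name] = raw
            if "status" not in kwargs:
                # no recorded death implies alive at follow-up
                kwargs["status"] = "dead" if kwargs.get("death_date") else "alive"
            pid = kwargs.get("patient_id", "")
            if pid in seen:
                raise MetadataError(f"line {line_no}: duplicate patient id {pid!r}")
            seen.add(pid)
            records.append(ClinicalRecord(**kwargs))
    return records


def _encode_leaf(row: TemplateRow, record: ClinicalRecord,
                 terminology: TerminologyTable) -> SRContentItem | None:
    raw = getattr(record, row.field) if row.field else None
    if raw is None:
        if row.requirement == "M":
            raise TemplateError(
                f"mandatory item {row.concept_role!r} has no value in record "
                f"{record.patient_id!r}"
            )
        return None
    concept = terminology.lookup(row.concept_role)
    if row.value_type == "CODE":
        role = (row.value_map or {}).get(str(raw))
        if role is None:
            raise TemplateError(
                f"value {raw!r} for {row.concept_role!r} is outside the template value set"
            )
        value: object = terminology.lookup(role)
    elif row.value_type == "NUM":
        value = NumValue.from_float(float(raw), terminology.lookup(row.units_role))
    elif row.value_type == "DATETIME":
        value = raw.strftime("%Y%m%d") if isinstance(raw, date) else str(raw)
    else:  # TEXT
        value = str(raw)
    return SRContentItem(row.value_type, concept, value, row.relationship or "CONTAINS")


def build_clinical_tree(record: ClinicalRecord, template: TemplateDefinition,
                        terminology: TerminologyTable) -> SRContentItem:
    """Instantiate the template for one record; empty optional sections elided."""
    root_row = template.rows[0]
    # children grouped per container row, assembled bottom-up
    stack: list[tuple[TemplateRow, list[SRContentItem]]] = [(root_row, [])]

    def pop_container() -> None:
        row, children = stack.pop()
        if children or row.requirement == "M":
            stack[-1][1].append(
                SRContentItem("CONTAINER", terminology.lookup(row.concept_role),
                              relationship=row.relationship or "CONTAINS",
                              children=tuple(children))
            )

    for row in template.rows[1:]:
        while stack[-1][0].level >= row.level:
            pop_container()
        if row.value_type == "CONTAINER":
            stack.append((row, []))
        else:
            item = _encode_leaf(row, record, terminology)
            if item is not None:
                stack[-1][1].append(item)
    while len(stack) > 1:
        pop_container()
    _root_row, children = stack[0]
    return SRContentItem("CONTAINER", terminology.lookup(root_row.concept_role),
                         children=tuple(children))


def encode_clinical_sr(
    record: ClinicalRecord,
    template: TemplateDefinition,
    context: CompositeContext,
    terminology: TerminologyTable,
    path,
    rng: random.Random | None = None,
) -> SRDocument:
    """Encode one patient's record as an SR file in the "Clinical Data" study."""
    if context.patient_id != record.patient_id:
        raise MetadataError(
            f"context patient id {context.patient_id!r} does not match record "
            f"{record.patient_id!r}"
        )
    from dataclasses import replace

    context = replace(
        context,
        study_description=CLINICAL_DESCRIPTION,
        series_description=CLINICAL_DESCRIPTION,
        modality="SR",
    )
    tree = build_clinical_tree(record, template, terminology)
    doc = SRDocument(context=context, tree=tree)
    return serialize_sr(doc, Path(path), rng, template_id=template.template_id,
                        mapping_resource="99PQI")


def decode_clinical_sr(path, template: TemplateDefinition,
                       terminology: TerminologyTable) -> ClinicalRecord:
    """Invert :func:`encode_clinical_sr` for all template-covered fields.

    Unrecognized content items produce a warning, not a failure; a wrong
    root concept is a hard error.
    """
    doc = parse_sr(path)
    root_row = template.rows[0]
    root_concept = terminology.lookup(root_row.concept_role)
    root = doc.tree
    if (root.concept_name.value, root.concept_name.scheme) != (
            root_concept.value, root_concept.scheme):
        raise TemplateError(
            f"wrong root concept {root.concept_name} (expected {root_concept})"
        )

    code_key = lambda c: (c.value, c.scheme)
    concept_of = {code_key(terminology.lookup(r.concept_role)): r for r in template.rows}

    kwargs: dict = {"patient_id": doc.context.patient_id}
    reverse_maps: dict[str, dict] = {}
    for row in template.rows:
        if row.value_map:
            reverse_maps[row.concept_role] = {
                code_key(terminology.lookup(role)): raw for raw, role in row.value_map.items()
            }

    def walk(item: SRContentItem) -> None:
        for child in item.children:
            row = concept_of.get(code_key(child.concept_name))
            if row is None:
                warnings.warn(
                    f"unrecognized content item {child.concept_name} in clinical SR",
                    stacklevel=2,
                )
                continue
            if child.value_type == "CONTAINER":
                walk(child)
                continue
            if row.field is None:
                continue
            if row.value_type == "CODE":
                kwargs[row.field] = reverse_maps[row.concept_role].get(
                    code_key(child.value)
                )
            elif row.value_type == "NUM":
                kwargs[row.field] = child.value.value
            elif row.value_type == "DATETIME":
                kwargs[row.field] = datetime.strptime(str(child.value)[:8], "%Y%m%d").date()
            else:
                kwargs[row.field] = str(child.value)

    walk(root)
    return ClinicalRecord(**kwargs)
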