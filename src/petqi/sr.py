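"""TID 1500 measurement-report structured reports.

A DICOM SR document is a tree of content items; each non-container item is
a name-value pair whose name is a coded concept.  The measurement report
root template (TID 1500) arranges ROI measurements as: a root CONTAINER,
an Image Library listing the source images (grouped so acquisition
attributes are factored to group level), and an Imaging Measurements
section holding one measurement group per ROI.  Each group carries its
observation context — tracking identifier and UID, activity session and
time point (positive integers as strings), finding type and site, the
referenced segment of the SEG object, the segmented source series and the
real-world value map used — followed by the NUM measurement items, with
derivation modifiers attached via (121401, DCM, "Derivation").  Omitted
measurements produce no NUM item at all.

Serialization order is deterministic (context items before measurements,
measurements in panel order) so text dumps are byte-stable.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from pydicom import dcmread
from pydicom.dataset import Dataset

from . import _dicomio
from .core import CodedConcept, CompositeContext, TerminologyTable, is_valid_uid, make_uid
from .errors import DicomParseError, TemplateError
from .indices import Measurement

__all__ = [
    "VALUE_TYPES",
    "RELATIONSHIPS",
    "NumValue",
    "ImageReference",
    "SRContentItem",
    "MeasurementGroup",
    "SRDocument",
    "build_measurement_report",
    "serialize_sr",
    "parse_sr",
    "dump_sr_tree",
    "sr_to_csv",
    "CSV_HEADER",
]

VALUE_TYPES = ("CONTAINER", "CODE", "NUM", "TEXT", "UIDREF", "IMAGE", "PNAME", "DATETIME")
RELATIONSHIPS = (
    "CONTAINS",
    "HAS CONCEPT MOD",
    "HAS OBS CONTEXT",
    "HAS ACQ CONTEXT",
    "INFERRED FROM",
    "SELECTED FROM",
)


def format_ds(value: float) -> str:
    """Decimal-string rendering of a float within the 16-character DS limit."""
    s = f"{float(value):.10g}"
    return s


@dataclass(frozen=True)
class NumValue:
    """Numeric payload of a NUM item: decimal string plus UCUM units concept."""

    value_str: str
    units: CodedConcept

    @classmethod
    def from_float(cls, value: float, units: CodedConcept) -> "NumValue":
        return cls(value_str=format_ds(value), units=units)

    @property
    def value(self) -> float:
        return float(self.value_str)


@dataclass(frozen=True)
class ImageReference:
    sop_class_uid: str
    sop_instance_uid: str
    segment_number: int | None = None


@dataclass(frozen=True)
class SRContentItem:
    """One node of the SR content tree."""

    value_type: str
    concept_name: CodedConcept
    value: object = None
    relationship: str | None = None
    children: tuple["SRContentItem", ...] = ()

    def __post_init__(self) -> None:
        if self.value_type not in VALUE_TYPES:
            raise TemplateError(f"invalid value type {self.value_type!r}")
        if self.relationship is not None and self.relationship not in RELATIONSHIPS:
            raise TemplateError(f"invalid relationship {self.relationship!r}")
        if self.value_type == "NUM" and not isinstance(self.value, NumValue):
            raise TemplateError("NUM items carry a NumValue (numeric value + UCUM units)")

    def iter_depth_first(self, depth: int = 0):
        yield depth, self
        for child in self.children:
            yield from child.iter_depth_first(depth + 1)


@dataclass(frozen=True)
class MeasurementGroup:
    """Context and measurements for one tracked, segment-referenced ROI."""

    tracking_id: str
    tracking_uid: str
    activity_session: int
    time_point: int
    referenced_seg_uid: str
    segment_number: int
    source_series_uid: str
    rwvm_uid: str
    measurements: tuple[Measurement, ...]
    finding_type: CodedConcept | None = None
    finding_site: CodedConcept | None = None

    def __post_init__(self) -> None:
        if not self.tracking_id:
            raise TemplateError("measurement group requires a tracking identifier")
        if not is_valid_uid(self.tracking_uid):
            raise TemplateError(f"malformed tracking UID {self.tracking_uid!r}")
        if self.segment_number < 1:
            raise TemplateError("segment_number must be >= 1")
        if self.activity_session < 1 or self.time_point < 1:
            raise TemplateError("activity session and time point are positive integers")


@dataclass(frozen=True)
class SRDocument:
    """A content tree plus the composite context it is encoded under."""

    context: CompositeContext
    tree: SRContentItem
    sop_instance_uid: str = ""


def build_measurement_report(
    groups: Sequence[MeasurementGroup],
    context: CompositeContext,
    terminology: TerminologyTable,
    image_library: Sequence[tuple[str, Sequence[ImageReference]]] = (),
) -> SRDocument:
    """Assemble the TID 1500 content tree for the given measurement groups.

    *image_library* lists (series description label, image references) per
    source series; common attributes are factored to the group container.
    """
    if not groups:
        raise TemplateError("a measurement report requires at least one measurement group")

    lib_children = []
    for _label, refs in image_library:
        entries = tuple(
            SRContentItem(
                value_type="IMAGE",
                concept_name=terminology.lookup("sr.image_library_entry"),
                value=ref,
                relationship="CONTAINS",
            )
            for ref in refs
        )
        lib_children.append(
            SRContentItem(
                value_type="CONTAINER",
                concept_name=terminology.lookup("sr.image_library_group"),
                relationship="CONTAINS",
                children=entries,
            )
        )
    library = SRContentItem(
        value_type="CONTAINER",
        concept_name=terminology.lookup("sr.image_library"),
        relationship="CONTAINS",
        children=tuple(lib_children),
    )

    group_items = []
    for group in groups:
        reported = [m for m in group.measurements if not m.omitted]
        if not reported:
            raise TemplateError(
                f"measurement group {group.tracking_id!r} has no reportable measurements"
            )
        children: list[SRContentItem] = [
            SRContentItem("TEXT", terminology.lookup("sr.tracking_id"),
                          group.tracking_id, "HAS OBS CONTEXT"),
            SRContentItem("UIDREF", terminology.lookup("sr.tracking_uid"),
                          group.tracking_uid, "HAS OBS CONTEXT"),
            SRContentItem("TEXT", terminology.lookup("sr.activity_session"),
                          str(group.activity_session), "HAS OBS CONTEXT"),
            SRContentItem("TEXT", terminology.lookup("sr.time_point"),
                          str(group.time_point), "HAS OBS CONTEXT"),
        ]
        if group.finding_type is not None:
            children.append(SRContentItem("CODE", terminology.lookup("sr.finding"),
                                          group.finding_type, "HAS CONCEPT MOD"))
        if group.finding_site is not None:
            children.append(SRContentItem("CODE", terminology.lookup("sr.finding_site"),
                                          group.finding_site, "HAS CONCEPT MOD"))
        children.append(
            SRContentItem(
                "IMAGE",
                terminology.lookup("sr.referenced_segment"),
                ImageReference(_dicomio.SEGMENTATION_STORAGE, group.referenced_seg_uid,
                               group.segment_number),
                "CONTAINS",
            )
        )
        children.append(SRContentItem("UIDREF", terminology.lookup("sr.source_series"),
                                      group.source_series_uid, "CONTAINS"))
        children.append(SRContentItem("UIDREF", terminology.lookup("sr.rwvm_ref"),
                                      group.rwvm_uid, "CONTAINS"))
        for m in reported:
            modifiers = ()
            if m.derivation_role:
                modifiers = (
                    SRContentItem("CODE", terminology.lookup("derivation"),
                                  terminology.lookup(m.derivation_role), "HAS CONCEPT MOD"),
                )
            children.append(
                SRContentItem(
                    "NUM",
                    terminology.lookup(m.quantity_role),
                    NumValue.from_float(m.value, terminology.lookup(m.units_role)),
                    "CONTAINS",
                    children=modifiers,
                )
            )
        group_items.append(
            SRContentItem(
                "CONTAINER",
                terminology.lookup("sr.measurement_group"),
                relationship="CONTAINS",
                children=tuple(children),
            )
        )

    measurements_section = SRContentItem(
        "CONTAINER",
        terminology.lookup("sr.imaging_measurements"),
        relationship="CONTAINS",
        children=tuple(group_items),
    )
    root = SRContentItem(
        "CONTAINER",
        terminology.lookup("sr.report"),
        children=(library, measurements_section),
    )
    return SRDocument(context=context, tree=root)


# ---------------------------------------------------------------------------
# DICOM serialization

def _item_to_dataset(item: SRContentItem) -> Dataset:
    ds = Dataset()
    if item.relationship is not None:
        ds.RelationshipType = item.relationship
    ds.ValueType = item.value_type
    ds.ConceptNameCodeSequence = [_dicomio.code_item(item.concept_name)]
    if item.value_type == "CONTAINER":
        ds.ContinuityOfContent = "SEPARATE"
    elif item.value_type == "TEXT":
        ds.TextValue = str(item.value)
    elif item.value_type == "UIDREF":
        ds.UID = str(item.value)
    elif item.value_type == "PNAME":
        ds.PersonName = str(item.value)
    elif item.value_type == "DATETIME":
        ds.DateTime = str(item.value)
    elif item.value_type == "CODE":
        ds.ConceptCodeSequence = [_dicomio.code_item(item.value)]
    elif item.value_type == "NUM":
        num: NumValue = item.value
        mv = Dataset()
        mv.NumericValue = num.value_str
        mv.MeasurementUnitsCodeSequence = [_dicomio.code_item(num.units)]
        ds.MeasuredValueSequence = [mv]
    elif item.value_type == "IMAGE":
        ref: ImageReference = item.value
        r = Dataset()
        r.ReferencedSOPClassUID = ref.sop_class_uid
        r.ReferencedSOPInstanceUID = ref.sop_instance_uid
        if ref.segment_number is not None:
            r.ReferencedSegmentNumber = ref.segment_number
        ds.ReferencedSOPSequence = [r]
    if item.children:
        ds.ContentSequence = [_item_to_dataset(c) for c in item.children]
    return ds


def _item_from_dataset(ds: Dataset, is_root: bool = False) -> SRContentItem:
    vt = str(ds.ValueType)
    concept = _dicomio.concept_from_item(ds.ConceptNameCodeSequence[0])
    value: object = None
    if vt == "TEXT":
        value = str(ds.TextValue)
    elif vt == "UIDREF":
        value = str(ds.UID)
    elif vt == "PNAME":
        value = str(ds.PersonName)
    elif vt == "DATETIME":
        value = str(ds.DateTime)
    elif vt == "CODE":
        value = _dicomio.concept_from_item(ds.ConceptCodeSequence[0])
    elif vt == "NUM":
        mv = ds.MeasuredValueSequence[0]
        value = NumValue(
            value_str=str(mv.NumericValue),
            units=_dicomio.concept_from_item(mv.MeasurementUnitsCodeSequence[0]),
        )
    elif vt == "IMAGE":
        r = ds.ReferencedSOPSequence[0]
        seg = getattr(r, "ReferencedSegmentNumber", None)
        value = ImageReference(
            sop_class_uid=str(r.ReferencedSOPClassUID),
            sop_instance_uid=str(r.ReferencedSOPInstanceUID),
            segment_number=int(seg) if seg is not None else None,
        )
    children = tuple(
        _item_from_dataset(c) for c in getattr(ds, "ContentSequence", [])
    )
    relationship = None if is_root else str(getattr(ds, "RelationshipType", "CONTAINS"))
    return SRContentItem(
        value_type=vt,
        concept_name=concept,
        value=value,
        relationship=relationship,
        children=children,
    )


def serialize_sr(doc: SRDocument, path, rng: random.Random | None = None,
                 *, template_id: str = "1500",
                 mapping_resource: str = "DCMR") -> SRDocument:
    """Write the document as a DICOM Comprehensive SR file."""
    rng = rng or random.Random()
    sop_uid = doc.sop_instance_uid or make_uid(rng)
    ds = _dicomio.new_dataset(_dicomio.COMPREHENSIVE_SR_STORAGE, sop_uid)
    _dicomio.apply_context(ds, doc.context)
    ds.Modality = "SR"
    ds.CompletionFlag = "COMPLETE"
    ds.VerificationFlag = "UNVERIFIED"
    ds.PreliminaryFlag = "FINAL"
    ds.ContentDate = doc.context.study_date
    ds.ContentTime = doc.context.study_time
    ds.InstanceNumber = 1

    root = _item_to_dataset(doc.tree)
    for elem in root:
        ds[elem.tag] = elem
    template = Dataset()
    template.MappingResource = mapping_resource
    template.TemplateIdentifier = template_id
    ds.ContentTemplateSequence = [template]
    _dicomio.save(ds, Path(path))
    return SRDocument(context=doc.context, tree=doc.tree, sop_instance_uid=sop_uid)


def parse_sr(path) -> SRDocument:
    """Read a serialized SR file back into a content tree + context."""
    ds = dcmread(path)
    if str(getattr(ds, "Modality", "")) != "SR" or not hasattr(ds, "ValueType"):
        raise DicomParseError(f"{path} is not a structured report")
    try:
        tree = _item_from_dataset(ds, is_root=True)
    except (AttributeError, IndexError) as exc:
        raise DicomParseError(f"malformed SR content tree: {exc}") from exc
    return SRDocument(
        context=_dicomio.context_from_dataset(ds),
        tree=tree,
        sop_instance_uid=str(ds.SOPInstanceUID),
    )


# ---------------------------------------------------------------------------
# rendering

def _format_value(item: SRContentItem) -> str:
    if item.value_type == "CONTAINER":
        return ""
    if item.value_type == "NUM":
        num: NumValue = item.value
        u = num.units
        return f' = "{num.value_str}" ({u.value},{u.scheme},"{u.meaning}")'
    if item.value_type == "CODE":
        return f" = {item.value}"
    if item.value_type == "IMAGE":
        ref: ImageReference = item.value
        seg = f",segment {ref.segment_number}" if ref.segment_number is not None else ""
        return f" = ({ref.sop_class_uid},{ref.sop_instance_uid}{seg})"
    return f' = "{item.value}"'


def dump_sr_tree(tree: SRContentItem) -> str:
    """Deterministic SR-tree text dump, one line per content item."""
    lines = []
    for depth, item in tree.iter_depth_first():
        rel = f"{item.relationship.lower()} " if item.relationship else ""
        lines.append(
            "  " * depth + f"<{rel}{item.value_type}:{item.concept_name}{_format_value(item)}>"
        )
    return "\n".join(lines) + "\n"


CSV_HEADER = [
    "patient_id",
    "study_instance_uid",
    "tracking_id",
    "tracking_uid",
    "time_point",
    "session",
    "finding_site",
    "quantity_value",
    "quantity_scheme",
    "quantity_meaning",
    "derivation",
    "value",
    "units",
]


def _find_children(item: SRContentItem, concept: CodedConcept | None = None,
                   value_type: str | None = None):
    for c in item.children:
        if concept is not None and (c.concept_name.value, c.concept_name.scheme) != (
                concept.value, concept.scheme):
            continue
        if value_type is not None and c.value_type != value_type:
            continue
        yield c


def sr_to_csv(doc: SRDocument, terminology: TerminologyTable) -> list[list[str]]:
    """Flatten a measurement report to CSV rows (header first, one row per NUM)."""
    report_concept = terminology.lookup("sr.report")
    root = doc.tree
    if (root.concept_name.value, root.concept_name.scheme) != (
            report_concept.value, report_concept.scheme):
        raise TemplateError(
            f"not a measurement report: root concept is {root.concept_name}"
        )
    rows = [list(CSV_HEADER)]
    measurements_concept = terminology.lookup("sr.imaging_measurements")
    group_concept = terminology.lookup("sr.measurement_group")
    for section in _find_children(root, measurements_concept, "CONTAINER"):
        for group in _find_children(section, group_concept, "CONTAINER"):
            def first_text(role: str) -> str:
                for c in _find_children(group, terminology.lookup(role)):
                    return str(c.value)
                return ""

            tracking_id = first_text("sr.tracking_id")
            tracking_uid = first_text("sr.tracking_uid")
            session = first_text("sr.activity_session")
            time_point = first_text("sr.time_point")
            site = ""
            for c in _find_children(group, terminology.lookup("sr.finding_site"), "CODE"):
                site = c.value.meaning
            for num_item in group.children:
                if num_item.value_type != "NUM":
                    continue
                derivation = ""
                for mod in _find_children(num_item, terminology.lookup("derivation"), "CODE"):
                    derivation = mod.value.meaning
                q = num_item.concept_name
                num: NumValue = num_item.value
                rows.append([
                    doc.context.patient_id,
                    doc.context.study_instance_uid,
                    tracking_id,
                    tracking_uid,
                    time_point,
                    session,
                    site,
                    q.value,
                    q.scheme,
                    q.meaning,
                    derivation,
                    num.value_str,
                    num.units.value,
                ])
    return rows


def csv_text(rows: list[list[str]]) -> str:
    buf = io.StringIO()
    csv.writer(buf, lineterminator="\n").writerows(rows)
    return buf.getvalue()
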