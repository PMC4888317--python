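"""Three-tier validation of the toolkit's DICOM output.

Tier 1 (:func:`validate_iod`) checks each object against a documented
subset of its information-object requirements: presence of required
attributes, UID grammar, enumerated values such as the segment algorithm
type, and internal consistency (frame counts, referenced-image lists).

Tier 2 (:func:`check_entity_consistency`) checks *across* objects: every
object with the same PatientID must carry identical patient-level
attributes, and every object with the same StudyInstanceUID identical
study-level attributes — the composite-context contract that binds a
study's objects together.

Tier 3 (:func:`validate_tid1500`) checks measurement-report content trees
against the template: required context items present at the right level,
units on numeric items, code meanings agreeing with the terminology table.
Unrecognized content items trigger warnings (they usually signal an item
misplaced in the tree), not errors.

Validators report findings; they never raise on bad input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pydicom import dcmread
from pydicom.dataset import Dataset

from . import _dicomio
from .core import TerminologyTable, is_valid_uid
from .seg import ALGORITHM_TYPES
from .sr import SRContentItem, SRDocument

__all__ = ["Finding", "validate_iod", "check_entity_consistency", "validate_tid1500",
           "IOD_REQUIRED"]

ERROR = "ERROR"
WARNING = "WARNING"


@dataclass(frozen=True)
class Finding:
    severity: str  # ERROR or WARNING
    object_id: str
    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity} [{self.object_id}] {self.path}: {self.message}"


_COMMON_REQUIRED = (
    "PatientID", "PatientName", "StudyInstanceUID", "StudyDate",
    "SeriesInstanceUID", "SOPInstanceUID", "SOPClassUID", "Modality",
)

# Documented required-attribute subset per object type (not full IOD parity).
IOD_REQUIRED: dict[str, tuple[str, ...]] = {
    _dicomio.PET_IMAGE_STORAGE: _COMMON_REQUIRED + (
        "Rows", "Columns", "PixelSpacing", "ImagePositionPatient",
        "ImageOrientationPatient", "FrameOfReferenceUID", "RescaleSlope",
        "PatientWeight", "RadiopharmaceuticalInformationSequence", "DecayCorrection",
        "PixelData",
    ),
    _dicomio.CT_IMAGE_STORAGE: _COMMON_REQUIRED + (
        "Rows", "Columns", "PixelSpacing", "ImagePositionPatient",
        "ImageOrientationPatient", "FrameOfReferenceUID", "PixelData",
    ),
    _dicomio.SEGMENTATION_STORAGE: _COMMON_REQUIRED + (
        "Rows", "Columns", "BitsAllocated", "SegmentationType", "SegmentSequence",
        "NumberOfFrames", "PerFrameFunctionalGroupsSequence",
        "SharedFunctionalGroupsSequence", "FrameOfReferenceUID", "ContentCreatorName",
        "ClinicalTrialTimePointID", "PixelData",
    ),
    _dicomio.RWVM_STORAGE: _COMMON_REQUIRED + (
        "ReferencedImageRealWorldValueMappingSequence",
    ),
    _dicomio.COMPREHENSIVE_SR_STORAGE: _COMMON_REQUIRED + (
        "ValueType", "ConceptNameCodeSequence", "ContentSequence", "CompletionFlag",
        "ContentTemplateSequence",
    ),
}

_UID_KEYWORDS = (
    "SOPInstanceUID", "SOPClassUID", "StudyInstanceUID", "SeriesInstanceUID",
    "FrameOfReferenceUID",
)


def _read(path_or_ds) -> tuple[Dataset | None, str]:
    if isinstance(path_or_ds, Dataset):
        return path_or_ds, str(getattr(path_or_ds, "SOPInstanceUID", "<dataset>"))
    try:
        ds = dcmread(path_or_ds)
        return ds, Path(path_or_ds).name
    except Exception as exc:  # report, never raise
        return None, f"{path_or_ds}: {exc}"


def validate_iod(path_or_ds) -> list[Finding]:
    """Per-object required-attribute, UID-grammar and enumerated-value checks."""
    ds, object_id = _read(path_or_ds)
    if ds is None:
        return [Finding(ERROR, object_id, "<file>", "unreadable DICOM file")]
    findings: list[Finding] = []
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    required = IOD_REQUIRED.get(sop_class)
    if required is None:
        return [Finding(WARNING, object_id, "SOPClassUID",
                        f"no IOD checks defined for SOP class {sop_class!r}")]
    for keyword in required:
        value = getattr(ds, keyword, None)
        if value is None or (isinstance(value, str) and value == ""):
            findings.append(Finding(ERROR, object_id, keyword, "required attribute absent"))
    for keyword in _UID_KEYWORDS:
        value = getattr(ds, keyword, None)
        if value is not None and not is_valid_uid(str(value)):
            findings.append(Finding(ERROR, object_id, keyword,
                                    f"malformed UID {str(value)!r}"))

    if sop_class == _dicomio.SEGMENTATION_STORAGE:
        findings += _check_seg(ds, object_id)
    elif sop_class == _dicomio.RWVM_STORAGE:
        findings += _check_rwvm(ds, object_id)
    return findings


def _check_seg(ds: Dataset, object_id: str) -> list[Finding]:
    findings = []
    if int(getattr(ds, "BitsAllocated", 0)) != 1:
        findings.append(Finding(ERROR, object_id, "BitsAllocated",
                                "binary segmentation requires BitsAllocated = 1"))
    numbers = []
    for i, seg in enumerate(getattr(ds, "SegmentSequence", []), start=1):
        alg = str(getattr(seg, "SegmentAlgorithmType", ""))
        if alg not in ALGORITHM_TYPES:
            findings.append(
                Finding(ERROR, object_id, f"SegmentSequence[{i}].SegmentAlgorithmType",
                        f"{alg!r} is not one of {ALGORITHM_TYPES}")
            )
        elif alg != "MANUAL" and not str(getattr(seg, "SegmentAlgorithmName", "")):
            findings.append(
                Finding(ERROR, object_id, f"SegmentSequence[{i}].SegmentAlgorithmName",
                        "algorithm name required for non-MANUAL segments")
            )
        for seq in ("SegmentedPropertyCategoryCodeSequence",
                    "SegmentedPropertyTypeCodeSequence"):
            if not getattr(seg, seq, None):
                findings.append(Finding(ERROR, object_id, f"SegmentSequence[{i}].{seq}",
                                        "coded semantics absent"))
        numbers.append(int(getattr(seg, "SegmentNumber", 0)))
    if numbers != list(range(1, len(numbers) + 1)):
        findings.append(Finding(ERROR, object_id, "SegmentSequence",
                                f"segment numbers not contiguous from 1: {numbers}"))
    n_frames = int(getattr(ds, "NumberOfFrames", 0))
    per_frame = list(getattr(ds, "PerFrameFunctionalGroupsSequence", []))
    if len(per_frame) != n_frames:
        findings.append(Finding(ERROR, object_id, "PerFrameFunctionalGroupsSequence",
                                f"{len(per_frame)} items for NumberOfFrames={n_frames}"))
    rows, cols = int(getattr(ds, "Rows", 0)), int(getattr(ds, "Columns", 0))
    expected = (n_frames * rows * cols + 7) // 8
    expected += expected % 2
    payload = len(bytes(getattr(ds, "PixelData", b"")))
    if payload != expected:
        findings.append(Finding(ERROR, object_id, "PixelData",
                                f"payload {payload} bytes, expected {expected}"))
    return findings


def _check_rwvm(ds: Dataset, object_id: str) -> list[Finding]:
    findings = []
    try:
        top = ds.ReferencedImageRealWorldValueMappingSequence[0]
    except (AttributeError, IndexError):
        return findings  # absence already reported by the required-attribute pass
    refs = list(getattr(top, "ReferencedImageSequence", []))
    if not refs:
        findings.append(Finding(ERROR, object_id, "ReferencedImageSequence",
                                "RWVM references no image instances"))
    try:
        m = top.RealWorldValueMappingSequence[0]
    except (AttributeError, IndexError):
        findings.append(Finding(ERROR, object_id, "RealWorldValueMappingSequence",
                                "mapping item absent"))
        return findings
    first = int(getattr(m, "RealWorldValueFirstValueMapped", 0))
    last = int(getattr(m, "RealWorldValueLastValueMapped", -1))
    if first > last:
        findings.append(Finding(ERROR, object_id, "RealWorldValueFirstValueMapped",
                                f"first value {first} exceeds last value {last}"))
    if float(getattr(m, "RealWorldValueSlope", 0.0)) <= 0:
        findings.append(Finding(ERROR, object_id, "RealWorldValueSlope",
                                "slope must be positive"))
    if not getattr(m, "MeasurementUnitsCodeSequence", None):
        findings.append(Finding(ERROR, object_id, "MeasurementUnitsCodeSequence",
                                "units code absent"))
    return findings


_PATIENT_ATTRS = ("PatientName", "PatientSex", "PatientBirthDate")
_STUDY_ATTRS = ("PatientID", "StudyDate", "StudyTime", "StudyDescription")


def check_entity_consistency(paths_or_datasets: Iterable) -> list[Finding]:
    """Cross-object composite-context consistency by PatientID and StudyInstanceUID."""
    objects = []
    findings: list[Finding] = []
    for item in paths_or_datasets:
        ds, object_id = _read(item)
        if ds is None:
            findings.append(Finding(ERROR, object_id, "<file>", "unreadable DICOM file"))
            continue
        objects.append((ds, object_id))

    def check_groups(key_attr: str, attrs: tuple[str, ...], level: str) -> None:
        groups: dict[str, list] = {}
        for ds, object_id in objects:
            key = str(getattr(ds, key_attr, ""))
            if key:
                groups.setdefault(key, []).append((ds, object_id))
        for key, members in groups.items():
            ref_ds, ref_id = members[0]
            for attr in attrs:
                ref_value = str(getattr(ref_ds, attr, ""))
                for ds, object_id in members[1:]:
                    value = str(getattr(ds, attr, ""))
                    if value != ref_value:
                        findings.append(Finding(
                            ERROR, object_id, attr,
                            f"{level} attribute differs within {key_attr}={key}: "
                            f"{value!r} vs {ref_value!r} (in {ref_id})",
                        ))

    check_groups("PatientID", _PATIENT_ATTRS, "patient")
    check_groups("StudyInstanceUID", _STUDY_ATTRS, "study")
    return findings


def validate_tid1500(doc_or_tree, terminology: TerminologyTable) -> list[Finding]:
    """Template-compliance checks for a measurement-report content tree."""
    tree: SRContentItem = doc_or_tree.tree if isinstance(doc_or_tree, SRDocument) else doc_or_tree
    object_id = getattr(doc_or_tree, "sop_instance_uid", "") or "<tree>"
    findings: list[Finding] = []

    known = {}
    for role in terminology.roles():
        c = terminology.lookup(role)
        known[(c.value, c.scheme)] = c

    def code_meaning_check(item: SRContentItem, path: str) -> None:
        for concept in filter(None, [item.concept_name,
                                     item.value if item.value_type == "CODE" else None]):
            expected = known.get((concept.value, concept.scheme))
            if expected is not None and expected.meaning != concept.meaning:
                findings.append(Finding(
                    ERROR, object_id, path,
                    f"code meaning {concept.meaning!r} disagrees with terminology "
                    f"({expected.meaning!r}) for {concept.value}",
                ))

    report = terminology.lookup("sr.report")
    if (tree.concept_name.value, tree.concept_name.scheme) != (report.value, report.scheme):
        findings.append(Finding(ERROR, object_id, "1",
                                f"root concept {tree.concept_name} is not {report}"))
        return findings
    if tree.value_type != "CONTAINER":
        findings.append(Finding(ERROR, object_id, "1", "root item must be a CONTAINER"))

    def concept_is(item: SRContentItem, role: str) -> bool:
        c = terminology.lookup(role)
        return (item.concept_name.value, item.concept_name.scheme) == (c.value, c.scheme)

    sections = [c for c in tree.children if concept_is(c, "sr.imaging_measurements")]
    if not sections:
        findings.append(Finding(ERROR, object_id, "1",
                                "Imaging Measurements container absent"))

    group_context_roles = ("sr.tracking_id", "sr.tracking_uid", "sr.activity_session",
                           "sr.time_point", "sr.finding", "sr.finding_site",
                           "sr.referenced_segment", "sr.source_series", "sr.rwvm_ref")
    measurement_ok = set(known)  # any terminology concept is recognized

    for si, section in enumerate(sections, start=1):
        groups = [c for c in section.children if concept_is(c, "sr.measurement_group")]
        if not groups:
            findings.append(Finding(ERROR, object_id, f"1.{si}",
                                    "Imaging Measurements holds no measurement group"))
        for gi, group in enumerate(groups, start=1):
            gpath = f"1.{si}.{gi}"
            for role in ("sr.tracking_id", "sr.tracking_uid"):
                if not any(concept_is(c, role) for c in group.children):
                    findings.append(Finding(
                        ERROR, object_id, gpath,
                        f"required context item {terminology.lookup(role)} absent"))
            has_num = False
            for ci, child in enumerate(group.children, start=1):
                cpath = f"{gpath}.{ci}"
                code_meaning_check(child, cpath)
                if child.value_type == "NUM":
                    has_num = True
                    if child.value is None or child.value.units is None:
                        findings.append(Finding(ERROR, object_id, cpath,
                                                "NUM item without units"))
                key = (child.concept_name.value, child.concept_name.scheme)
                if key not in measurement_ok and not any(
                        concept_is(child, role) for role in group_context_roles):
                    findings.append(Finding(
                        WARNING, object_id, cpath,
                        f"unrecognized content item {child.concept_name} "
                        "(possibly misplaced in the tree)"))
            if not has_num:
                findings.append(Finding(ERROR, object_id, gpath,
                                        "measurement group holds no NUM item"))
    return findings
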