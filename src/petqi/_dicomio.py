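"""Internal pydicom helpers shared by the DICOM object writers and readers."""

from __future__ import annotations

from datetime import datetime

from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .core import CodedConcept, CompositeContext
from .errors import DicomParseError

PET_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.128"
CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
SEGMENTATION_STORAGE = "1.2.840.10008.5.1.4.1.1.66.4"
RWVM_STORAGE = "1.2.840.10008.5.1.4.1.1.67"
COMPREHENSIVE_SR_STORAGE = "1.2.840.10008.5.1.4.1.1.88.33"


def code_item(concept: CodedConcept) -> Dataset:
    """CodedConcept -> code sequence item dataset."""
    item = Dataset()
    if concept.scheme == "UCUM" or len(concept.value) > 16:
        item.LongCodeValue = concept.value
    else:
        item.CodeValue = concept.value
    item.CodingSchemeDesignator = concept.scheme
    item.CodeMeaning = concept.meaning
    return item


def concept_from_item(item: Dataset) -> CodedConcept:
    value = getattr(item, "CodeValue", None) or getattr(item, "LongCodeValue", None)
    if value is None:
        raise DicomParseError("code sequence item without CodeValue/LongCodeValue")
    return CodedConcept(str(value), str(item.CodingSchemeDesignator), str(item.CodeMeaning))


def new_dataset(sop_class_uid: str, sop_instance_uid: str) -> Dataset:
    """Fresh dataset with file meta for Explicit VR Little Endian encapsulation."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = sop_instance_uid
    return ds


def apply_context(ds: Dataset, context: CompositeContext) -> None:
    """Stamp the shared composite context onto a dataset."""
    ds.PatientID = context.patient_id
    ds.PatientName = context.patient_name
    ds.PatientSex = context.patient_sex
    ds.PatientBirthDate = (
        context.patient_birth_date.strftime("%Y%m%d") if context.patient_birth_date else ""
    )
    ds.StudyInstanceUID = context.study_instance_uid
    ds.StudyDate = context.study_date
    ds.StudyTime = context.study_time
    ds.StudyDescription = context.study_description
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.SeriesInstanceUID = context.series_instance_uid
    ds.SeriesNumber = context.series_number
    ds.SeriesDescription = context.series_description
    ds.Modality = context.modality


def context_from_dataset(ds: Dataset) -> CompositeContext:
    birth = getattr(ds, "PatientBirthDate", "") or None
    return CompositeContext(
        patient_id=str(ds.PatientID),
        patient_name=str(ds.PatientName),
        patient_sex=str(getattr(ds, "PatientSex", "")) or "O",
        study_instance_uid=str(ds.StudyInstanceUID),
        study_date=str(getattr(ds, "StudyDate", "")),
        study_time=str(getattr(ds, "StudyTime", "")),
        study_description=str(getattr(ds, "StudyDescription", "")),
        frame_of_reference_uid=str(getattr(ds, "FrameOfReferenceUID", "0")) or "0",
        series_instance_uid=str(ds.SeriesInstanceUID),
        series_number=int(getattr(ds, "SeriesNumber", 1) or 1),
        series_description=str(getattr(ds, "SeriesDescription", "")),
        modality=str(getattr(ds, "Modality", "")),
        patient_birth_date=datetime.strptime(birth, "%Y%m%d").date() if birth else None,
    )


def save(ds: Dataset, path) -> None:
    ds.save_as(path, enforce_file_format=True)
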