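"""Bit-packed multi-segment binary DICOM Segmentation objects.

Binary segmentations store one bit per voxel: the frames' bits are
concatenated into a single contiguous stream with *no* per-frame byte
alignment, LSB-first within each byte (the classic interoperability trap),
the final byte zero-padded and the payload padded to even length.  Frames
are ordered segment-major, then slice-ascending, and all-zero frames are
elided from the payload; each retained frame records its plane position
and (segment, slice) dimension indices so the decoder can reinsert the
elided slices as zeros.  Frames keep the full matrix size of the source
image — no bounding-box cropping.

Per-segment semantics (category/type/anatomic region coded triplets,
algorithm type, display color, tracking id/UID) travel in the segment
sequence; reader, session and time point identifiers travel in
ContentCreatorName, ClinicalTrialSeriesID and ClinicalTrialTimePointID.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from pydicom import dcmread
from pydicom.dataset import Dataset

from . import _dicomio
from .core import CodedConcept, CompositeContext, ImageGeometry, TerminologyTable, make_uid
from .errors import DicomParseError, GeometryError, MetadataError

__all__ = [
    "SegmentDescriptor",
    "DecodedSegmentation",
    "pack_bits",
    "unpack_bits",
    "encode_seg",
    "decode_seg",
    "seg_to_research",
    "research_to_seg",
    "encode_cielab",
    "decode_cielab",
    "write_mask_nifti",
    "read_mask_nifti",
]

ALGORITHM_TYPES = ("MANUAL", "SEMIAUTOMATIC", "AUTOMATIC")


def encode_cielab(L: float, a: float, b: float) -> tuple[int, int, int]:
    """CIELab display color to the scaled 16-bit encoding.

    L* in [0, 100] scales to [0, 65535]; a*, b* in [-128, 127] map by
    ((v + 128) / 255) * 65535, rounded to nearest.
    """
    if not (0 <= L <= 100 and -128 <= a <= 127 and -128 <= b <= 127):
        raise ValueError(f"CIELab value out of range: ({L}, {a}, {b})")
    return (
        int(round(L / 100.0 * 65535.0)),
        int(round((a + 128.0) / 255.0 * 65535.0)),
        int(round((b + 128.0) / 255.0 * 65535.0)),
    )


def decode_cielab(triple: Sequence[int]) -> tuple[float, float, float]:
    L16, a16, b16 = triple
    return (
        L16 / 65535.0 * 100.0,
        a16 / 65535.0 * 255.0 - 128.0,
        b16 / 65535.0 * 255.0 - 128.0,
    )


@dataclass(frozen=True)
class SegmentDescriptor:
    """Coded semantics and provenance of one segment."""

    segment_number: int
    label: str
    category: CodedConcept
    type: CodedConcept
    algorithm_type: str
    tracking_id: str
    tracking_uid: str
    anatomic_region: CodedConcept | None = None
    anatomic_region_modifier: CodedConcept | None = None
    algorithm_name: str = ""
    display_color: tuple[float, float, float] = (50.0, 0.0, 0.0)  # CIELab

    def __post_init__(self) -> None:
        if self.segment_number < 1:
            raise MetadataError("segment_number must be >= 1")
        if self.algorithm_type not in ALGORITHM_TYPES:
            raise MetadataError(
                f"algorithm_type must be one of {ALGORITHM_TYPES}, got {self.algorithm_type!r}"
            )
        if self.algorithm_type != "MANUAL" and not self.algorithm_name:
            raise MetadataError("algorithm_name is required unless algorithm_type is MANUAL")


# ---------------------------------------------------------------------------
# bit packing

def pack_bits(frames: Sequence[np.ndarray]) -> bytes:
    """Concatenate binary frames into a contiguous LSB-first bit stream.

    No per-frame byte alignment: a frame may start mid-byte.  The final
    byte is zero-padded and the payload padded to even length.
    """
    if len(frames) == 0:
        return b""
    arrs = []
    shape = np.asarray(frames[0]).shape
    for f in frames:
        a = np.asarray(f)
        if a.shape != shape:
            raise ValueError(f"frame shape {a.shape} differs from {shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("frames must be binary (0/1) for bit packing")
        arrs.append(a.astype(np.uint8).ravel())
    bits = np.concatenate(arrs)
    packed = np.packbits(bits, bitorder="little").tobytes()
    if len(packed) % 2:
        packed += b"\x00"
    return packed


def unpack_bits(data: bytes, frame_count: int, rows: int, cols: int) -> np.ndarray:
    """Exact inverse of :func:`pack_bits`; returns (frame_count, rows, cols) uint8."""
    total_bits = frame_count * rows * cols
    needed = (total_bits + 7) // 8
    if len(data) < needed:
        raise DicomParseError(
            f"bit-packed payload truncated: need {needed} bytes for "
            f"{frame_count} frames, got {len(data)}"
        )
    bits = np.unpackbits(np.frombuffer(data[:needed], dtype=np.uint8), bitorder="little")
    return bits[:total_bits].reshape(frame_count, rows, cols)


# ---------------------------------------------------------------------------
# encode / decode

def _segment_item(d: SegmentDescriptor) -> Dataset:
    item = Dataset()
    item.SegmentNumber = d.segment_number
    item.SegmentLabel = d.label
    item.SegmentAlgorithmType = d.algorithm_type
    if d.algorithm_name:
        item.SegmentAlgorithmName = d.algorithm_name
    item.SegmentedPropertyCategoryCodeSequence = [_dicomio.code_item(d.category)]
    item.SegmentedPropertyTypeCodeSequence = [_dicomio.code_item(d.type)]
    if d.anatomic_region is not None:
        region = _dicomio.code_item(d.anatomic_region)
        if d.anatomic_region_modifier is not None:
            region.AnatomicRegionModifierSequence = [
                _dicomio.code_item(d.anatomic_region_modifier)
            ]
        item.AnatomicRegionSequence = [region]
    item.RecommendedDisplayCIELabValue = list(encode_cielab(*d.display_color))
    item.TrackingID = d.tracking_id
    item.TrackingUID = d.tracking_uid
    return item


def _descriptor_from_item(item: Dataset) -> SegmentDescriptor:
    region = None
    modifier = None
    if hasattr(item, "AnatomicRegionSequence"):
        region_item = item.AnatomicRegionSequence[0]
        region = _dicomio.concept_from_item(region_item)
        if hasattr(region_item, "AnatomicRegionModifierSequence"):
            modifier = _dicomio.concept_from_item(region_item.AnatomicRegionModifierSequence[0])
    return SegmentDescriptor(
        segment_number=int(item.SegmentNumber),
        label=str(item.SegmentLabel),
        category=_dicomio.concept_from_item(item.SegmentedPropertyCategoryCodeSequence[0]),
        type=_dicomio.concept_from_item(item.SegmentedPropertyTypeCodeSequence[0]),
        algorithm_type=str(item.SegmentAlgorithmType),
        algorithm_name=str(getattr(item, "SegmentAlgorithmName", "")),
        tracking_id=str(getattr(item, "TrackingID", "")),
        tracking_uid=str(getattr(item, "TrackingUID", "")),
        anatomic_region=region,
        anatomic_region_modifier=modifier,
        display_color=decode_cielab([int(v) for v in item.RecommendedDisplayCIELabValue]),
    )


def encode_seg(
    masks: Sequence[np.ndarray],
    descriptors: Sequence[SegmentDescriptor],
    source_series,
    *,
    content_creator: str,
    time_point_id: str,
    series_session_id: str,
    rng: random.Random,
    series_number: int = 100,
    series_description: str = "Segmentation",
    path=None,
) -> Dataset:
    """Encode per-segment binary volumes as one multi-segment SEG object.

    *source_series* supplies the grid, composite context and the source
    slice SOP instance UIDs (any object with ``geometry``, ``context``,
    ``instance_uids`` and ``sop_class_uid`` attributes, e.g. a
    :class:`~petqi.phantom.PhantomSeries`).
    """
    geom: ImageGeometry = source_series.geometry
    if len(masks) != len(descriptors):
        raise MetadataError("one descriptor per mask is required")
    if len(masks) == 0:
        raise MetadataError("at least one segment is required")
    numbers = [d.segment_number for d in descriptors]
    if numbers != list(range(1, len(descriptors) + 1)):
        raise MetadataError(f"segment numbers must be contiguous from 1, got {numbers}")
    vols = []
    for m in masks:
        a = np.asarray(m)
        if a.shape != geom.shape:
            raise GeometryError(f"mask shape {a.shape} does not match source grid {geom.shape}")
        if not np.isin(a, (0, 1)).all():
            raise MetadataError("segment masks must be binary (0/1)")
        vols.append(a.astype(np.uint8))
    if not any(v.any() for v in vols):
        raise MetadataError("refusing to encode an empty segmentation (all masks empty)")

    context = source_series.context.derive_series(
        rng,
        series_number=series_number,
        series_description=series_description,
        modality="SEG",
    )
    ds = _dicomio.new_dataset(_dicomio.SEGMENTATION_STORAGE, make_uid(rng))
    _dicomio.apply_context(ds, context)
    ds.FrameOfReferenceUID = context.frame_of_reference_uid
    ds.PositionReferenceIndicator = ""
    ds.InstanceNumber = 1
    ds.ImageType = ["DERIVED", "PRIMARY"]
    ds.ContentLabel = "SEGMENTATION"
    ds.ContentDescription = series_description
    ds.ContentCreatorName = content_creator
    ds.ClinicalTrialTimePointID = str(time_point_id)
    ds.ClinicalTrialSeriesID = str(series_session_id)
    ds.ContentDate = context.study_date
    ds.ContentTime = context.study_time

    rows, cols, n_slices = geom.dimensions
    ds.Rows = rows
    ds.Columns = cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 1
    ds.BitsStored = 1
    ds.HighBit = 0
    ds.PixelRepresentation = 0
    ds.LossyImageCompression = "00"
    ds.SegmentationType = "BINARY"
    ds.SegmentSequence = [_segment_item(d) for d in descriptors]

    dim_org_uid = make_uid(rng)
    org = Dataset()
    org.DimensionOrganizationUID = dim_org_uid
    ds.DimensionOrganizationSequence = [org]

    shared = Dataset()
    measures = Dataset()
    measures.PixelSpacing = [geom.pixel_spacing[0], geom.pixel_spacing[1]]
    measures.SliceThickness = geom.slice_spacing
    measures.SpacingBetweenSlices = geom.slice_spacing
    orient = Dataset()
    orient.ImageOrientationPatient = list(geom.row_direction) + list(geom.column_direction)
    shared.PixelMeasuresSequence = [measures]
    shared.PlaneOrientationSequence = [orient]
    ds.SharedFunctionalGroupsSequence = [shared]

    # frames: segment-major, slices ascending, empty frames elided
    frames = []
    per_frame = []
    for vol, desc in zip(vols, descriptors):
        for k in range(n_slices):
            frame = vol[k]
            if not frame.any():
                continue
            frames.append(frame)
            fg = Dataset()
            seg_id = Dataset()
            seg_id.ReferencedSegmentNumber = desc.segment_number
            fg.SegmentIdentificationSequence = [seg_id]
            pos = Dataset()
            pos.ImagePositionPatient = [float(x) for x in geom.slice_position_mm(k)]
            fg.PlanePositionSequence = [pos]
            fc = Dataset()
            fc.DimensionIndexValues = [desc.segment_number, k + 1]
            fg.FrameContentSequence = [fc]
            per_frame.append(fg)
    ds.NumberOfFrames = len(frames)
    ds.PerFrameFunctionalGroupsSequence = per_frame
    ds.PixelData = pack_bits(frames)

    # reference every slice of the segmented source series
    ref_instances = []
    for uid in source_series.instance_uids:
        r = Dataset()
        r.ReferencedSOPClassUID = source_series.sop_class_uid
        r.ReferencedSOPInstanceUID = uid
        ref_instances.append(r)
    ref_series = Dataset()
    ref_series.SeriesInstanceUID = source_series.context.series_instance_uid
    ref_series.ReferencedInstanceSequence = ref_instances
    ds.ReferencedSeriesSequence = [ref_series]

    if path is not None:
        _dicomio.save(ds, Path(path))
    return ds


@dataclass(frozen=True)
class DecodedSegmentation:
    """Fully reconstructed segmentation: one full-extent binary volume per segment."""

    masks: Mapping[int, np.ndarray]  # segment number -> (slices, rows, cols) uint8
    descriptors: tuple[SegmentDescriptor, ...]
    context: CompositeContext
    geometry: ImageGeometry
    frame_map: tuple[tuple[int, int, tuple[float, float, float]], ...]
    source_instance_uids: tuple[str, ...]
    referenced_series_uid: str
    content_creator: str
    time_point_id: str
    series_session_id: str
    sop_instance_uid: str


def decode_seg(path_or_ds) -> DecodedSegmentation:
    """Decode a SEG file, reinserting elided slices as zeros."""
    ds = path_or_ds if isinstance(path_or_ds, Dataset) else dcmread(path_or_ds)
    if str(ds.SOPClassUID) != _dicomio.SEGMENTATION_STORAGE:
        raise DicomParseError(f"not a Segmentation object (SOP class {ds.SOPClassUID})")
    rows, cols = int(ds.Rows), int(ds.Columns)
    n_frames = int(ds.NumberOfFrames)
    per_frame = list(ds.PerFrameFunctionalGroupsSequence)
    if len(per_frame) != n_frames:
        raise DicomParseError(
            f"NumberOfFrames={n_frames} but {len(per_frame)} per-frame items"
        )
    frames = unpack_bits(bytes(ds.PixelData), n_frames, rows, cols)

    shared = ds.SharedFunctionalGroupsSequence[0]
    measures = shared.PixelMeasuresSequence[0]
    orient = shared.PlaneOrientationSequence[0].ImageOrientationPatient
    row_dir = tuple(float(v) for v in orient[:3])
    col_dir = tuple(float(v) for v in orient[3:])
    normal = np.cross(row_dir, col_dir)
    slice_spacing = float(getattr(measures, "SpacingBetweenSlices", measures.SliceThickness))

    ref_series = ds.ReferencedSeriesSequence[0]
    source_uids = tuple(
        str(r.ReferencedSOPInstanceUID) for r in ref_series.ReferencedInstanceSequence
    )
    n_slices = len(source_uids)

    frame_map = []
    origin = None
    for idx, fg in enumerate(per_frame):
        try:
            seg_num = int(fg.SegmentIdentificationSequence[0].ReferencedSegmentNumber)
            pos = tuple(float(v) for v in fg.PlanePositionSequence[0].ImagePositionPatient)
            slice_index = int(fg.FrameContentSequence[0].DimensionIndexValues[1]) - 1
        except (AttributeError, IndexError) as exc:
            raise DicomParseError(f"malformed per-frame group at frame {idx}: {exc}") from exc
        if not 0 <= slice_index < n_slices:
            raise DicomParseError(f"frame {idx}: slice index {slice_index} out of range")
        frame_map.append((seg_num, slice_index, pos))
        if origin is None:
            origin = np.asarray(pos) - slice_index * slice_spacing * normal

    geometry = ImageGeometry(
        origin=tuple(origin) if origin is not None else (0.0, 0.0, 0.0),
        row_direction=row_dir,
        column_direction=col_dir,
        pixel_spacing=(float(measures.PixelSpacing[0]), float(measures.PixelSpacing[1])),
        slice_spacing=slice_spacing,
        dimensions=(rows, cols, n_slices),
    )

    descriptors = tuple(_descriptor_from_item(item) for item in ds.SegmentSequence)
    masks = {
        d.segment_number: np.zeros((n_slices, rows, cols), dtype=np.uint8) for d in descriptors
    }
    for frame, (seg_num, slice_index, _pos) in zip(frames, frame_map):
        masks[seg_num][slice_index] = frame

    return DecodedSegmentation(
        masks=masks,
        descriptors=descriptors,
        context=_dicomio.context_from_dataset(ds),
        geometry=geometry,
        frame_map=tuple(frame_map),
        source_instance_uids=source_uids,
        referenced_series_uid=str(ref_series.SeriesInstanceUID),
        content_creator=str(getattr(ds, "ContentCreatorName", "")),
        time_point_id=str(getattr(ds, "ClinicalTrialTimePointID", "")),
        series_session_id=str(getattr(ds, "ClinicalTrialSeriesID", "")),
        sop_instance_uid=str(ds.SOPInstanceUID),
    )


# ---------------------------------------------------------------------------
# research-format bridge (NIfTI)

def _nifti_affine(geom: ImageGeometry) -> np.ndarray:
    """Affine mapping (col, row, slice) voxel indices to RAS mm (NIfTI space)."""
    affine = np.eye(4)
    rd = np.asarray(geom.row_direction, float)
    cd = np.asarray(geom.column_direction, float)
    n = geom.slice_normal
    affine[:3, 0] = rd * geom.pixel_spacing[1]
    affine[:3, 1] = cd * geom.pixel_spacing[0]
    affine[:3, 2] = n * geom.slice_spacing
    affine[:3, 3] = np.asarray(geom.origin, float)
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    return lps_to_ras @ affine


def write_mask_nifti(mask: np.ndarray, geometry: ImageGeometry, path) -> Path:
    """Write a (slices, rows, cols) binary volume as NIfTI on the source grid."""
    data = np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, _nifti_affine(geometry))
    nib.save(img, str(path))
    return Path(path)


def read_mask_nifti(path) -> tuple[np.ndarray, ImageGeometry]:
    """Read a NIfTI mask back into (slices, rows, cols) plus its grid."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ img.affine  # RAS -> LPS
    col_step, row_step, slice_step = affine[:3, 0], affine[:3, 1], affine[:3, 2]
    pix = (float(np.linalg.norm(row_step)), float(np.linalg.norm(col_step)))
    slice_spacing = float(np.linalg.norm(slice_step))
    geom = ImageGeometry(
        origin=tuple(affine[:3, 3]),
        row_direction=tuple(col_step / np.linalg.norm(col_step)),
        column_direction=tuple(row_step / np.linalg.norm(row_step)),
        pixel_spacing=pix,
        slice_spacing=slice_spacing,
        dimensions=(data.shape[1], data.shape[0], data.shape[2]),
    )
    return np.transpose(data, (2, 1, 0)), geom


def write_volume_nifti(volume: np.ndarray, geometry: ImageGeometry, path) -> Path:
    """Write a (slices, rows, cols) scalar volume (e.g. SUV) as float32 NIfTI."""
    data = np.transpose(np.asarray(volume, dtype=np.float32), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _nifti_affine(geometry)), str(path))
    return Path(path)


def read_volume_nifti(path) -> tuple[np.ndarray, ImageGeometry]:
    """Read a scalar NIfTI volume back into (slices, rows, cols) float plus grid."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ img.affine
    col_step, row_step, slice_step = affine[:3, 0], affine[:3, 1], affine[:3, 2]
    geom = ImageGeometry(
        origin=tuple(affine[:3, 3]),
        row_direction=tuple(col_step / np.linalg.norm(col_step)),
        column_direction=tuple(row_step / np.linalg.norm(row_step)),
        pixel_spacing=(float(np.linalg.norm(row_step)), float(np.linalg.norm(col_step))),
        slice_spacing=float(np.linalg.norm(slice_step)),
        dimensions=(data.shape[1], data.shape[0], data.shape[2]),
    )
    return np.transpose(data, (2, 1, 0)), geom


def seg_to_research(path, out_dir) -> list[Path]:
    """Convert a SEG file to one NIfTI mask per segment; lossless on voxels."""
    decoded = decode_seg(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for num, mask in sorted(decoded.masks.items()):
        out = out_dir / f"segment_{num}.nii"
        write_mask_nifti(mask, decoded.geometry, out)
        written.append(out)
    return written


_REQUIRED_SEGMENT_META = ("label", "category_role", "type_role", "algorithm_type", "tracking_id")


def descriptors_from_config(
    entries: Sequence[Mapping], terminology: TerminologyTable, rng: random.Random
) -> list[SegmentDescriptor]:
    """Build segment descriptors from declarative metadata entries.

    Each entry binds a segment to terminology roles:
    ``{label, category_role, type_role, region_role?, algorithm_type,
    algorithm_name?, color?, tracking_id, tracking_uid?}``.
    """
    descriptors = []
    for i, entry in enumerate(entries, start=1):
        missing = [k for k in _REQUIRED_SEGMENT_META if k not in entry]
        if missing:
            raise MetadataError(
                f"segment metadata entry {i} is missing required keys: {missing}"
            )
        region = (
            terminology.lookup(entry["region_role"]) if entry.get("region_role") else None
        )
        descriptors.append(
            SegmentDescriptor(
                segment_number=i,
                label=entry["label"],
                category=terminology.lookup(entry["category_role"]),
                type=terminology.lookup(entry["type_role"]),
                anatomic_region=region,
                algorithm_type=entry["algorithm_type"],
                algorithm_name=entry.get("algorithm_name", ""),
                display_color=tuple(entry.get("color", (50.0, 0.0, 0.0))),
                tracking_id=entry["tracking_id"],
                tracking_uid=entry.get("tracking_uid") or make_uid(rng),
            )
        )
    return descriptors


def research_to_seg(
    mask_paths: Sequence,
    metadata_entries: Sequence[Mapping],
    source_series,
    terminology: TerminologyTable,
    *,
    content_creator: str,
    time_point_id: str = "1",
    series_session_id: str = "1",
    rng: random.Random,
    path=None,
) -> Dataset:
    """Encode research-format (NIfTI) masks as a SEG, metadata from config."""
    masks = []
    for p in mask_paths:
        mask, geom = read_mask_nifti(p)
        if not np.isin(mask, (0, 1)).all():
            raise MetadataError(f"mask {p} is not binary (labels other than 0/1 present)")
        if not geom.same_grid(source_series.geometry, tol=1e-3):
            raise GeometryError(f"mask {p} grid does not match the source series grid")
        masks.append(mask)
    descriptors = descriptors_from_config(metadata_entries, terminology, rng)
    return encode_seg(
        masks,
        descriptors,
        source_series,
        content_creator=content_creator,
        time_point_id=time_point_id,
        series_session_id=series_session_id,
        rng=rng,
        path=path,
    )
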