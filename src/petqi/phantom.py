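"""Synthetic PET/CT phantom studies with ground-truth spherical lesions.

The generator emulates what the rest of the toolkit needs from an acquired
FDG PET/CT study: an activity-concentration PET series (Bq/ml) with
radiopharmaceutical metadata, a companion CT sharing the frame of
reference, ground-truth lesion and reference-region masks on the PET grid,
a reader-variation perturbation, and the enumeration of segmentation
sessions for a repeatability study design (readers x tools x sessions).

Lesions are hard-edged spheres rasterized by voxel-center inclusion — no
partial-volume modelling — so volumes and means are analytically checkable.
Voxels inside a lesion take the lesion's activity; elsewhere the uniform
background activity applies.  Noise is additive Gaussian on activity,
clipped at zero.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import yaml
from pydicom import dcmread
from scipy import ndimage

from . import _dicomio
from .core import CompositeContext, ImageGeometry, make_uid
from .errors import DicomParseError, PhantomSpecError
from .suv import RadiopharmInfo

__all__ = [
    "SphereRegion",
    "PhantomSpec",
    "StudyDesign",
    "SegmentationTask",
    "PhantomSeries",
    "generate_pet_series",
    "generate_ct_series",
    "ground_truth_mask",
    "perturb_mask",
    "enumerate_study_design",
    "write_image_series",
    "read_image_series",
]

# Stored-value scaling: the series maximum maps to this stored value.  A
# power of two keeps max-activity voxels exact under float round-trip.
_STORED_MAX = 32768.0


@dataclass(frozen=True)
class SphereRegion:
    """A spherical region: center (mm, LPS), radius (mm), role, activity (Bq/ml)."""

    center: tuple[float, float, float]
    radius: float
    role: str
    activity: float = 0.0


def _default_lesions() -> list[SphereRegion]:
    return [
        SphereRegion(center=(40.0, 40.0, 30.0), radius=12.0, role="lesion.primary", activity=6000.0),
        SphereRegion(center=(88.0, 60.0, 50.0), radius=9.0, role="lesion.node", activity=4000.0),
    ]


def _default_reference_regions() -> list[SphereRegion]:
    return [
        SphereRegion(center=(40.0, 90.0, 40.0), radius=12.0, role="rr.region.liver"),
        SphereRegion(center=(90.0, 30.0, 56.0), radius=10.0, role="rr.region.cerebellum"),
        SphereRegion(center=(90.0, 90.0, 24.0), radius=8.0, role="rr.region.aortic_arch"),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic PET/CT study.

    Defaults describe a desk-scale FDG study: 64x64x40 grid at 2 mm
    isotropic spacing, 1 kBq/ml background, a hot primary tumor and one
    lymph node, three reference regions, a 370 MBq injection of a tracer
    with the F-18 half-life one hour before the series.
    """

    dimensions: tuple[int, int, int] = (64, 64, 40)  # (rows, cols, slices)
    pixel_spacing: tuple[float, float] = (2.0, 2.0)
    slice_spacing: float = 2.0
    background_activity: float = 1000.0
    lesions: tuple[SphereRegion, ...] = field(default_factory=lambda: tuple(_default_lesions()))
    reference_regions: tuple[SphereRegion, ...] = field(
        default_factory=lambda: tuple(_default_reference_regions())
    )
    patient_weight: float = 75.0  # kg
    injected_dose: float = 3.7e8  # Bq
    half_life: float = 6586.2  # s (F-18)
    injection_time: datetime = datetime(2016, 1, 15, 9, 0, 0)
    series_time: datetime = datetime(2016, 1, 15, 10, 0, 0)
    noise_sigma: float = 50.0  # Bq/ml
    lesion_hu: float = 60.0
    background_hu: float = 40.0
    date_shift_days: int = 0  # single fixed offset applied to all dates
    seed: int = 2016

    def __post_init__(self) -> None:
        if self.background_activity < 0 or any(l.activity < 0 for l in self.lesions):
            raise PhantomSpecError("activities must be >= 0")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")
        if self.series_time < self.injection_time:
            raise PhantomSpecError("series_time must not precede injection_time")
        if self.patient_weight <= 0 or self.injected_dose <= 0 or self.half_life <= 0:
            raise PhantomSpecError("weight, dose and half-life must be positive")
        geom = self.geometry
        extent = (
            (geom.dimensions[1] - 1) * geom.pixel_spacing[1],
            (geom.dimensions[0] - 1) * geom.pixel_spacing[0],
            (geom.dimensions[2] - 1) * geom.slice_spacing,
        )
        for region in tuple(self.lesions) + tuple(self.reference_regions):
            for axis in range(3):
                if region.center[axis] - region.radius < 0 or \
                        region.center[axis] + region.radius > extent[axis]:
                    raise PhantomSpecError(
                        f"sphere {region.role!r} extends outside the grid on axis {axis}"
                    )

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(
            origin=(0.0, 0.0, 0.0),
            row_direction=(1.0, 0.0, 0.0),
            column_direction=(0.0, 1.0, 0.0),
            pixel_spacing=self.pixel_spacing,
            slice_spacing=self.slice_spacing,
            dimensions=self.dimensions,
        )

    @property
    def regions(self) -> tuple[SphereRegion, ...]:
        """All spheres, lesions first then reference regions (mask indexing order)."""
        return tuple(self.lesions) + tuple(self.reference_regions)

    @property
    def radiopharm(self) -> RadiopharmInfo:
        shift = timedelta(days=self.date_shift_days)
        return RadiopharmInfo(
            injected_dose=self.injected_dose,
            half_life=self.half_life,
            injection_time=self.injection_time + shift,
            series_time=self.series_time + shift,
        )

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("lesions", "reference_regions"):
            if key in raw:
                raw[key] = tuple(SphereRegion(**{**r, "center": tuple(r["center"])}) for r in raw[key])
        for key in ("injection_time", "series_time"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = datetime.fromisoformat(raw[key])
        for key in ("dimensions", "pixel_spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class StudyDesign:
    """Repeatability design: lesion tasks = readers x tools x sessions, plus RRs."""

    n_readers: int = 3
    n_tools: int = 2
    n_sessions: int = 2
    reference_region_count: int = 3
    time_point: int = 1

    def __post_init__(self) -> None:
        if min(self.n_readers, self.n_tools, self.n_sessions, self.time_point) < 1:
            raise PhantomSpecError("readers, tools, sessions and time point must be >= 1")
        if self.reference_region_count < 0:
            raise PhantomSpecError("reference_region_count must be >= 0")


@dataclass(frozen=True)
class SegmentationTask:
    """One segmentation session: produces one SEG object and one measurement SR."""

    kind: str  # "lesion" or "rr"
    reader: int = 0
    tool: int = 0
    session: int = 0
    rr_index: int = 0
    time_point: int = 1


def enumerate_study_design(design: StudyDesign) -> list[SegmentationTask]:
    """All SEG-producing tasks of the design, lesion sessions first."""
    tasks = [
        SegmentationTask(kind="lesion", reader=r, tool=t, session=s, time_point=design.time_point)
        for r in range(1, design.n_readers + 1)
        for t in range(1, design.n_tools + 1)
        for s in range(1, design.n_sessions + 1)
    ]
    tasks += [
        SegmentationTask(kind="rr", rr_index=i, time_point=design.time_point)
        for i in range(design.reference_region_count)
    ]
    return tasks


@dataclass(frozen=True)
class PhantomSeries:
    """One generated image series plus everything needed to encode it."""

    context: CompositeContext
    geometry: ImageGeometry
    activity: np.ndarray  # float64, (slices, rows, cols); Bq/ml for PET, HU for CT
    stored: np.ndarray  # integer stored values
    rescale_slope: float
    rescale_intercept: float
    instance_uids: tuple[str, ...]
    sop_class_uid: str
    radiopharm: RadiopharmInfo | None = None
    patient_weight: float | None = None


def _study_context(spec: PhantomSpec) -> CompositeContext:
    """Deterministic study-level context; PET and CT derive from the same stream."""
    rng = random.Random(f"{spec.seed}:study")
    shifted = spec.series_time + timedelta(days=spec.date_shift_days)
    return CompositeContext(
        patient_id=f"PHANTOM-01-{spec.seed % 10000:04d}",
        patient_name=f"Phantom^{spec.seed % 10000:04d}",
        patient_sex="O",
        study_instance_uid=make_uid(rng),
        study_date=shifted.strftime("%Y%m%d"),
        study_time=shifted.strftime("%H%M%S"),
        study_description="PET/CT phantom study",
        frame_of_reference_uid=make_uid(rng),
        series_instance_uid=make_uid(rng),  # replaced per series
        series_number=0,
        series_description="",
        modality="",
    )


def _sphere_mask(geometry: ImageGeometry, region: SphereRegion) -> np.ndarray:
    x, y, z = geometry.voxel_centers()
    d2 = (x - region.center[0]) ** 2 + (y - region.center[1]) ** 2 + (z - region.center[2]) ** 2
    return d2 <= region.radius ** 2


def ground_truth_mask(spec: PhantomSpec, region_index: int) -> np.ndarray:
    """Binary mask of spec.regions[region_index] on the PET grid.

    Voxel set exactly where the sphere covers the voxel center; a zero
    radius therefore yields an empty mask.
    """
    regions = spec.regions
    if not 0 <= region_index < len(regions):
        raise PhantomSpecError(f"region index {region_index} out of range (have {len(regions)})")
    region = regions[region_index]
    if region.radius <= 0:
        return np.zeros(spec.geometry.shape, dtype=bool)
    return _sphere_mask(spec.geometry, region)


def generate_pet_series(spec: PhantomSpec) -> PhantomSeries:
    """Activity volume (Bq/ml) with lesions on a uniform background, plus metadata.

    Stored values are 16-bit unsigned integers under a single series-wide
    rescale slope chosen so the maximum activity maps to a stored value of
    32768; reading ``stored * slope`` recovers the activity.
    """
    geom = spec.geometry
    activity = np.full(geom.shape, float(spec.background_activity))
    for lesion in spec.lesions:
        activity[_sphere_mask(geom, lesion)] = lesion.activity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        activity = np.clip(activity + rng.normal(0.0, spec.noise_sigma, geom.shape), 0.0, None)
    peak = float(activity.max())
    slope = peak / _STORED_MAX if peak > 0 else 1.0
    stored = np.clip(np.round(activity / slope), 0, 65535).astype(np.uint16)

    study = _study_context(spec)
    rng_uid = random.Random(f"{spec.seed}:pet")
    context = study.derive_series(
        rng_uid, series_number=1, series_description="PET phantom", modality="PT"
    )
    uids = tuple(make_uid(rng_uid) for _ in range(geom.dimensions[2]))
    return PhantomSeries(
        context=context,
        geometry=geom,
        activity=stored.astype(float) * slope,
        stored=stored,
        rescale_slope=slope,
        rescale_intercept=0.0,
        instance_uids=uids,
        sop_class_uid=_dicomio.PET_IMAGE_STORAGE,
        radiopharm=spec.radiopharm,
        patient_weight=spec.patient_weight,
    )


def generate_ct_series(spec: PhantomSpec) -> PhantomSeries:
    """Companion CT in HU, same study and frame of reference, distinct series."""
    geom = spec.geometry
    hu = np.full(geom.shape, float(spec.background_hu))
    for lesion in spec.lesions:
        hu[_sphere_mask(geom, lesion)] = spec.lesion_hu
    stored = np.round(hu).astype(np.int16)

    study = _study_context(spec)
    rng_uid = random.Random(f"{spec.seed}:ct")
    context = study.derive_series(
        rng_uid, series_number=2, series_description="CT phantom", modality="CT"
    )
    uids = tuple(make_uid(rng_uid) for _ in range(geom.dimensions[2]))
    return PhantomSeries(
        context=context,
        geometry=geom,
        activity=stored.astype(float),
        stored=stored,
        rescale_slope=1.0,
        rescale_intercept=0.0,
        instance_uids=uids,
        sop_class_uid=_dicomio.CT_IMAGE_STORAGE,
    )


_CROSS3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def perturb_mask(mask: np.ndarray, rng: np.random.Generator, rate: float = 0.3) -> np.ndarray:
    """Simulate reader variation: random <=1-voxel boundary erosion/dilation.

    Each voxel of the inner boundary is dropped, and each voxel of the
    outer boundary added, independently with probability *rate*.  The
    eroded core is never touched, so any mask larger than a 3x3x3 cube
    stays non-empty.  ``rate=0`` is the identity.
    """
    mask = np.asarray(mask, dtype=bool)
    if rate < 0 or rate > 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or not mask.any():
        return mask.copy()
    eroded = ndimage.binary_erosion(mask, structure=_CROSS3D)
    dilated = ndimage.binary_dilation(mask, structure=_CROSS3D)
    inner = mask & ~eroded
    outer = dilated & ~mask
    out = mask.copy()
    out[inner] = rng.random(int(inner.sum())) >= rate
    out[outer] = rng.random(int(outer.sum())) < rate
    return out


# ---------------------------------------------------------------------------
# DICOM slice-file I/O (one file per slice, PS3.10 encapsulation)

def _dcm_datetime(dt: datetime) -> str:
    return dt.strftime("%Y%m%d%H%M%S")


def write_image_series(series: PhantomSeries, out_dir) -> list[Path]:
    """Write one DICOM file per slice; returns the written paths in slice order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = series.geometry
    rows, cols, n_slices = geom.dimensions
    paths = []
    for k in range(n_slices):
        ds = _dicomio.new_dataset(series.sop_class_uid, series.instance_uids[k])
        _dicomio.apply_context(ds, series.context)
        ds.FrameOfReferenceUID = series.context.frame_of_reference_uid
        ds.PositionReferenceIndicator = ""
        ds.InstanceNumber = k + 1
        ds.ImageType = ["DERIVED", "PRIMARY"]
        ds.Rows = rows
        ds.Columns = cols
        ds.PixelSpacing = [geom.pixel_spacing[0], geom.pixel_spacing[1]]
        ds.SliceThickness = geom.slice_spacing
        ds.ImagePositionPatient = [float(v) for v in geom.slice_position_mm(k)]
        ds.ImageOrientationPatient = list(geom.row_direction) + list(geom.column_direction)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0 if series.stored.dtype == np.uint16 else 1
        ds.RescaleSlope = series.rescale_slope
        ds.RescaleIntercept = series.rescale_intercept
        if series.radiopharm is not None:
            rp = series.radiopharm
            ds.Units = "BQML"
            ds.DecayCorrection = rp.decay_correction
            ds.PatientWeight = series.patient_weight
            ds.SeriesDate = rp.series_time.strftime("%Y%m%d")
            ds.SeriesTime = rp.series_time.strftime("%H%M%S")
            ds.AcquisitionDate = ds.SeriesDate
            ds.AcquisitionTime = ds.SeriesTime
            rp_item = ds.__class__()
            rp_item.RadionuclideTotalDose = rp.injected_dose
            rp_item.RadionuclideHalfLife = rp.half_life
            rp_item.RadiopharmaceuticalStartDateTime = _dcm_datetime(rp.injection_time)
            ds.RadiopharmaceuticalInformationSequence = [rp_item]
        ds.PixelData = np.ascontiguousarray(series.stored[k]).tobytes()
        path = out_dir / f"{series.context.modality.lower()}_{k:03d}.dcm"
        _dicomio.save(ds, path)
        paths.append(path)
    return paths


def read_image_series(paths_or_dir, time_source: str = "series") -> PhantomSeries:
    """Read a single-series directory (or explicit file list) back into memory.

    *time_source* selects the timestamp used as the decay-correction
    reference for SUV ("series", the default, or "acquisition").
    """
    if isinstance(paths_or_dir, (str, Path)) and Path(paths_or_dir).is_dir():
        paths = sorted(Path(paths_or_dir).glob("*.dcm"))
    else:
        paths = [Path(p) for p in paths_or_dir]
    if not paths:
        raise DicomParseError("no DICOM files found")
    datasets = [dcmread(p) for p in paths]
    series_uids = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(series_uids) != 1:
        raise DicomParseError(f"expected one series, found {len(series_uids)}")
    first = datasets[0]
    row_dir = tuple(float(v) for v in first.ImageOrientationPatient[:3])
    col_dir = tuple(float(v) for v in first.ImageOrientationPatient[3:])
    normal = np.cross(row_dir, col_dir)
    keyed = sorted(
        datasets, key=lambda ds: float(np.dot(normal, [float(v) for v in ds.ImagePositionPatient]))
    )
    origin = np.array([float(v) for v in keyed[0].ImagePositionPatient])
    offsets = tuple(
        float(np.dot(normal, np.array([float(v) for v in ds.ImagePositionPatient]) - origin))
        for ds in keyed
    )
    spacing = (float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    slice_spacing = float(offsets[1] - offsets[0]) if len(offsets) > 1 else float(
        getattr(first, "SliceThickness", 1.0)
    )
    geom = ImageGeometry(
        origin=tuple(origin),
        row_direction=row_dir,
        column_direction=col_dir,
        pixel_spacing=spacing,
        slice_spacing=slice_spacing,
        dimensions=(int(first.Rows), int(first.Columns), len(keyed)),
        slice_positions=offsets,
    )
    slopes = {float(getattr(ds, "RescaleSlope", 1.0)) for ds in keyed}
    dtype = np.uint16 if int(getattr(first, "PixelRepresentation", 0)) == 0 else np.int16
    stored = np.stack(
        [np.frombuffer(ds.PixelData, dtype=dtype).reshape(int(ds.Rows), int(ds.Columns))
         for ds in keyed]
    )
    slope = slopes.pop() if len(slopes) == 1 else float("nan")
    radiopharm = None
    weight = None
    if hasattr(first, "RadiopharmaceuticalInformationSequence"):
        rp = first.RadiopharmaceuticalInformationSequence[0]
        start = datetime.strptime(str(rp.RadiopharmaceuticalStartDateTime)[:14], "%Y%m%d%H%M%S")
        if time_source == "acquisition":
            ref_date, ref_time = str(first.AcquisitionDate), str(first.AcquisitionTime)
        else:
            ref_date, ref_time = str(first.SeriesDate), str(first.SeriesTime)
        series_dt = datetime.strptime(ref_date + ref_time[:6], "%Y%m%d%H%M%S")
        radiopharm = RadiopharmInfo(
            injected_dose=float(rp.RadionuclideTotalDose),
            half_life=float(rp.RadionuclideHalfLife),
            injection_time=start,
            series_time=series_dt,
            decay_correction=str(getattr(first, "DecayCorrection", "START")),
        )
        weight = float(first.PatientWeight)
    return PhantomSeries(
        context=_dicomio.context_from_dataset(first),
        geometry=geom,
        activity=stored.astype(float) * (slope if slope == slope else 1.0),
        stored=stored,
        rescale_slope=slope,
        rescale_intercept=float(getattr(first, "RescaleIntercept", 0.0)),
        instance_uids=tuple(str(ds.SOPInstanceUID) for ds in keyed),
        sop_class_uid=str(first.SOPClassUID),
        radiopharm=radiopharm,
        patient_weight=weight,
    )
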