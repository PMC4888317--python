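"""Body-weight SUV normalization as DICOM Real World Value Mapping.

SUVbw is the tissue activity concentration divided by the decay-corrected
injected dose per unit body weight:

    SUVbw [g/ml] = c [Bq/ml] * 1000 * W [kg] / (D [Bq] * 2^(-dt / T_half))

where ``dt`` is the time from injection to the series start (the series is
assumed decay-corrected to its start, DecayCorrection "START").  Rather
than rewriting the PET pixel data, the factor is encoded as a standalone
Real World Value Mapping (RWVM) object: a linear stored-value -> SUV
transform together with coded quantity ("Standardized Uptake Value"),
method (body weight) and UCUM units (``g/ml{SUVbw}``), referencing every
slice of the PET series it applies to.  The PET rescale slope is folded
into the RWVM slope so the map applies directly to stored pixel values;
one RWVM object is emitted per PET series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from pydicom import dcmread
from pydicom.dataset import Dataset

from . import _dicomio
from .core import CodedConcept, CompositeContext, TerminologyTable, make_uid
from .errors import ChronologyError, DicomParseError, MetadataError, UnsupportedInputError

__all__ = [
    "RadiopharmInfo",
    "RealWorldValueMapping",
    "compute_suvbw_factor",
    "build_rwvm",
    "apply_rwvm",
    "write_rwvm",
    "read_rwvm",
]


@dataclass(frozen=True)
class RadiopharmInfo:
    """Radiopharmaceutical administration metadata from the PET header."""

    injected_dose: float  # Bq
    half_life: float  # s
    injection_time: datetime
    series_time: datetime
    decay_correction: str = "START"

    def __post_init__(self) -> None:
        if self.injected_dose is None or self.injected_dose <= 0:
            raise MetadataError("injected_dose must be positive")
        if self.half_life is None or self.half_life <= 0:
            raise MetadataError("half_life must be positive")
        if self.injection_time is None or self.series_time is None:
            raise MetadataError("injection_time and series_time are required")
        if self.series_time < self.injection_time:
            raise ChronologyError(
                f"series time {self.series_time} precedes injection time {self.injection_time}"
            )

    @property
    def delta_t(self) -> float:
        """Seconds from injection to series start."""
        return (self.series_time - self.injection_time).total_seconds()


def compute_suvbw_factor(weight: float, rp: RadiopharmInfo) -> float:
    """SUVbw factor in (g/ml) per (Bq/ml): 1000*W / (D * 2^(-dt/T_half)).

    Multiplying an activity concentration in Bq/ml by the factor yields
    SUVbw in g/ml.  As dt -> 0 the factor tends to 1000*W/D exactly.
    """
    if weight is None or weight <= 0:
        raise MetadataError("patient weight must be positive (kg)")
    decayed_dose = rp.injected_dose * 2.0 ** (-rp.delta_t / rp.half_life)
    return 1000.0 * weight / decayed_dose


@dataclass(frozen=True)
class RealWorldValueMapping:
    """Linear stored-value -> real-world-value transform with coded semantics."""

    first_value: int
    last_value: int
    slope: float
    intercept: float
    quantity: CodedConcept
    method: CodedConcept
    units: CodedConcept
    referenced_instance_uids: tuple[str, ...]
    referenced_series_uid: str
    referenced_sop_class_uid: str = _dicomio.PET_IMAGE_STORAGE
    label: str = "SUVbw"
    explanation: str = "Standardized Uptake Value body weight"
    sop_instance_uid: str = ""
    study_instance_uid: str = ""

    def __post_init__(self) -> None:
        if self.first_value > self.last_value:
            raise MetadataError("first_value must be <= last_value")
        if self.slope <= 0:
            raise MetadataError("RWVM slope must be positive")
        if not self.referenced_instance_uids:
            raise MetadataError("RWVM must reference at least one PET instance")


def build_rwvm(
    factor: float,
    rescale_slope: float,
    stored_range: tuple[int, int],
    pet_instance_uids,
    terminology: TerminologyTable,
    *,
    series_uid: str,
    sop_class_uid: str = _dicomio.PET_IMAGE_STORAGE,
) -> RealWorldValueMapping:
    """Fold the SUV factor and the series rescale slope into one RWVM.

    The PET series must carry a single series-wide rescale slope; pass the
    set of observed slopes as ``rescale_slope`` being NaN-free and unique —
    a per-slice-varying slope is rejected rather than emitting per-slice
    maps.
    """
    if isinstance(rescale_slope, (set, frozenset, list, tuple)):
        slopes = set(float(s) for s in rescale_slope)
        if len(slopes) != 1:
            raise UnsupportedInputError(
                f"non-uniform rescale slope across the series: {sorted(slopes)}"
            )
        rescale_slope = slopes.pop()
    if rescale_slope != rescale_slope or rescale_slope <= 0:
        raise UnsupportedInputError(f"invalid series rescale slope {rescale_slope!r}")
    return RealWorldValueMapping(
        first_value=int(stored_range[0]),
        last_value=int(stored_range[1]),
        slope=factor * rescale_slope,
        intercept=0.0,
        quantity=terminology.lookup("suv.quantity"),
        method=terminology.lookup("suv.method"),
        units=terminology.lookup("suv.units.rwvm"),
        referenced_instance_uids=tuple(str(u) for u in pet_instance_uids),
        referenced_series_uid=str(series_uid),
        referenced_sop_class_uid=sop_class_uid,
    )


def apply_rwvm(stored: np.ndarray, rwvm: RealWorldValueMapping) -> np.ndarray:
    """Map stored values to SUV (g/ml): ``stored * slope + intercept``.

    Stored values outside [first_value, last_value] are still mapped, but a
    warning reporting their count is emitted.
    """
    stored = np.asarray(stored)
    out_of_range = int(np.count_nonzero((stored < rwvm.first_value) | (stored > rwvm.last_value)))
    if out_of_range:
        warnings.warn(
            f"{out_of_range} stored values outside the RWVM range "
            f"[{rwvm.first_value}, {rwvm.last_value}]; mapped anyway",
            stacklevel=2,
        )
    return stored.astype(float) * rwvm.slope + rwvm.intercept


def _quantity_definition_item(name: CodedConcept, value: CodedConcept) -> Dataset:
    item = Dataset()
    item.ValueType = "CODE"
    item.ConceptNameCodeSequence = [_dicomio.code_item(name)]
    item.ConceptCodeSequence = [_dicomio.code_item(value)]
    return item


def write_rwvm(
    rwvm: RealWorldValueMapping,
    context: CompositeContext,
    path,
    terminology: TerminologyTable,
    rng=None,
) -> RealWorldValueMapping:
    """Write a standalone DICOM RWVM object sharing the PET study context."""
    import random

    rng = rng or random.Random()
    sop_uid = rwvm.sop_instance_uid or make_uid(rng)
    ds = _dicomio.new_dataset(_dicomio.RWVM_STORAGE, sop_uid)
    _dicomio.apply_context(ds, context)
    ds.Modality = "RWV"
    now = datetime.now()
    ds.ContentDate = context.study_date or now.strftime("%Y%m%d")
    ds.ContentTime = context.study_time or now.strftime("%H%M%S")
    ds.InstanceNumber = 1

    map_item = Dataset()
    map_item.RealWorldValueFirstValueMapped = rwvm.first_value
    map_item.RealWorldValueLastValueMapped = rwvm.last_value
    map_item.RealWorldValueSlope = rwvm.slope
    map_item.RealWorldValueIntercept = rwvm.intercept
    map_item.LUTLabel = rwvm.label
    map_item.LUTExplanation = rwvm.explanation
    map_item.MeasurementUnitsCodeSequence = [_dicomio.code_item(rwvm.units)]
    map_item.QuantityDefinitionSequence = [
        _quantity_definition_item(terminology.lookup("rwvm.quantity_name"), rwvm.quantity),
        _quantity_definition_item(terminology.lookup("rwvm.method_name"), rwvm.method),
    ]

    refs = []
    for uid in rwvm.referenced_instance_uids:
        ref = Dataset()
        ref.ReferencedSOPClassUID = rwvm.referenced_sop_class_uid
        ref.ReferencedSOPInstanceUID = uid
        refs.append(ref)
    top = Dataset()
    top.ReferencedImageSequence = refs
    top.RealWorldValueMappingSequence = [map_item]
    ds.ReferencedImageRealWorldValueMappingSequence = [top]

    series_ref = Dataset()
    series_ref.SeriesInstanceUID = rwvm.referenced_series_uid
    ds.ReferencedSeriesSequence = [series_ref]

    _dicomio.save(ds, Path(path))
    return RealWorldValueMapping(
        **{
            **rwvm.__dict__,
            "sop_instance_uid": sop_uid,
            "study_instance_uid": context.study_instance_uid,
        }
    )


def read_rwvm(path) -> RealWorldValueMapping:
    """Parse a standalone RWVM file back into a mapping object."""
    ds = dcmread(path)
    if str(ds.SOPClassUID) != _dicomio.RWVM_STORAGE:
        raise DicomParseError(
            f"not a Real World Value Mapping object (SOP class {ds.SOPClassUID})"
        )
    try:
        top = ds.ReferencedImageRealWorldValueMappingSequence[0]
        map_item = top.RealWorldValueMappingSequence[0]
        refs = tuple(str(r.ReferencedSOPInstanceUID) for r in top.ReferencedImageSequence)
        sop_class = str(top.ReferencedImageSequence[0].ReferencedSOPClassUID)
    except (AttributeError, IndexError) as exc:
        raise DicomParseError(f"malformed RWVM object: {exc}") from exc
    qdef = list(getattr(map_item, "QuantityDefinitionSequence", []))
    if len(qdef) < 2:
        raise DicomParseError("RWVM object lacks quantity/method definitions")
    series_uid = ""
    if hasattr(ds, "ReferencedSeriesSequence"):
        series_uid = str(ds.ReferencedSeriesSequence[0].SeriesInstanceUID)
    return RealWorldValueMapping(
        first_value=int(map_item.RealWorldValueFirstValueMapped),
        last_value=int(map_item.RealWorldValueLastValueMapped),
        slope=float(map_item.RealWorldValueSlope),
        intercept=float(map_item.RealWorldValueIntercept),
        quantity=_dicomio.concept_from_item(qdef[0].ConceptCodeSequence[0]),
        method=_dicomio.concept_from_item(qdef[1].ConceptCodeSequence[0]),
        units=_dicomio.concept_from_item(map_item.MeasurementUnitsCodeSequence[0]),
        referenced_instance_uids=refs,
        referenced_series_uid=series_uid,
        referenced_sop_class_uid=sop_class,
        label=str(getattr(map_item, "LUTLabel", "")),
        explanation=str(getattr(map_item, "LUTExplanation", "")),
        sop_instance_uid=str(ds.SOPInstanceUID),
        study_instance_uid=str(ds.StudyInstanceUID),
    )
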