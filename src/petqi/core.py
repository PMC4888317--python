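"""Shared data model: coded concepts, composite context, image geometry, UIDs.

Every object this toolkit writes carries *semantics* as coded concepts —
(value, scheme, meaning) triplets drawn from SNOMED ("SRT"), the DICOM
lexicon ("DCM"), the NCI Thesaurus ("NCIt"), UCUM for units, or a private
scheme whose designator starts with "99".  Concepts are never hard-coded in
the builders; they are resolved from a terminology table keyed by symbolic
roles (e.g. ``lesion.primary.type``) so codes can be corrected in
configuration without touching code.

Coordinate convention: patient LPS (the DICOM convention), voxel indices
0-based, volumes stored as numpy arrays with axes ``(slice, row, column)``
and slices ordered ascending along the slice normal.
"""

from __future__ import annotations

import importlib.resources
import random
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterator, Mapping

import numpy as np
import yaml

from .errors import GeometryError, MetadataError, TerminologyError

__all__ = [
    "CodedConcept",
    "CompositeContext",
    "ImageGeometry",
    "TerminologyTable",
    "load_default_terminology",
    "make_uid",
    "is_valid_uid",
]

_UID_RE = re.compile(r"^[0-9]+(\.[0-9]+)*$")
_GENERATED_UID_RE = re.compile(r"^2\.25\.[0-9]+$")


def is_valid_uid(uid: str) -> bool:
    """True if *uid* satisfies the DICOM UID grammar (digits and dots, <=64 chars)."""
    return bool(uid) and len(uid) <= 64 and _UID_RE.match(uid) is not None


def make_uid(rng: random.Random) -> str:
    """Generate a UUID-derived UID: ``2.25.`` + decimal 128-bit random integer.

    Deterministic for a seeded ``random.Random``; total length <= 44 < 64.
    """
    return "2.25." + str(rng.getrandbits(128))


@dataclass(frozen=True)
class CodedConcept:
    """A (code value, coding scheme designator, code meaning) triplet."""

    value: str
    scheme: str
    meaning: str

    def __post_init__(self) -> None:
        if not (self.value and self.scheme and self.meaning):
            raise MetadataError(
                f"coded concept requires non-empty value/scheme/meaning, "
                f"got ({self.value!r}, {self.scheme!r}, {self.meaning!r})"
            )
        # UCUM unit expressions and URN-style schemes may exceed the classic
        # 16-char SH limit; ordinary code values may not.
        if self.scheme not in ("UCUM", "URN") and len(self.value) > 16:
            raise MetadataError(
                f"code value {self.value!r} exceeds 16 characters for scheme {self.scheme}"
            )

    @property
    def is_private(self) -> bool:
        """Private coding schemes are marked by a designator starting with 99."""
        return self.scheme.startswith("99")

    def __str__(self) -> str:
        return f'({self.value},{self.scheme},"{self.meaning}")'


class TerminologyTable:
    """Role-keyed map from symbolic roles to coded concepts, loaded from config."""

    def __init__(self, concepts: Mapping[str, CodedConcept]):
        self._concepts = dict(concepts)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping[str, str]]) -> "TerminologyTable":
        concepts = {}
        for role, entry in raw.items():
            try:
                concepts[role] = CodedConcept(
                    value=str(entry["value"]),
                    scheme=str(entry["scheme"]),
                    meaning=str(entry["meaning"]),
                )
            except (KeyError, TypeError) as exc:
                raise MetadataError(f"malformed terminology entry for role {role!r}") from exc
        return cls(concepts)

    @classmethod
    def from_file(cls, path) -> "TerminologyTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise MetadataError(f"terminology file {path} does not hold a role mapping")
        return cls.from_mapping(raw)

    def lookup(self, role: str) -> CodedConcept:
        try:
            return self._concepts[role]
        except KeyError:
            raise TerminologyError(f"unknown terminology role: {role!r}") from None

    def __contains__(self, role: str) -> bool:
        return role in self._concepts

    def roles(self) -> Iterator[str]:
        return iter(self._concepts)

    def find_role(self, concept: CodedConcept) -> str | None:
        """Reverse lookup: first role bound to (value, scheme), else None."""
        for role, c in self._concepts.items():
            if c.value == concept.value and c.scheme == concept.scheme:
                return role
        return None


def load_default_terminology() -> TerminologyTable:
    """Load the terminology table shipped with the package."""
    ref = importlib.resources.files("petqi").joinpath("data/terminology.yaml")
    with importlib.resources.as_file(ref) as path:
        return TerminologyTable.from_file(path)


@dataclass(frozen=True)
class CompositeContext:
    """Patient/study/series identifying attributes shared by related objects.

    All objects with the same ``study_instance_uid`` must carry identical
    patient- and study-level fields; the validation module enforces this.
    """

    patient_id: str
    patient_name: str
    patient_sex: str
    study_instance_uid: str
    study_date: str
    study_time: str
    study_description: str
    frame_of_reference_uid: str
    series_instance_uid: str
    series_number: int
    series_description: str
    modality: str
    patient_birth_date: date | None = None

    def __post_init__(self) -> None:
        for name in ("study_instance_uid", "series_instance_uid", "frame_of_reference_uid"):
            uid = getattr(self, name)
            if not is_valid_uid(uid):
                raise MetadataError(f"{name} is not a valid UID: {uid!r}")
        if not self.patient_id:
            raise MetadataError("patient_id must be non-empty")

    def derive_series(self, rng: random.Random, *, series_number: int,
                      series_description: str, modality: str) -> "CompositeContext":
        """New series context within the same patient/study/frame of reference."""
        return replace(
            self,
            series_instance_uid=make_uid(rng),
            series_number=series_number,
            series_description=series_description,
            modality=modality,
        )


def _unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"direction vector must have 3 components, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class ImageGeometry:
    """Regular 3-D grid in patient LPS millimetre coordinates.

    ``dimensions`` is (rows, columns, slices); the in-memory array axis
    order is (slice, row, column).  ``row_direction`` is the direction of
    increasing column index (along an image row), ``column_direction`` of
    increasing row index, matching the DICOM image-orientation convention.
    """

    origin: tuple[float, float, float]
    row_direction: tuple[float, float, float]
    column_direction: tuple[float, float, float]
    pixel_spacing: tuple[float, float]  # (row spacing, column spacing) mm
    slice_spacing: float
    dimensions: tuple[int, int, int]  # (rows, columns, slices)
    slice_positions: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        r = _unit(self.row_direction)
        c = _unit(self.column_direction)
        if abs(np.linalg.norm(r) - 1) > 1e-6 or abs(np.linalg.norm(c) - 1) > 1e-6:
            raise GeometryError("direction vectors must be unit length")
        if abs(float(np.dot(r, c))) > 1e-6:
            raise GeometryError("row and column directions must be orthogonal")
        if self.pixel_spacing[0] <= 0 or self.pixel_spacing[1] <= 0 or self.slice_spacing <= 0:
            raise GeometryError("spacings must be positive")
        if any(d < 1 for d in self.dimensions):
            raise GeometryError(f"dimensions must be >= 1, got {self.dimensions}")
        if not self.slice_positions:
            object.__setattr__(
                self,
                "slice_positions",
                tuple(float(i) * self.slice_spacing for i in range(self.dimensions[2])),
            )
        if len(self.slice_positions) != self.dimensions[2]:
            raise GeometryError("slice_positions length must equal slice count")
        diffs = np.diff(self.slice_positions)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise GeometryError("slice_positions must be strictly monotonic")

    @property
    def slice_normal(self) -> np.ndarray:
        return np.cross(self.row_direction, self.column_direction)

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (mm^3 / 1000)."""
        return self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_spacing / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        """numpy array shape (slices, rows, columns)."""
        rows, cols, slices = self.dimensions
        return (slices, rows, cols)

    def slice_position_mm(self, slice_index: int) -> np.ndarray:
        """LPS position of the (0,0) voxel of slice *slice_index* (ImagePositionPatient)."""
        return np.asarray(self.origin, float) + self.slice_positions[slice_index] * self.slice_normal

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """LPS coordinates of every voxel center as three (slices, rows, cols) arrays."""
        rows, cols, slices = self.dimensions
        s = np.asarray(self.slice_positions, float)[:, None, None]
        r = np.arange(rows, dtype=float)[None, :, None] * self.pixel_spacing[0]
        c = np.arange(cols, dtype=float)[None, None, :] * self.pixel_spacing[1]
        o = np.asarray(self.origin, float)
        n = self.slice_normal
        rd = np.asarray(self.row_direction, float)
        cd = np.asarray(self.column_direction, float)
        x = o[0] + s * n[0] + r * cd[0] + c * rd[0]
        y = o[1] + s * n[1] + r * cd[1] + c * rd[1]
        z = o[2] + s * n[2] + r * cd[2] + c * rd[2]
        return x, y, z

    def same_grid(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return (
            self.dimensions == other.dimensions
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.row_direction, other.row_direction, atol=tol)
            and np.allclose(self.column_direction, other.column_direction, atol=tol)
            and np.allclose(self.pixel_spacing, other.pixel_spacing, atol=tol)
            and abs(self.slice_spacing - other.slice_spacing) <= tol
            and np.allclose(self.slice_positions, other.slice_positions, atol=tol)
        )
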