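"""Quantitative uptake indices from an SUV volume and a binary ROI.

The lesion panel is the 22-index set used for FDG PET tumor burden
quantification: the SUV summary statistics (mean, min, max, median,
variance, RMS, quartiles, upper adjacent value), segmentation volume,
Total Lesion Glycolysis (TLG = mean SUV x volume), per-quarter means and
glycolysis over the four quarters of the lesion's intensity range,
Standardized Added Metabolic Activity (SAM) with its background term, and
SUVpeak (maximum 1 cm^3 sphere-averaged SUV).  Indices that cannot be
computed meaningfully for a given ROI (e.g. SUVpeak for a sub-1 cm^3
lesion) are carried as explicitly *omitted* entries so the panel always
reports the same 22 names, and downstream structured reports can drop the
omitted ones without placeholders.

Reference regions get a separate 7-statistic summary (mean, max, min,
standard deviation, median, Q1, Q3), and lesion-to-reference SUV ratios
(SUVr) are plain quotients of any two such statistics.

The panel is table-driven (``PANEL_SPEC``): each row names the index, its
terminology roles for quantity/derivation/units, so the coded output can
be corrected in configuration without touching the formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import ImageGeometry
from .errors import EmptyROIError, GeometryError

__all__ = [
    "ROISample",
    "Measurement",
    "IndexPanel",
    "RRSummary",
    "PanelConfig",
    "PANEL_SPEC",
    "PEAK_SPHERE_RADIUS_MM",
    "extract_roi",
    "compute_panel",
    "compute_suv_peak",
    "compute_rr_summary",
    "compute_suvr",
]

# Sphere of volume 1 cm^3: r = (3*1000 / 4 pi)^(1/3) mm
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

# (name, quantity role, derivation role or None, units role)
PANEL_SPEC: tuple[tuple[str, str, str | None, str], ...] = (
    ("SUVmean", "quantity.suvbw", "derivation.mean", "suv.units.sr"),
    ("SUVmin", "quantity.suvbw", "derivation.min", "suv.units.sr"),
    ("SUVmax", "quantity.suvbw", "derivation.max", "suv.units.sr"),
    ("SUVmedian", "quantity.suvbw", "derivation.median", "suv.units.sr"),
    ("SUVvariance", "quantity.suvbw", "derivation.variance", "suv.units.sr"),
    ("SUVrms", "quantity.suvbw", "derivation.rms", "suv.units.sr"),
    ("Q1", "quantity.suvbw", "derivation.q1", "suv.units.sr"),
    ("Q3", "quantity.suvbw", "derivation.q3", "suv.units.sr"),
    ("upper_adjacent", "quantity.suvbw", "derivation.upper_adjacent", "suv.units.sr"),
    ("volume", "quantity.volume", None, "units.ml"),
    ("TLG", "quantity.tlg", None, "units.g"),
    ("q1_range_mean", "quantity.suvbw", "derivation.q1_range_mean", "suv.units.sr"),
    ("q2_range_mean", "quantity.suvbw", "derivation.q2_range_mean", "suv.units.sr"),
    ("q3_range_mean", "quantity.suvbw", "derivation.q3_range_mean", "suv.units.sr"),
    ("q4_range_mean", "quantity.suvbw", "derivation.q4_range_mean", "suv.units.sr"),
    ("glycolysis_q1", "quantity.glycolysis_q1", None, "units.g"),
    ("glycolysis_q2", "quantity.glycolysis_q2", None, "units.g"),
    ("glycolysis_q3", "quantity.glycolysis_q3", None, "units.g"),
    ("glycolysis_q4", "quantity.glycolysis_q4", None, "units.g"),
    ("SAM", "quantity.sam", None, "units.g"),
    ("SAM_background", "quantity.sam_background", None, "suv.units.sr"),
    ("SUVpeak", "quantity.suvbw", "derivation.peak", "suv.units.sr"),
)

RR_SUMMARY_SPEC: tuple[tuple[str, str], ...] = (
    ("mean", "derivation.mean"),
    ("max", "derivation.max"),
    ("min", "derivation.min"),
    ("stddev", "derivation.stddev"),
    ("median", "derivation.median"),
    ("Q1", "derivation.q1"),
    ("Q3", "derivation.q3"),
)


@dataclass(frozen=True)
class ROISample:
    """SUV values at mask-set voxels, in slice-major (slice, row, column) scan order."""

    suv_values: np.ndarray
    voxel_volume: float  # ml
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        if self.voxel_volume <= 0:
            raise GeometryError("voxel_volume must be positive")

    @property
    def n(self) -> int:
        return int(self.suv_values.size)


@dataclass(frozen=True)
class Measurement:
    name: str
    value: float | None
    quantity_role: str
    derivation_role: str | None
    units_role: str
    omitted: bool = False


@dataclass(frozen=True)
class IndexPanel:
    """The 22 named lesion indices, with omitted entries flagged, order fixed."""

    measurements: tuple[Measurement, ...]

    def value(self, name: str) -> float:
        m = self[name]
        if m.omitted:
            raise KeyError(f"index {name!r} was omitted for this ROI")
        return float(m.value)

    def __getitem__(self, name: str) -> Measurement:
        for m in self.measurements:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measurements)

    @property
    def omitted_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measurements if m.omitted)


@dataclass(frozen=True)
class RRSummary:
    """Seven reference-region statistics (g/ml); stddev uses the n-1 denominator."""

    mean: float
    max: float
    min: float
    stddev: float
    median: float
    Q1: float
    Q3: float

    def as_measurements(self) -> tuple[Measurement, ...]:
        return tuple(
            Measurement(
                name=name,
                value=getattr(self, name),
                quantity_role="quantity.suvbw",
                derivation_role=role,
                units_role="suv.units.sr",
            )
            for name, role in RR_SUMMARY_SPEC
        )


@dataclass(frozen=True)
class PanelConfig:
    """Tunables of the panel: SAM shell radii (Chebyshev, voxels) and peak cutoff."""

    sam_shell_inner: int = 2
    sam_shell_outer: int = 4
    peak_min_volume_ml: float = 1.0
    # masks of *all* lesion segments, excluded from the SAM background shell
    exclusion_masks: tuple = field(default_factory=tuple)


def extract_roi(suv: np.ndarray, mask: np.ndarray, geometry: ImageGeometry) -> ROISample:
    """Gather SUV values at mask voxels in fixed slice-major scan order."""
    suv = np.asarray(suv, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if suv.shape != geometry.shape or mask.shape != geometry.shape:
        raise GeometryError(
            f"volume {suv.shape} / mask {mask.shape} do not match grid {geometry.shape}"
        )
    if not mask.any():
        raise EmptyROIError("mask selects no voxels")
    # boolean indexing of a C-ordered array is already (slice, row, col)-major
    return ROISample(suv_values=suv[mask], voxel_volume=geometry.voxel_volume_ml,
                     geometry=geometry)


def _tukey_upper_adjacent(values: np.ndarray, q1: float, q3: float) -> float:
    fence = q3 + 1.5 * (q3 - q1)
    return float(values[values <= fence].max())


def compute_suv_peak(
    suv: np.ndarray, mask: np.ndarray, geometry: ImageGeometry,
    min_volume_ml: float = 1.0,
) -> float | None:
    """Maximum 1 cm^3 sphere-averaged SUV over sphere centers on mask voxels.

    The sphere is discretized by voxel-center inclusion and may extend
    beyond the mask (but not the grid); the average runs over all in-grid
    voxels in the sphere.  Returns ``None`` (omitted) when the mask volume
    is below *min_volume_ml* — no meaningful peak exists for ROIs smaller
    than the averaging sphere.
    """
    suv = np.asarray(suv, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if suv.shape != geometry.shape or mask.shape != geometry.shape:
        raise GeometryError("volume/mask do not match the grid")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise EmptyROIError("mask selects no voxels")
    if n_mask * geometry.voxel_volume_ml < min_volume_ml:
        return None
    ds, dr, dc = geometry.slice_spacing, geometry.pixel_spacing[0], geometry.pixel_spacing[1]
    ks = int(np.floor(PEAK_SPHERE_RADIUS_MM / ds))
    kr = int(np.floor(PEAK_SPHERE_RADIUS_MM / dr))
    kc = int(np.floor(PEAK_SPHERE_RADIUS_MM / dc))
    zz, yy, xx = np.meshgrid(
        np.arange(-ks, ks + 1) * ds,
        np.arange(-kr, kr + 1) * dr,
        np.arange(-kc, kc + 1) * dc,
        indexing="ij",
    )
    kernel = (zz ** 2 + yy ** 2 + xx ** 2) <= PEAK_SPHERE_RADIUS_MM ** 2
    kernel = kernel.astype(float)
    sums = ndimage.convolve(suv, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(suv), kernel, mode="constant", cval=0.0)
    means = sums / counts
    return float(means[mask].max())


def _sam_background_mean(
    suv: np.ndarray, mask: np.ndarray, config: PanelConfig
) -> float | None:
    """Mean SUV in a shell at Chebyshev distance [inner, outer] voxels from the mask,
    excluding every lesion mask."""
    box = np.ones((3, 3, 3), dtype=bool)  # Chebyshev unit ball
    inner = ndimage.binary_dilation(mask, structure=box,
                                    iterations=config.sam_shell_inner - 1) if \
        config.sam_shell_inner > 1 else mask
    outer = ndimage.binary_dilation(mask, structure=box, iterations=config.sam_shell_outer)
    shell = outer & ~inner
    for excl in config.exclusion_masks:
        shell &= ~np.asarray(excl, dtype=bool)
    shell &= ~mask
    if not shell.any():
        return None
    return float(suv[shell].mean())


def compute_panel(
    roi: ROISample,
    suv: np.ndarray,
    mask: np.ndarray,
    geometry: ImageGeometry,
    config: PanelConfig | None = None,
) -> IndexPanel:
    """Compute the full 22-index lesion panel.

    Conventions: variance uses the n-1 denominator (zero for a single
    voxel); quartiles interpolate linearly between order statistics; the
    intensity range [min, max] splits into four equal quarters, the top
    quarter closed, and per-quarter means are omitted when the range is
    degenerate (max == min) while per-quarter glycolysis then attributes
    all voxels to the closed top quarter so the quarters always sum to TLG.
    """
    config = config or PanelConfig()
    suv = np.asarray(suv, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    v = np.asarray(roi.suv_values, dtype=float)
    if v.size == 0:
        raise EmptyROIError("empty ROI sample")
    vv = roi.voxel_volume

    n = v.size
    mean = float(v.mean())
    vmin, vmax = float(v.min()), float(v.max())
    median = float(np.median(v))
    variance = float(v.var(ddof=1)) if n > 1 else 0.0
    rms = float(np.sqrt(np.mean(v ** 2)))
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    upper_adj = _tukey_upper_adjacent(v, q1, q3)
    volume = n * vv
    tlg = mean * volume

    values: dict[str, float | None] = {
        "SUVmean": mean, "SUVmin": vmin, "SUVmax": vmax, "SUVmedian": median,
        "SUVvariance": variance, "SUVrms": rms, "Q1": q1, "Q3": q3,
        "upper_adjacent": upper_adj, "volume": volume, "TLG": tlg,
    }

    # intensity-range quarters: quarter k covers [min + (k-1)/4*(max-min),
    # min + k/4*(max-min)), top quarter closed
    span = vmax - vmin
    if span > 0:
        quarter_index = np.minimum((4 * (v - vmin) / span).astype(int), 3)
    else:
        quarter_index = np.full(n, 3)  # degenerate range: all voxels in top quarter
    for k in range(4):
        sel = quarter_index == k
        name = f"q{k + 1}_range_mean"
        if span > 0 and sel.any():
            values[name] = float(v[sel].mean())
        else:
            values[name] = None
        values[f"glycolysis_q{k + 1}"] = float(v[sel].sum() * vv)

    background = _sam_background_mean(suv, mask, config)
    if background is None:
        values["SAM"] = None
        values["SAM_background"] = None
    else:
        values["SAM_background"] = background
        values["SAM"] = (mean - background) * volume

    values["SUVpeak"] = compute_suv_peak(suv, mask, geometry,
                                         min_volume_ml=config.peak_min_volume_ml)

    measurements = tuple(
        Measurement(
            name=name,
            value=values[name],
            quantity_role=qrole,
            derivation_role=drole,
            units_role=urole,
            omitted=values[name] is None,
        )
        for name, qrole, drole, urole in PANEL_SPEC
    )
    return IndexPanel(measurements=measurements)


def compute_rr_summary(roi: ROISample) -> RRSummary:
    """Seven-statistic summary for a normal-tissue reference region."""
    v = np.asarray(roi.suv_values, dtype=float)
    if v.size == 0:
        raise EmptyROIError("empty reference-region sample")
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    return RRSummary(
        mean=float(v.mean()),
        max=float(v.max()),
        min=float(v.min()),
        stddev=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        median=float(np.median(v)),
        Q1=q1,
        Q3=q3,
    )


def panel_to_text(panel: IndexPanel) -> str:
    """Render the panel as the key-value research interchange text."""
    lines = []
    for m in panel.measurements:
        lines.append(f"{m.name} = (omitted)" if m.omitted else f"{m.name} = {m.value:.10g}")
    return "\n".join(lines) + "\n"


def panel_from_text(text: str) -> IndexPanel:
    """Parse key-value text back into a panel (names must match PANEL_SPEC)."""
    values: dict[str, float | None] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {line_no}: expected 'name = value'")
        name, _, raw = (part.strip() for part in line.partition("="))
        values[name] = None if raw == "(omitted)" else float(raw)
    known = {row[0] for row in PANEL_SPEC}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown index names: {sorted(unknown)}")
    measurements = tuple(
        Measurement(name=name, value=values.get(name), quantity_role=qrole,
                    derivation_role=drole, units_role=urole,
                    omitted=values.get(name) is None)
        for name, qrole, drole, urole in PANEL_SPEC
    )
    return IndexPanel(measurements=measurements)


def compute_suvr(lesion_stat: float, rr_stat: float) -> float:
    """Lesion-to-reference SUV ratio; the reference statistic must be positive."""
    if rr_stat <= 0:
        raise ValueError(f"reference-region statistic must be positive, got {rr_stat}")
    return lesion_stat / rr_stat
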