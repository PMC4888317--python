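# Methods

## SUV model and decay-correction convention

Body-weight SUV is computed as

    SUV_bw [g/ml] = c [Bq/ml] · 1000 · W [kg] / (D [Bq] · 2^(−Δt / T½))

with W the patient weight, D the injected dose, T½ the radionuclide
half-life (seconds) and Δt the elapsed time from injection to the series
reference time. The convention adopted here is that the PET series is
decay-corrected to its start (`DecayCorrection = "START"`), so Δt runs
from the injection timestamp to the series date/time; a switch allows the
acquisition timestamp instead for series where the two differ. Same-day
acquisition is assumed; a negative Δt is a chronology error, not silently
clamped. As Δt → 0 the factor reduces to 1000·W/D exactly.

The factor is never applied destructively. It is encoded as a Real World
Value Mapping whose slope is the product of the SUV factor and the PET
series rescale slope, so the map applies directly to stored pixel values.
A series with per-slice-varying rescale slopes is rejected (one mapping per
series is emitted, not per-slice maps). The first/last mapped values are
the actual stored minimum/maximum of the series; applying the map outside
that range still maps the value but counts and reports it as a warning.

## Phantom model

The synthetic study stands in for an acquired FDG PET/CT: a uniform
background (default 1000 Bq/ml) with spherical lesions, rasterized by
voxel-center inclusion with hard edges — deliberately no partial-volume
effect, so ground-truth volumes and means are analytically checkable.
Lesion voxels take the lesion activity (replacement, not additive), which
makes the recovered ROI mean exactly `activity × SUV factor` on noiseless
data. Defaults: 64×64×40 grid at 2 mm isotropic spacing; a 12 mm primary
tumor at 6000 Bq/ml and a 9 mm node at 4000 Bq/ml; three reference regions
(liver, cerebellum, aortic arch spheres); W = 75 kg, D = 370 MBq,
T½ = 6586.2 s, Δt = 3600 s.

Noise is additive Gaussian on activity (default σ = 50 Bq/ml, i.e. 5% of
background), clipped at zero — a simple stand-in that keeps the intensity
range non-degenerate; it does not model Poisson counting statistics,
attenuation, scatter or reconstruction correlations. Stored values are
16-bit unsigned integers under a single series-wide rescale slope that maps
the series maximum to 32768; the power of two keeps maximum-activity
voxels bit-exact through the stored→real round trip. The companion CT is a
uniform ≈40 HU soft-tissue volume with lesions at ≈60 HU sharing the frame
of reference — spatial localization only, no anatomical realism.

Reader variation is simulated by flipping inner- and outer-boundary voxels
of a mask independently with probability 0.3 (≤1 voxel of boundary change;
the eroded core is never touched, so any mask larger than 3×3×3 stays
non-empty). This emulates contour disagreement magnitude, not its spatial
correlation structure; Dice against the unperturbed sphere stays ≳0.85 for
≥10 mm lesions at 2 mm spacing.

What passing tests on this phantom do **not** show: robustness to
partial-volume effects, reconstruction artifacts, motion, or realistic
reader behavior. They do show that the encoding chain is lossless and the
statistics are computed as specified.

## Index panel conventions

The lesion panel always reports the same 22 named indices; an index that
cannot be computed meaningfully is carried as an explicitly *omitted*
entry (and produces no numeric item in the structured report — no
placeholder zeros). Conventions chosen where more than one definition is
defensible:

- variance and standard deviation use the n−1 denominator (0 for a single
  voxel); quartiles interpolate linearly between order statistics;
- the upper adjacent value is the Tukey upper whisker: the largest sample
  value ≤ Q3 + 1.5·(Q3 − Q1);
- intensity-range quarters split [min, max] into four equal bins, the top
  bin closed; per-quarter means are omitted when max = min, while
  per-quarter glycolysis then attributes all voxels to the top bin so the
  four quarters always sum to TLG;
- SUV peak is the maximum sphere-averaged SUV over a 1 cm³ sphere
  (r ≈ 6.2035 mm) discretized by voxel-center inclusion; candidate centers
  are restricted to mask voxels but the averaging sphere may extend beyond
  the mask (not beyond the grid), so min(volume) ≤ peak ≤ max(volume). The
  peak is omitted when the mask volume is below the 1 cm³ sphere volume;
- SAM = (lesion mean − background mean) × lesion volume, with the
  background mean taken over a shell at Chebyshev distance 2–4 voxels from
  the mask, excluding every lesion segment; shell radii are configurable,
  and SAM is omitted if the shell is empty.

The panel is table-driven: each index row names its quantity, derivation
and units terminology roles, so the coded output can be corrected in
configuration without changing formulas. The panel size (22) is a fixed
contract; corrections to individual formulas must not silently change it.

## SEG encoding choices

Binary frames are packed one bit per voxel, LSB-first within each byte,
concatenated across frames with no per-frame byte alignment (the classic
interoperability trap — stated explicitly and locked by a bit-level
oracle test), zero-padded in the final byte and padded to even payload
length. Frames are ordered segment-major then slice-ascending; the
ordering is fixed by this package (it is a free choice in the standard)
to make byte-level golden tests possible. All-zero frames are elided;
each retained frame records its plane position and (segment, slice)
dimension indices, and the decoder reinserts elided slices as zeros using
the referenced source-series length for the full extent. Frames keep the
full image matrix — no bounding-box cropping. Reference regions are
encoded one segment per object; tumor and nodes segmented in the same
session share one multi-segment object. Display colors are CIELab scaled
to 16 bits (L\* ∈ [0,100] → [0,65535]; a\*, b\* ∈ [−128,127] via
((v+128)/255)·65535), quantized to ±0.5 units on round trip.

The research bridge uses NIfTI (LPS↔RAS handled in the affine); masks are
strictly binary — a label value of 2 is an error, not a truncation.

## Structured reports

Measurement reports follow the TID 1500 arrangement: root container,
image library (references grouped per source series), imaging-measurements
section with one group per ROI. Group context items (tracking identifier
and UID, activity session, time point, finding type/site, referenced
segment, source series, RWVM reference) precede the numeric items, which
follow panel order; serialization is therefore deterministic and the text
dump byte-stable. Session and time point are encoded as integer-string
TEXT items. Numeric values are carried as decimal strings (≤16
characters, `%.10g`), so a value like 5.90721 survives
serialize→parse→dump/CSV bit-exactly. Tracking identifiers follow the
project conventions: "primary tumor", "lymph node *n*" (nodes are not
tracked across sessions), "*region* reference region".

Structural concepts that the standard defines (report, image library,
measurement group, tracking id/uid, derivation, SUVbw, peak) use their
published codes; concepts without a published code in this configuration
(activity session, time point, most derivation statistics, the
quarter/SAM quantities, the whole clinical template) use the private
`99PQI` scheme, flagged as placeholders in the terminology file for later
reconciliation. The clinical template itself ships as a declarative,
explicitly non-normative configuration (demographics / risk factors /
diagnosis / treatment / outcome sections).

## Validation tiers

IOD checking covers a documented subset (the `IOD_REQUIRED` table in
`validation.py`): required-attribute presence, UID grammar, enumerated
algorithm types, frame/payload arithmetic for SEG, reference completeness
for RWVM — not full standard parity. Entity consistency groups objects by
PatientID and StudyInstanceUID and reports any patient- or study-level
attribute that differs within a group, naming both values. Template
validation errors on missing required context items, missing units and
code-meaning disagreements, and warns (only) on unrecognized content
items. Validators always report findings and never raise on bad input, so
a batch run can be triaged from its manifest.

## Problem sizes and determinism

The default phantom (64×64×40) keeps the full batch — 80 image slices,
1 RWVM, 15 SEG, 15 SR, 1 clinical SR, plus validation of all of them —
within a few seconds on one CPU; the test suite's property checks use
16×16×8 grids for the 100-fixture codec identity and ≤1000-voxel ROIs for
the loop-oracle comparisons. A single seed drives phantom noise, mask
perturbation and every UID stream through independent derived sub-streams,
so reruns reproduce manifests identically.

## Known limitations

- No scanner physics: attenuation, scatter, randoms, reconstruction and
  partial-volume effects are out of scope by design.
- SUV variants normalized by body surface area or lean body mass are not
  implemented; only body-weight SUV.
- DICOM output targets Explicit VR Little Endian only; no compressed
  transfer syntaxes, fractional segmentations or surface representations.
- The IOD validator's subset is intentionally narrow; passing it does not
  certify conformance against the full standard.
- Private placeholder codes must be reconciled against curated code lists
  before cross-vendor interoperability testing.
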