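# petqi

Standards-based encoding of quantitative PET/CT analysis results as DICOM
objects, for imaging-biomarker research pipelines that need their outputs —
not just their input images — to be interoperable, indexable and
self-describing.

Quantitative FDG PET analysis of head-and-neck (and other) tumors produces
several kinds of derived data: a normalization of the PET voxel values to
Standardized Uptake Value, volumetric segmentations of tumors, lymph nodes
and normal-tissue reference regions, panels of ROI uptake statistics, and
the clinical context needed to interpret them. `petqi` encodes each with
the matching part of the DICOM standard, and ships a synthetic phantom
generator plus a three-tier validator so the entire chain is testable at
desk scale without scanner data.

## What it encodes

- **SUV normalization → Real World Value Mapping (RWVM).**
  Body-weight SUV is SUV_bw = c · 1000·W / (D · 2^(−Δt/T½)), where
  c is the activity concentration (Bq/ml), W the patient weight (kg),
  D the injected dose (Bq), T½ the radionuclide half-life and Δt the time
  from injection to the (decay-corrected) series start. Instead of
  rewriting pixels, the linear stored-value→SUV transform is written as a
  standalone RWVM object with coded quantity/method and UCUM units
  (`g/ml{SUVbw}`), referencing every slice of the PET series.
- **Segmentations → bit-packed binary SEG objects.** One bit per voxel,
  frames concatenated with no per-frame byte alignment (LSB-first within
  bytes), all-zero frames elided, full-size frames, multi-segment objects
  with coded category/type/anatomic-region semantics, algorithm type,
  CIELab display colors and tracking IDs/UIDs; lossless NIfTI bridge for
  research formats.
- **ROI measurements → TID 1500 structured reports.** A 22-index lesion
  panel (SUV mean/min/max/median/variance/RMS, quartiles, upper adjacent
  value, volume, total lesion glycolysis, intensity-range quarter means and
  glycolysis, standardized added metabolic activity and its background,
  SUV peak over a 1 cm³ sphere), a 7-statistic reference-region summary and
  SUV ratios — encoded as measurement groups with tracking, session, time
  point, finding site, referenced segment and RWVM provenance; exportable
  as a deterministic tree dump or CSV.
- **Clinical records → template-driven SRs.** Demographics, risk factors,
  diagnosis, treatment and outcome from a tab-delimited export, one SR per
  patient in a separate "Clinical Data" study sharing the patient context.
- **Validation.** Per-object IOD subset checks, cross-object composite
  context consistency, and SR template compliance, reported as findings
  rather than exceptions.

All coded semantics resolve through a configurable terminology table
(`src/petqi/data/terminology.yaml`); concepts without a published code use
an explicitly private `99PQI` scheme and can be corrected without touching
code.

## Worked example

Generate a phantom study (64×64×40 grid, 2 mm voxels, hot primary tumor and
one lymph node on a 1 kBq/ml background, three reference regions), compute
the SUV mapping, and quantify the primary lesion:

```sh
$ petqi generate-phantom --out study --seed 7
$ petqi compute-suv study/pet --out-rwvm rwvm.dcm --out-suv suv.nii --seed 7
SUVbw factor: 0.00029607502 (g/ml)/(Bq/ml)
RWVM slope: 5.5517309e-05
$ petqi compute-indices --suv suv.nii --mask study/masks/00_lesion_primary.nii
SUVmean = 1.776339446
SUVmin = 1.732473135
SUVmax = 1.819191217
...
volume = 7.4
TLG = 13.1449119
...
SUVpeak = 1.779065263
```

The factor is 1000·75 kg / (3.7×10⁸ Bq · 2^(−3600/6586.2)) ≈ 2.96×10⁻⁴:
after one F-18 half-life-hour of decay correction, a lesion at
6000 Bq/ml reads SUV ≈ 1.78. The RWVM slope folds in the series rescale
slope so it applies directly to stored pixel values. The lesion volume is
925 voxels × 8 mm³ = 7.4 ml, and TLG = mean SUV × volume ≈ 13.1 g.

The full batch reproduces the repeatability design (3 readers × 2 tools ×
2 sessions, 3 reference regions):

```sh
$ petqi run-batch --out batch --seed 7
{
  "lesion_tasks": 12,
  "RWVM": 1,
  "SEG": 15,
  "SR": 15,
  "CLINICAL_SR": 1
}
status: ok
```

i.e. twelve lesion segmentation sessions plus three reference-region
objects, one measurement SR per SEG, one RWVM per PET series and one
clinical SR per patient — all passing validation. `petqi dump-sr` renders
any measurement report as a content-tree dump, e.g. a peak measurement:

```
<contains NUM:(126401,DCM,"SUVbw") = "5.90721" ({SUVbw} g/ml,UCUM,"Standardized Uptake Value body weight")>
  <has concept mod CODE:(121401,DCM,"Derivation") = (126031,DCM,"Peak Value Within ROI")>
```

and `petqi sr2csv` flattens it to one CSV row per numeric measurement.

## Layout

- `src/petqi/core.py` — coded concepts, terminology, composite context, geometry, UIDs
- `src/petqi/phantom.py` — synthetic PET/CT studies, masks, study-design enumeration
- `src/petqi/suv.py` — SUVbw factor and RWVM build/apply/read/write
- `src/petqi/indices.py` — 22-index lesion panel, reference-region summary, SUVr
- `src/petqi/seg.py` — bit-packed SEG codec and NIfTI bridge
- `src/petqi/sr.py` — TID 1500 builder/serializer/parser, dump and CSV export
- `src/petqi/clinical.py` — clinical table parsing and template-driven SRs
- `src/petqi/validation.py` — IOD, entity-consistency and template validators
- `src/petqi/pipeline.py`, `src/petqi/cli.py` — batch orchestration and the `petqi` CLI

See `docs/methods.md` for the model conventions, parameter defaults and
limitations.
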