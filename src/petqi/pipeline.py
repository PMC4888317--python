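"""Batch orchestration: phantom study -> RWVM + SEGs + SRs + clinical SR.

Reproduces the full conversion pipeline on one study: generate (or load)
the PET/CT series, compute the SUVbw factor and emit one RWVM object,
enumerate the segmentation study design (readers x tools x sessions plus
automatic reference regions), encode one SEG per session, compute the
quantitative index panel per segment and emit one TID 1500 measurement SR
per SEG, encode one clinical SR per patient in a separate "Clinical Data"
study, validate everything, and write a JSON manifest.

For the default design (3 readers x 2 tools x 2 sessions, 3 reference
regions) one study yields 1 RWVM, 15 SEG, 15 measurement SR and 1 clinical
SR objects.

A single seed drives the phantom voxels, the mask perturbations and every
UID stream (independent sub-streams per purpose), so a rerun with the same
configuration reproduces the manifest identically.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path

import numpy as np
import yaml

from . import _dicomio
from .clinical import (ClinicalRecord, encode_clinical_sr, load_default_template,
                       parse_clinical_table)
from .core import CompositeContext, TerminologyTable, load_default_terminology, make_uid
from .indices import PanelConfig, compute_panel, compute_rr_summary, extract_roi
from .phantom import (PhantomSpec, StudyDesign, enumerate_study_design,
                      generate_ct_series, generate_pet_series, ground_truth_mask,
                      perturb_mask, write_image_series)
from .seg import SegmentDescriptor, encode_seg
from .sr import ImageReference, MeasurementGroup, build_measurement_report, serialize_sr
from .suv import apply_rwvm, build_rwvm, compute_suvbw_factor, write_rwvm
from .validation import check_entity_consistency, validate_iod, validate_tid1500

__all__ = ["PipelineConfig", "run_study_batch"]

_SEGMENT_COLORS = ((52.0, -60.0, 50.0), (90.0, -5.0, 85.0), (40.0, 60.0, 30.0))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the batch needs; loadable from YAML."""

    out_dir: Path
    seed: int = 2016
    phantom_spec: PhantomSpec | None = None  # None -> defaults with this seed
    design: StudyDesign = field(default_factory=StudyDesign)
    terminology_path: Path | None = None  # None -> shipped table
    clinical_table: Path | None = None  # None -> one synthetic record
    perturb_rate: float = 0.3

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "phantom_spec" in raw and isinstance(raw["phantom_spec"], (str, Path)):
            raw["phantom_spec"] = PhantomSpec.from_file(raw["phantom_spec"])
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = StudyDesign(**raw["design"])
        raw["out_dir"] = Path(raw["out_dir"])
        return cls(**raw)


def _rr_name(role: str) -> str:
    return role.split(".")[-1].replace("_", " ")


def _default_clinical_record(patient_id: str) -> ClinicalRecord:
    return ClinicalRecord(
        patient_id=patient_id,
        sex="M",
        age=62.0,
        smoking="yes",
        alcohol="yes",
        pathology="Squamous cell carcinoma",
        stage="T2N1M0",
        primary_site="base of tongue",
        nodal_sites="level II",
        surgery="no",
        radiation_dose_gy=70.0,
        chemotherapy="yes",
        followup_date=date(2016, 6, 15),
        status="alive",
    )


def run_study_batch(config: PipelineConfig) -> dict:
    """Run the full conversion pipeline for one study; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    terminology = (
        TerminologyTable.from_file(config.terminology_path)
        if config.terminology_path
        else load_default_terminology()
    )
    spec = config.phantom_spec or PhantomSpec(seed=config.seed)
    design = config.design
    rng = random.Random(f"{config.seed}:pipeline")
    mask_rng = np.random.default_rng(config.seed + 1)

    manifest: dict = {"seed": config.seed, "out_dir": str(out_dir), "objects": []}

    def record(obj_type: str, path: Path, **uids) -> None:
        manifest["objects"].append({"type": obj_type, "path": str(path), **uids})

    # --- image series -----------------------------------------------------
    pet = generate_pet_series(spec)
    ct = generate_ct_series(spec)
    pet_paths = write_image_series(pet, out_dir / "pet")
    ct_paths = write_image_series(ct, out_dir / "ct")
    for p in pet_paths:
        record("PET", p, series_instance_uid=pet.context.series_instance_uid)
    for p in ct_paths:
        record("CT", p, series_instance_uid=ct.context.series_instance_uid)

    # --- SUV factor and the single RWVM object ----------------------------
    factor = compute_suvbw_factor(pet.patient_weight, pet.radiopharm)
    rwvm = build_rwvm(
        factor,
        pet.rescale_slope,
        (int(pet.stored.min()), int(pet.stored.max())),
        pet.instance_uids,
        terminology,
        series_uid=pet.context.series_instance_uid,
    )
    rwvm_context = pet.context.derive_series(
        rng, series_number=10, series_description="SUVbw mapping", modality="RWV"
    )
    rwvm_path = out_dir / "rwvm.dcm"
    rwvm = write_rwvm(rwvm, rwvm_context, rwvm_path, terminology, rng)
    record("RWVM", rwvm_path, sop_instance_uid=rwvm.sop_instance_uid)
    suv = apply_rwvm(pet.stored, rwvm)

    # --- segmentation tasks ------------------------------------------------
    n_lesions = len(spec.lesions)
    truth_lesions = [ground_truth_mask(spec, i) for i in range(n_lesions)]
    truth_rrs = [ground_truth_mask(spec, n_lesions + i)
                 for i in range(len(spec.reference_regions))]
    primary_tracking_uids = [make_uid(rng) for _ in range(n_lesions)]
    rr_tracking_uids = [make_uid(rng) for _ in range(len(spec.reference_regions))]

    tasks = enumerate_study_design(design)
    seg_records = []  # (seg dataset path info, groups for the SR)
    sr_count = 0
    seg_count = 0
    measurement_srs = []

    for task in tasks:
        if task.kind == "lesion":
            masks = [perturb_mask(m, mask_rng, config.perturb_rate) for m in truth_lesions]
            tool_name = "" if task.tool == 1 else "petqi-graphseg"
            algorithm_type = "MANUAL" if task.tool == 1 else "SEMIAUTOMATIC"
            descriptors = []
            node_counter = 0
            for i, lesion in enumerate(spec.lesions):
                is_primary = lesion.role == "lesion.primary"
                if is_primary:
                    label, tracking_id = "Primary tumor", "primary tumor"
                    tracking_uid = primary_tracking_uids[i]
                else:
                    node_counter += 1
                    label = f"Lymph node {node_counter}"
                    tracking_id = f"lymph node {node_counter}"
                    tracking_uid = make_uid(rng)  # nodes are not tracked across sessions
                role_prefix = "lesion.primary" if is_primary else "lesion.node"
                descriptors.append(SegmentDescriptor(
                    segment_number=i + 1,
                    label=label,
                    category=terminology.lookup(f"{role_prefix}.category"),
                    type=terminology.lookup(f"{role_prefix}.type"),
                    anatomic_region=terminology.lookup(f"{role_prefix}.region"),
                    algorithm_type=algorithm_type,
                    algorithm_name=tool_name,
                    display_color=_SEGMENT_COLORS[i % len(_SEGMENT_COLORS)],
                    tracking_id=tracking_id,
                    tracking_uid=tracking_uid,
                ))
            tag = f"reader{task.reader}_tool{task.tool}_session{task.session}"
            description = (f"Tumor segmentation - Reader{task.reader} "
                           f"{algorithm_type.capitalize()} trial {task.session}")
            session_number = task.session
            content_creator = f"Reader^{task.reader}"
        else:
            region = spec.reference_regions[task.rr_index]
            name = _rr_name(region.role)
            masks = [truth_rrs[task.rr_index]]
            descriptors = [SegmentDescriptor(
                segment_number=1,
                label=f"{name} reference region",
                category=terminology.lookup("rr.category"),
                type=terminology.lookup("rr.type"),
                anatomic_region=terminology.lookup(region.role),
                algorithm_type="AUTOMATIC",
                algorithm_name="petqi-rr-auto",
                display_color=(70.0, 0.0, -40.0),
                tracking_id=f"{name} reference region",
                tracking_uid=rr_tracking_uids[task.rr_index],
            )]
            tag = f"rr{task.rr_index + 1}_{name.replace(' ', '_')}"
            description = f"Reference region segmentation - {name}"
            session_number = 1
            content_creator = "petqi-rr-auto"

        seg_path = out_dir / f"seg_{tag}.dcm"
        seg_ds = encode_seg(
            masks,
            descriptors,
            pet,
            content_creator=content_creator,
            time_point_id=str(task.time_point),
            series_session_id=str(session_number),
            rng=rng,
            series_number=100 + seg_count,
            series_description=description,
            path=seg_path,
        )
        seg_count += 1
        record("SEG", seg_path, sop_instance_uid=str(seg_ds.SOPInstanceUID),
               series_instance_uid=str(seg_ds.SeriesInstanceUID))

        # --- one measurement SR per SEG -----------------------------------
        groups = []
        for descriptor, mask in zip(descriptors, masks):
            roi = extract_roi(suv, mask, pet.geometry)
            if task.kind == "lesion":
                panel = compute_panel(
                    roi, suv, mask, pet.geometry,
                    PanelConfig(exclusion_masks=tuple(masks)),
                )
                measurements = panel.measurements
                finding_type = descriptor.type
            else:
                measurements = compute_rr_summary(roi).as_measurements()
                finding_type = descriptor.type
            groups.append(MeasurementGroup(
                tracking_id=descriptor.tracking_id,
                tracking_uid=descriptor.tracking_uid,
                activity_session=session_number,
                time_point=task.time_point,
                referenced_seg_uid=str(seg_ds.SOPInstanceUID),
                segment_number=descriptor.segment_number,
                source_series_uid=pet.context.series_instance_uid,
                rwvm_uid=rwvm.sop_instance_uid,
                measurements=tuple(measurements),
                finding_type=finding_type,
                finding_site=descriptor.anatomic_region,
            ))
        library = [(
            "PET series",
            [ImageReference(pet.sop_class_uid, uid) for uid in pet.instance_uids],
        )]
        if task.kind == "lesion":
            sr_description = (f"tumor measurements - Reader{task.reader} "
                              f"{algorithm_type.capitalize()} trial {task.session}")
        else:
            sr_description = f"measurements - {descriptors[0].tracking_id}"
        sr_context = pet.context.derive_series(
            rng, series_number=200 + sr_count,
            series_description=sr_description, modality="SR",
        )
        doc = build_measurement_report(groups, sr_context, terminology, library)
        sr_path = out_dir / f"sr_{tag}.dcm"
        doc = serialize_sr(doc, sr_path, rng)
        sr_count += 1
        measurement_srs.append((sr_path, doc))
        record("SR", sr_path, sop_instance_uid=doc.sop_instance_uid)

    # --- clinical SR (separate study, same patient) ------------------------
    if config.clinical_table:
        records = parse_clinical_table(config.clinical_table)
        clinical_records = [replace(r, patient_id=pet.context.patient_id)
                            for r in records[:1]]
    else:
        clinical_records = [_default_clinical_record(pet.context.patient_id)]
    template = load_default_template()
    clinical_count = 0
    for rec in clinical_records:
        clinical_context = CompositeContext(
            patient_id=pet.context.patient_id,
            patient_name=pet.context.patient_name,
            patient_sex=pet.context.patient_sex,
            patient_birth_date=pet.context.patient_birth_date,
            study_instance_uid=make_uid(rng),
            study_date=pet.context.study_date,
            study_time=pet.context.study_time,
            study_description="Clinical Data",
            frame_of_reference_uid=make_uid(rng),
            series_instance_uid=make_uid(rng),
            series_number=1,
            series_description="Clinical Data",
            modality="SR",
        )
        clinical_path = out_dir / f"clinical_sr_{clinical_count + 1}.dcm"
        clinical_doc = encode_clinical_sr(rec, template, clinical_context, terminology,
                                          clinical_path, rng)
        clinical_count += 1
        record("CLINICAL_SR", clinical_path, sop_instance_uid=clinical_doc.sop_instance_uid)

    # --- validation --------------------------------------------------------
    all_paths = [Path(o["path"]) for o in manifest["objects"]]
    findings = []
    for p in all_paths:
        findings.extend(validate_iod(p))
    findings.extend(check_entity_consistency(all_paths))
    for _path, doc in measurement_srs:
        findings.extend(validate_tid1500(doc, terminology))

    errors = [f for f in findings if f.severity == "ERROR"]
    manifest["counts"] = {
        "lesion_tasks": sum(1 for t in tasks if t.kind == "lesion"),
        "RWVM": 1,
        "SEG": seg_count,
        "SR": sr_count,
        "CLINICAL_SR": clinical_count,
    }
    manifest["validation"] = {
        "errors": len(errors),
        "warnings": len(findings) - len(errors),
        "findings": [str(f) for f in findings],
    }
    manifest["status"] = "ok" if not errors else "validation-errors"
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
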