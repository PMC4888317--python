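"""TID 1500 measurement reports: build, serialize/parse, dump, CSV export."""

import random

import numpy as np
import pytest

from petqi.core import make_uid
from petqi.errors import DicomParseError, TemplateError
from petqi.indices import Measurement, compute_panel, extract_roi
from petqi.phantom import ground_truth_mask
from petqi.sr import (ImageReference, MeasurementGroup, SRContentItem,
                      build_measurement_report, csv_text, dump_sr_tree, parse_sr,
                      serialize_sr, sr_to_csv)
from petqi.suv import apply_rwvm, build_rwvm, compute_suvbw_factor


@pytest.fixture(scope="module")
def full_panel(terminology):
    """Panel on a noisy phantom lesion: non-degenerate range, no omitted index."""
    from petqi.phantom import PhantomSpec, generate_pet_series

    spec = PhantomSpec()  # default additive noise keeps the intensity range open
    series = generate_pet_series(spec)
    factor = compute_suvbw_factor(series.patient_weight, series.radiopharm)
    rwvm = build_rwvm(factor, series.rescale_slope,
                      (int(series.stored.min()), int(series.stored.max())),
                      series.instance_uids, terminology,
                      series_uid=series.context.series_instance_uid)
    suv = apply_rwvm(series.stored, rwvm)
    mask = ground_truth_mask(spec, 0)
    roi = extract_roi(suv, mask, series.geometry)
    return compute_panel(roi, suv, mask, series.geometry)


def make_group(measurements, rng, pet_series, terminology, tracking_id="primary tumor"):
    return MeasurementGroup(
        tracking_id=tracking_id,
        tracking_uid=make_uid(rng),
        activity_session=1,
        time_point=1,
        referenced_seg_uid=make_uid(rng),
        segment_number=1,
        source_series_uid=pet_series.context.series_instance_uid,
        rwvm_uid=make_uid(rng),
        measurements=tuple(measurements),
        finding_type=terminology.lookup("lesion.primary.type"),
        finding_site=terminology.lookup("lesion.primary.region"),
    )


def make_report(measurements, pet_series, terminology, seed=3, **group_kwargs):
    rng = random.Random(seed)
    group = make_group(measurements, rng, pet_series, terminology, **group_kwargs)
    library = [("PET series",
                [ImageReference(pet_series.sop_class_uid, u)
                 for u in pet_series.instance_uids])]
    context = pet_series.context.derive_series(
        rng, series_number=200, series_description="tumor measurements", modality="SR")
    return build_measurement_report([group], context, terminology, library), rng


PEAK_MEASUREMENT = Measurement("SUVpeak", 5.90721, "quantity.suvbw", "derivation.peak",
                               "suv.units.sr")


class TestBuild:
    def test_peak_measurement_coding(self, pet_series, terminology):
        doc, _ = make_report([PEAK_MEASUREMENT], pet_series, terminology)
        dump = dump_sr_tree(doc.tree)
        assert '(126401,DCM,"SUVbw")' in dump
        assert '(126031,DCM,"Peak Value Within ROI")' in dump
        assert '(121401,DCM,"Derivation")' in dump

    def test_tracking_identifier_conventions(self, pet_series, terminology):
        doc, _ = make_report([PEAK_MEASUREMENT], pet_series, terminology,
                             tracking_id="liver reference region")
        assert '"liver reference region"' in dump_sr_tree(doc.tree)
        doc, _ = make_report([PEAK_MEASUREMENT], pet_series, terminology,
                             tracking_id="lymph node 1")
        assert '"lymph node 1"' in dump_sr_tree(doc.tree)

    def test_empty_group_rejected_at_build(self, pet_series, terminology):
        omitted = Measurement("SUVpeak", None, "quantity.suvbw", "derivation.peak",
                              "suv.units.sr", omitted=True)
        with pytest.raises(TemplateError):
            make_report([omitted], pet_series, terminology)

    def test_missing_tracking_id_is_template_error(self, pet_series, terminology):
        with pytest.raises(TemplateError, match="tracking"):
            make_report([PEAK_MEASUREMENT], pet_series, terminology, tracking_id="")

    def test_omitted_measurements_produce_no_num_item(self, full_panel, pet_series,
                                                      terminology):
        # force one omission by dropping SUVpeak
        measurements = tuple(
            Measurement(m.name, None if m.name == "SUVpeak" else m.value,
                        m.quantity_role, m.derivation_role, m.units_role,
                        omitted=m.name == "SUVpeak")
            for m in full_panel.measurements
        )
        doc, _ = make_report(measurements, pet_series, terminology)
        nums = [i for _d, i in doc.tree.iter_depth_first() if i.value_type == "NUM"]
        assert len(nums) == 21


class TestSerializeParse:
    def test_full_panel_round_trip(self, full_panel, pet_series, terminology, tmp_path):
        doc, rng = make_report(full_panel.measurements, pet_series, terminology)
        path = tmp_path / "sr.dcm"
        serialize_sr(doc, path, rng)
        parsed = parse_sr(path)
        assert parsed.tree == doc.tree
        assert parsed.context.patient_id == doc.context.patient_id
        assert parsed.context.study_instance_uid == doc.context.study_instance_uid

    def test_worked_example_value_survives_serialization(self, pet_series, terminology,
                                                         tmp_path):
        doc, rng = make_report([PEAK_MEASUREMENT], pet_series, terminology)
        path = tmp_path / "peak.dcm"
        serialize_sr(doc, path, rng)
        parsed = parse_sr(path)
        dump = dump_sr_tree(parsed.tree)
        line = next(l for l in dump.splitlines() if "SUVbw" in l and "NUM" in l)
        assert '"5.90721"' in line
        assert '(126401,DCM,"SUVbw")' in line
        assert '({SUVbw} g/ml,UCUM' in line
        rows = sr_to_csv(parsed, terminology)
        assert rows[1][rows[0].index("value")] == "5.90721"

    def test_parse_non_sr_is_typed_error(self, tmp_path, pet_series):
        from petqi.phantom import write_image_series

        paths = write_image_series(pet_series, tmp_path / "pet")
        with pytest.raises(DicomParseError):
            parse_sr(paths[0])

    def test_serialized_report_passes_template_validation(self, full_panel, pet_series,
                                                          terminology, tmp_path):
        from petqi.validation import validate_tid1500

        doc, rng = make_report(full_panel.measurements, pet_series, terminology)
        serialize_sr(doc, tmp_path / "sr.dcm", rng)
        parsed = parse_sr(tmp_path / "sr.dcm")
        findings = validate_tid1500(parsed, terminology)
        assert [f for f in findings if f.severity == "ERROR"] == []


class TestDump:
    def test_single_item_tree(self, terminology):
        root = SRContentItem("CONTAINER", terminology.lookup("sr.report"))
        dump = dump_sr_tree(root)
        assert dump.count("\n") == 1
        assert "Imaging Measurement Report" in dump

    def test_dump_is_deterministic(self, full_panel, pet_series, terminology):
        doc, _ = make_report(full_panel.measurements, pet_series, terminology)
        assert dump_sr_tree(doc.tree) == dump_sr_tree(doc.tree)


class TestCsv:
    def test_row_count_equals_num_items(self, full_panel, pet_series, terminology):
        doc, _ = make_report(full_panel.measurements, pet_series, terminology)
        rows = sr_to_csv(doc, terminology)
        nums = sum(1 for _d, i in doc.tree.iter_depth_first() if i.value_type == "NUM")
        assert len(rows) - 1 == nums
        # the full phantom panel has no omissions: all 22 indices present
        assert nums == 22

    def test_header_stable(self, full_panel, pet_series, terminology):
        doc, _ = make_report(full_panel.measurements, pet_series, terminology)
        rows = sr_to_csv(doc, terminology)
        assert rows[0] == [
            "patient_id", "study_instance_uid", "tracking_id", "tracking_uid",
            "time_point", "session", "finding_site", "quantity_value",
            "quantity_scheme", "quantity_meaning", "derivation", "value", "units",
        ]
        text = csv_text(rows)
        assert text.splitlines()[0].startswith("patient_id,")

    def test_non_report_tree_rejected(self, terminology, pet_series):
        from petqi.sr import SRDocument

        root = SRContentItem("CONTAINER", terminology.lookup("clinical.report"))
        doc = SRDocument(context=pet_series.context, tree=root)
        with pytest.raises(TemplateError):
            sr_to_csv(doc, terminology)
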