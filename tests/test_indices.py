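"""Lesion index panel, SUVpeak, reference-region summary, SUV ratios.

Every panel statistic is cross-checked against a naive loop-based
recomputation on small ROIs, and SUVpeak against exhaustive center
enumeration.
"""

import math

import numpy as np
import pytest

from petqi.core import ImageGeometry
from petqi.errors import EmptyROIError, GeometryError
from petqi.indices import (PANEL_SPEC, PEAK_SPHERE_RADIUS_MM, IndexPanel, PanelConfig,
                           compute_panel, compute_rr_summary, compute_suv_peak,
                           compute_suvr, extract_roi, panel_from_text, panel_to_text)
from petqi.phantom import (PhantomSpec, SphereRegion, generate_pet_series,
                           ground_truth_mask)
from petqi.suv import apply_rwvm, build_rwvm, compute_suvbw_factor


def small_geometry(shape=(10, 12, 14), spacing=2.0):
    slices, rows, cols = shape
    return ImageGeometry(
        origin=(0.0, 0.0, 0.0),
        row_direction=(1.0, 0.0, 0.0),
        column_direction=(0.0, 1.0, 0.0),
        pixel_spacing=(spacing, spacing),
        slice_spacing=spacing,
        dimensions=(rows, cols, slices),
    )


def naive_panel_oracle(values, voxel_ml):
    """Loop-based recomputation of the closed-form panel statistics."""
    values = sorted(float(v) for v in values)
    n = len(values)
    mean = sum(values) / n
    variance = sum((v - mean) ** 2 for v in values) / (n - 1) if n > 1 else 0.0
    rms = math.sqrt(sum(v * v for v in values) / n)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        return values[lo] + (pos - lo) * (values[hi] - values[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    fence = q3 + 1.5 * (q3 - q1)
    upper_adjacent = max(v for v in values if v <= fence)
    volume = n * voxel_ml
    return {
        "SUVmean": mean, "SUVmin": values[0], "SUVmax": values[-1], "SUVmedian": med,
        "SUVvariance": variance, "SUVrms": rms, "Q1": q1, "Q3": q3,
        "upper_adjacent": upper_adjacent, "volume": volume, "TLG": mean * volume,
    }


def brute_force_peak(suv, mask, geom):
    """Exhaustive sphere-mean enumeration over every mask voxel center."""
    slices, rows, cols = suv.shape
    sp_s, sp_r, sp_c = geom.slice_spacing, geom.pixel_spacing[0], geom.pixel_spacing[1]
    best = -math.inf
    centers = np.argwhere(mask)
    for cs, cr, cc in centers:
        total, count = 0.0, 0
        for s in range(slices):
            for r in range(rows):
                for c in range(cols):
                    d2 = (((s - cs) * sp_s) ** 2 + ((r - cr) * sp_r) ** 2
                          + ((c - cc) * sp_c) ** 2)
                    if d2 <= PEAK_SPHERE_RADIUS_MM ** 2:
                        total += suv[s, r, c]
                        count += 1
        best = max(best, total / count)
    return best


class TestExtractRoi:
    def test_sample_length(self):
        geom = small_geometry()
        suv = np.ones(geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[0, 0, 0] = mask[3, 4, 5] = mask[9, 11, 13] = True
        roi = extract_roi(suv, mask, geom)
        assert roi.n == 3

    def test_full_volume_mask(self):
        geom = small_geometry()
        suv = np.random.default_rng(0).random(geom.shape)
        roi = extract_roi(suv, np.ones(geom.shape, dtype=bool), geom)
        assert roi.n == suv.size
        # fixed slice-major scan order
        assert np.array_equal(roi.suv_values, suv.ravel())

    def test_shape_mismatch_is_error(self):
        geom = small_geometry()
        with pytest.raises(GeometryError):
            extract_roi(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), geom)

    def test_empty_mask_is_error(self):
        geom = small_geometry()
        with pytest.raises(EmptyROIError):
            extract_roi(np.ones(geom.shape), np.zeros(geom.shape, bool), geom)


class TestPanel:
    def test_uniform_roi_closed_form(self):
        geom = small_geometry(spacing=2.0)  # voxel = 0.008 ml... use 5 mm for 0.125 ml
        geom = ImageGeometry(
            origin=(0.0, 0.0, 0.0), row_direction=(1.0, 0.0, 0.0),
            column_direction=(0.0, 1.0, 0.0), pixel_spacing=(5.0, 5.0),
            slice_spacing=5.0, dimensions=(10, 10, 10))
        suv = np.zeros(geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:7, 2:6, 2:6] = True  # 5*4*4 = 80 voxels of 0.125 ml
        suv[mask] = 5.0
        roi = extract_roi(suv, mask, geom)
        panel = compute_panel(roi, suv, mask, geom)
        assert panel.value("SUVmean") == 5.0
        assert panel.value("volume") == pytest.approx(10.0)
        assert panel.value("TLG") == pytest.approx(50.0)
        assert panel.value("SUVvariance") == 0.0
        assert panel.value("SUVrms") == 5.0

    def test_four_point_sample_statistics(self):
        geom = small_geometry()
        suv = np.zeros(geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[0, 0, :4] = True
        suv[0, 0, :4] = [1.0, 2.0, 3.0, 4.0]
        roi = extract_roi(suv, mask, geom)
        panel = compute_panel(roi, suv, mask, geom)
        assert panel.value("SUVmedian") == pytest.approx(2.5)
        assert panel.value("SUVrms") == pytest.approx(math.sqrt(30 / 4))

    def test_panel_reports_exactly_22_named_indices(self):
        geom = small_geometry()
        rng = np.random.default_rng(1)
        suv = rng.random(geom.shape) + 1.0
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:8, 2:9, 2:9] = True
        panel = compute_panel(extract_roi(suv, mask, geom), suv, mask, geom)
        assert len(panel.measurements) == 22
        assert len(set(panel.names)) == 22
        assert set(panel.names) == {row[0] for row in PANEL_SPEC}

    def test_panel_order_invariants(self):
        geom = small_geometry()
        rng = np.random.default_rng(2)
        suv = rng.lognormal(0.5, 0.4, geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[1:9, 1:10, 1:12] = True
        panel = compute_panel(extract_roi(suv, mask, geom), suv, mask, geom)
        assert (panel.value("SUVmin") <= panel.value("Q1") <= panel.value("SUVmedian")
                <= panel.value("Q3") <= panel.value("SUVmax"))
        assert panel.value("SUVmin") <= panel.value("SUVmean") <= panel.value("SUVmax")
        assert panel.value("SUVrms") >= abs(panel.value("SUVmean"))
        assert panel.value("SUVvariance") >= 0
        assert panel.value("TLG") == panel.value("SUVmean") * panel.value("volume")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_statistics_match_naive_loop_oracle(self, seed):
        geom = small_geometry(shape=(8, 9, 10))
        rng = np.random.default_rng(seed)
        suv = rng.random(geom.shape) * 8.0
        mask = rng.random(geom.shape) < 0.5  # ~360 voxels < 1000
        if not mask.any():
            mask[0, 0, 0] = True
        roi = extract_roi(suv, mask, geom)
        panel = compute_panel(roi, suv, mask, geom)
        oracle = naive_panel_oracle(roi.suv_values, geom.voxel_volume_ml)
        for name, expected in oracle.items():
            assert panel.value(name) == pytest.approx(expected, rel=1e-9), name

    @pytest.mark.parametrize("seed", [0, 7])
    def test_quarter_glycolysis_sums_to_tlg(self, seed):
        geom = small_geometry()
        rng = np.random.default_rng(seed)
        suv = rng.random(geom.shape) * 10.0
        mask = rng.random(geom.shape) < 0.3
        panel = compute_panel(extract_roi(suv, mask, geom), suv, mask, geom)
        total = sum(panel.value(f"glycolysis_q{k}") for k in range(1, 5))
        assert total == pytest.approx(panel.value("TLG"), rel=1e-9)

    def test_degenerate_range_omits_quarter_means_but_keeps_sum_rule(self):
        geom = small_geometry()
        suv = np.full(geom.shape, 3.0)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        panel = compute_panel(extract_roi(suv, mask, geom), suv, mask, geom)
        for k in range(1, 5):
            assert panel[f"q{k}_range_mean"].omitted
        total = sum(panel.value(f"glycolysis_q{k}") for k in range(1, 5))
        assert total == pytest.approx(panel.value("TLG"), rel=1e-12)

    def test_key_value_text_round_trip(self):
        geom = small_geometry()
        rng = np.random.default_rng(3)
        suv = rng.random(geom.shape) + 0.5
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        panel = compute_panel(extract_roi(suv, mask, geom), suv, mask, geom)
        back = panel_from_text(panel_to_text(panel))
        assert back.names == panel.names
        assert back.omitted_names == panel.omitted_names
        for m in panel.measurements:
            if not m.omitted:
                assert back.value(m.name) == pytest.approx(m.value, rel=1e-9)


class TestSuvPeak:
    def test_uniform_field_peak_is_the_value(self):
        geom = small_geometry(shape=(12, 12, 12))
        suv = np.full(geom.shape, 4.0)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[3:9, 3:9, 3:9] = True  # 216 voxels * 8 mm3 = 1.73 ml
        assert compute_suv_peak(suv, mask, geom) == pytest.approx(4.0, rel=1e-12)

    def test_small_roi_is_omitted(self):
        geom = small_geometry()
        suv = np.ones(geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:4, 2:6, 2:6] = True  # 32 voxels * 8 mm3 = 0.256 ml < 1 cm3
        assert compute_suv_peak(suv, mask, geom) is None

    def test_matches_exhaustive_enumeration_and_is_bounded(self):
        geom = small_geometry(shape=(9, 9, 9), spacing=3.0)
        rng = np.random.default_rng(4)
        suv = rng.random(geom.shape) * 6.0
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        peak = compute_suv_peak(suv, mask, geom)
        assert peak == pytest.approx(brute_force_peak(suv, mask, geom), rel=1e-12)
        assert suv.min() <= peak <= suv.max()


class TestParameterRecovery:
    def test_noiseless_lesion_mean_and_volume(self, terminology):
        activity = 5000.0
        region = SphereRegion((40.0, 40.0, 30.0), 11.0, "lesion.primary", activity)
        spec = PhantomSpec(noise_sigma=0.0, lesions=(region,), reference_regions=())
        series = generate_pet_series(spec)
        factor = compute_suvbw_factor(series.patient_weight, series.radiopharm)
        rwvm = build_rwvm(factor, series.rescale_slope,
                          (int(series.stored.min()), int(series.stored.max())),
                          series.instance_uids, terminology,
                          series_uid=series.context.series_instance_uid)
        suv = apply_rwvm(series.stored, rwvm)
        mask = ground_truth_mask(spec, 0)
        roi = extract_roi(suv, mask, series.geometry)
        panel = compute_panel(roi, suv, mask, series.geometry)
        assert panel.value("SUVmean") == pytest.approx(activity * factor, rel=1e-6)
        assert panel.value("volume") == pytest.approx(
            int(mask.sum()) * series.geometry.voxel_volume_ml, rel=1e-12)


class TestRRSummaryAndRatio:
    def test_constant_sample(self):
        geom = small_geometry()
        suv = np.full(geom.shape, 2.5)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        s = compute_rr_summary(extract_roi(suv, mask, geom))
        assert s.stddev == 0.0
        assert s.mean == s.max == s.min == s.median == s.Q1 == s.Q3 == 2.5

    def test_three_point_sample(self):
        geom = small_geometry()
        suv = np.zeros(geom.shape)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[0, 0, :3] = True
        suv[0, 0, :3] = [1.0, 2.0, 3.0]
        s = compute_rr_summary(extract_roi(suv, mask, geom))
        assert s.mean == pytest.approx(2.0)
        assert s.median == pytest.approx(2.0)

    def test_quartile_ordering_on_random_fixture(self):
        geom = small_geometry()
        rng = np.random.default_rng(8)
        suv = rng.random(geom.shape)
        mask = rng.random(geom.shape) < 0.4
        s = compute_rr_summary(extract_roi(suv, mask, geom))
        assert s.min <= s.Q1 <= s.median <= s.Q3 <= s.max

    def test_suvr(self):
        assert compute_suvr(6.0, 2.0) == pytest.approx(3.0)
        assert compute_suvr(1.7, 1.7) == pytest.approx(1.0)
        assert compute_suvr(4.2 * 3, 1.3 * 3) == pytest.approx(compute_suvr(4.2, 1.3))
        with pytest.raises(ValueError):
            compute_suvr(1.0, 0.0)
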