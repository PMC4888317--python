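"""SEG codec: bit packing against a brute-force oracle, encode/decode identity,
frame elision, CIELab color encoding, NIfTI bridge."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petqi.core import make_uid
from petqi.errors import DicomParseError, GeometryError, MetadataError
from petqi.phantom import PhantomSpec, generate_pet_series, ground_truth_mask
from petqi.seg import (SegmentDescriptor, decode_cielab, decode_seg, encode_cielab,
                       encode_seg, pack_bits, read_mask_nifti, research_to_seg,
                       seg_to_research, unpack_bits, write_mask_nifti)


def brute_force_pack(frames):
    """Bit-by-bit reference packer: LSB-first, no inter-frame alignment."""
    bits = []
    for frame in frames:
        bits.extend(int(v) for v in np.asarray(frame).ravel())
    out = bytearray((len(bits) + 7) // 8)
    for i, bit in enumerate(bits):
        if bit:
            out[i // 8] |= 1 << (i % 8)
    if len(out) % 2:
        out.append(0)
    return bytes(out)


class TestPackBits:
    def test_single_byte_lsb_first(self):
        packed = pack_bits([np.array([1, 0, 0, 0, 0, 0, 0, 0])])
        assert packed[0] == 0x01

    def test_two_unaligned_frames(self):
        f1 = np.zeros(12, dtype=int)
        f1[[0, 11]] = 1
        f2 = np.zeros(12, dtype=int)
        f2[0] = 1
        packed = pack_bits([f1, f2])
        assert packed[:3] == bytes([0x01, 0x18, 0x00])
        assert len(packed) % 2 == 0

    def test_all_zero_frames(self):
        packed = pack_bits([np.zeros(20, dtype=int)] * 3)
        expected = (3 * 20 + 7) // 8
        expected += expected % 2
        assert packed == b"\x00" * expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            pack_bits([np.array([0, 2, 1])])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(1, 7), rng.integers(1, 9))
        frames = [rng.integers(0, 2, shape) for _ in range(rng.integers(1, 5))]
        assert pack_bits(frames) == brute_force_pack(frames)


class TestUnpackBits:
    @given(
        st.integers(1, 4), st.integers(1, 9), st.integers(1, 9),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_property(self, n_frames, rows, cols, seed):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 2, (n_frames, rows, cols))
        packed = pack_bits(list(frames))
        back = unpack_bits(packed, n_frames, rows, cols)
        assert np.array_equal(back, frames)

    def test_truncated_payload_is_error(self):
        with pytest.raises(DicomParseError):
            unpack_bits(b"\x01", 2, 4, 4)


class TestCielab:
    def test_white_point(self):
        assert encode_cielab(100, 0, 0) == (65535, 32896, 32896)

    def test_lower_bound(self):
        assert encode_cielab(0, -128, -128) == (0, 0, 0)

    def test_round_trip_within_quantization(self):
        for triple in [(50.0, 20.0, -30.0), (99.9, -127.5, 126.9), (0.1, 0.0, 0.0)]:
            back = decode_cielab(encode_cielab(*triple))
            assert np.allclose(back, triple, atol=0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_cielab(101, 0, 0)


@pytest.fixture()
def descriptors(terminology):
    rng = random.Random(17)
    return [
        SegmentDescriptor(
            segment_number=1,
            label="Primary tumor",
            category=terminology.lookup("lesion.primary.category"),
            type=terminology.lookup("lesion.primary.type"),
            anatomic_region=terminology.lookup("lesion.primary.region"),
            algorithm_type="MANUAL",
            tracking_id="primary tumor",
            tracking_uid=make_uid(rng),
            display_color=(52.0, -60.0, 50.0),
        ),
        SegmentDescriptor(
            segment_number=2,
            label="Lymph node 1",
            category=terminology.lookup("lesion.node.category"),
            type=terminology.lookup("lesion.node.type"),
            anatomic_region=terminology.lookup("lesion.node.region"),
            algorithm_type="SEMIAUTOMATIC",
            algorithm_name="petqi-graphseg",
            tracking_id="lymph node 1",
            tracking_uid=make_uid(rng),
            display_color=(90.0, -5.0, 85.0),
        ),
    ]


class TestEncodeDecode:
    def test_two_segment_round_trip(self, tmp_path, pet_series, noiseless_spec,
                                    descriptors):
        masks = [ground_truth_mask(noiseless_spec, 0).astype(np.uint8),
                 ground_truth_mask(noiseless_spec, 1).astype(np.uint8)]
        path = tmp_path / "seg.dcm"
        rng = random.Random(5)
        encode_seg(masks, descriptors, pet_series, content_creator="Reader^1",
                   time_point_id="1", series_session_id="2", rng=rng, path=path)
        decoded = decode_seg(path)
        assert np.array_equal(decoded.masks[1], masks[0])
        assert np.array_equal(decoded.masks[2], masks[1])
        import dataclasses
        for got, want in zip(decoded.descriptors, descriptors):
            assert np.allclose(got.display_color, want.display_color, atol=0.5)
            assert dataclasses.replace(got, display_color=want.display_color) == want
        assert decoded.content_creator == "Reader^1"
        assert decoded.time_point_id == "1"
        assert decoded.series_session_id == "2"
        assert decoded.geometry.same_grid(pet_series.geometry, tol=1e-6)
        assert decoded.source_instance_uids == pet_series.instance_uids

    def test_elision_retains_only_nonempty_slices(self, tmp_path, pet_series,
                                                  descriptors):
        geom = pet_series.geometry
        mask = np.zeros(geom.shape, dtype=np.uint8)
        mask[10:15] = 1  # 5 of 40 slices populated
        rng = random.Random(6)
        ds = encode_seg([mask], descriptors[:1], pet_series, content_creator="R",
                        time_point_id="1", series_session_id="1", rng=rng,
                        path=tmp_path / "one.dcm")
        assert int(ds.NumberOfFrames) == 5
        decoded = decode_seg(tmp_path / "one.dcm")
        assert np.array_equal(decoded.masks[1], mask)
        # elided slices reconstructed as zeros
        assert decoded.masks[1][:10].sum() == 0 and decoded.masks[1][15:].sum() == 0
        assert len(decoded.frame_map) == 5
        assert [m[1] for m in decoded.frame_map] == list(range(10, 15))

    @pytest.mark.parametrize("seed", range(12))
    def test_voxel_count_invariant_on_random_masks(self, tmp_path, seed, descriptors):
        spec = PhantomSpec(dimensions=(16, 16, 8), lesions=(), reference_regions=(),
                           seed=seed)
        series = generate_pet_series(spec)
        rng_np = np.random.default_rng(seed)
        masks = [(rng_np.random(series.geometry.shape) < 0.2).astype(np.uint8)
                 for _ in range(2)]
        if not any(m.any() for m in masks):
            masks[0][0, 0, 0] = 1
        path = tmp_path / f"seg_{seed}.dcm"
        encode_seg(masks, descriptors, series, content_creator="R", time_point_id="1",
                   series_session_id="1", rng=random.Random(seed), path=path)
        decoded = decode_seg(path)
        for i, m in enumerate(masks, start=1):
            assert np.array_equal(decoded.masks[i], m)
            assert decoded.masks[i].sum() == m.sum()

    def test_grid_mismatch_rejected(self, pet_series, descriptors):
        with pytest.raises(GeometryError):
            encode_seg([np.ones((2, 2, 2), np.uint8)], descriptors[:1], pet_series,
                       content_creator="R", time_point_id="1", series_session_id="1",
                       rng=random.Random(0))

    def test_empty_object_rejected(self, pet_series, descriptors):
        empty = np.zeros(pet_series.geometry.shape, np.uint8)
        with pytest.raises(MetadataError):
            encode_seg([empty], descriptors[:1], pet_series, content_creator="R",
                       time_point_id="1", series_session_id="1", rng=random.Random(0))


class TestDescriptors:
    def test_algorithm_name_required_unless_manual(self, terminology):
        with pytest.raises(MetadataError):
            SegmentDescriptor(
                segment_number=1, label="x",
                category=terminology.lookup("rr.category"),
                type=terminology.lookup("rr.type"),
                algorithm_type="AUTOMATIC", tracking_id="t", tracking_uid="2.25.1")

    def test_unknown_algorithm_type_rejected(self, terminology):
        with pytest.raises(MetadataError):
            SegmentDescriptor(
                segment_number=1, label="x",
                category=terminology.lookup("rr.category"),
                type=terminology.lookup("rr.type"),
                algorithm_type="AUTO", tracking_id="t", tracking_uid="2.25.1")


class TestResearchBridge:
    def test_nifti_round_trip_voxels_and_geometry(self, tmp_path, noiseless_spec):
        mask = ground_truth_mask(noiseless_spec, 0).astype(np.uint8)
        geom = noiseless_spec.geometry
        path = tmp_path / "mask.nii"
        write_mask_nifti(mask, geom, path)
        back, back_geom = read_mask_nifti(path)
        assert np.array_equal(back, mask)
        assert back_geom.same_grid(geom, tol=1e-6)

    def test_seg_to_research_and_back(self, tmp_path, pet_series, noiseless_spec,
                                      descriptors, terminology):
        masks = [ground_truth_mask(noiseless_spec, 0).astype(np.uint8),
                 ground_truth_mask(noiseless_spec, 1).astype(np.uint8)]
        seg_path = tmp_path / "seg.dcm"
        encode_seg(masks, descriptors, pet_series, content_creator="R",
                   time_point_id="1", series_session_id="1", rng=random.Random(1),
                   path=seg_path)
        written = seg_to_research(seg_path, tmp_path / "masks")
        assert len(written) == 2
        entries = [
            {"label": "Primary tumor", "category_role": "lesion.primary.category",
             "type_role": "lesion.primary.type", "region_role": "lesion.primary.region",
             "algorithm_type": "MANUAL", "tracking_id": "primary tumor"},
            {"label": "Lymph node 1", "category_role": "lesion.node.category",
             "type_role": "lesion.node.type", "region_role": "lesion.node.region",
             "algorithm_type": "MANUAL", "tracking_id": "lymph node 1"},
        ]
        seg2 = tmp_path / "seg2.dcm"
        research_to_seg(written, entries, pet_series, terminology,
                        content_creator="R", rng=random.Random(2), path=seg2)
        decoded = decode_seg(seg2)
        assert np.array_equal(decoded.masks[1], masks[0])
        assert np.array_equal(decoded.masks[2], masks[1])

    def test_non_binary_research_mask_rejected(self, tmp_path, pet_series, terminology):
        labels = np.zeros(pet_series.geometry.shape, dtype=np.uint8)
        labels[5, 5, 5] = 2
        path = tmp_path / "labels.nii"
        write_mask_nifti(labels, pet_series.geometry, path)
        with pytest.raises(MetadataError):
            research_to_seg([path], [{"label": "x", "category_role": "rr.category",
                                      "type_role": "rr.type", "algorithm_type": "MANUAL",
                                      "tracking_id": "t"}],
                            pet_series, terminology, content_creator="R",
                            rng=random.Random(0))

    def test_missing_metadata_roles_listed(self, tmp_path, pet_series, terminology,
                                           noiseless_spec):
        mask = ground_truth_mask(noiseless_spec, 0).astype(np.uint8)
        path = tmp_path / "m.nii"
        write_mask_nifti(mask, pet_series.geometry, path)
        with pytest.raises(MetadataError, match="category_role"):
            research_to_seg([path], [{"label": "x"}], pet_series, terminology,
                            content_creator="R", rng=random.Random(0))
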