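import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bruiseage.dataset import assign_stage
from bruiseage.phantom import _subject_profile, render_sample
from bruiseage.preprocess import (
    DegenerateReferenceError,
    HyperCube,
    LesionMask,
    LesionNotFoundError,
    ReferencePair,
    build_dataset,
    build_dataset_from_cohort,
    extract_patch,
    load_patches,
    mask_center,
    radiometric_normalize,
    save_patches,
    segment_lesion,
)
from bruiseage.phantom import write_cohort
from conftest import TINY_PARAMS


def _cube(values, kind="radiance"):
    return HyperCube(np.asarray(values, dtype=np.float32), kind=kind)


class TestRadiometricNormalize:
    def test_white_maps_to_one_dark_to_zero(self):
        white = np.full(3, 0.9)
        dark = np.full(3, 0.1)
        ones = radiometric_normalize(_cube(np.tile(white[:, None, None], (1, 4, 4))), ReferencePair(white, dark))
        zeros = radiometric_normalize(_cube(np.tile(dark[:, None, None], (1, 4, 4))), ReferencePair(white, dark))
        np.testing.assert_allclose(ones.values, 1.0, atol=1e-6)
        np.testing.assert_allclose(zeros.values, 0.0, atol=1e-6)

    def test_midpoint_value(self):
        out = radiometric_normalize(
            _cube(np.full((1, 1, 1), 0.55)), ReferencePair(np.array([1.0]), np.array([0.10]))
        )
        assert out.values[0, 0, 0] == pytest.approx(0.5, abs=1e-6)
        assert out.kind == "reflectance"

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_roundtrip_recovers_reflectance(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.random((4, 5, 6)).astype(np.float64)
        white = rng.uniform(0.8, 1.0, 4)
        dark = rng.uniform(0.0, 0.1, 4)
        raw = dark[:, None, None] + r * (white - dark)[:, None, None]
        out = radiometric_normalize(_cube(raw), ReferencePair(white, dark))
        np.testing.assert_allclose(out.values, r, rtol=2e-6, atol=2e-6)

    def test_values_are_not_clipped(self):
        white, dark = np.array([1.0]), np.array([0.0])
        out = radiometric_normalize(_cube(np.full((1, 2, 2), 1.5)), ReferencePair(white, dark))
        assert out.values.max() == pytest.approx(1.5)

    def test_degenerate_reference_names_band_and_pixel(self):
        white = np.array([0.9, 0.5])
        dark = np.array([0.1, 0.5])  # band 1 degenerate
        with pytest.raises(DegenerateReferenceError, match="band 1"):
            radiometric_normalize(_cube(np.zeros((2, 2, 2))), ReferencePair(white, dark))

    def test_full_cube_references_accepted(self):
        rng = np.random.default_rng(1)
        white = rng.uniform(0.8, 1.0, (3, 4, 4))
        dark = rng.uniform(0.0, 0.1, (3, 4, 4))
        raw = dark + 0.5 * (white - dark)
        out = radiometric_normalize(_cube(raw), ReferencePair(white, dark))
        np.testing.assert_allclose(out.values, 0.5, atol=1e-5)


class TestMaskCenter:
    def test_single_pixel(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, 20] = True
        assert mask_center(mask) == (10, 20)

    def test_two_pixel_mean(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[0, 2] = True
        assert mask_center(mask) == (0, 1)

    def test_filled_square_centroid(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:8, 3:8] = True  # 5x5 square with top-left (3, 3)
        assert mask_center(mask) == (5, 5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_center(np.zeros((4, 4), dtype=bool))


class TestExtractPatch:
    def test_centered_window_arithmetic(self):
        cube = _cube(np.zeros((2, 512, 512)))
        patch = extract_patch(cube, (256, 256), size=64)
        assert patch.origin == (224, 224)
        assert patch.values.shape == (2, 64, 64)

    def test_corner_center_is_clamped_not_padded(self):
        values = np.arange(512 * 512, dtype=np.float32).reshape(1, 512, 512)
        patch = extract_patch(_cube(values), (0, 0), size=64)
        assert patch.origin == (0, 0)
        np.testing.assert_array_equal(patch.values, values[:, :64, :64])

    def test_all_bands_retained(self):
        cube = _cube(np.zeros((17, 40, 40)))
        assert extract_patch(cube, (20, 20), size=16).values.shape[0] == 17

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patch(_cube(np.zeros((1, 32, 32))), (16, 16), size=64)

    @given(r=st.integers(0, 39), c=st.integers(0, 39), size=st.sampled_from([4, 8, 16, 40]))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_output_always_full_size(self, r, c, size):
        patch = extract_patch(_cube(np.zeros((1, 40, 40))), (r, c), size=size)
        assert patch.values.shape == (1, size, size)
        assert 0 <= patch.origin[0] <= 40 - size
        assert 0 <= patch.origin[1] <= 40 - size


@pytest.fixture(scope="module")
def reflectance():
    profile = _subject_profile(TINY_PARAMS, 1)
    sample = render_sample(profile, 4.0, TINY_PARAMS, np.random.default_rng(5))
    cube = HyperCube(sample.cube, kind="radiance")
    return radiometric_normalize(cube, ReferencePair(sample.white, sample.dark)), sample


class TestSegmentLesion:

    def test_builtin_mask_overlaps_ground_truth(self, reflectance):
        refl, sample = reflectance
        mask = segment_lesion(refl)
        inter = (mask.mask & sample.mask).sum()
        union = (mask.mask | sample.mask).sum()
        assert inter / union > 0.5
        assert mask.provenance == "builtin-segmenter"

    def test_uniform_cube_has_no_lesion(self):
        uniform = HyperCube(np.full((4, 20, 20), 0.5, dtype=np.float32), kind="reflectance")
        with pytest.raises(LesionNotFoundError):
            segment_lesion(uniform)

    def test_mask_restricted_to_prompt_box(self, reflectance):
        refl, sample = reflectance
        r, c = mask_center(LesionMask(sample.mask, "ground-truth"))
        box = (max(0, r - 9), r + 9, max(0, c - 9), c + 9)
        mask = segment_lesion(refl, prompt_box=box)
        outside = mask.mask.copy()
        outside[box[0] : box[1], box[2] : box[3]] = False
        assert not outside.any()


class TestBuildDataset:
    def test_patch_cohort_shapes_and_stages(self, tiny_patches):
        assert len(tiny_patches) == len(TINY_PARAMS.acquisition_days) * TINY_PARAMS.n_subjects
        patches = tiny_patches.patches()
        assert patches.shape[1:] == (TINY_PARAMS.n_bands, 16, 16)
        for s in tiny_patches:
            assert s.stage == assign_stage(s.age_days)
            assert s.mask_provenance == "ground-truth"

    def test_pipeline_is_deterministic(self, tiny_cohort):
        a, _ = build_dataset_from_cohort(tiny_cohort, patch_size=16, mask_source="truth")
        b, _ = build_dataset_from_cohort(tiny_cohort, patch_size=16, mask_source="truth")
        np.testing.assert_array_equal(a.patches(), b.patches())

    def test_zero_contrast_sample_excluded_with_reason(self, tiny_cohort):
        # a lesion-free impostor: uniform cube and an empty truth mask
        import copy

        cohort = tiny_cohort.with_samples(list(tiny_cohort.samples[:6]))
        flat = copy.deepcopy(cohort.samples[0])
        flat.mask = np.zeros_like(flat.mask)
        flat.sample_id = "FLAT"
        cohort.samples.append(flat)
        dataset, exclusions = build_dataset_from_cohort(cohort, patch_size=16, mask_source="truth")
        assert len(dataset) == 6
        assert [e.sample_id for e in exclusions] == ["FLAT"]

    def test_builtin_segmentation_pipeline_keeps_visible_lesions(self, tiny_cohort):
        middle = tiny_cohort.with_samples(
            [s for s in tiny_cohort if 3 <= s.age_days <= 9]
        )
        dataset, exclusions = build_dataset_from_cohort(
            middle, patch_size=16, mask_source="builtin"
        )
        assert len(dataset) >= len(middle.samples) - 1
        for s in dataset:
            assert s.mask_provenance == "builtin-segmenter"


class TestFileRoundtrips:
    def test_envi_cohort_roundtrip_matches_in_memory_pipeline(self, tmp_path, tiny_cohort):
        small = tiny_cohort.with_samples(list(tiny_cohort.samples[:3]))
        meta = write_cohort(small, tmp_path / "cohort")
        from_files, _ = build_dataset(meta, patch_size=16, mask_source="truth")
        in_memory, _ = build_dataset_from_cohort(small, patch_size=16, mask_source="truth")
        assert len(from_files) == len(in_memory)
        np.testing.assert_allclose(
            from_files.patches(), in_memory.patches(), rtol=1e-5, atol=1e-5
        )
        np.testing.assert_allclose(from_files.axis.centers, in_memory.axis.centers, atol=1e-3)

    def test_missing_file_names_offending_row(self, tmp_path, tiny_cohort):
        small = tiny_cohort.with_samples(list(tiny_cohort.samples[:1]))
        meta = write_cohort(small, tmp_path / "cohort")
        import pandas as pd

        table = pd.read_csv(meta)
        table.loc[0, "path_cube"] = str(tmp_path / "gone.img")
        bad_meta = tmp_path / "bad.csv"
        table.to_csv(bad_meta, index=False)
        with pytest.raises(FileNotFoundError, match=small.samples[0].sample_id):
            build_dataset(bad_meta)

    def test_hdf5_patch_container_roundtrip(self, tmp_path, tiny_patches):
        path = tmp_path / "patches.h5"
        save_patches(tiny_patches, path)
        loaded = load_patches(path)
        np.testing.assert_array_equal(loaded.patches(), tiny_patches.patches())
        assert [s.subject_id for s in loaded] == [s.subject_id for s in tiny_patches]
        np.testing.assert_allclose(loaded.axis.centers, tiny_patches.axis.centers)
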