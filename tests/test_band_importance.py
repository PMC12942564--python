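import numpy as np
import pytest

from bruiseage.band_importance import (
    BandScore,
    BandSubset,
    apply_subset,
    make_subset,
    nearest_band,
    occlusion_importance,
    rank_consensus,
    smoothgrad_importance,
    top_k,
)
from bruiseage.models import CnnConfig, build_cnn
from bruiseage.phantom import make_wavelength_axis, WavelengthAxis
from conftest import make_patch_cohort

AXIS_204 = make_wavelength_axis(204, 400, 1000)


class LinearBandModel:
    """Toy model: y = sum_b w_b * mean(band b).  Exposes the same surface the
    attribution functions need (predict + input_gradients)."""

    def __init__(self, weights):
        self.weights = np.asarray(weights, dtype=np.float64)

    def predict(self, patches):
        return np.tensordot(patches.mean(axis=(2, 3)), self.weights, axes=(1, 0))

    def input_gradients(self, patches):
        n, bands, p, q = patches.shape
        g = np.zeros_like(patches, dtype=np.float64)
        g += self.weights[None, :, None, None] / (p * q)
        return g


class TestNearestBand:
    def test_endpoints_exact(self):
        assert nearest_band(AXIS_204, 400) == 0
        assert nearest_band(AXIS_204, 1000) == 203

    def test_460nm_maps_to_band_20(self):
        # exhaustive-oracle check: |center_i - 460| minimized at i=20
        oracle = int(np.argmin([abs(c - 460) for c in AXIS_204.centers]))
        assert oracle == 20
        assert nearest_band(AXIS_204, 460) == 20

    def test_tie_broken_toward_lower_index(self):
        axis = WavelengthAxis(np.array([400.0, 500.0, 600.0]))
        assert nearest_band(axis, 450) == 0

    def test_far_outside_range_rejected(self):
        with pytest.raises(ValueError):
            nearest_band(AXIS_204, 1200)


class TestMakeSubset:
    def test_rgb_bands_near_bayer_peaks(self):
        subset = make_subset("rgb", AXIS_204)
        assert len(subset) == 3
        for target, actual in zip((460, 540, 650), subset.wavelengths):
            assert abs(actual - target) < 1.5

    def test_physio_has_six_unique_bands(self):
        subset = make_subset("physio", AXIS_204)
        assert len(subset) == 6
        assert len(set(subset.indices.tolist())) == 6
        rgb = set(make_subset("rgb", AXIS_204).indices.tolist())
        assert rgb <= set(subset.indices.tolist())

    def test_full_is_identity(self):
        subset = make_subset("full", AXIS_204)
        np.testing.assert_array_equal(subset.indices, np.arange(204))

    def test_topk_requires_consensus(self):
        with pytest.raises(ValueError):
            make_subset("topk", AXIS_204, k=5)


class TestSmoothGrad:
    def test_zero_noise_single_draw_equals_vanilla_saliency(self):
        model = build_cnn(
            CnnConfig(n_bands=6, spectral_channels=(3, 3, 3), spatial_channels=(4, 4), head_hidden=8),
            seed=0,
        )
        patches = np.random.default_rng(0).random((4, 6, 8, 8)).astype(np.float32)
        sg = smoothgrad_importance(model, patches, noise_frac=0.0, n_draws=1, seed=0)
        grads = model.input_gradients(patches)
        vanilla = np.abs(grads.mean(axis=(2, 3))).mean(axis=0)
        np.testing.assert_allclose(sg.values, vanilla, rtol=1e-6)

    def test_unused_band_scores_zero(self):
        model = LinearBandModel([1.0, 0.0, 2.0])
        patches = np.random.default_rng(1).random((5, 3, 4, 4)).astype(np.float32)
        sg = smoothgrad_importance(model, patches, n_draws=5, seed=0)
        assert sg.values[1] == 0

    def test_linear_model_recovers_coefficient_ratio(self):
        model = LinearBandModel([3.0, 1.0])
        patches = np.random.default_rng(2).random((6, 2, 4, 4)).astype(np.float32)
        sg = smoothgrad_importance(model, patches, n_draws=3, seed=0)
        assert sg.values[0] / sg.values[1] == pytest.approx(3.0, rel=1e-6)

    def test_zero_draws_rejected(self):
        with pytest.raises(ValueError):
            smoothgrad_importance(LinearBandModel([1.0]), np.zeros((1, 1, 2, 2)), n_draws=0)

    def test_deterministic_under_seed(self):
        model = LinearBandModel([1.0, 2.0])
        patches = np.random.default_rng(3).random((3, 2, 4, 4)).astype(np.float32)
        a = smoothgrad_importance(model, patches, n_draws=4, seed=9)
        b = smoothgrad_importance(model, patches, n_draws=4, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestOcclusion:
    def _setup(self, bands=6, n=20):
        model = build_cnn(
            CnnConfig(
                n_bands=bands, spectral_channels=(3, 3, 3), spatial_channels=(4, 4), head_hidden=8
            ),
            seed=1,
        )
        rng = np.random.default_rng(4)
        patches = rng.random((n, bands, 8, 8)).astype(np.float32)
        truths = rng.uniform(0, 20, n)
        return model, patches, truths

    def test_matches_brute_force_reevaluation(self):
        model, patches, truths = self._setup()
        scores = occlusion_importance(model, patches, truths)
        fill = patches.mean(axis=(0, 2, 3))
        baseline = np.mean(np.abs(model.predict(patches) - truths))
        for b in range(patches.shape[1]):
            occluded = patches.copy()
            for i in range(len(occluded)):  # deliberate per-sample loop
                occluded[i, b, :, :] = fill[b]
            mae = np.mean(np.abs(model.predict(occluded) - truths))
            assert scores.values[b] == pytest.approx(mae - baseline, abs=1e-9)

    def test_identity_replacement_gives_all_zero_scores(self):
        model, patches, truths = self._setup(n=6)
        scores = occlusion_importance(model, patches, truths, replacement="identity")
        np.testing.assert_array_equal(scores.values, 0)

    def test_unused_band_scores_zero(self):
        model = LinearBandModel([1.0, 0.0, 2.0])
        rng = np.random.default_rng(5)
        patches = rng.random((8, 3, 4, 4)).astype(np.float32)
        truths = rng.uniform(0, 20, 8)
        scores = occlusion_importance(model, patches, truths)
        assert scores.values[1] == pytest.approx(0, abs=1e-7)

    def test_unknown_policy_rejected(self):
        model, patches, truths = self._setup(n=2)
        with pytest.raises(ValueError):
            occlusion_importance(model, patches, truths, replacement="noise")


class TestRankConsensus:
    def test_idempotent_on_identical_scores(self):
        a = BandScore(np.array([0.9, 0.5, 0.1]), "smoothgrad")
        consensus = rank_consensus(a, a)
        np.testing.assert_array_equal(consensus.values, [1, 2, 3])

    def test_hand_computed_example(self):
        a = BandScore(np.array([0.9, 0.7, 0.3, 0.1]), "smoothgrad")
        b = BandScore(np.array([0.8, 0.9, 0.2, 0.1]), "occlusion")
        consensus = rank_consensus(a, b)
        np.testing.assert_allclose(consensus.values, [1.5, 1.5, 3, 4])

    def test_symmetry_and_rank_mean_conservation(self):
        rng = np.random.default_rng(0)
        a = BandScore(rng.random(204), "smoothgrad")
        b = BandScore(rng.random(204), "occlusion")
        ab, ba = rank_consensus(a, b), rank_consensus(b, a)
        np.testing.assert_array_equal(ab.values, ba.values)
        assert ab.values.min() >= 1
        assert ab.values.max() <= 204
        assert ab.values.mean() == pytest.approx((204 + 1) / 2)

    def test_matches_brute_force_rank_computation(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(30), rng.random(30)

        def brute_ranks(v):
            order = sorted(range(len(v)), key=lambda i: -v[i])
            ranks = np.empty(len(v))
            for rank, i in enumerate(order, start=1):
                ranks[i] = rank
            return ranks

        consensus = rank_consensus(BandScore(a, "smoothgrad"), BandScore(b, "occlusion"))
        expected = (brute_ranks(a) + brute_ranks(b)) / 2
        np.testing.assert_allclose(consensus.values, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_consensus(BandScore(np.ones(3), "smoothgrad"), BandScore(np.ones(4), "occlusion"))


class TestTopK:
    def _consensus(self, values):
        return BandScore(np.asarray(values, dtype=float), "consensus-rank")

    def test_k_equals_n_gives_full_subset(self):
        subset = top_k(self._consensus([3, 1, 2]), k=3)
        np.testing.assert_array_equal(subset.indices, [0, 1, 2])

    def test_tie_at_cut_broken_by_lower_index(self):
        subset = top_k(self._consensus([1.5, 1.5, 3, 4]), k=2)
        np.testing.assert_array_equal(subset.indices, [0, 1])

    def test_k_one_selects_argmin(self):
        subset = top_k(self._consensus([4, 2, 9, 7]), k=1)
        np.testing.assert_array_equal(subset.indices, [1])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            top_k(self._consensus([1, 2]), k=3)


def test_importance_csv_roundtrips_topk_subset(tmp_path):
    from bruiseage.band_importance import importance_table, load_topk_subset

    rng = np.random.default_rng(7)
    axis = make_wavelength_axis(12, 400, 1000)
    a = BandScore(rng.random(12), "smoothgrad")
    b = BandScore(rng.random(12), "occlusion")
    consensus = rank_consensus(a, b)
    subset = top_k(consensus, k=4, axis=axis)
    path = tmp_path / "importance.csv"
    importance_table(a, b, consensus, subset, axis).to_csv(path, index=False)
    loaded = load_topk_subset(path)
    np.testing.assert_array_equal(loaded.indices, subset.indices)
    np.testing.assert_allclose(loaded.wavelengths, subset.wavelengths)


class TestApplySubset:
    def test_full_subset_is_identity(self):
        ds = make_patch_cohort(n_bands=5)
        subset = BandSubset("full", np.arange(5), np.full(5, np.nan))
        np.testing.assert_array_equal(apply_subset(ds, subset).patches(), ds.patches())

    def test_reduction_shapes_and_band_order(self):
        ds = make_patch_cohort(n_bands=6, patch=8)
        subset = BandSubset("topk", np.array([1, 4]), np.full(2, np.nan))
        reduced = apply_subset(ds, subset)
        assert reduced.patches().shape[1] == 2
        np.testing.assert_array_equal(reduced.patches()[:, 0], ds.patches()[:, 1])
        np.testing.assert_array_equal(reduced.patches()[:, 1], ds.patches()[:, 4])

    def test_out_of_range_index_rejected(self):
        ds = make_patch_cohort(n_bands=4)
        subset = BandSubset("topk", np.array([2, 9]), np.full(2, np.nan))
        with pytest.raises(IndexError):
            apply_subset(ds, subset)
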