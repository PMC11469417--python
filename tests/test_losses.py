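"""Training objectives: closed forms, brute-force oracle equality, sampler."""

import numpy as np
import pytest

from dreme.geometry import VolumeGrid
from dreme.losses import (AugmentationConfig, LossWeights, augment_scores,
                          loss_augmentation, loss_image_similarity,
                          loss_mbc_orthonormality_fields,
                          loss_projection_similarity, loss_self_consistency,
                          loss_tv, loss_zero_mean)
from dreme.motion import DVF, invert_dvf, warp_volume

import oracles


class TestImageSimilarity:
    def test_identical_is_zero(self, rng):
        v = rng.random((8, 8, 8))
        assert loss_image_similarity(v, v) == 0.0

    def test_constant_offset_closed_form(self, rng):
        v = rng.random((8, 8, 8))
        assert loss_image_similarity(v + 0.37, v) == pytest.approx(0.37 ** 2,
                                                                   rel=1e-10)

    def test_matches_bruteforce(self, rng):
        a, b = rng.random((6, 5, 4)), rng.random((6, 5, 4))
        assert loss_image_similarity(a, b) == pytest.approx(
            oracles.mse_loops(a, b), rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            loss_image_similarity(rng.random((4, 4, 4)), rng.random((5, 4, 4)))


class TestProjectionSimilarity:
    def test_single_pixel_delta_closed_form(self):
        nb, nv, nu = 32, 6, 8
        a = np.zeros((nb, nv, nu))
        b = a.copy()
        b[3, 2, 5] = 0.25
        assert loss_projection_similarity(a, b) == pytest.approx(
            0.25 ** 2 / (nb * nv * nu), rel=1e-12)

    def test_matches_bruteforce(self, rng):
        a, b = rng.random((5, 4, 6)), rng.random((5, 4, 6))
        assert loss_projection_similarity(a, b) == pytest.approx(
            oracles.mse_loops(a, b), rel=1e-12)


class TestTV:
    def test_constant_volume_is_zero(self):
        assert loss_tv(np.full((6, 6, 6), 3.2)) == 0.0

    def test_step_closed_form(self):
        """1D step of height h along x: one face sheet of |h| per crossing."""
        v = np.zeros((8, 5, 4))
        v[4:] = 1.5
        n_faces = 5 * 4
        assert loss_tv(v) == pytest.approx(1.5 * n_faces / v.size, rel=1e-12)

    def test_matches_bruteforce(self, rng):
        v = rng.random((5, 6, 4))
        assert loss_tv(v) == pytest.approx(oracles.tv_loops(v), rel=1e-10)


class TestMBCOrthonormality:
    def _normalize(self, f):
        n = f[0, 0].size
        for i in range(3):
            for k in range(3):
                norm = np.sqrt((f[i, k] ** 2).mean())
                if norm > 0:
                    f[i, k] /= norm
        return f

    def test_orthonormal_fields_are_zero(self, rng):
        """Gram-Schmidt-orthonormalized fields give (near-)zero penalty."""
        f = rng.normal(0, 1, (3, 3, 6, 6, 6))
        n = 6 * 6 * 6
        for k in range(3):
            flat = f[:, k].reshape(3, n)
            q, _ = np.linalg.qr(flat.T)
            f[:, k] = (q.T * np.sqrt(n)).reshape(3, 6, 6, 6)
        assert loss_mbc_orthonormality_fields(f) < 1e-20

    def test_single_level_norm_two(self):
        f = np.zeros((3, 3, 4, 4, 4))
        f[0, 1] = np.sqrt(2.0)  # ||e||^2 (voxel mean) = 2
        # contribution (2-1)^2/9 plus the 8 zero-norm penalties (0-1)^2 each
        assert loss_mbc_orthonormality_fields(f) == pytest.approx(
            (1.0 + 8.0) / 9.0, rel=1e-12)

    def test_matches_bruteforce(self, rng):
        f = rng.normal(0, 1, (3, 3, 5, 4, 3))
        assert loss_mbc_orthonormality_fields(f) == pytest.approx(
            oracles.mbc_loops(f), rel=1e-10)


class TestZeroMean:
    def test_symmetric_batch_is_zero(self, rng):
        w = rng.normal(0, 1, (16, 3, 3))
        w = np.concatenate([w, -w])
        assert loss_zero_mean(w) == pytest.approx(0.0, abs=1e-25)

    def test_constant_scores_closed_form(self):
        w = np.full((32, 3, 3), 0.7)
        assert loss_zero_mean(w) == pytest.approx(0.7 ** 2, rel=1e-12)

    def test_matches_bruteforce(self, rng):
        w = rng.normal(0, 2, (12, 3, 3))
        assert loss_zero_mean(w) == pytest.approx(
            oracles.zero_mean_loops(w), rel=1e-10)


class TestSelfConsistency:
    def test_zero_dvf_is_zero(self, rng):
        grid = VolumeGrid(rng.random((12, 12, 8), dtype=np.float32), (4, 4, 4))
        assert loss_self_consistency(grid, DVF.zeros(grid)) == 0.0

    def test_constant_translation_near_zero(self, rng):
        import scipy.ndimage as ndi
        data = ndi.gaussian_filter(rng.random((16, 16, 12)), 2.0)
        grid = VolumeGrid(data.astype(np.float32), (4.0, 4.0, 4.0))
        disp = np.zeros(grid.shape + (3,), np.float32)
        disp[..., 2] = 8.0  # exactly two voxels
        val = loss_self_consistency(grid, DVF(disp, grid.spacing, grid.origin))
        assert val < 1e-12

    def test_matches_step_by_step_oracle(self, rng):
        import scipy.ndimage as ndi
        data = ndi.gaussian_filter(rng.random((14, 14, 10)), 1.5)
        grid = VolumeGrid(data.astype(np.float32), (4.0, 4.0, 4.0))
        pts = grid.voxel_centers().reshape(grid.shape + (3,))
        disp = np.zeros(grid.shape + (3,), np.float32)
        disp[..., 2] = 3.0 * np.sin(2 * np.pi * pts[..., 0] / 90.0)
        dvf = DVF(disp, grid.spacing, grid.origin)
        # oracle: explicit warp -> invert -> warp -> masked MSE
        from dreme.losses import self_consistency_mask
        warped = warp_volume(grid, dvf)
        dinv = invert_dvf(dvf, 3)
        back = warp_volume(warped, dinv)
        m = self_consistency_mask(dvf, dinv)
        expected = oracles.mse_loops(back.data[m], grid.data[m])
        assert loss_self_consistency(grid, dvf) == pytest.approx(expected,
                                                                 rel=1e-10)


class TestAugmentation:
    def test_identity_ranges_leave_scores_unchanged(self, rng):
        cfg = AugmentationConfig(r1_range=(1.0, 1.0), r2_range=(1.0, 1.0))
        w = rng.normal(0, 1, (8, 3, 3))
        np.testing.assert_array_equal(augment_scores(w, cfg, rng), w)

    def test_zero_scores_stay_zero(self, rng):
        cfg = AugmentationConfig()
        assert np.all(augment_scores(np.zeros((4, 3, 3)), cfg, rng) == 0)

    def test_ratio_bounds_over_many_draws(self, rng):
        cfg = AugmentationConfig()
        w = np.ones((10000, 3, 3))
        out = augment_scores(w, cfg, rng)
        assert out.min() >= 0.6 * 0.8 - 1e-12
        assert out.max() <= 2.0 * 1.2 + 1e-12

    def test_loss_closed_form_and_bruteforce(self, rng):
        nb = 16
        p = np.zeros((nb, 3, 3))
        t = p.copy()
        t[5, 1, 2] = 0.4
        assert loss_augmentation(p, t) == pytest.approx(0.4 ** 2 / (9 * nb),
                                                        rel=1e-12)
        p, t = rng.normal(0, 1, (6, 3, 3)), rng.normal(0, 1, (6, 3, 3))
        assert loss_augmentation(p, t) == pytest.approx(
            oracles.aug_loss_loops(p, t), rel=1e-10)


class TestLossWeights:
    def test_default_weight_table(self):
        w = LossWeights()
        assert (w.image_sim, w.projection_sim, w.tv, w.mbc, w.zero_mean,
                w.self_consistency, w.augmentation) == \
            (1.0, 1.0, 2e-4, 1.0, 1e-3, 1e3, 1e-4)

    def test_ablate_changes_exactly_one_weight(self):
        base = LossWeights()
        for name in ("zero_mean", "self_consistency", "augmentation"):
            ab = base.ablate(name)
            diffs = [k for k in vars(base)
                     if getattr(base, k) != getattr(ab, k)]
            assert diffs == [name]
            assert getattr(ab, name) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(tv=-1.0)
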