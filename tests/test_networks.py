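"""Spatial coordinate network and CNN motion encoder."""

import numpy as np
import pytest

import dreme._autodiff as ad
from dreme._autodiff import Tensor
from dreme.geometry import VolumeGrid, project_tensor
from dreme.losses import projection_similarity_t
from dreme.motion import MotionBasisSet, evaluate_basis_t, warp_tensor
from dreme.networks import (MotionEncoderCNN, SpatialINR, encode_projection,
                            preprocess_frame, render_volume)


@pytest.fixture
def grid():
    return VolumeGrid(np.zeros((20, 20, 12), np.float32), (4.0, 4.0, 4.0))


def _make_inr(grid, seed=0, **kw):
    lo = np.asarray(grid.origin) - 2.0
    hi = np.asarray(grid.origin) + np.asarray(grid.extent) + 2.0
    defaults = dict(n_levels=4, log2_table=12, base_resolution=4, growth=1.5,
                    hidden=16)
    defaults.update(kw)
    return SpatialINR(lo, hi, np.random.default_rng(seed), **defaults)


class TestSpatialINR:
    def test_zero_head_renders_constant(self, grid):
        inr = _make_inr(grid)
        inr.layers[-1].W.data[:] = 0
        inr.layers[-1].b.data[:] = 0
        out = render_volume(inr, grid)
        expected = np.log(2.0) * inr.output_scale  # softplus(0) * scale
        np.testing.assert_allclose(out.data, expected, rtol=1e-5)

    def test_render_deterministic(self, grid):
        inr = _make_inr(grid, seed=3)
        a = render_volume(inr, grid)
        b = render_volume(inr, grid)
        np.testing.assert_array_equal(a.data, b.data)

    def test_out_of_bounds_grid_raises(self, grid):
        inr = _make_inr(grid)
        big = VolumeGrid(np.zeros((20, 20, 12), np.float32), (40.0, 40.0, 40.0))
        with pytest.raises(ValueError):
            render_volume(inr, big)

    def test_fits_sphere_phantom(self, grid):
        """Image-domain warm start alone drives the render close to a known
        target (relative error < 0.1)."""
        from dreme.trainer import Adam
        from dreme.losses import image_similarity_t

        x = [np.asarray(grid.origin)[i] + np.arange(grid.shape[i]) * 4.0
             for i in range(3)]
        X, Y, Z = np.meshgrid(*x, indexing="ij")
        target = (0.02 * ((X ** 2 + Y ** 2 + Z ** 2) < 30 ** 2)).astype(np.float32)
        inr = _make_inr(grid, seed=1, n_levels=6, log2_table=14,
                        base_resolution=4, growth=1.6, hidden=32)
        opt = Adam([(inr.parameters(), 1e-2)], grad_clip=10)
        flat = target.reshape(-1)
        for _ in range(250):
            pred = inr.render_t(grid)
            loss = image_similarity_t(pred.reshape(flat.size), Tensor(flat))
            opt.zero_grad(); loss.backward(); opt.step()
        out = render_volume(inr, grid)
        re = np.linalg.norm(out.data - target) / np.linalg.norm(target)
        assert re < 0.1


class TestMotionEncoder:
    def test_nine_outputs_and_eval_determinism(self, rng):
        cnn = MotionEncoderCNN(np.random.default_rng(0), input_size=(48, 64),
                               verbose=False)
        frame = rng.random((48, 64)).astype(np.float32)
        s1 = encode_projection(cnn, frame)
        s2 = encode_projection(cnn, frame)
        assert s1.flat.shape == (9,)
        np.testing.assert_array_equal(s1.w, s2.w)

    def test_parameter_count_printed(self, capsys):
        cnn = MotionEncoderCNN(np.random.default_rng(0), input_size=(48, 64))
        out = capsys.readouterr().out
        assert str(cnn.n_parameters) in out

    def test_nan_input_rejected(self):
        cnn = MotionEncoderCNN(np.random.default_rng(0), input_size=(24, 32),
                               verbose=False)
        bad = np.full((24, 32), np.nan, dtype=np.float32)
        with pytest.raises(ValueError):
            encode_projection(cnn, bad)

    def test_eval_mode_uses_frozen_running_stats(self, rng):
        cnn = MotionEncoderCNN(np.random.default_rng(0), input_size=(24, 32),
                               verbose=False)
        before = [bn.running_mean.copy() for bn in cnn.bns]
        cnn.encode(rng.random((4, 24, 32)).astype(np.float32), training=False)
        for bn, b in zip(cnn.bns, before):
            np.testing.assert_array_equal(bn.running_mean, b)
        # training mode does update them
        cnn.encode(rng.random((4, 24, 32)).astype(np.float32), training=True)
        assert any(not np.array_equal(bn.running_mean, b)
                   for bn, b in zip(cnn.bns, before))

    def test_preprocess_resizes_and_scales(self, rng):
        frame = rng.random((36, 48)).astype(np.float32) * 5
        out = preprocess_frame(frame, (96, 128), norm=5.0)
        assert out.shape == (96, 128)
        assert out.max() <= 1.0 + 1e-5


def test_gradient_flow_through_full_chain(grid, rng):
    """The projection loss sends finite nonzero gradients to the hash
    tables, the MLP, the B-spline coefficients and the CNN."""
    from dreme.geometry import ScanGeometry

    inr = _make_inr(grid, seed=2)
    cnn = MotionEncoderCNN(np.random.default_rng(1), input_size=(24, 32),
                           verbose=False)
    basis = MotionBasisSet.covering([grid], base_control=(4, 4, 4))
    for c in basis.coefficients:
        c.data = rng.normal(0, 0.1, c.data.shape).astype(np.float32)
    geom = ScanGeometry(sad=500, sdd=800, n_u=32, n_v=24, du=4.0, dv=4.0,
                        angles=[30.0])

    frames = rng.random((4, 24, 32)).astype(np.float32)
    scores = cnn.forward_t(Tensor(frames[:, None]), training=True)
    fields = evaluate_basis_t(basis, grid)
    n_vox = grid.n_voxels
    comps = [(scores.reshape(4, 3, 3)[0:1, :, k]
              @ fields[:, k].reshape(3, n_vox)).reshape(n_vox)
             for k in range(3)]
    disp = ad.stack(comps, axis=-1)
    # add fixed texture so the warp has a nonzero spatial gradient even
    # though the untrained network renders a near-constant volume
    texture = Tensor(rng.random(grid.shape, dtype=np.float32) * 0.01)
    vol = inr.render_t(grid) + texture
    warped = warp_tensor(vol, disp, grid)
    drr = project_tensor(warped, grid, geom, 30.0)
    loss = projection_similarity_t(drr.reshape(1, 24, 32),
                                   Tensor(rng.random((1, 24, 32),
                                                     dtype=np.float32)))
    loss.backward()

    for name, params in [("hash", inr.encoder.tables),
                         ("mlp", [l.W for l in inr.layers]),
                         ("bspline", basis.coefficients),
                         ("cnn", [c.W for c in cnn.convs] + [cnn.fc.W])]:
        grads = [p.grad for p in params if p.grad is not None]
        assert grads, f"no gradient reached {name}"
        total = sum(float(np.abs(g).sum()) for g in grads)
        assert np.isfinite(total) and total > 0, f"degenerate grad for {name}"
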