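"""Projector, projection-set plumbing and FDK reconstruction."""

import numpy as np
import pytest

import dreme._autodiff as ad
from dreme.geometry import (ProjectionSet, ScanGeometry, VolumeGrid,
                            fdk_reconstruct, forward_project, project_set,
                            project_tensor, ramp_filter_rows, ramp_kernel)

from oracles import dense_ray_integral, siddon_path_lengths


def _sphere_volume(n=48, sp=2.0, radius=30.0, mu=0.02):
    x = (np.arange(n) - (n - 1) / 2) * sp
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    data = ((X ** 2 + Y ** 2 + Z ** 2) < radius ** 2).astype(np.float32) * mu
    return VolumeGrid(data, (sp, sp, sp)), (X, Y, Z)


def test_zero_volume_projects_to_zero(small_geometry):
    vol = VolumeGrid(np.zeros((12, 12, 12), np.float32), (3, 3, 3))
    proj = forward_project(vol, small_geometry, 42.0)
    assert proj.shape == (small_geometry.n_v, small_geometry.n_u)
    assert np.all(proj == 0)


def test_uniform_cube_ray_path_length():
    """A ray straight through a uniform unit-attenuation cube integrates to
    the full side length; off-center rays match an exact Siddon oracle."""
    n, sp = 32, 2.0
    vol = VolumeGrid(np.ones((n, n, n), np.float32), (sp, sp, sp))
    geom = ScanGeometry(sad=1000, sdd=1500, n_u=31, n_v=31, du=1.0, dv=1.0,
                        angles=[0.0])
    proj = forward_project(vol, geom, 0.0)
    assert proj[15, 15] == pytest.approx(n * sp, rel=1e-5)
    # oblique rays against Siddon
    src = geom.source_position(0.0)
    det00, us, vs = geom.detector_frame(0.0)
    for iu, iv in [(3, 7), (25, 28), (15, 2)]:
        dst = det00 + iu * us + iv * vs
        expected = siddon_path_lengths(vol, src, dst)
        assert proj[iv, iu] == pytest.approx(expected, rel=2e-3, abs=1e-3)


def test_projector_matches_dense_integrator(random_volume16):
    geom = ScanGeometry(sad=400, sdd=700, n_u=10, n_v=8, du=4.0, dv=4.0,
                        angles=[27.0])
    proj = forward_project(random_volume16, geom, 27.0, step=0.5)
    src = geom.source_position(27.0)
    det00, us, vs = geom.detector_frame(27.0)
    ref = np.zeros_like(proj)
    for iv in range(geom.n_v):
        for iu in range(geom.n_u):
            ref[iv, iu] = dense_ray_integral(random_volume16, src,
                                             det00 + iu * us + iv * vs, 0.05)
    assert np.abs(proj - ref).max() < 0.01 * proj.max()


def test_project_set_cardinality_and_consistency(random_volume16):
    geom = ScanGeometry(sad=400, sdd=700, n_u=12, n_v=10, du=4.0, dv=4.0,
                        angles=[0.0, 120.0, 240.0])
    ps = project_set(random_volume16, geom)
    assert ps.n_projections == 3
    for i, a in enumerate(geom.angles):
        np.testing.assert_array_equal(
            ps.frames[i], forward_project(random_volume16, geom, a))


def test_projection_periodicity(random_volume16):
    geom = ScanGeometry(sad=400, sdd=700, n_u=12, n_v=10, du=4.0, dv=4.0,
                        angles=[45.0])
    a = forward_project(random_volume16, geom, 45.0)
    b = forward_project(random_volume16, geom, 45.0 + 360.0)
    np.testing.assert_allclose(a, b, atol=1e-4 * max(a.max(), 1e-9))


def test_projector_adjointness(random_volume16, rng):
    """<A v, p> == <v, A^T p> (the projector/backprojector are transposes)."""
    geom = ScanGeometry(sad=500, sdd=800, n_u=24, n_v=20, du=2.0, dv=2.0,
                        angles=[63.0])
    vt = ad.Tensor(random_volume16.data, requires_grad=True)
    out = project_tensor(vt, random_volume16, geom, 63.0)
    p = rng.random(out.shape).astype(np.float32)
    lhs = float((out.numpy() * p).sum())
    out.backward(p)
    rhs = float((vt.grad * random_volume16.data).sum())
    assert abs(lhs - rhs) <= 1e-4 * abs(lhs)


def test_rotational_symmetry():
    """A smooth rotationally symmetric blob projects identically from every
    gantry angle (up to the trilinear discretization floor)."""
    n, sp, sigma = 64, 2.0, 14.0
    x = (np.arange(n) - (n - 1) / 2) * sp
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    blob = 0.02 * np.exp(-(X ** 2 + Y ** 2 + Z ** 2) / (2 * sigma ** 2))
    vol = VolumeGrid(blob.astype(np.float64), (sp, sp, sp))
    geom = ScanGeometry(sad=1000, sdd=1500, n_u=48, n_v=48, du=2.0, dv=2.0,
                        angles=np.linspace(0, 300, 6))
    ps = project_set(vol, geom, step=0.5)
    spread = np.abs(ps.frames - ps.frames[0]).max()
    assert spread < 1e-3 * ps.frames.max()


def test_invalid_inputs():
    with pytest.raises(ValueError):
        VolumeGrid(np.zeros((4, 4, 4)), (0.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        ScanGeometry(sad=1000, sdd=900, n_u=4, n_v=4, du=1, dv=1, angles=[0])
    geom = ScanGeometry(sad=500, sdd=800, n_u=8, n_v=8, du=2, dv=2, angles=[0])
    with pytest.raises(ValueError):
        ProjectionSet(np.zeros((1, 4, 4)), geom)  # frame shape mismatch


class TestFDK:
    def test_static_sphere_round_trip(self):
        vol, (X, Y, Z) = _sphere_volume()
        geom = ScanGeometry(sad=1000, sdd=1500, n_u=96, n_v=96, du=2.0, dv=2.0,
                            angles=np.arange(0, 360, 1.0))
        ps = project_set(vol, geom)
        rec = fdk_reconstruct(ps, vol.shape, vol.spacing)
        inside = (X ** 2 + Y ** 2 + Z ** 2) < 25.0 ** 2
        assert rec.data[inside].mean() == pytest.approx(0.02, rel=0.10)
        re = np.linalg.norm(rec.data - vol.data) / np.linalg.norm(vol.data)
        assert re < 0.2

    def test_zero_projections_reconstruct_to_zero(self):
        geom = ScanGeometry(sad=1000, sdd=1500, n_u=32, n_v=32, du=4.0, dv=4.0,
                            angles=np.arange(0, 360, 4.0))
        ps = ProjectionSet(np.zeros((90, 32, 32), np.float32), geom)
        rec = fdk_reconstruct(ps, (16, 16, 16), (4.0, 4.0, 4.0))
        assert np.allclose(rec.data, 0)

    def test_ramp_filter_impulse_response(self):
        """Filtering a unit impulse reproduces the discrete ramp kernel."""
        du = 1.5
        n = 32
        row = np.zeros((1, n))
        row[0, n // 2] = 1.0
        filt = ramp_filter_rows(row, du)[0]
        expected = ramp_kernel(n, du) * du
        half = expected[n - n // 2: 2 * n - n // 2]
        np.testing.assert_allclose(filt, half, atol=1e-9 / du)

    def test_error_decreases_with_view_count(self):
        vol, _ = _sphere_volume(n=32, sp=2.0, radius=20.0)
        geom_full = ScanGeometry(sad=1000, sdd=1500, n_u=64, n_v=64,
                                 du=2.0, dv=2.0, angles=np.arange(0, 360, 1.0))
        ps = project_set(vol, geom_full)
        errs = []
        for nview in (90, 180, 360):
            sel = np.linspace(0, 359, nview, endpoint=False).astype(int)
            sub_geom = ScanGeometry(sad=1000, sdd=1500, n_u=64, n_v=64,
                                    du=2.0, dv=2.0, angles=geom_full.angles[sel])
            sub = ProjectionSet(ps.frames[sel], sub_geom)
            rec = fdk_reconstruct(sub, vol.shape, vol.spacing)
            errs.append(np.linalg.norm(rec.data - vol.data)
                        / np.linalg.norm(vol.data))
        assert errs[0] > errs[1] > errs[2]
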