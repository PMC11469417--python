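"""Shared fixtures: small geometries, phantoms, and the scaled-down study."""

from __future__ import annotations

import numpy as np
import pytest

from dreme.evaluation import evaluate_scenarios
from dreme.geometry import ScanGeometry, VolumeGrid
from dreme.model import DremeModel, ModelConfig
from dreme.phantom import (PhantomSpec, build_phantom, default_geometry,
                           make_trajectory, simulate_scan)
from dreme.trainer import TrainingSchedule, train_dreme


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    return ScanGeometry(sad=500.0, sdd=800.0, n_u=24, n_v=20, du=2.0, dv=2.0,
                        angles=[0.0, 33.0, 120.5])


@pytest.fixture
def random_volume16(rng):
    return VolumeGrid(rng.random((16, 16, 16), dtype=np.float32), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def desk_setup():
    """Desk-profile phantom, geometry and training scan (X3-analog)."""
    cfg = ModelConfig.desk()
    spec = PhantomSpec(shape=cfg.grid_shape_hi, spacing=cfg.grid_spacing_hi)
    geom = default_geometry(n_projections=240, n_u=64, n_v=48, du=4.0, dv=4.0)
    phantom, mask = build_phantom(spec)
    traj = make_trajectory("frequency-varying",
                           duration_s=geom.n_projections / geom.frame_rate,
                           fps=geom.frame_rate, seed=1)
    scan, truth = simulate_scan(phantom, mask, traj, geom, spec)
    return dict(config=cfg, spec=spec, geometry=geom, phantom=phantom,
                mask=mask, trajectory=traj, scan=scan, truth=truth)


@pytest.fixture(scope="session")
def trained_study(desk_setup):
    """One full desk-profile training run plus the 7-scenario evaluation.

    Shared by the simulation-study and parameter-recovery checks; this is
    the expensive fixture of the suite (several minutes of optimization).
    """
    model, report = train_dreme(desk_setup["scan"], TrainingSchedule.desk(),
                                desk_setup["config"], seed=17)
    table = evaluate_scenarios(model, desk_setup["spec"], eval_stride=12,
                               seed=23)
    return dict(model=model, report=report, table=table, **desk_setup)


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained but finalized model (valid forward path, fast)."""
    geom = default_geometry(n_projections=12, n_u=32, n_v=24, du=6.0, dv=6.0)
    cfg = ModelConfig(grid_shape_lo=(16, 16, 8), grid_spacing_lo=(8.0, 8.0, 8.0),
                      grid_shape_hi=(32, 32, 16), grid_spacing_hi=(4.0, 4.0, 4.0),
                      inr_levels=4, inr_log2_table=12, inr_base_resolution=4,
                      inr_growth=1.5, inr_hidden=16, step_scale=1.0)
    model = DremeModel(geom, cfg, seed=5)
    rng = np.random.default_rng(0)
    frames = rng.random((geom.n_projections, geom.n_v, geom.n_u)).astype(np.float32)
    pre = np.stack([model.preprocess(f) for f in frames])
    # give the motion basis some nonzero content so DVFs are not trivially zero
    for c in model.basis.coefficients:
        c.data = rng.normal(0, 0.3, c.data.shape).astype(np.float32)
    model.finalize(model.cnn.encode(pre).reshape(-1, 3, 3), float(frames.max()))
    model._train_frames = frames
    return model
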