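"""Training orchestration: schedule contract, freezing, determinism,
augmentation batches, and a small convergence smoke test."""

import numpy as np
import pandas as pd
import pytest

from dreme.geometry import forward_project
from dreme.losses import AugmentationConfig
from dreme.model import ModelConfig
from dreme.motion import compose_dvf, warp_volume, MBCScores
from dreme.phantom import (PhantomSpec, build_phantom, default_geometry,
                           make_trajectory, simulate_scan)
from dreme.trainer import (TrainingSchedule, _BatchSampler, _augmented_drrs,
                           make_augmented_batch, train_dreme)


def _tiny_problem(n_proj=24):
    cfg = ModelConfig(grid_shape_lo=(24, 24, 12), grid_spacing_lo=(8.0, 8.0, 8.0),
                      grid_shape_hi=(48, 48, 24), grid_spacing_hi=(4.0, 4.0, 4.0),
                      inr_levels=5, inr_log2_table=13, inr_base_resolution=4,
                      inr_growth=1.6, inr_hidden=24, step_scale=1.0,
                      image_subsample=16384)
    spec = PhantomSpec(shape=cfg.grid_shape_hi, spacing=cfg.grid_spacing_hi)
    geom = default_geometry(n_projections=n_proj, n_u=48, n_v=36, du=5.5,
                            dv=5.5)
    phantom, mask = build_phantom(spec)
    traj = make_trajectory("regular", duration_s=n_proj / 11.0, fps=11.0)
    scan, truth = simulate_scan(phantom, mask, traj, geom, spec)
    return cfg, spec, scan, truth


def test_standard_schedule_stage_ledger():
    sched = TrainingSchedule.standard()
    names = [s.name for s in sched.stages]
    assert names == ["I-a", "I-b", "I-c", "II-a", "II-b", "II-c", "II-d"]
    assert [s.epochs for s in sched.stages] == [400, 700, 1700, 1000, 1000,
                                                1000, 1000]
    assert [s.lr_inr for s in sched.stages] == [4e-4, 4e-5, 1e-5, 1e-3, 4e-4,
                                                1e-4, 0.0]
    assert [s.lr_encoder for s in sched.stages] == [0.0, 0.0, 1e-3, 0.0, 0.0,
                                                    1e-4, 1e-4]
    assert [s.lr_bspline for s in sched.stages] == [0.0, 0.0, 1e-3, 0.0, 0.0,
                                                    1e-4, 0.0]
    assert sched.stages[6].augmentation == "motion_and_angle"
    assert sched.stages[4].augmentation == "angle_only"
    assert [s.resolution for s in sched.stages] == ["lo"] * 3 + ["hi"] * 4


def test_zero_epoch_schedule_is_a_noop():
    cfg, spec, scan, _ = _tiny_problem(n_proj=8)
    sched = TrainingSchedule.standard(epochs={n: 0 for n in
                                              "I-a I-b I-c II-a II-b II-c II-d".split()})
    model, report = train_dreme(scan, sched, cfg, seed=9)
    assert model.finalized
    for stage, comps in report["stage_hashes"].items():
        for comp, (before, after) in comps.items():
            assert before == after


def test_frozen_components_unchanged_across_stages():
    """Every component trained with zero learning rate in a stage has
    bitwise identical parameters before and after that stage."""
    cfg, spec, scan, _ = _tiny_problem(n_proj=16)
    sched = TrainingSchedule.desk(epochs={"I-a": 4, "I-b": 4, "I-c": 4,
                                          "II-a": 4, "II-b": 4, "II-c": 4,
                                          "II-d": 4})
    model, report = train_dreme(scan, sched, cfg, seed=11)
    frozen_map = {"I-a": ["cnn", "basis"], "I-b": ["cnn", "basis"],
                  "II-a": ["cnn", "basis"], "II-b": ["cnn", "basis"],
                  "II-d": ["inr", "basis"]}
    for stage, frozen in frozen_map.items():
        for comp in frozen:
            before, after = report["stage_hashes"][stage][comp]
            assert before == after, f"{comp} changed during {stage}"
    # and the trained components do change
    for stage, comp in [("I-a", "inr"), ("I-c", "basis"), ("II-d", "cnn")]:
        before, after = report["stage_hashes"][stage][comp]
        assert before != after


def test_training_is_deterministic_given_seed():
    cfg, spec, scan, _ = _tiny_problem(n_proj=8)
    epochs = {"I-a": 10, "I-b": 0, "I-c": 0, "II-a": 0, "II-b": 0,
              "II-c": 0, "II-d": 0}
    m1, r1 = train_dreme(scan, TrainingSchedule.desk(epochs=epochs), cfg, seed=4)
    m2, r2 = train_dreme(scan, TrainingSchedule.desk(epochs=epochs), cfg, seed=4)
    assert r1["stage_hashes"]["I-a"] == r2["stage_hashes"]["I-a"]
    for k, v in m1.state()["inr"].items():
        np.testing.assert_array_equal(v, m2.state()["inr"][k])


def test_projection_loss_converges_on_sinusoidal_scan():
    """On a small one-trajectory scan the projection-domain loss drops below
    10% of its first-epoch value by the end of stage-I training."""
    cfg, spec, scan, _ = _tiny_problem(n_proj=48)
    sched = TrainingSchedule.desk(epochs={"I-a": 80, "I-b": 60, "I-c": 280,
                                          "II-a": 0, "II-b": 0, "II-c": 0,
                                          "II-d": 0})
    model, report = train_dreme(scan, sched, cfg, seed=2)
    h = pd.DataFrame(report["history"])
    prj = h.dropna(subset=["projection"])["projection"]
    assert prj.iloc[-1] < 0.10 * prj.iloc[0]


def test_batch_sampler_covers_each_cycle(rng):
    s = _BatchSampler(10, 4, rng)
    seen = np.concatenate([s.next() for _ in range(5)])  # 2 cycles
    assert sorted(seen[:10].tolist()) == list(range(10))
    assert sorted(seen[10:20].tolist()) == list(range(10))


class TestAugmentedBatch:
    def test_seeded_angles_reproducible(self, tiny_model):
        cfg = AugmentationConfig(mode="angle_only")
        frames = tiny_model._train_frames[:4]
        d1, t1, a1 = make_augmented_batch(tiny_model, frames, cfg,
                                          np.random.default_rng(3))
        d2, t2, a2 = make_augmented_batch(tiny_model, frames, cfg,
                                          np.random.default_rng(3))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(t1, t2)

    def test_degenerate_motion_ranges_match_angle_only(self, tiny_model):
        frames = tiny_model._train_frames[:3]
        cfg_m = AugmentationConfig(mode="motion_and_angle",
                                   r1_range=(1.0, 1.0), r2_range=(1.0, 1.0))
        cfg_a = AugmentationConfig(mode="angle_only")
        _, tm, _ = make_augmented_batch(tiny_model, frames, cfg_m,
                                        np.random.default_rng(0))
        _, ta, _ = make_augmented_batch(tiny_model, frames, cfg_a,
                                        np.random.default_rng(0))
        np.testing.assert_allclose(tm, ta, atol=1e-12)

    def test_off_mode_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            make_augmented_batch(tiny_model, tiny_model._train_frames[:1],
                                 AugmentationConfig(mode="off"),
                                 np.random.default_rng(0))

    def test_augmented_drr_consistent_with_direct_render(self, tiny_model):
        """With unchanged scores, the augmentation DRR at a given angle
        equals projecting the directly warped reference volume."""
        from dreme.geometry import default_step
        model = tiny_model
        w = model.solved_scores[1]
        vol = model.reference_volume()
        fields = model.basis_fields()
        rng = np.random.default_rng(8)
        drrs, angles = _augmented_drrs(vol.data, fields, w[None],
                                       model.grid_hi, model.geometry,
                                       default_step(model.grid_hi,
                                                    model.config.step_scale),
                                       rng)
        dvf = compose_dvf(MBCScores(w), model.basis, model.grid_hi,
                          fields=fields)
        direct = forward_project(warp_volume(vol, dvf), model.geometry,
                                 angles[0],
                                 default_step(model.grid_hi,
                                              model.config.step_scale))
        np.testing.assert_allclose(drrs[0], direct, atol=1e-5)
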