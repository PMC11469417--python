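# dreme

**Dynamic cone-beam CT reconstruction with real-time single-projection
motion estimation.**

Radiotherapy of thoracic and abdominal tumors needs to know where the
target is *right now*, but a rotating gantry delivers only one 2D x-ray
projection at a time, and a conventional CBCT reconstruction of the
pre-treatment scan is blurred by breathing.  `dreme` solves both problems
from a single standard pre-treatment scan, with no planning 4D-CT, no prior
motion model and no population training data:

1. **Dynamic reconstruction.**  The scan is explained as a static reference
   volume `I_ref(x)` (a hash-encoded coordinate network) deformed per
   projection by a low-rank motion model
   `d_k(x,p) = Σ_{i=1..3} w_{i,k}(p)·e_{i,k}(x)`, where the spatial motion
   basis components `e_{i,k}` are learnable multi-level B-spline fields and
   the nine scores `w_{i,k}(p)` are produced by a CNN *motion encoder* that
   reads the projection itself.  Training matches digitally reconstructed
   radiographs of the deformed volumes to the measured projections, with
   ortho-normality, zero-mean-score, total-variation and DVF
   self-consistency regularization, in a seven-stage progressive
   multiresolution schedule.
2. **Real-time inference.**  Because the encoder maps *any* projection to
   scores, a single intra-treatment x-ray at an arbitrary gantry angle
   yields the nine scores, hence a dense 3D displacement field, a
   volumetric image (warped reference), and a propagated tumor contour —
   one CNN pass plus a linear composition.

The package is for researchers in image-guided radiotherapy who want a
transparent, CPU-runnable reference implementation of this one-shot
dual-task approach, including the synthetic dynamic-thorax study used to
validate it.  Everything (projector, FDK, B-spline motion model, hash
encoder, CNN, autodiff engine) is plain numpy/numba — no GPU required.

## Worked example

Simulate a 240-frame scan of the breathing thorax phantom (frequency-varying
"X3" trajectory), train, and run single-projection inference:

```python
import numpy as np
from dreme import (ModelConfig, PhantomSpec, TrainingSchedule, build_phantom,
                   default_geometry, make_trajectory, simulate_scan,
                   train_dreme, infer_realtime, evaluate_scenarios)

cfg  = ModelConfig.desk()                       # 96x96x48 @ 2 mm profile
spec = PhantomSpec(shape=cfg.grid_shape_hi, spacing=cfg.grid_spacing_hi)
geom = default_geometry(n_projections=240, n_u=64, n_v=48, du=4.0, dv=4.0)
phantom, tumor = build_phantom(spec)
traj = make_trajectory("frequency-varying", duration_s=240/11, fps=11, seed=1)
scan, truth = simulate_scan(phantom, tumor, traj, geom, spec)

model, report = train_dreme(scan, TrainingSchedule.desk(), cfg, seed=17)

scores, dvf, volume = infer_realtime(model, scan.frames[0])
print(scores.w.round(2))        # 3x3 score matrix [level, direction]
print(np.abs(dvf.displacement[..., 2]).max())   # peak SI displacement, mm

table = evaluate_scenarios(model, spec, eval_stride=10, seed=23)
print(table[["scenario", "come_mean", "dsc_mean", "ssim_mean", "re_mean"]])
```

On the desk profile (one CPU core, ~15 min of training) this prints a
cross-scenario table like

```
         scenario  come_mean  dsc_mean  ssim_mean  re_mean
          regular      1.189     0.929      0.936    0.128
frequency-varying      1.108     0.927      0.936    0.127
   extended-range      1.382     0.920      0.934    0.131
              ...        ...       ...        ...      ...
          overall      1.149     0.928      0.936    0.128
```

i.e. the propagated tumor contour lands within ~1.1 mm of the ground-truth
center of mass on average over seven breathing scenarios (including one
with amplitudes beyond anything seen in training), with test projections at
gantry angles offset 90.27° from every training angle.  `come_mean` is in
mm; the other metrics are dimensionless.

A thin CLI wraps the same library calls:

```bash
dreme simulate --trajectory frequency-varying --out scan.h5 --seed 1
dreme train    --projections scan.h5 --out model.ckpt --seed 17
dreme infer    --model model.ckpt --frame scan.h5 --index 0 --out result
dreme evaluate --model model.ckpt --out metrics.csv
```

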