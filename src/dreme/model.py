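"""The trained model state: reference-volume network, motion basis, encoder.

A `DremeModel` bundles everything single-projection inference needs: the
spatial coordinate network (reference CBCT), the B-spline motion basis, the
CNN motion encoder, the training scan geometry, and frozen preprocessing
constants.  The trainer owns its construction; inference and I/O consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import ScanGeometry, VolumeGrid
from .motion import MotionBasisSet, evaluate_basis
from .networks import MotionEncoderCNN, SpatialINR, preprocess_frame, render_volume


@dataclass
class ModelConfig:
    """Architecture and problem-size configuration.

    The defaults reproduce the full-scale study setup (4 mm / 2 mm stage
    grids over a 400x400x200 mm field of view).  `desk()` returns the
    scaled-down profile used by the test-suite and the bundled study script.
    """

    grid_shape_lo: tuple[int, int, int] = (100, 100, 50)
    grid_spacing_lo: tuple[float, float, float] = (4.0, 4.0, 4.0)
    grid_shape_hi: tuple[int, int, int] = (200, 200, 100)
    grid_spacing_hi: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # spatial coordinate network
    inr_levels: int = 12
    inr_features: int = 2
    inr_log2_table: int = 19
    inr_base_resolution: int = 8
    inr_growth: float = 1.38
    inr_hidden: int = 64
    inr_n_hidden: int = 2
    # motion basis
    basis_base_control: tuple[int, int, int] = (6, 6, 4)
    basis_levels: int = 3
    # motion encoder
    cnn_input: tuple[int, int] = (96, 128)
    # projector / training numerics
    step_scale: float = 0.5
    n_batch: int = 32
    sc_frames: int = 4
    sc_stride: int = 2
    image_subsample: int | None = 131072
    grad_clip: float = 10.0
    # divide measured frames and DRRs by the scan maximum inside the
    # projection-domain loss (off: raw line integrals are compared)
    normalize_projections: bool = False

    @classmethod
    def desk(cls) -> "ModelConfig":
        """Laptop-class profile: 96x96x48 at 2 mm, lighter hash encoder."""
        return cls(grid_shape_lo=(48, 48, 24), grid_spacing_lo=(4.0, 4.0, 4.0),
                   grid_shape_hi=(96, 96, 48), grid_spacing_hi=(2.0, 2.0, 2.0),
                   inr_levels=8, inr_log2_table=19, inr_base_resolution=8,
                   inr_growth=1.45, inr_hidden=64, step_scale=1.0)

    @classmethod
    def mini(cls) -> "ModelConfig":
        """Very small profile for unit tests and smoke runs."""
        return cls(grid_shape_lo=(32, 32, 16), grid_spacing_lo=(6.0, 6.0, 6.0),
                   grid_shape_hi=(64, 64, 32), grid_spacing_hi=(3.0, 3.0, 3.0),
                   inr_levels=6, inr_log2_table=15, inr_base_resolution=6,
                   inr_growth=1.5, inr_hidden=32, step_scale=1.0,
                   image_subsample=65536)


class DremeModel:
    """Trainable/trained model state for one pre-treatment scan."""

    def __init__(self, geometry: ScanGeometry, config: ModelConfig, seed: int = 17):
        self.geometry = geometry
        self.config = config
        self.seed = int(seed)
        ss = np.random.SeedSequence(seed)
        r_inr, r_cnn = [np.random.default_rng(s) for s in ss.spawn(2)]

        self.grid_lo = VolumeGrid(np.zeros(config.grid_shape_lo, np.float32),
                                  config.grid_spacing_lo)
        self.grid_hi = VolumeGrid(np.zeros(config.grid_shape_hi, np.float32),
                                  config.grid_spacing_hi)
        lo = np.minimum(self.grid_lo.origin, self.grid_hi.origin)
        hi = np.maximum(np.asarray(self.grid_lo.origin) + self.grid_lo.extent,
                        np.asarray(self.grid_hi.origin) + self.grid_hi.extent)
        margin = 0.5 * np.asarray(config.grid_spacing_lo)
        self.inr = SpatialINR(lo - margin, hi + margin, r_inr,
                              n_levels=config.inr_levels,
                              n_features=config.inr_features,
                              log2_table=config.inr_log2_table,
                              base_resolution=config.inr_base_resolution,
                              growth=config.inr_growth,
                              hidden=config.inr_hidden,
                              n_hidden=config.inr_n_hidden)
        self.cnn = MotionEncoderCNN(r_cnn, input_size=config.cnn_input,
                                    verbose=False)
        self.basis = MotionBasisSet.covering(
            [self.grid_lo, self.grid_hi],
            base_control=config.basis_base_control,
            n_levels=config.basis_levels)

        self.frame_norm: float = 1.0
        self.solved_scores: np.ndarray | None = None   # (Np, 3, 3)
        self._iref_hi: VolumeGrid | None = None
        self._fields_hi: np.ndarray | None = None
        self.finalized = False

    # -- inference-side accessors ----------------------------------------
    def preprocess(self, frame: np.ndarray) -> np.ndarray:
        return preprocess_frame(frame, self.config.cnn_input, self.frame_norm)

    def reference_volume(self, grid: VolumeGrid | None = None) -> VolumeGrid:
        if grid is None or grid is self.grid_hi:
            if self._iref_hi is None:
                self._iref_hi = render_volume(self.inr, self.grid_hi)
            return self._iref_hi
        return render_volume(self.inr, grid)

    def basis_fields(self, grid: VolumeGrid | None = None) -> np.ndarray:
        if grid is None or grid is self.grid_hi:
            if self._fields_hi is None:
                self._fields_hi = evaluate_basis(self.basis, self.grid_hi)
            return self._fields_hi
        return evaluate_basis(self.basis, grid)

    def invalidate_caches(self):
        self._iref_hi = None
        self._fields_hi = None

    def finalize(self, solved_scores: np.ndarray, frame_norm: float):
        self.solved_scores = np.asarray(solved_scores, dtype=np.float64)
        self.frame_norm = float(frame_norm)
        self.invalidate_caches()
        self.finalized = True

    # -- (de)serialization -------------------------------------------------
    def state(self) -> dict:
        return {"inr": self.inr.state(), "cnn": self.cnn.state(),
                "basis": self.basis.state()}

    def load_state(self, s: dict):
        self.inr.load_state(s["inr"])
        self.cnn.load_state(s["cnn"])
        self.basis.load_state(s["basis"])
        self.invalidate_caches()

    def config_dict(self) -> dict:
        return asdict(self.config)
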