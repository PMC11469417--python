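"""File formats: volumes (NIfTI/MetaImage), projection stacks (HDF5),
geometry (YAML) and model checkpoints (HDF5)."""

from __future__ import annotations

import io as _io
import os

import h5py
import nibabel as nib
import numpy as np
import yaml

from .geometry import ProjectionSet, ScanGeometry, VolumeGrid
from .model import DremeModel, ModelConfig
from .motion import DVF

_GEOM_FIELDS = ("sad", "sdd", "n_u", "n_v", "du", "dv",
                "detector_offset_u", "frame_rate")


# -- volumes ----------------------------------------------------------------

def save_volume(path: str, volume: VolumeGrid):
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), path)
    elif path.endswith(".mha"):
        _save_metaimage(path, volume)
    else:
        raise ValueError("unsupported volume format (use .nii/.nii.gz/.mha)")


def load_volume(path: str) -> VolumeGrid:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        return VolumeGrid(np.asarray(img.dataobj), spacing,
                          tuple(affine[:3, 3]))
    if path.endswith(".mha"):
        return _load_metaimage(path)
    raise ValueError("unsupported volume format")


_MHA_TYPES = {"MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
              "MET_UCHAR": np.uint8, "MET_SHORT": np.int16}


def _save_metaimage(path: str, volume: VolumeGrid):
    data = np.asarray(volume.data)
    code = {v: k for k, v in _MHA_TYPES.items()}.get(data.dtype.type)
    if code is None:
        data = data.astype(np.float32)
        code = "MET_FLOAT"
    header = (
        "ObjectType = Image\nNDims = 3\nBinaryData = True\n"
        "BinaryDataByteOrderMSB = False\nCompressedData = False\n"
        "TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        f"Offset = {' '.join(str(o) for o in volume.origin)}\n"
        "CenterOfRotation = 0 0 0\nAnatomicalOrientation = RAI\n"
        f"ElementSpacing = {' '.join(str(s) for s in volume.spacing)}\n"
        f"DimSize = {' '.join(str(n) for n in data.shape)}\n"
        f"ElementType = {code}\nElementDataFile = LOCAL\n")
    with open(path, "wb") as f:
        f.write(header.encode())
        # MetaImage raw block is x-fastest; our arrays are x-slowest
        f.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def _load_metaimage(path: str) -> VolumeGrid:
    with open(path, "rb") as f:
        raw = f.read()
    head, _, body = raw.partition(b"ElementDataFile = LOCAL\n")
    meta = dict(line.split(" = ", 1)
                for line in head.decode().strip().splitlines())
    dims = tuple(int(v) for v in meta["DimSize"].split())
    spacing = tuple(float(v) for v in meta["ElementSpacing"].split())
    origin = tuple(float(v) for v in meta["Offset"].split())
    dtype = _MHA_TYPES[meta["ElementType"].strip()]
    data = np.frombuffer(body, dtype=dtype).reshape(dims[::-1]).transpose(2, 1, 0)
    return VolumeGrid(data.copy(), spacing, origin)


def save_dvf(path: str, dvf: DVF):
    """3-component displacement field as a 4D NIfTI (mm)."""
    affine = np.diag(list(dvf.spacing) + [1.0])
    affine[:3, 3] = dvf.origin
    nib.save(nib.Nifti1Image(np.asarray(dvf.displacement, dtype=np.float32),
                             affine), str(path))


# -- geometry / projections -------------------------------------------------

def geometry_to_yaml(geom: ScanGeometry) -> str:
    d = {k: getattr(geom, k) for k in _GEOM_FIELDS}
    d = {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
         for k, v in d.items()}
    d["angles"] = [float(a) for a in geom.angles]
    return yaml.safe_dump(d)


def geometry_from_yaml(text: str) -> ScanGeometry:
    d = yaml.safe_load(text)
    return ScanGeometry(angles=np.asarray(d.pop("angles")), **d)


def save_projections(path: str, projections: ProjectionSet):
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=projections.frames,
                         compression="gzip", compression_opts=4)
        f.create_dataset("angles", data=projections.geometry.angles)
        f.create_dataset("acquisition_index",
                         data=projections.acquisition_index)
        for k in _GEOM_FIELDS:
            f.attrs[k] = getattr(projections.geometry, k)


def load_projections(path: str) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        frames = f["frames"][()]
        angles = f["angles"][()]
        idx = f["acquisition_index"][()] if "acquisition_index" in f else None
        kw = {k: f.attrs[k] for k in _GEOM_FIELDS}
    geom = ScanGeometry(angles=angles, **{k: kw[k] for k in kw})
    return ProjectionSet(frames, geom, idx)


# -- model checkpoints ------------------------------------------------------

def save_checkpoint(path: str, model: DremeModel):
    if not model.finalized:
        raise ValueError("refusing to checkpoint an unfinalized model")
    with h5py.File(path, "w") as f:
        for comp, state in model.state().items():
            g = f.create_group(comp)
            for k, v in state.items():
                g.create_dataset(k, data=v)
        f.attrs["config"] = yaml.safe_dump(model.config_dict())
        f.attrs["geometry"] = geometry_to_yaml(model.geometry)
        f.attrs["frame_norm"] = model.frame_norm
        f.attrs["seed"] = model.seed
        f.create_dataset("solved_scores", data=model.solved_scores)


def load_checkpoint(path: str) -> DremeModel:
    with h5py.File(path, "r") as f:
        cfg_d = yaml.safe_load(f.attrs["config"])
        for k in ("grid_shape_lo", "grid_spacing_lo", "grid_shape_hi",
                  "grid_spacing_hi", "basis_base_control", "cnn_input"):
            cfg_d[k] = tuple(cfg_d[k])
        config = ModelConfig(**cfg_d)
        geom = geometry_from_yaml(f.attrs["geometry"])
        model = DremeModel(geom, config, seed=int(f.attrs["seed"]))
        state = {comp: {k: f[comp][k][()] for k in f[comp]}
                 for comp in ("inr", "cnn", "basis")}
        model.load_state(state)
        model.finalize(f["solved_scores"][()], float(f.attrs["frame_norm"]))
    return model
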