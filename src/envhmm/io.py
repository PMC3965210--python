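"""Reading and writing the pipeline's interchange formats.

A NumPy ``.npz`` archive with named datasets is the interchange medium
between stages; small fixtures can also be imported from delimited text.
Models are serialized to JSON, tabular outputs to CSV, and spatial maps
optionally to NIfTI on a regular voxel grid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .containers import EnvelopeDataset, StatePath
from .hmm import HMMModel, HMMPriors

__all__ = [
    "save_envelope_dataset",
    "load_envelope_dataset",
    "save_state_path",
    "load_state_path",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "load_delimited_matrix",
    "vector_to_nifti",
]


def save_envelope_dataset(path, dataset: EnvelopeDataset, true_states: StatePath = None):
    arrays = {
        "data": dataset.data,
        "sampling_rate": np.array([dataset.sampling_rate]),
        "segment_boundaries": dataset.segment_boundaries,
    }
    if dataset.voxel_coords is not None:
        arrays["voxel_coords"] = dataset.voxel_coords
    if true_states is not None:
        arrays["true_states"] = true_states.states
    np.savez_compressed(path, **arrays)


def load_envelope_dataset(path) -> tuple[EnvelopeDataset, np.ndarray]:
    """Returns (dataset, true_states-or-None)."""
    with np.load(path) as z:
        ds = EnvelopeDataset(
            z["data"],
            float(z["sampling_rate"][0]),
            voxel_coords=z["voxel_coords"] if "voxel_coords" in z else None,
            segment_boundaries=z["segment_boundaries"],
        )
        true_states = z["true_states"] if "true_states" in z else None
    return ds, true_states


def save_state_path(path, state_path: StatePath, gamma: np.ndarray = None):
    arrays = {
        "states": state_path.states,
        "sampling_rate": np.array([state_path.sampling_rate]),
        "segment_boundaries": state_path.segment_boundaries,
        "n_states": np.array([state_path.n_states]),
    }
    if gamma is not None:
        arrays["gamma"] = gamma
    np.savez_compressed(path, **arrays)


def load_state_path(path) -> StatePath:
    with np.load(path) as z:
        return StatePath(
            z["states"],
            float(z["sampling_rate"][0]),
            segment_boundaries=z["segment_boundaries"],
            n_states=int(z["n_states"][0]),
        )


def _to_jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def model_to_dict(model: HMMModel) -> dict:
    d = {
        "n_states": model.n_states,
        "n_features": model.n_features,
        "priors": {k: _to_jsonable(v) for k, v in dataclasses.asdict(model.priors).items()},
    }
    for name in ("trans_alpha", "init_alpha", "beta", "m", "W", "nu"):
        d[name] = _to_jsonable(getattr(model, name))
    return d


def model_from_dict(d: dict) -> HMMModel:
    pri = HMMPriors(**{
        k: (np.asarray(v, float) if isinstance(v, list) else v)
        for k, v in d["priors"].items()
    })
    return HMMModel(
        n_states=d["n_states"],
        n_features=d["n_features"],
        priors=pri,
        trans_alpha=np.asarray(d["trans_alpha"], float),
        init_alpha=np.asarray(d["init_alpha"], float),
        beta=np.asarray(d["beta"], float),
        m=np.asarray(d["m"], float),
        W=np.asarray(d["W"], float),
        nu=np.asarray(d["nu"], float),
    )


def save_model(path, model: HMMModel, extra: dict = None):
    d = model_to_dict(model)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def load_model(path) -> HMMModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def load_delimited_matrix(path, delimiter=None) -> np.ndarray:
    """Load a 2-D matrix from whitespace- or character-delimited text."""
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))


def vector_to_nifti(values, voxel_coords, out_path, grid_spacing_mm: float = None):
    """Write a V-length vector as a NIfTI volume on the voxels' regular grid.

    The grid spacing is inferred from the coordinates when not given;
    voxels outside the vector are NaN.
    """
    import nibabel as nib

    values = np.asarray(values, dtype=np.float64)
    coords = np.asarray(voxel_coords, dtype=np.float64)
    if grid_spacing_mm is None:
        diffs = [np.diff(np.unique(coords[:, i])) for i in range(3)]
        spacings = [d.min() for d in diffs if d.size]
        if not spacings:
            raise ValueError("cannot infer a grid spacing from a single voxel")
        grid_spacing_mm = float(min(spacings))
    origin = coords.min(axis=0)
    ijk = np.round((coords - origin) / grid_spacing_mm).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
    affine = np.diag([grid_spacing_mm] * 3 + [1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol, affine), str(out_path))
    return out_path
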