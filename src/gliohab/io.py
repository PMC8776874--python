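"""File IO: NIfTI volumes, cohort tables, and model persistence.

Volumes travel as NIfTI-1 (any affine is accepted, but all of a subject's
volumes must share it exactly); tables are UTF-8 CSV with a header row;
nested outputs are JSON.  The trained two-level model is persisted as a
single JSON document (prototype weights included as nested lists) so runs
remain text-only and diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .clustering import ProtoclusterLabeling, TwoLevelHabitatClustering
from .features import CHANNEL_NAMES, SubjectStack
from .som import BatchSOM

logger = logging.getLogger(__name__)

CHANNEL_FILES = {name: f"{name}.nii.gz" for name in CHANNEL_NAMES}


def save_volume(data: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    affine = np.eye(4) if affine is None else affine
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_subject(stack: SubjectStack, directory) -> None:
    """Write a subject's channels and masks as NIfTI under one directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for c, name in enumerate(CHANNEL_NAMES):
        save_volume(stack.channels[c], directory / CHANNEL_FILES[name])
    save_volume(stack.brain_mask, directory / "brain_mask.nii.gz")
    save_volume(stack.tumor_mask, directory / "tumor_mask.nii.gz")


def load_subject(directory, subject_id: str, idh_status: Optional[str] = None,
                 age: Optional[float] = None) -> SubjectStack:
    """Load one subject's four channels and masks from a directory.

    Shapes and affines are validated across all volumes; the tumor mask
    must lie within the brain mask (SubjectStack enforces it).
    """
    directory = Path(directory)
    channels = []
    affine_ref = None
    shapes = {}
    for name in CHANNEL_NAMES:
        path = directory / CHANNEL_FILES[name]
        data, affine = load_volume(path)
        shapes[path.name] = data.shape
        if affine_ref is None:
            affine_ref = affine
        elif not np.array_equal(affine, affine_ref):
            raise ValueError(f"{path.name}: affine differs from the first channel")
        channels.append(data)
    brain, aff_b = load_volume(directory / "brain_mask.nii.gz")
    tumor, aff_t = load_volume(directory / "tumor_mask.nii.gz")
    shapes["brain_mask"] = brain.shape
    shapes["tumor_mask"] = tumor.shape
    if len(set(shapes.values())) != 1:
        raise ValueError(f"shape mismatch across volumes: {shapes}")
    for name, aff in (("brain_mask", aff_b), ("tumor_mask", aff_t)):
        if not np.array_equal(aff, affine_ref):
            raise ValueError(f"{name}: affine differs from the channels")
    stack = SubjectStack(subject_id=subject_id, channels=np.stack(channels),
                         brain_mask=brain > 0.5, tumor_mask=tumor > 0.5,
                         idh_status=idh_status, age=age)
    logger.info("loaded subject %s: shape %s, %d brain voxels, %d tumor voxels",
                subject_id, stack.shape, int(stack.brain_mask.sum()),
                int(stack.tumor_mask.sum()))
    return stack


def read_cohort_table(path) -> pd.DataFrame:
    """Read the cohort CSV (subject_id, idh_status, optional age, path)."""
    df = pd.read_csv(path)
    required = {"subject_id", "idh_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    bad = set(df["idh_status"]) - {"mutant", "wildtype"}
    if bad:
        raise ValueError(f"unknown IDH status values: {sorted(bad)}")
    return df


def write_cohort_table(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)


def save_model(model: TwoLevelHabitatClustering, path) -> None:
    """Persist a fitted two-level model as one JSON document."""
    doc = {
        "params": model.get_params(),
        "prototypes": model.som_.prototypes_.tolist(),
        "grid_h": model.som_.grid_h,
        "grid_w": model.som_.grid_w,
        "node_labels": model.labeling_.node_labels.tolist(),
        "n_clusters": model.labeling_.n_clusters,
        "inertia": model.labeling_.inertia,
        "quantization_errors": model.som_.quantization_errors_,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> TwoLevelHabitatClustering:
    doc = json.loads(Path(path).read_text())
    model = TwoLevelHabitatClustering(**doc["params"])
    som = BatchSOM(grid_h=doc["grid_h"], grid_w=doc["grid_w"])
    som.prototypes_ = np.asarray(doc["prototypes"], dtype=float)
    som.grid_coords_ = som._grid_coords()
    som.quantization_errors_ = doc["quantization_errors"]
    som.n_features_in_ = som.prototypes_.shape[1]
    model.som_ = som
    model.labeling_ = ProtoclusterLabeling(
        n_clusters=doc["n_clusters"],
        node_labels=np.asarray(doc["node_labels"], dtype=int),
        inertia=doc["inertia"], seed=model.random_state,
        restarts=model.n_restarts)
    return model


def write_json(obj, path) -> None:
    """Serialize with sorted keys and full float repr (bit-stable reruns)."""
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
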