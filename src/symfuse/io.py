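"""Reading and writing the pipeline's on-disk formats.

Phenotypes travel as TSV keyed by ``subject_id``; feature matrices as TSV
with a JSON sidecar carrying modality and provenance; spatial maps and masks
as NIfTI-1 (via nibabel) with the affine preserved round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import FeatureMatrix


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Load a phenotype TSV with a ``subject_id`` key column.

    Raises on duplicate subject ids and on rows whose field count differs
    from the header (reported with the 1-based line number).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty phenotype file")
    n_fields = len(lines[0].split("\t"))
    for i, line in enumerate(lines[1:], start=2):
        if line and len(line.split("\t")) != n_fields:
            raise ValueError(f"{path}: malformed row at line {i} "
                             f"({len(line.split(chr(9)))} fields, "
                             f"expected {n_fields})")
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject_id(s): "
                         f"{sorted(set(dup))}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_feature_matrix(X: FeatureMatrix, path: str | Path) -> None:
    """TSV (subject_id + one column per voxel) plus a ``.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(X.values,
                      columns=[f"v{i:05d}" for i in range(X.n_voxels)])
    df.insert(0, "subject_id", X.subject_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {"modality": X.modality, "provenance": X.provenance}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    ids = df["subject_id"].astype(str).tolist()
    values = df.drop(columns="subject_id").to_numpy(float)
    return FeatureMatrix(values, modality=meta.get("modality", "unknown"),
                         subject_ids=ids,
                         provenance=meta.get("provenance", []))


def write_nifti_map(values: np.ndarray, path: str | Path,
                    affine: np.ndarray | None = None,
                    shape: tuple[int, ...] | None = None) -> None:
    """Write a voxel vector (or 3-D/4-D array) as NIfTI-1."""
    arr = np.asarray(values, dtype=np.float64)
    if shape is not None:
        arr = arr.reshape(shape)
    elif arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_nifti_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti_mask(mask: np.ndarray, path: str | Path,
                     affine: np.ndarray | None = None) -> None:
    write_nifti_map(np.asarray(mask, dtype=np.float64), path, affine=affine)


def read_nifti_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_nifti_map(path)
    return data > 0.5, affine


def check_affine(a: np.ndarray, b: np.ndarray, context: str = "") -> None:
    if not np.allclose(a, b, atol=1e-6):
        raise ValueError(f"affine mismatch{': ' + context if context else ''}")


def write_json_report(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, default=default))
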