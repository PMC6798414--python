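"""Standard-format adapters: NIfTI volumes, TSV tables, GMT gene sets, JSON.

Conventions: the 4-D NIfTI's last dimension is time with index 0 the
precontrast volume (recorded in a sidecar JSON when the pipeline writes a
series); voxel coordinates are 0-based (x, y, z) matching the NIfTI affine;
masks are written as byte volumes.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_series",
    "write_series",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "write_json",
    "read_json",
]


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file -> (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data, affine=None, dtype=None) -> Path:
    """Write an array as NIfTI; boolean arrays are stored as uint8 masks."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    if dtype is not None:
        data = data.astype(dtype)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    path = Path(path)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def write_series(path, image_txyz: np.ndarray, affine=None, timepoints=None) -> Path:
    """Write a T x X x Y x Z series as an X x Y x Z x T NIfTI + sidecar JSON."""
    arr = np.moveaxis(np.asarray(image_txyz, dtype=float), 0, -1)
    path = write_nifti(path, arr, affine)
    sidecar = {"time_axis": "last", "precontrast_index": 0}
    if timepoints is not None:
        sidecar["timepoints_minutes"] = [float(t) for t in np.asarray(timepoints).ravel()]
    write_json(Path(str(path)).with_suffix("").with_suffix(".json"), sidecar)
    return path


def read_series(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a 4-D NIfTI series -> (T x X x Y x Z array, affine, sidecar dict)."""
    data, affine = read_nifti(path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D series, got shape {data.shape}")
    sidecar_path = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar = read_json(sidecar_path) if sidecar_path.exists() else {}
    return np.moveaxis(data, -1, 0), affine, sidecar


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(path, df: pd.DataFrame, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene ids...

    Trailing tabs and blank lines are tolerated; sets with no genes are
    skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = [p for p in line.split("\t")]
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line {lineno}: need name, description, genes")
        name = parts[0].strip()
        genes = [g.strip() for g in parts[2:] if g.strip()]
        if not genes:
            warnings.warn(f"GMT set {name!r} (line {lineno}) has no genes; skipped")
            continue
        sets[name] = genes
    return sets


def write_gmt(path, gene_sets: dict, description: str = "na") -> Path:
    path = Path(path)
    lines = [f"{name}\t{description}\t" + "\t".join(genes) for name, genes in gene_sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_json(path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
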