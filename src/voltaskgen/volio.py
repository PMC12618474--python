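"""Grids, masks, volume I/O, subject manifests, and checkpoint bookkeeping.

All stages of the pipeline share a single notion of the analysis domain: a
3D voxel grid plus a boolean gray-matter mask (:class:`MaskedGrid`).  Every
vectorized quantity (feature matrices, loss evaluations, metric inputs) uses
the same canonical voxel order — ascending C-order linear index over the
grid, last axis fastest — so results are reproducible bit-for-bit.

Volumes travel as NIfTI (.nii/.nii.gz) via :mod:`nibabel`; values outside
the mask are written as 0, never NaN.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MaskedGrid",
    "ContrastBattery",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "apply_mask",
    "scatter_mask",
    "load_manifest",
    "save_manifest",
    "save_checkpoint",
    "load_checkpoint",
]

#: entrywise tolerance when comparing affines (float round-trip via headers)
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when a volume's grid disagrees with the expected one."""


@dataclass(frozen=True)
class MaskedGrid:
    """A 3D voxel grid with an in-brain / gray-matter mask.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts ``(nx, ny, nz)``.
    affine : (4, 4) ndarray
        Voxel-to-world transform.
    mask : (nx, ny, nz) ndarray of bool
        True for voxels inside the analysis domain.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != dims:
            raise ValueError(f"mask shape {mask.shape} != dims {dims}")
        if not mask.any():
            raise ValueError("mask must contain at least one voxel")
        object.__setattr__(self, "mask", mask)

    @property
    def n_mask(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def matches(self, other: "MaskedGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def check_compatible(self, other: "MaskedGrid", atol: float = AFFINE_ATOL) -> None:
        if not self.matches(other, atol=atol):
            raise GridMismatchError(
                f"grid mismatch: dims {self.dims} vs {other.dims}, "
                f"max |affine diff| = "
                f"{np.abs(self.affine - other.affine).max():.3g}"
            )


@dataclass(frozen=True)
class ContrastBattery:
    """Ordered task-contrast names, optionally grouped by task domain."""

    contrasts: tuple[str, ...]
    domains: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.contrasts)
        object.__setattr__(self, "contrasts", names)
        if len(names) == 0:
            raise ValueError("battery must contain at least one contrast")
        if len(set(names)) != len(names):
            raise ValueError("contrast names must be unique")

    def __len__(self) -> int:
        return len(self.contrasts)

    def index(self, name: str) -> int:
        try:
            return self.contrasts.index(name)
        except ValueError:
            raise KeyError(f"contrast {name!r} not in battery") from None


# ---------------------------------------------------------------------------
# Volume I/O


def load_volume(path, expected_grid: MaskedGrid | None = None):
    """Load a 3D or 4D NIfTI volume.

    Returns ``(data, affine)``; if *expected_grid* is given, the volume's
    spatial dims and affine are checked against it (affines entrywise at
    ``AFFINE_ATOL``) and a :class:`GridMismatchError` is raised on
    disagreement — the signal for heterogeneous inputs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = np.asarray(img.affine, dtype=float)
    if expected_grid is not None:
        if tuple(data.shape[:3]) != expected_grid.dims or not np.allclose(
            affine, expected_grid.affine, atol=AFFINE_ATOL, rtol=0.0
        ):
            raise GridMismatchError(
                f"{path}: shape {data.shape[:3]} / affine disagree with "
                f"expected grid {expected_grid.dims}"
            )
    return data, affine


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D/4D array as NIfTI (float32 on disk)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Masking

def apply_mask(volume: np.ndarray, grid: MaskedGrid) -> np.ndarray:
    """Extract in-mask values in canonical voxel order.

    Canonical order is the ascending C-order linear index over the grid
    (last axis fastest).  For a 4D volume with trailing channel/time axis the
    result has shape ``(n_mask, extra)``.
    """
    volume = np.asarray(volume)
    if tuple(volume.shape[:3]) != grid.dims:
        raise ValueError(
            f"volume shape {volume.shape[:3]} does not match grid {grid.dims}"
        )
    return volume[grid.mask]


def scatter_mask(values: np.ndarray, grid: MaskedGrid) -> np.ndarray:
    """Inverse of :func:`apply_mask`: scatter values back, zeros outside."""
    values = np.asarray(values)
    if values.shape[0] != grid.n_mask:
        raise ValueError(
            f"expected {grid.n_mask} in-mask values, got {values.shape[0]}"
        )
    out = np.zeros(grid.dims + values.shape[1:], dtype=values.dtype)
    out[grid.mask] = values
    return out


# ---------------------------------------------------------------------------
# Subject manifests

REQUIRED_MANIFEST_COLUMNS = ("subject_id", "split")


def load_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Read a subject manifest (CSV or TSV, header row required).

    Columns: ``subject_id``, ``split`` (train/validation/test) plus one
    path column per modality.  Subject ids must be unique; with
    *check_paths* every referenced file must resolve (relative paths are
    resolved against the manifest's directory).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    for col in REQUIRED_MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    if check_paths:
        base = path.parent
        path_cols = [c for c in df.columns if c.endswith("_path") or c == "path"]
        for col in path_cols:
            for p in df[col].dropna():
                resolved = Path(p)
                if not resolved.is_absolute():
                    resolved = base / resolved
                if not resolved.exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def save_manifest(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Checkpoints
#
# A checkpoint is a single zip archive containing one .npy per parameter
# array plus a JSON metadata block (architecture spec, contrast battery,
# seed, loss config).  Backbone and output-layer parameters are stored under
# separate prefixes so the head-swap transfer protocol can address the
# output layer per contrast without touching the backbone.


def save_checkpoint(path, backbone: Mapping[str, np.ndarray],
                    head: Mapping[str, np.ndarray], meta: dict) -> None:
    """Write parameters + JSON metadata to a single zip archive."""
    path = Path(path)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for prefix, params in (("backbone", backbone), ("head", head)):
            for name, arr in params.items():
                buf = io.BytesIO()
                np.save(buf, np.asarray(arr))
                zf.writestr(f"{prefix}/{name}.npy", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2, sort_keys=True))


def load_checkpoint(path):
    """Read a checkpoint archive; returns ``(backbone, head, meta)``."""
    path = Path(path)
    backbone: dict[str, np.ndarray] = {}
    head: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json").decode("utf-8"))
        for entry in zf.namelist():
            if not entry.endswith(".npy"):
                continue
            prefix, name = entry.split("/", 1)
            arr = np.load(io.BytesIO(zf.read(entry)))
            target = backbone if prefix == "backbone" else head
            target[name[: -len(".npy")]] = arr
    return backbone, head, meta
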