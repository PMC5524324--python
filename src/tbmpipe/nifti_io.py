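"""NIfTI-1 round-trip I/O for images, label maps and deformation fields.

The package's (x, y, z) index convention maps directly onto the NIfTI
array axes with a diagonal affine (spacing on the diagonal, origin in the
translation column). Label dictionaries travel in a JSON sidecar next to
the label file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import GridSpec, ImageVolume, LabelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
]


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_header(img: nib.Nifti1Image, expect_4d: bool = False) -> GridSpec:
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0.0, atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ValueError("affine must carry positive spacings on the diagonal")
    shape = img.shape[:3]
    ndim = len(img.shape)
    if expect_4d and ndim != 4:
        raise ValueError(f"expected a 4D field volume, got {ndim}D")
    if not expect_4d and ndim != 3:
        raise ValueError(f"expected a 3D volume, got {ndim}D")
    return GridSpec(shape=tuple(shape), spacing=tuple(spacing), origin=tuple(aff[:3, 3]))


def write_volume(image: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(image.data.astype(np.float64), _affine(image.grid)), path)
    return path


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), grid)


def write_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Labels as an unsigned-integer NIfTI plus a ``<stem>.labels.json``
    sidecar carrying the dictionary."""
    path = Path(path)
    data = labels.labels
    if data.min() < 0:
        raise ValueError("label ids must be non-negative for NIfTI storage")
    nib.save(nib.Nifti1Image(data.astype(np.uint16), _affine(labels.grid)), path)
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps({str(k): v for k, v in labels.dictionary.items()}, indent=1, sort_keys=True)
    )
    return path


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".labels.json")


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"label volume {path} does not hold an integer dtype")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing label dictionary sidecar: {sidecar}")
    dictionary = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return LabelVolume(data.astype(np.int16), grid, dictionary)


def write_field(displacement_mm: np.ndarray, grid: GridSpec, path: str | Path) -> Path:
    """Displacement field as 4D NIfTI, last axis = (x, y, z) component, mm."""
    u = np.asarray(displacement_mm, dtype=np.float64)
    if u.shape != grid.shape + (3,):
        raise ValueError(f"field shape {u.shape} != {grid.shape + (3,)}")
    nib.save(nib.Nifti1Image(u, _affine(grid)), Path(path))
    return Path(path)


def read_field(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    grid = _grid_from_header(img, expect_4d=True)
    u = np.asarray(img.dataobj, dtype=np.float64)
    if u.shape[-1] != 3:
        raise ValueError("field volume must have 3 components on the last axis")
    return u, grid
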