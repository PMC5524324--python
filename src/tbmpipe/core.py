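"""Core grid and volume containers shared by every pipeline stage.

Coordinate convention (fixed package-wide): array axes are (x, y, z) in
index order, world coordinate of voxel (i, j, k) is
``index * spacing + origin`` (mm, voxel-center). Displacement fields are
stored in mm as 4D arrays with the last axis holding the (x, y, z)
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "ImageVolume",
    "LabelVolume",
    "REGION_NAMES",
    "REGION_IDS",
    "DEFAULT_SPACING",
    "DEFAULT_SHAPE",
    "SMALL_SHAPE",
]

DEFAULT_SPACING = (0.175, 0.175, 0.5)
DEFAULT_SHAPE = (96, 96, 60)
SMALL_SHAPE = (64, 64, 48)

#: Canonical label ids. 0 is background; the 18 named regions follow.
REGION_NAMES: dict[int, str] = {
    0: "background",
    1: "skull",
    2: "brain_other",
    3: "ventricles",
    4: "caudate_L",
    5: "caudate_R",
    6: "putamen_L",
    7: "putamen_R",
    8: "SN_L",
    9: "SN_R",
    10: "hippocampus_L",
    11: "hippocampus_R",
    12: "ctx_motor_L",
    13: "ctx_motor_R",
    14: "ctx_parietal_L",
    15: "ctx_parietal_R",
    16: "ctx_temporal_L",
    17: "ctx_temporal_R",
    18: "ctx_visual_ref",
}

REGION_IDS: dict[str, int] = {name: lid for lid, name in REGION_NAMES.items()}


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D sampling grid: voxel counts, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridSpec requires 3 axes")
        if any(n < 8 for n in self.shape):
            raise ValueError(f"all voxel counts must be >= 8, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge-to-edge size per axis in mm (count * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate arrays broadcastable to ``shape``."""
        axes = [
            (np.arange(n) * s + o).astype(np.float64)
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def index_from_world(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Convert world coordinates (…, 3) to fractional voxel indices."""
        xyz_mm = np.asarray(xyz_mm, dtype=np.float64)
        return (xyz_mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def matches(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class ImageVolume:
    """3D scalar image on a :class:`GridSpec`."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.grid)


@dataclass
class LabelVolume:
    """Integer ROI map on a :class:`GridSpec` plus a label dictionary."""

    labels: np.ndarray
    grid: GridSpec
    dictionary: Mapping[int, str] = field(default_factory=lambda: dict(REGION_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.labels = self.labels.astype(np.int16, copy=False)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )
        self.dictionary = {int(k): str(v) for k, v in dict(self.dictionary).items()}
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.dictionary)
        if unknown:
            raise ValueError(f"labels contain ids missing from dictionary: {sorted(unknown)}")

    @property
    def names(self) -> dict[str, int]:
        return {v: k for k, v in self.dictionary.items()}

    def id_of(self, region: str) -> int:
        try:
            return self.names[region]
        except KeyError:
            raise KeyError(f"unknown region name: {region!r}") from None

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of a named region."""
        return self.labels == self.id_of(region)

    def voxel_count(self, region: str) -> int:
        return int(np.count_nonzero(self.mask(region)))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.grid, dict(self.dictionary))


def brain_mask(labels: LabelVolume, erode_voxels: int = 0) -> np.ndarray:
    """Union of all brain-tissue labels (everything except background/skull).

    Optionally eroded to keep boundary artifacts out of voxel-wise stats.
    """
    from scipy import ndimage

    non_brain = {labels.id_of("background"), labels.id_of("skull")}
    mask = ~np.isin(labels.labels, list(non_brain))
    if erode_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode_voxels)
    return mask
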