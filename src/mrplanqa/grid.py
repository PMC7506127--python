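"""Shared voxel-grid geometry and the containers built on it.

All dose grids and structure masks in an analysis live on one
:class:`VoxelGrid`: a regular, axis-aligned lattice with anisotropic
spacing (the head-and-neck convention here is 1 x 1 mm in-plane and
3 mm slices).  Voxel ``(0, 0, 0)`` has its centre at ``origin_mm`` and
indices map to physical coordinates as ``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = ["VoxelGrid", "DoseGrid", "StructureMask", "StructureSet", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two objects that must share a voxel grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each axis ``(nx, ny, nz)``.
    spacing_mm
        Voxel pitch along each axis in millimetres; strictly positive.
    origin_mm
        Physical coordinate of the centre of voxel ``(0, 0, 0)``.
    """

    shape: Tuple[int, int, int]
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be three positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def coordinate_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centres (1-D arrays, mm)."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def meshgrid(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-centre coordinates (three ``shape``-shaped arrays, mm)."""
        return tuple(np.meshgrid(*self.coordinate_arrays(), indexing="ij"))

    def affine(self) -> np.ndarray:
        """4x4 index-to-physical affine (for NIfTI export)."""
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


def _check_same_grid(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.shape != b.shape or a.spacing_mm != b.spacing_mm:
        raise GridMismatchError(f"grids differ: {a} vs {b}")


@dataclass(frozen=True)
class DoseGrid:
    """Per-voxel absorbed dose in Gy on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise GridMismatchError(
                f"dose array shape {values.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(self.grid, values)


@dataclass(frozen=True)
class StructureMask:
    """A named binary region on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask {self.name!r} shape {voxels.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "voxels", voxels)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def issubset(self, other: "StructureMask") -> bool:
        _check_same_grid(self.grid, other.grid)
        return bool(np.all(~self.voxels | other.voxels))


@dataclass
class StructureSet(Mapping):
    """Mapping of structure name -> :class:`StructureMask` on one grid."""

    grid: VoxelGrid
    masks: Dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        _check_same_grid(self.grid, mask.grid)
        if mask.name in self.masks:
            raise ValueError(f"duplicate structure name {mask.name!r}")
        self.masks[mask.name] = mask

    def add_array(self, name: str, voxels: np.ndarray) -> StructureMask:
        mask = StructureMask(name, self.grid, voxels)
        self.add(mask)
        return mask

    def __getitem__(self, name: str) -> StructureMask:
        try:
            return self.masks[name]
        except KeyError:
            raise KeyError(
                f"structure {name!r} not present; available: {sorted(self.masks)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"missing required structures: {missing}")
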