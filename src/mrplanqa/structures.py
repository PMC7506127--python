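"""Derived regions: skin shell, air-cavity interface shells, PRV margins, normal tissue.

All derivations are distance-based with the anisotropic Euclidean metric
(spacing in mm).  Margin expansions and normal tissue use voxel-centre
distances.  Millimetre shells, which are sub-voxel objects on a CT
grid, are thresholded on a partial-volume depth computed on a 2x
refined sub-lattice (:func:`refined_depth`), which tracks the continuum
shell volume of smooth bodies instead of snapping to whole voxel
layers.  On a 1 x 1 x 3 mm grid a 1-mm shell still selects a single
in-plane voxel layer and no purely axial (superior/inferior) layer —
axial sub-lattice neighbours are 1.5 mm away — matching slice-wise
contouring practice.

Conventions
-----------
* Grid edges count as exterior: a mask voxel on the edge of the array is
  a boundary voxel.
* Thresholds at exactly the shell thickness / margin are included
  (closed, ``<=``); normal tissue uses a strict ``>`` ("greater than
  1 cm from the PTV"), so NT and the margin expansion partition the body.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import StructureMask, StructureSet, _check_same_grid

__all__ = [
    "distance_to_complement",
    "distance_from_mask",
    "refined_depth",
    "refined_distance_from_mask",
    "skin_shell",
    "cavity_interface_shell",
    "expand_margin",
    "normal_tissue",
    "derive_standard_regions",
]


def distance_to_complement(mask: StructureMask) -> np.ndarray:
    """Distance (mm) from each inside-mask voxel to the nearest outside voxel.

    Outside voxels (and everything beyond the grid edge, which counts as
    outside) get 0.  Distances are centre-to-centre Euclidean with the
    grid's anisotropic spacing.
    """
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    padded = np.pad(mask.voxels, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.grid.spacing_mm)
    return np.asarray(dist[1:-1, 1:-1, 1:-1], dtype=np.float64)


def distance_from_mask(mask: StructureMask) -> np.ndarray:
    """Distance (mm) from each voxel to the nearest voxel of ``mask`` (0 inside)."""
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing_mm)
    return np.asarray(dist, dtype=np.float64)


def _upsample2(voxels: np.ndarray) -> np.ndarray:
    return voxels.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)


def _meanpool2(field: np.ndarray) -> np.ndarray:
    nx, ny, nz = field.shape
    return (
        field.reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2)
        .mean(axis=(1, 3, 5))
    )


def refined_depth(mask: StructureMask) -> np.ndarray:
    """Partial-volume-aware depth of inside-mask voxels below the mask surface.

    Computed on a 2x refined sub-lattice (half spacing per axis, grid
    edge as exterior) and mean-pooled back, so a voxel whose corner is
    exposed is shallower than one shielded on all faces.  Millimetre
    shells — sub-voxel objects on a CT grid — are thresholded on this
    depth; it tracks the continuum shell volume of smooth bodies more
    closely than the voxel-centre distance staircase does.
    """
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    half = tuple(s / 2 for s in mask.grid.spacing_mm)
    up = np.pad(_upsample2(mask.voxels), 1, constant_values=False)
    dist = ndimage.distance_transform_edt(up, sampling=half)
    return _meanpool2(np.asarray(dist[1:-1, 1:-1, 1:-1], dtype=np.float64))


def refined_distance_from_mask(mask: StructureMask) -> np.ndarray:
    """Partial-volume-aware distance to ``mask``, sub-lattice analogue of
    :func:`distance_from_mask`."""
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    half = tuple(s / 2 for s in mask.grid.spacing_mm)
    dist = ndimage.distance_transform_edt(~_upsample2(mask.voxels), sampling=half)
    return _meanpool2(np.asarray(dist, dtype=np.float64))


def skin_shell(body: StructureMask, thickness_mm: float = 1.0) -> StructureMask:
    """The first ``thickness_mm`` of tissue under the body outline.

    Voxels inside the body whose distance to the body exterior is
    ``<= thickness_mm``.  Always a subset of the body.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness_mm must be positive, got {thickness_mm}")
    depth = refined_depth(body)
    shell = body.voxels & (depth <= thickness_mm)
    return StructureMask("skin", body.grid, shell)


def cavity_interface_shell(
    cavity: StructureMask, body: StructureMask, thickness_mm: float = 1.0
) -> StructureMask:
    """The first ``thickness_mm`` of tissue outside an air cavity.

    Non-cavity voxels inside the body within ``thickness_mm`` of the
    cavity; disjoint from the cavity itself.  Empty cavity -> empty shell.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness_mm must be positive, got {thickness_mm}")
    _check_same_grid(cavity.grid, body.grid)
    name = f"{cavity.name}_interface"
    if cavity.is_empty():
        return StructureMask(name, body.grid, np.zeros(body.grid.shape, dtype=bool))
    if not cavity.issubset(body):
        raise ValueError(f"cavity {cavity.name!r} is not contained in {body.name!r}")
    dist = refined_distance_from_mask(cavity)
    shell = body.voxels & ~cavity.voxels & (dist <= thickness_mm)
    return StructureMask(name, body.grid, shell)


def expand_margin(
    mask: StructureMask, margin_mm: float, clip: StructureMask
) -> StructureMask:
    """All voxels within ``margin_mm`` of ``mask``, clipped to ``clip``.

    ``margin_mm = 0`` reduces to ``mask & clip``.  Used for PRV margins
    (3 mm brain stem, 5 mm spinal cord).
    """
    if margin_mm < 0:
        raise ValueError(f"margin_mm must be >= 0, got {margin_mm}")
    _check_same_grid(mask.grid, clip.grid)
    name = f"{mask.name}_prv" if margin_mm > 0 else mask.name
    if mask.is_empty():
        return StructureMask(name, mask.grid, np.zeros(mask.grid.shape, dtype=bool))
    dist = distance_from_mask(mask)
    expanded = (dist <= margin_mm) & clip.voxels
    return StructureMask(name, mask.grid, expanded)


def normal_tissue(
    body: StructureMask, ptv: StructureMask, margin_mm: float = 10.0
) -> StructureMask:
    """Body voxels strictly farther than ``margin_mm`` from the PTV.

    Complementary (within the body) to ``expand_margin(ptv, margin_mm,
    body)``, so the two partition the body exactly.
    """
    if ptv.is_empty():
        raise ValueError("PTV mask is empty")
    if not ptv.issubset(body):
        raise ValueError("PTV is not contained in the body")
    dist = distance_from_mask(ptv)
    nt = body.voxels & (dist > margin_mm)
    return StructureMask("normal_tissue", body.grid, nt)


def derive_standard_regions(
    structs: StructureSet,
    shell_thickness_mm: float = 1.0,
    prv_margins_mm: dict | None = None,
    nt_margin_mm: float = 10.0,
    cavity_names: tuple = ("larynx_trachea", "pharynx"),
) -> StructureSet:
    """Add the bespoke evaluation regions to a primary structure set, in place.

    Adds ``skin`` (1 mm under the body outline), one ``<cavity>_interface``
    shell per air cavity (1 mm outside the cavity), PRVs for the brain
    stem (+3 mm) and spinal cord (+5 mm), and ``normal_tissue`` (body
    more than ``nt_margin_mm`` from the PTV).  Structures already present
    are left untouched.
    """
    if prv_margins_mm is None:
        prv_margins_mm = {"brain_stem": 3.0, "spinal_cord": 5.0}
    structs.require("body", "ptv")
    body = structs["body"]

    if "skin" not in structs:
        structs.add(skin_shell(body, shell_thickness_mm))
    for cavity_name in cavity_names:
        if cavity_name in structs:
            shell = cavity_interface_shell(structs[cavity_name], body, shell_thickness_mm)
            if shell.name not in structs:
                structs.add(shell)
    for organ, margin in prv_margins_mm.items():
        if organ in structs:
            prv = expand_margin(structs[organ], margin, body)
            if prv.name not in structs:
                structs.add(prv)
    if "normal_tissue" not in structs:
        structs.add(normal_tissue(body, structs["ptv"], nt_margin_mm))
    return structs
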