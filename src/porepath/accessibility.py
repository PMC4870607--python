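"""Sphere accessibility of the pore space, in 3D or from chosen faces.

A virtual sphere of diameter ``d`` "fits" with its centre on a pore voxel
iff no wall voxel centre lies strictly within ``d/2`` (centre-to-centre
Euclidean distance in micrometres).  The accessible centre space is the
set of fitting positions connected to an open face through fitting
positions; the accessible pore space is that set swept by the sphere.

Open faces are padded with free space so the sphere can approach from
outside and touch surface pores; sealed faces are padded with wall,
emulating enclosure by impenetrable voxels.  All distance comparisons use
exact integer squared distances (via the distance-transform feature
transform), so results are free of floating-point tie ambiguity and match
a brute-force ball test exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import PORE, WALL, FaceSet, VoxelGrid, VolumeError, _structure

__all__ = [
    "AccessibilityResult",
    "InterconnectivityCurve",
    "flood_fill_fraction",
    "center_space",
    "accessible_region",
    "interconnectivity_percent",
    "interconnectivity_curve",
    "pad_for_faces",
    "radius_voxels",
    "squared_radius_voxels",
    "pad_width",
]


# ---------------------------------------------------------------------------
# Shared geometry helpers (also used by the brute-force oracle)
# ---------------------------------------------------------------------------


def radius_voxels(diameter_um: float, spacing_um: float) -> float:
    return diameter_um / (2.0 * spacing_um)


def squared_radius_voxels(diameter_um: float, spacing_um: float) -> float:
    r = radius_voxels(diameter_um, spacing_um)
    return r * r


def pad_width(diameter_um: float, spacing_um: float) -> int:
    """Padding thickness: ceil(d/2) + 1 voxels, so the outermost open slab
    is always sphere-feasible."""
    return int(math.ceil(radius_voxels(diameter_um, spacing_um))) + 1


def pad_for_faces(data: np.ndarray, faces: FaceSet, pad: int) -> np.ndarray:
    """Pad a PORE/WALL array by ``pad`` voxels on every side.

    A padded voxel is free space (PORE) iff every axis along which it lies
    out of bounds has its corresponding side open; otherwise it is WALL.
    With all six faces open the entire surround is free; with one face
    open only that face's outward prism is free.
    """
    if pad < 1:
        raise VolumeError(f"pad must be >= 1, got {pad}")
    shape = data.shape
    free = np.ones([s + 2 * pad for s in shape], dtype=bool)
    for ax in range(3):
        idx = np.arange(shape[ax] + 2 * pad) - pad
        ok = (idx >= 0) & (idx < shape[ax])
        if faces.is_open(ax, 0):
            ok |= idx < 0
        if faces.is_open(ax, 1):
            ok |= idx >= shape[ax]
        sl = [None, None, None]
        sl[ax] = slice(None)
        free &= ok[tuple(sl)]
    out = np.where(free, PORE, WALL).astype(np.uint8)
    core = tuple(slice(pad, pad + s) for s in shape)
    out[core] = data
    return out


def _squared_distance_to(mask: np.ndarray) -> np.ndarray:
    """Exact integer squared voxel distance from every voxel to the nearest
    True voxel of ``mask``; +inf everywhere if ``mask`` is empty."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    ind = ndimage.distance_transform_edt(
        ~mask, return_distances=False, return_indices=True
    )
    d2 = np.zeros(mask.shape, dtype=np.int64)
    for ax, coords in enumerate(np.indices(mask.shape, dtype=np.int64)):
        d2 += (coords - ind[ax]) ** 2
    return d2


def _entry_seed(padded_shape: tuple[int, ...], faces: FaceSet) -> np.ndarray:
    """Outermost slab of every open face: where the sphere starts outside."""
    seed = np.zeros(padded_shape, dtype=bool)
    for face in faces.sorted():
        ax = "zyx".index(face[0])
        sl: list[slice | int] = [slice(None)] * 3
        sl[ax] = 0 if face[1] == "-" else padded_shape[ax] - 1
        seed[tuple(sl)] = True
    return seed


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessibilityResult:
    """Accessible centre space and swept pore space for one diameter/face set."""

    diameter_um: float
    faces: FaceSet
    center_mask: np.ndarray  # where the sphere centre can sit, connected to an open face
    access_mask: np.ndarray  # pore voxels swept by the sphere from those positions
    accessible_volume_um3: float
    spacing_um: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.center_mask.shape


@dataclass(frozen=True)
class InterconnectivityCurve:
    """Accessible-pore-volume percentage versus virtual object diameter."""

    faces: FaceSet
    points: tuple[tuple[float, float], ...]  # (diameter_um, percent)
    grid_shape: tuple[int, int, int]
    spacing_um: float
    accounting: str = "swept"

    @property
    def diameters_um(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def percents(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["diameter_um", "interconnectivity_percent", "faces"])
            for d, p in self.points:
                w.writerow([repr(float(d)), repr(float(p)), str(self.faces)])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def flood_fill_fraction(grid: VoxelGrid, connectivity: int = 26) -> float:
    """Size of the largest connected pore component as % of all pore voxels."""
    pore = grid.pore_mask()
    total = int(pore.sum())
    if total == 0:
        raise VolumeError("volume has no pore space")
    labels, n = ndimage.label(pore, structure=_structure(connectivity))
    if n <= 1:
        return 100.0
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return 100.0 * counts.max() / total


def center_space(grid: VoxelGrid, diameter_um: float) -> np.ndarray:
    """Pore voxels where a sphere of the given diameter fits, irrespective
    of connectivity to any face.

    For ``diameter_um`` up to twice the spacing this is the full pore mask
    (a pore voxel's nearest wall centre is at least one spacing away).
    """
    if diameter_um < 0:
        raise VolumeError(f"diameter must be >= 0, got {diameter_um}")
    d2 = _squared_distance_to(grid.wall_mask())
    return grid.pore_mask() & (d2 >= squared_radius_voxels(diameter_um, grid.spacing_um))


def _empty_result(grid: VoxelGrid, diameter_um: float, faces: FaceSet) -> AccessibilityResult:
    empty = np.zeros(grid.shape, dtype=bool)
    return AccessibilityResult(
        diameter_um=float(diameter_um),
        faces=faces,
        center_mask=empty,
        access_mask=empty.copy(),
        accessible_volume_um3=0.0,
        spacing_um=grid.spacing_um,
    )


def accessible_region(
    grid: VoxelGrid,
    diameter_um: float,
    faces: FaceSet,
    connectivity: int = 6,
) -> AccessibilityResult:
    """Centre space and swept pore space accessible from the open faces.

    Centre connectivity defaults to 6 (a sphere sliding between two
    diagonally adjacent positions may clip walls under 26-connectivity);
    pass ``connectivity=26`` for the permissive variant.
    """
    if diameter_um < 0:
        raise VolumeError(f"diameter must be >= 0, got {diameter_um}")
    if diameter_um > max(grid.shape) * grid.spacing_um:
        warnings.warn(
            f"diameter {diameter_um} um exceeds the volume extent; result is empty",
            stacklevel=2,
        )
        return _empty_result(grid, diameter_um, faces)

    spacing = grid.spacing_um
    r2 = squared_radius_voxels(diameter_um, spacing)
    pad = pad_width(diameter_um, spacing)
    padded = pad_for_faces(grid.data, faces, pad)
    pore = padded == PORE

    fit = pore & (_squared_distance_to(padded == WALL) >= r2)

    labels, n = ndimage.label(fit, structure=_structure(connectivity))
    seed_labels = np.unique(labels[_entry_seed(padded.shape, faces) & fit])
    seed_labels = seed_labels[seed_labels > 0]
    center = np.isin(labels, seed_labels) if seed_labels.size else np.zeros_like(fit)

    if not center.any():
        return _empty_result(grid, diameter_um, faces)

    # Swept pore space: pore voxels strictly within d/2 of a centre position,
    # plus the centre positions themselves.
    d2c = _squared_distance_to(center)
    access = pore & ((d2c < r2) | center)

    core = tuple(slice(pad, pad + s) for s in grid.shape)
    center_c = center[core]
    access_c = access[core]
    return AccessibilityResult(
        diameter_um=float(diameter_um),
        faces=faces,
        center_mask=center_c,
        access_mask=access_c,
        accessible_volume_um3=float(access_c.sum()) * grid.voxel_volume_um3,
        spacing_um=spacing,
    )


def interconnectivity_percent(
    grid: VoxelGrid, result: AccessibilityResult, accounting: str = "swept"
) -> float:
    """Accessible pore volume as a percentage of total pore volume.

    Equivalent to (V - V_s) / (V - V_m) x 100 with V the ROI volume, V_s
    the inaccessible volume after the sweep, and V_m the solid volume.

    ``accounting="swept"`` counts the pore voxels swept by the sphere (the
    physically accessible volume); it can rise slightly with diameter
    because the sweep radius grows while the centre space shrinks.
    ``accounting="center"`` counts centre positions only and is exactly
    non-increasing in diameter.
    """
    if result.shape != grid.shape:
        raise VolumeError(
            f"result shape {result.shape} does not match grid shape {grid.shape}"
        )
    if accounting not in ("swept", "center"):
        raise VolumeError(f"accounting must be 'swept' or 'center', got {accounting!r}")
    n_pore = grid.n_pore
    if n_pore == 0:
        raise VolumeError("volume has no pore space")
    mask = result.access_mask if accounting == "swept" else result.center_mask
    return 100.0 * float(mask.sum()) / n_pore


def interconnectivity_curve(
    grid: VoxelGrid,
    diameters_um,
    faces: FaceSet,
    connectivity: int = 6,
    accounting: str = "swept",
) -> InterconnectivityCurve:
    """One accessibility evaluation per diameter.

    Exactly non-increasing under ``accounting="center"``; the default
    swept-volume accounting tracks the physically accessible volume and may
    wobble upward by a sweep-radius worth of voxels at small diameters.
    """
    diameters = [float(d) for d in diameters_um]
    if len(diameters) < 2:
        raise VolumeError("need at least 2 diameters for a curve")
    if any(b <= a for a, b in zip(diameters, diameters[1:])):
        raise VolumeError(f"diameters must be strictly increasing, got {diameters}")
    pts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # oversized diameters yield empty results
        for d in diameters:
            res = accessible_region(grid, d, faces, connectivity=connectivity)
            pts.append((d, interconnectivity_percent(grid, res, accounting=accounting)))
    return InterconnectivityCurve(
        faces=faces,
        points=tuple(pts),
        grid_shape=grid.shape,
        spacing_um=grid.spacing_um,
        accounting=accounting,
    )
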