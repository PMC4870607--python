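"""Binary 3D volume types, TIFF/raw I/O, and minimal binary preprocessing.

Conventions
-----------
* Axis order is ``(z, y, x)`` with ``z`` the solidification / primary
  invasion axis.
* In memory a voxel is ``PORE`` (0) or ``WALL`` (1); on disk the solid
  phase is bright (``WALL`` = 255, ``PORE`` = 0).
* Voxel spacing is a single isotropic edge length in micrometres.
  Anisotropic spacing metadata is rejected at read time rather than
  silently mishandled downstream by the distance transform.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "PORE",
    "WALL",
    "FACES",
    "VoxelGrid",
    "FaceSet",
    "read_volume",
    "write_volume",
    "despeckle_keep_largest",
    "median_filter_small",
    "voxels_to_um",
    "um_to_voxels",
]

PORE: int = 0
WALL: int = 1

_WALL_ON_DISK = 255

#: Face labels in canonical order: low/high side of each axis, z first.
FACES: tuple[str, ...] = ("z-", "z+", "y-", "y+", "x-", "x+")

_AXIS_OF = {"z": 0, "y": 1, "x": 2}


class VolumeError(ValueError):
    """Raised for invalid volumes, spacing metadata, or phase arguments."""


def _face_axis_side(face: str) -> tuple[int, int]:
    """Map a face label like ``'z-'`` to ``(axis_index, side)``; side 0=low, 1=high."""
    if len(face) != 2 or face[0] not in _AXIS_OF or face[1] not in "-+":
        raise VolumeError(f"unknown face label {face!r}; expected one of {FACES}")
    return _AXIS_OF[face[0]], 0 if face[1] == "-" else 1


@dataclass(frozen=True)
class FaceSet:
    """The set of open (accessible) faces of a volume; the rest are sealed.

    All six faces open corresponds to fully 3D accessibility analysis;
    exactly one open face gives the directional variant.
    """

    open_faces: frozenset[str]

    def __post_init__(self) -> None:
        faces = frozenset(self.open_faces)
        for f in faces:
            _face_axis_side(f)  # validates
        if not faces:
            raise VolumeError("FaceSet must contain at least one open face")
        object.__setattr__(self, "open_faces", faces)

    @classmethod
    def all_open(cls) -> "FaceSet":
        return cls(frozenset(FACES))

    @classmethod
    def single(cls, face: str) -> "FaceSet":
        return cls(frozenset({face}))

    @classmethod
    def from_spec(cls, spec: str) -> "FaceSet":
        """Parse ``'3d'`` or a single face label like ``'z-'``."""
        if spec.lower() == "3d":
            return cls.all_open()
        return cls.single(spec)

    @property
    def is_all_open(self) -> bool:
        return self.open_faces == frozenset(FACES)

    @property
    def single_face(self) -> str | None:
        """The lone open face label, or ``None`` if more than one is open."""
        if len(self.open_faces) == 1:
            return next(iter(self.open_faces))
        return None

    def is_open(self, axis: int, side: int) -> bool:
        label = "zyx"[axis] + ("-" if side == 0 else "+")
        return label in self.open_faces

    def sorted(self) -> tuple[str, ...]:
        return tuple(f for f in FACES if f in self.open_faces)

    def __str__(self) -> str:  # stable, for reports/CSV
        return "3d" if self.is_all_open else "+".join(self.sorted())


@dataclass(frozen=True)
class VoxelGrid:
    """A binary 3D pore/wall image with isotropic physical spacing.

    ``data`` holds ``PORE``/``WALL`` labels as ``uint8`` in ``(z, y, x)``
    axis order.  Total ROI volume is ``data.size * spacing_um**3``; the
    solid-material volume is the wall count times the voxel volume.
    """

    data: np.ndarray
    spacing_um: float
    axes: tuple[str, str, str] = ("z", "y", "x")
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeError(f"volume must be 3D, got ndim={arr.ndim}")
        if min(arr.shape) < 3:
            raise VolumeError(f"all dimensions must be >= 3 voxels, got {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (PORE, WALL)).all():
            raise VolumeError(
                f"volume must be binary PORE/WALL (0/1); found values {vals[:10]}"
            )
        if not (np.isscalar(self.spacing_um) or np.ndim(self.spacing_um) == 0):
            raise VolumeError(f"spacing must be an isotropic scalar, got {self.spacing_um!r}")
        if not float(self.spacing_um) > 0:
            raise VolumeError(f"spacing_um must be > 0, got {self.spacing_um}")
        object.__setattr__(self, "data", arr.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing_um", float(self.spacing_um))
        object.__setattr__(self, "axes", tuple(self.axes))

    # -- masks and bookkeeping -------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def pore_mask(self) -> np.ndarray:
        return self.data == PORE

    def wall_mask(self) -> np.ndarray:
        return self.data == WALL

    @property
    def n_pore(self) -> int:
        return int((self.data == PORE).sum())

    @property
    def n_wall(self) -> int:
        return int((self.data == WALL).sum())

    @property
    def voxel_volume_um3(self) -> float:
        return self.spacing_um**3

    @property
    def total_volume_um3(self) -> float:
        return self.data.size * self.voxel_volume_um3

    @property
    def pore_volume_um3(self) -> float:
        return self.n_pore * self.voxel_volume_um3

    @property
    def wall_volume_um3(self) -> float:
        return self.n_wall * self.voxel_volume_um3

    def with_data(self, data: np.ndarray, note: str = "") -> "VoxelGrid":
        prov = self.provenance if not note else f"{self.provenance};{note}".lstrip(";")
        return replace(self, data=data, provenance=prov)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SPACING_RE = re.compile(r"spacing_um\s*=\s*([0-9.eE+-]+)")


def read_volume(
    path: str | Path,
    spacing_um: float | None = None,
    threshold: float | None = None,
) -> VoxelGrid:
    """Read a multipage TIFF stack (or ``.npy`` + JSON sidecar) as a VoxelGrid.

    Grayscale data require ``threshold``: values >= threshold become WALL
    (the imaged solid is bright), values below become PORE.  Already-binary
    data map nonzero -> WALL.  ``spacing_um`` overrides any stored metadata;
    if omitted, the metadata value is required.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"cannot read volume: {path} does not exist")

    meta_spacing: float | None = None
    if path.suffix.lower() in {".npy", ".raw"}:
        arr, meta_spacing = _read_raw(path)
    else:
        try:
            with tifffile.TiffFile(path) as tf:
                arr = tf.asarray()
                desc = tf.pages[0].description or ""
        except Exception as exc:  # corrupt / non-TIFF
            raise VolumeError(f"unreadable volume file {path}: {exc}") from exc
        m = _SPACING_RE.search(desc)
        if m:
            meta_spacing = float(m.group(1))

    if arr.ndim == 2:  # single-page stack is still not a volume
        raise VolumeError(f"{path} holds 2D data; a 3D stack is required")
    if arr.ndim != 3:
        raise VolumeError(f"{path} holds {arr.ndim}D data; a 3D stack is required")

    if spacing_um is None:
        spacing_um = meta_spacing
    if spacing_um is None:
        raise VolumeError(f"{path} carries no spacing metadata; pass spacing_um explicitly")

    uniq = np.unique(arr)
    if np.isin(uniq, (0, 1)).all() or np.isin(uniq, (0, _WALL_ON_DISK)).all():
        data = (arr != 0).astype(np.uint8)
    else:
        if threshold is None:
            raise VolumeError(
                f"{path} is grayscale (values {uniq[:5]}...); a threshold is required"
            )
        data = (arr >= threshold).astype(np.uint8)

    return VoxelGrid(data=data, spacing_um=float(spacing_um), provenance=f"read:{path.name}")


def _read_raw(path: Path) -> tuple[np.ndarray, float | None]:
    """Raw array container with a JSON sidecar {shape, spacing_um, axis_order}."""
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise VolumeError(f"raw container {path} has no JSON sidecar")
    meta = json.loads(sidecar.read_text())
    spacing = meta.get("spacing_um")
    if spacing is not None and np.ndim(spacing) != 0:
        vals = np.asarray(spacing, dtype=float)
        if np.ptp(vals) > 0:
            raise VolumeError(f"anisotropic spacing {spacing} rejected; isotropic voxels only")
        spacing = float(vals[0])
    if meta.get("axis_order", "zyx") != "zyx":
        raise VolumeError(f"unsupported axis_order {meta.get('axis_order')!r}; expected 'zyx'")
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        arr = np.fromfile(path, dtype=np.uint8).reshape(meta["shape"])
    return arr, (float(spacing) if spacing is not None else None)


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a multipage 8-bit TIFF (WALL=255, PORE=0) with spacing metadata.

    ``read_volume(write_volume(g)) == g`` on data and spacing.
    """
    path = Path(path)
    disk = np.where(grid.data == WALL, _WALL_ON_DISK, 0).astype(np.uint8)
    try:
        tifffile.imwrite(
            path,
            disk,
            photometric="minisblack",
            description=f"spacing_um={grid.spacing_um!r}",
        )
    except OSError as exc:
        raise VolumeError(f"cannot write volume to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Minimal binary preprocessing
# ---------------------------------------------------------------------------


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise VolumeError(f"connectivity must be 6, 18 or 26; got {connectivity}")


def despeckle_keep_largest(
    grid: VoxelGrid, phase: int = PORE, connectivity: int = 26
) -> VoxelGrid:
    """Keep only the largest connected component of ``phase``.

    All other voxels of that phase are reassigned to the opposite phase.
    On a size tie the component containing the lowest-index voxel in scan
    order wins (labels are assigned in scan order and ``argmax`` keeps the
    first maximum).  Idempotent; never increases the phase's voxel count.
    """
    if phase not in (PORE, WALL):
        raise VolumeError(f"phase must be PORE or WALL, got {phase}")
    mask = grid.data == phase
    if not mask.any():
        raise VolumeError("no voxels of the chosen phase to despeckle")
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n <= 1:
        return grid
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    keep = int(np.argmax(counts))
    other = WALL if phase == PORE else PORE
    out = grid.data.copy()
    out[mask & (labels != keep)] = other
    return grid.with_data(out, note=f"despeckle(phase={phase})")


def median_filter_small(grid: VoxelGrid) -> VoxelGrid:
    """2x2x2 majority filter on the binary volume.

    Each voxel is replaced by the majority label of the 2x2x2 window
    anchored at it (the voxel plus its +1 neighbours; edge-replicated at
    the high boundary).  A 4-4 tie becomes WALL, so filtering can only
    close, never open, marginal passages.
    """
    w = (grid.data == WALL).astype(np.uint8)
    wp = np.pad(w, ((0, 1), (0, 1), (0, 1)), mode="edge")
    counts = np.zeros(grid.shape, dtype=np.uint8)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                counts += wp[
                    dz : dz + grid.shape[0],
                    dy : dy + grid.shape[1],
                    dx : dx + grid.shape[2],
                ]
    out = np.where(counts >= 4, WALL, PORE).astype(np.uint8)
    return grid.with_data(out, note="median2")


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------


def voxels_to_um(n_voxels: float, spacing_um: float) -> float:
    """Convert a voxel count/length to micrometres: ``n * spacing``."""
    if not n_voxels > 0:
        raise VolumeError(f"n_voxels must be > 0, got {n_voxels}")
    if not spacing_um > 0:
        raise VolumeError(f"spacing_um must be > 0, got {spacing_um}")
    return float(n_voxels) * float(spacing_um)


def um_to_voxels(length_um: float, spacing_um: float) -> float:
    """Inverse of :func:`voxels_to_um`; does not round."""
    if not length_um > 0:
        raise VolumeError(f"length_um must be > 0, got {length_um}")
    if not spacing_um > 0:
        raise VolumeError(f"spacing_um must be > 0, got {spacing_um}")
    return float(length_um) / float(spacing_um)
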