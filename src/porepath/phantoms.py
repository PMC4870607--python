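"""Synthetic porous structures with constructed ground truth, plus the
brute-force sphere-accessibility oracle used to validate the fast path.

Every generator is deterministic given its arguments (including the seed).
Nominal ground-truth passage widths are stated in voxels; discretization
can shift the realized threshold by about one voxel, so tests re-measure
each phantom with the direct bisection oracle rather than trusting the
nominal parameter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .accessibility import (
    _entry_seed,
    pad_for_faces,
    pad_width,
    squared_radius_voxels,
)
from .volume import PORE, WALL, FaceSet, VoxelGrid, VolumeError, despeckle_keep_largest

__all__ = [
    "PhantomSpec",
    "make_throat_lattice",
    "make_disordered_throat_lattice",
    "make_lamellar",
    "make_equiaxed_foam",
    "make_random_blob",
    "brute_force_accessible",
]

_ORACLE_MAX_VOXELS = 70**3


# ---------------------------------------------------------------------------
# Spec container (CLI sidecar / provenance)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic structure.

    ``ground_truth`` maps a face label to the nominal percolation diameter
    (in μm) defined by construction, where one exists.
    """

    kind: str
    shape: tuple[int, int, int]
    spacing_um: float = 1.0
    seed: int = 0
    params: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    _BUILDERS = {
        "throat_lattice": "make_throat_lattice",
        "disordered_throat_lattice": "make_disordered_throat_lattice",
        "lamellar": "make_lamellar",
        "equiaxed_foam": "make_equiaxed_foam",
        "random_blob": "make_random_blob",
    }

    def build(self) -> VoxelGrid:
        if self.kind not in self._BUILDERS:
            raise VolumeError(f"unknown phantom kind {self.kind!r}")
        fn = globals()[self._BUILDERS[self.kind]]
        kwargs = dict(self.params)
        if self.kind in ("disordered_throat_lattice", "lamellar", "equiaxed_foam", "random_blob"):
            kwargs["seed"] = self.seed
        return fn(self.shape, spacing_um=self.spacing_um, **kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        meta = json.loads(open(path).read())
        meta["shape"] = tuple(meta["shape"])
        return cls(**meta)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _check_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 3:
        raise VolumeError(f"shape must be 3D with every dimension >= 3, got {shape}")
    return shape


def make_throat_lattice(
    shape,
    spacing_um: float = 1.0,
    pitch: int = 16,
    pore_diameter: int = 10,
    throat_width: int = 6,
) -> VoxelGrid:
    """Cubic lattice of spherical pores joined along each axis by square
    prismatic throats of the given width (voxels).

    The throats run the full length of the volume through every pore row,
    so by construction the percolation diameter along each axis equals the
    throat width (± discretization).
    """
    shape = _check_shape(shape)
    if not (pore_diameter > throat_width >= 2):
        raise VolumeError(
            f"need pore_diameter > throat_width >= 2, got {pore_diameter}, {throat_width}"
        )
    if not pitch > pore_diameter:
        raise VolumeError(f"need pitch > pore_diameter, got {pitch}, {pore_diameter}")

    c0 = pitch // 2
    rel = []
    for ax in range(3):
        idx = np.arange(shape[ax])
        r = ((idx - c0 + pitch // 2) % pitch) - pitch // 2
        sl = [None, None, None]
        sl[ax] = slice(None)
        rel.append(r[tuple(sl)])

    pore_r2 = (pore_diameter / 2.0) ** 2
    pore = (rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2) <= pore_r2

    w_lo, w_hi = (throat_width - 1) // 2, throat_width // 2
    in_throat = [(rel[ax] >= -w_lo) & (rel[ax] <= w_hi) for ax in range(3)]
    for ax in range(3):
        b, c = [a for a in range(3) if a != ax]
        pore = pore | (in_throat[b] & in_throat[c])

    data = np.where(pore, PORE, WALL).astype(np.uint8)
    return VoxelGrid(
        data, spacing_um, provenance=f"throat_lattice(pitch={pitch},t={throat_width})"
    )


def make_disordered_throat_lattice(
    shape,
    spacing_um: float = 1.0,
    pitch: int = 16,
    pore_diameter: int = 10,
    width_range: tuple[int, int] = (4, 12),
    seed: int = 0,
) -> VoxelGrid:
    """Throat lattice with per-throat widths drawn uniformly from
    ``width_range`` (inclusive, voxels).

    Transport along an axis is limited by the narrowest throat on the best
    path, so the structure has a genuine percolation transition somewhere
    inside ``width_range``; the realized threshold must be measured with
    the direct bisection oracle, never assumed.
    """
    shape = _check_shape(shape)
    t_min, t_max = int(width_range[0]), int(width_range[1])
    if t_min < 2:
        raise VolumeError(f"minimum throat width must be >= 2 voxels, got {t_min}")
    if not (pore_diameter > t_max):
        raise VolumeError(f"need pore_diameter > max width, got {pore_diameter}, {t_max}")
    if not pitch > pore_diameter:
        raise VolumeError(f"need pitch > pore_diameter, got {pitch}, {pore_diameter}")

    rng = np.random.default_rng(seed)
    c0 = pitch // 2
    centers = [np.arange(c0, shape[ax], pitch) for ax in range(3)]
    data = np.full(shape, WALL, dtype=np.uint8)

    # Spherical pores.
    R = pore_diameter / 2.0
    m = int(math.ceil(R))
    off = np.arange(-m, m + 1)
    ball = (off[:, None, None] ** 2 + off[None, :, None] ** 2 + off[None, None, :] ** 2) <= R * R
    for cz in centers[0]:
        for cy in centers[1]:
            for cx in centers[2]:
                _stamp(data, ball, (cz - m, cy - m, cx - m))

    # Per-segment throats, including the entry/exit stubs to the faces.
    for ax in range(3):
        b, c = [a for a in range(3) if a != ax]
        bounds = [0, *[int(v) for v in centers[ax]], shape[ax]]
        for cb in centers[b]:
            for cc in centers[c]:
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    w = int(rng.integers(t_min, t_max + 1))
                    w_lo, w_hi = (w - 1) // 2, w // 2
                    sl: list[slice] = [slice(None)] * 3
                    sl[ax] = slice(lo, hi)
                    sl[b] = slice(max(cb - w_lo, 0), cb + w_hi + 1)
                    sl[c] = slice(max(cc - w_lo, 0), cc + w_hi + 1)
                    data[tuple(sl)] = PORE

    return VoxelGrid(
        data,
        spacing_um,
        provenance=f"disordered_throat_lattice(pitch={pitch},w={t_min}-{t_max},seed={seed})",
    )


def _stamp(data: np.ndarray, mask: np.ndarray, corner) -> None:
    """OR a small PORE mask into ``data`` at ``corner``, clipping to bounds."""
    src = []
    dst = []
    for ax in range(3):
        lo = corner[ax]
        hi = lo + mask.shape[ax]
        s_lo = max(0, -lo)
        s_hi = mask.shape[ax] - max(0, hi - data.shape[ax])
        if s_lo >= s_hi:
            return
        src.append(slice(s_lo, s_hi))
        dst.append(slice(lo + s_lo, lo + s_hi))
    region = data[tuple(dst)]
    region[mask[tuple(src)]] = PORE


def make_lamellar(
    shape,
    spacing_um: float = 1.0,
    channel_width: int = 12,
    wall_thickness: int = 3,
    hole_diameter: int = 5,
    holes_per_wall: int = 4,
    seed: int = 0,
) -> VoxelGrid:
    """Parallel plates normal to x with open channels running along z/y.

    The channel gap sets the passable diameter for travel along z; the
    circular holes pierced through each plate set it for travel along x.
    With ``holes_per_wall=0`` the x direction never percolates.
    """
    shape = _check_shape(shape)
    if holes_per_wall > 0 and hole_diameter < 2:
        raise VolumeError(f"hole_diameter must be >= 2 voxels, got {hole_diameter}")
    if holes_per_wall > 0 and not channel_width > hole_diameter:
        raise VolumeError(
            f"need channel_width > hole_diameter, got {channel_width}, {hole_diameter}"
        )

    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    period = channel_width + wall_thickness
    x_rel = np.arange(nx) % period
    wall_x = x_rel >= channel_width
    data = np.broadcast_to(
        np.where(wall_x, WALL, PORE).astype(np.uint8)[None, None, :], shape
    ).copy()

    if holes_per_wall > 0:
        h = hole_diameter
        half = 0.5 if h % 2 == 0 else 0.0  # even diameters centre between voxels
        r2 = (h / 2.0) ** 2
        margin = h  # keep holes clear of the z/y boundaries
        zz = np.arange(nz, dtype=float)[:, None]
        yy = np.arange(ny, dtype=float)[None, :]
        wall_starts = range(channel_width, nx, period)
        for x0 in wall_starts:
            x1 = min(x0 + wall_thickness, nx)
            for _ in range(holes_per_wall):
                cz = float(rng.integers(margin, max(nz - margin, margin + 1))) + half
                cy = float(rng.integers(margin, max(ny - margin, margin + 1))) + half
                disk = ((zz - cz) ** 2 + (yy - cy) ** 2) <= r2
                data[:, :, x0:x1][disk] = PORE

    return VoxelGrid(
        data,
        spacing_um,
        provenance=(
            f"lamellar(g={channel_width},wt={wall_thickness},h={hole_diameter},"
            f"n={holes_per_wall},seed={seed})"
        ),
    )


def make_equiaxed_foam(
    shape,
    spacing_um: float = 1.0,
    porosity: float = 0.9,
    correlation_length: float = 6.0,
    seed: int = 0,
) -> VoxelGrid:
    """Statistically isotropic foam: a smoothed Gaussian random field
    thresholded at the porosity quantile, then despeckled in both phases.

    Quantile thresholding hits the target porosity exactly before
    despeckling; the despeckle shifts it by at most a couple of points.
    """
    shape = _check_shape(shape)
    if not (0.5 < porosity < 0.99):
        raise VolumeError(f"porosity must lie in (0.5, 0.99), got {porosity}")
    if correlation_length < 3:
        raise VolumeError(f"correlation_length must be >= 3 voxels, got {correlation_length}")

    rng = np.random.default_rng(seed)
    fld = rng.standard_normal(shape)
    fld = ndimage.gaussian_filter(fld, sigma=correlation_length / 2.0, mode="wrap")
    cut = np.quantile(fld, porosity)
    data = np.where(fld <= cut, PORE, WALL).astype(np.uint8)

    grid = VoxelGrid(
        data,
        spacing_um,
        provenance=f"equiaxed_foam(phi={porosity},l={correlation_length},seed={seed})",
    )
    grid = despeckle_keep_largest(grid, phase=PORE)
    # Wall blobs of a thresholded random field are legitimately disconnected,
    # so keep-largest would gut the solid phase; drop only true speckles.
    out = grid.data.copy()
    labels, n = ndimage.label(out == WALL, structure=np.ones((3, 3, 3), bool))
    if n:
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < 27)[0]
        small = small[small > 0]
        if small.size:
            out[np.isin(labels, small)] = PORE
    return grid.with_data(out, note="despeckle(wall,small)")


def make_random_blob(
    shape,
    spacing_um: float = 1.0,
    porosity: float = 0.6,
    smooth_sigma: float = 1.2,
    seed: int = 0,
) -> VoxelGrid:
    """Small unstructured random binary phantom for oracle/property tests."""
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smooth_sigma)
    cut = np.quantile(fld, porosity)
    data = np.where(fld <= cut, PORE, WALL).astype(np.uint8)
    return VoxelGrid(data, spacing_um, provenance=f"random_blob(seed={seed})")


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _ball_offsets(r2: float, m: int) -> np.ndarray:
    """Footprint of integer offsets with |o|^2 strictly below r2."""
    off = np.arange(-m, m + 1)
    d2 = off[:, None, None] ** 2 + off[None, :, None] ** 2 + off[None, None, :] ** 2
    return d2 < r2


def brute_force_accessible(
    grid: VoxelGrid,
    diameter_um: float,
    faces: FaceSet,
    connectivity: int = 6,
    return_center: bool = False,
):
    """Reference implementation of sphere accessibility by explicit ball
    tests and breadth-first search; O(N x ball volume), guarded to small
    grids.

    Matches :func:`porepath.accessibility.accessible_region` by definition:
    a position is feasible iff its explicit discrete ball contains no wall
    voxel, feasible positions are connected by BFS from the open-face entry
    slabs, and the swept mask is the union of balls over reached positions.
    """
    if grid.data.size > _ORACLE_MAX_VOXELS:
        raise VolumeError(
            f"oracle limited to {_ORACLE_MAX_VOXELS} voxels; got {grid.data.size}"
        )
    if diameter_um < 0:
        raise VolumeError(f"diameter must be >= 0, got {diameter_um}")

    spacing = grid.spacing_um
    r2 = squared_radius_voxels(diameter_um, spacing)
    pad = pad_width(diameter_um, spacing)
    padded = pad_for_faces(grid.data, faces, pad)
    pore = padded == PORE
    wall = padded == WALL

    m = int(math.ceil(diameter_um / (2.0 * spacing)))
    ball = _ball_offsets(r2, m) if m > 0 else np.zeros((1, 1, 1), dtype=bool)

    if ball.any():
        blocked = ndimage.binary_dilation(wall, structure=ball)
        feasible = pore & ~blocked
    else:  # d = 0: every pore voxel is feasible
        feasible = pore

    seed = _entry_seed(padded.shape, faces) & feasible
    center = _bfs(feasible, seed, connectivity)

    if center.any():
        ball_inc = ball.copy()
        ball_inc[m if m > 0 else 0, m if m > 0 else 0, m if m > 0 else 0] = True
        swept = ndimage.binary_dilation(center, structure=ball_inc) & pore
    else:
        swept = np.zeros_like(pore)

    core = tuple(slice(pad, pad + s) for s in grid.shape)
    if return_center:
        return center[core], swept[core]
    return swept[core]


_NBRS6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_NBRS26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _bfs(feasible: np.ndarray, seed: np.ndarray, connectivity: int) -> np.ndarray:
    if connectivity == 6:
        nbrs = _NBRS6
    elif connectivity == 26:
        nbrs = _NBRS26
    else:
        raise VolumeError(f"oracle connectivity must be 6 or 26, got {connectivity}")
    nz, ny, nx = feasible.shape
    visited = np.zeros_like(feasible)
    q: deque = deque()
    for z, y, x in zip(*np.nonzero(seed)):
        visited[z, y, x] = True
        q.append((int(z), int(y), int(x)))
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in nbrs:
            za, ya, xa = z + dz, y + dy, x + dx
            if 0 <= za < nz and 0 <= ya < ny and 0 <= xa < nx:
                if feasible[za, ya, xa] and not visited[za, ya, xa]:
                    visited[za, ya, xa] = True
                    q.append((za, ya, xa))
    return visited
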