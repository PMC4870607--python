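"""Maximum accessible distance L(d) from one face and the percolation
diameter d_c extrapolated via the scaling law L ∝ (d − d_c)^(−0.88).

L is measured over accessible sphere-centre positions (the object's reach
is where its centre can travel); the swept volume would inflate L by d/2.
A point "percolates" when a centre position reaches the deepest slab a
sphere of that size can occupy — a sphere of radius r cannot centre
itself within r of the sealed far boundary.

Scan points fall into three regimes: Region 1 (percolates; L censored at
the dataset span), Region 2 (0 < L < span; usable for fitting), Region 3
(L below a depth floor of a few sphere radii; surface roughness only).
Only Region 2 points enter the fit: ordinary least squares of d on
L^(−1/exponent), whose intercept is d_c and whose gradient relates to the
smallest representative repeat length of the structure.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .accessibility import (
    _squared_distance_to,
    accessible_region,
    radius_voxels,
)
from .volume import FaceSet, VoxelGrid, VolumeError, _face_axis_side

__all__ = [
    "PercolationPoint",
    "PercolationFit",
    "InsufficientRegion2Error",
    "max_accessible_distance",
    "percolation_scan",
    "fit_percolation_diameter",
    "percolation_threshold_direct",
    "DEFAULT_EXPONENT",
    "DEFAULT_DEPTH_FLOOR_RADII",
]

#: Correlation-length exponent of 3D percolation; treated as given, never fitted.
DEFAULT_EXPONENT = 0.88

#: Region 3 / Region 2 boundary: L below this many sphere radii reflects
#: only surface pores.
DEFAULT_DEPTH_FLOOR_RADII = 3.0


class InsufficientRegion2Error(VolumeError):
    """Fewer than three usable (Region 2) points for the scaling-law fit."""


@dataclass(frozen=True)
class PercolationPoint:
    """One (d, L) measurement for travel from a single face."""

    diameter_um: float
    max_distance_um: float
    percolates: bool
    face: str
    region: int | None = None  # 1, 2 or 3 once classified

    def to_dict(self) -> dict:
        return {
            "d_um": self.diameter_um,
            "L_um": self.max_distance_um,
            "percolates": self.percolates,
            "face": self.face,
            "region": self.region,
        }


@dataclass(frozen=True)
class PercolationFit:
    """OLS fit of d against L^(−1/exponent) over Region 2 points."""

    points: tuple[PercolationPoint, ...]
    d_c_um: float
    gradient: float
    exponent: float
    r_squared: float
    face: str
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "face": self.face,
            "exponent": self.exponent,
            "points": [p.to_dict() for p in self.points],
            "d_c_um": self.d_c_um,
            "gradient": self.gradient,
            "r_squared": self.r_squared,
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _depth_floor_um(diameter_um: float, depth_floor_radii: float) -> float:
    return depth_floor_radii * diameter_um / 2.0


def max_accessible_distance(
    grid: VoxelGrid,
    diameter_um: float,
    face: str,
    connectivity: int = 6,
) -> PercolationPoint:
    """Deepest centre position reachable from ``face``, as a distance in μm.

    L = (1 + max depth index) × spacing over accessible centre voxels; 0 if
    nothing is reachable.  ``percolates`` is true when a centre voxel lies
    in the deepest slab the sphere can occupy, in which case L is reported
    as the full physical span along the travel axis.
    """
    faces = FaceSet.single(face)
    axis, side = _face_axis_side(face)
    n = grid.shape[axis]
    spacing = grid.spacing_um
    span_um = n * spacing

    res = accessible_region(grid, diameter_um, faces, connectivity=connectivity)
    if not res.center_mask.any():
        return PercolationPoint(float(diameter_um), 0.0, False, face)

    depth_idx = np.nonzero(res.center_mask.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    if side == 1:
        depth_idx = n - 1 - depth_idx
    max_depth = int(depth_idx.max())

    # Deepest slab a sphere centre can occupy: the artificial wall behind the
    # far face sits n - k voxels from depth k, so k_last = floor(n - r).
    r_vox = radius_voxels(diameter_um, spacing)
    k_last = min(n - 1, math.floor(n - r_vox + 1e-12))
    percolates = max_depth >= k_last
    L = span_um if percolates else (1 + max_depth) * spacing
    return PercolationPoint(float(diameter_um), float(L), bool(percolates), face)


def classify_region(
    point: PercolationPoint,
    depth_floor_radii: float = DEFAULT_DEPTH_FLOOR_RADII,
) -> PercolationPoint:
    if point.percolates:
        region = 1
    elif point.max_distance_um <= _depth_floor_um(point.diameter_um, depth_floor_radii):
        region = 3
    else:
        region = 2
    return PercolationPoint(
        point.diameter_um, point.max_distance_um, point.percolates, point.face, region
    )


def percolation_scan(
    grid: VoxelGrid,
    face: str,
    diameters_um,
    connectivity: int = 6,
    depth_floor_radii: float = DEFAULT_DEPTH_FLOOR_RADII,
) -> list[PercolationPoint]:
    """One classified (d, L) point per diameter.  L is non-increasing in d."""
    diameters = [float(d) for d in diameters_um]
    if len(diameters) < 3:
        raise VolumeError("need at least 3 diameters for a percolation scan")
    if any(b <= a for a, b in zip(diameters, diameters[1:])):
        raise VolumeError(f"diameters must be strictly increasing, got {diameters}")
    pts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in diameters:
            pts.append(
                classify_region(
                    max_accessible_distance(grid, d, face, connectivity=connectivity),
                    depth_floor_radii,
                )
            )
    return pts


def fit_percolation_diameter(
    points,
    exponent: float = DEFAULT_EXPONENT,
    depth_floor_radii: float = DEFAULT_DEPTH_FLOOR_RADII,
) -> PercolationFit:
    """Extrapolate d_c from Region 2 points by OLS of d on L^(−1/exponent).

    Percolating points are censored at the dataset span and surface-only
    points reflect roughness, so neither enters the regression.  A negative
    intercept is clamped to 0 with a warning flag.
    """
    pts = [
        p if p.region is not None else classify_region(p, depth_floor_radii)
        for p in points
    ]
    if not pts:
        raise VolumeError("no points supplied")
    if all(p.percolates for p in pts):
        raise InsufficientRegion2Error(
            "all points percolate (Region 1); no finite L measurements — "
            "enlarge the volume or scan larger diameters"
        )
    usable = [p for p in pts if p.region == 2]
    if len(usable) < 3:
        raise InsufficientRegion2Error(
            f"only {len(usable)} Region-2 points (need >= 3) — "
            "insufficient Region-2 data; enlarge the volume or refine the diameter scan"
        )
    faces = {p.face for p in usable}
    face = usable[0].face if len(faces) == 1 else "mixed"

    d = np.array([p.diameter_um for p in usable], dtype=float)
    x = np.array([p.max_distance_um for p in usable], dtype=float) ** (-1.0 / exponent)
    slope, intercept = np.polyfit(x, d, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    warns = []
    d_c = float(intercept)
    if d_c < 0:
        warns.append(f"negative intercept {d_c:.4g} clamped to 0")
        d_c = 0.0
    if slope <= 0:
        warns.append(f"non-positive gradient {slope:.4g}: L did not decrease with d")
    return PercolationFit(
        points=tuple(pts),
        d_c_um=d_c,
        gradient=float(slope),
        exponent=float(exponent),
        r_squared=float(r2),
        face=face,
        warnings=tuple(warns),
    )


def percolation_threshold_direct(
    grid: VoxelGrid,
    face: str,
    tol_um: float | None = None,
    connectivity: int = 6,
) -> float:
    """Largest diameter that still percolates, by bisection on the
    ``percolates`` flag.  The independent ground truth the scaling-law
    extrapolation is validated against.
    """
    spacing = grid.spacing_um
    if tol_um is None:
        tol_um = spacing / 2.0
    if tol_um < spacing / 4.0:
        raise VolumeError(f"tol_um must be >= spacing/4 = {spacing / 4.0}, got {tol_um}")

    def percolates(d: float) -> bool:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # oversize diameters are expected mid-search
            return max_accessible_distance(grid, d, face, connectivity=connectivity).percolates

    if not percolates(spacing):
        warnings.warn(
            f"structure never percolates along {face} even at d = one voxel",
            stacklevel=2,
        )
        return 0.0

    wall = grid.wall_mask()
    if wall.any():
        hi = 2.0 * spacing * math.sqrt(float(_squared_distance_to(wall).max())) + spacing
    else:
        hi = 2.0 * max(grid.shape) * spacing + spacing
    while percolates(hi):  # defensive; hi should already be non-percolating
        hi *= 2.0
    lo = spacing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        while hi - lo > tol_um:
            mid = 0.5 * (lo + hi)
            if percolates(mid):
                lo = mid
            else:
                hi = mid
    return float(lo)
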