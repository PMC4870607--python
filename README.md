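# porepath

Transport-pathway parameterization of porous structures from binary 3D
voxel images. Given a pore/wall volume (e.g. a binarized micro-CT stack),
`porepath` computes:

* **Flood fill** — the largest connected pore-space volume as a percentage
  of total pore volume.
* **Sphere accessibility** — the pore space accessible to a virtual sphere
  of any diameter, entering from all surfaces (3D mode) or from a single
  face (directional mode), with % interconnectivity defined as
  `(V − V_s) / (V − V_m) × 100` (accessible pore volume over total pore
  volume).
* **Percolation diameter** — the maximum accessible distance `L(d)` from a
  chosen face as a function of sphere diameter `d`, extrapolated via the
  3D-percolation scaling law `L ∝ (d − d_c)^−0.88`; the intercept of `d`
  against `L^(−1/0.88)` is `d_c`, the largest sphere that can travel
  infinitely far through the structure in that direction.

A sphere of diameter `d` "fits" at a pore voxel iff no wall voxel centre
lies strictly within `d/2` (Euclidean, centre-to-centre). The fast path
thresholds an exact integer squared distance transform and seeds
connectivity from the open faces; a brute-force oracle (explicit ball
tests + breadth-first search) reproduces it **exactly** and is part of the
test contract.

Since no reference micro-CT volumes ship with the package, a `phantoms`
module generates synthetic structures with constructed ground truth:
regular and disordered throat lattices (percolation threshold = throat
width), lamellar plate stacks pierced by holes (anisotropic thresholds by
construction), and statistically isotropic thresholded-Gaussian foams.

## Input format

Multipage 8-bit TIFF, wall = 255 / pore = 0, isotropic voxel spacing in
micrometres recorded as `spacing_um=<float>` in the ImageDescription tag
(or passed explicitly). Grayscale stacks need `--threshold`; values at or
above it become wall. A raw `.npy` + JSON sidecar
(`{shape, spacing_um, axis_order: "zyx"}`) is also accepted. Axis order is
`(z, y, x)` with `z` the solidification/primary invasion axis.
Anisotropic spacing is rejected.

## CLI

```sh
# full workflow: flood fill, curves, percolation fits
porepath analyze --input scaffold.tif --spacing-um 3.74 \
    --direction 3d --direction z- --direction x- --out report/

# one interconnectivity curve
porepath curve --input scaffold.tif --diameters geom:7.5:60:12 \
    --direction z- --out curve.csv

# fit d_c from (d, L) measurements
porepath fit --points scan.csv --out fit.json --plot fit.png

# synthetic structures
porepath phantom --kind lamellar --shape 64,64,64 --seed 1 \
    --param channel_width=12 --param hole_diameter=5 --out lam.tif
```

`analyze` exits with code 2 and a remediation hint when no direction
yields at least three Region-2 points (non-percolating, deeper than the
surface layer) — the signal that the analysed volume is too small
relative to the structure's transport length scales. Reruns with an
identical configuration are byte-identical; every report carries the
config hash.

## Library

```python
import porepath as pp

grid = pp.read_volume("scaffold.tif", spacing_um=3.74)
pp.flood_fill_fraction(grid)                      # Method-A style percentage
res = pp.accessible_region(grid, 30.0, pp.FaceSet.single("z-"))
pp.interconnectivity_percent(grid, res)           # % of pore volume swept
pts = pp.percolation_scan(grid, "z-", [15, 20, 25, 30, 40, 50])
pp.fit_percolation_diameter(pts).d_c_um           # scaling-law intercept
pp.percolation_threshold_direct(grid, "z-")       # bisection ground truth
```

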