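import warnings
from collections import deque

import numpy as np
import pytest

from porepath import (
    PORE,
    WALL,
    AccessibilityResult,
    FaceSet,
    VolumeError,
    VoxelGrid,
    accessible_region,
    brute_force_accessible,
    center_space,
    flood_fill_fraction,
    interconnectivity_curve,
    interconnectivity_percent,
    make_lamellar,
    make_throat_lattice,
)
from conftest import random_grid


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def bfs_component_sizes(pore: np.ndarray) -> list[int]:
    """Connected-component sizes by hand-rolled 26-connectivity BFS."""
    nz, ny, nx = pore.shape
    seen = np.zeros_like(pore, dtype=bool)
    nbrs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    sizes = []
    for z0, y0, x0 in zip(*np.nonzero(pore)):
        if seen[z0, y0, x0]:
            continue
        q = deque([(int(z0), int(y0), int(x0))])
        seen[z0, y0, x0] = True
        size = 0
        while q:
            z, y, x = q.popleft()
            size += 1
            for a, b, c in nbrs:
                zz, yy, xx = z + a, y + b, x + c
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if pore[zz, yy, xx] and not seen[zz, yy, xx]:
                        seen[zz, yy, xx] = True
                        q.append((zz, yy, xx))
        sizes.append(size)
    return sizes


def explicit_center_space(grid: VoxelGrid, diameter_um: float) -> np.ndarray:
    """Sphere-fit test at every voxel: no wall voxel centre strictly inside d/2."""
    r2 = (diameter_um / (2 * grid.spacing_um)) ** 2
    wall = grid.wall_mask()
    walls = np.argwhere(wall)
    out = np.zeros(grid.shape, dtype=bool)
    for z, y, x in np.argwhere(grid.pore_mask()):
        d2 = ((walls - (z, y, x)) ** 2).sum(axis=1)
        out[z, y, x] = not (d2 < r2).any() if walls.size else True
    return out


# ---------------------------------------------------------------------------
# flood fill
# ---------------------------------------------------------------------------


class TestFloodFill:
    def test_all_pore(self, all_pore):
        assert flood_fill_fraction(all_pore) == 100.0

    def test_two_components(self, two_blob_grid):
        assert flood_fill_fraction(two_blob_grid) == pytest.approx(70.0)

    def test_no_pore_error(self, all_wall):
        with pytest.raises(VolumeError, match="no pore"):
            flood_fill_fraction(all_wall)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        g = random_grid(seed, shape=(16, 16, 16), porosity=0.45)
        sizes = bfs_component_sizes(g.pore_mask())
        expected = 100.0 * max(sizes) / sum(sizes)
        assert flood_fill_fraction(g) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# centre space
# ---------------------------------------------------------------------------


class TestCenterSpace:
    def test_d0_is_full_pore(self, channel_grid):
        np.testing.assert_array_equal(center_space(channel_grid, 0.0), channel_grid.pore_mask())

    def test_small_d_is_full_pore(self, channel_grid):
        np.testing.assert_array_equal(center_space(channel_grid, 1.0), channel_grid.pore_mask())

    def test_negative_d_rejected(self, channel_grid):
        with pytest.raises(VolumeError):
            center_space(channel_grid, -1.0)

    def test_channel_core_line(self, channel_grid):
        # 5-wide channel: wall centres sit 3 voxels from the axis, so the
        # single-voxel core line survives exactly for 4 < d <= 6.
        mask = center_space(channel_grid, 5.0)
        expected = np.zeros(channel_grid.shape, dtype=bool)
        expected[:, 6, 6] = True
        np.testing.assert_array_equal(mask, expected)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5, 5.0, 6.0])
    def test_matches_explicit_sphere_check(self, channel_grid, d):
        np.testing.assert_array_equal(
            center_space(channel_grid, d), explicit_center_space(channel_grid, d)
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_explicit_sphere_check_random(self, seed):
        g = random_grid(seed, shape=(12, 12, 12), porosity=0.6)
        for d in (2.0, 3.5, 5.0):
            np.testing.assert_array_equal(center_space(g, d), explicit_center_space(g, d))

    def test_oversize_d_empty(self, channel_grid):
        assert not center_space(channel_grid, 100.0).any()

    def test_nesting_in_d(self):
        for seed in range(5):
            g = random_grid(seed, porosity=0.65)
            prev = center_space(g, 0.0)
            for d in (2.0, 3.0, 4.0, 6.0):
                cur = center_space(g, d)
                assert (cur <= prev).all()
                prev = cur


# ---------------------------------------------------------------------------
# accessible region
# ---------------------------------------------------------------------------


class TestAccessibleRegion:
    def test_all_pore_single_face(self, all_pore):
        res = accessible_region(all_pore, 4.0, FaceSet.single("z-"))
        np.testing.assert_array_equal(res.access_mask, all_pore.pore_mask())
        assert res.accessible_volume_um3 == all_pore.pore_volume_um3

    def test_dead_end_too_narrow(self):
        # 3-wide dead-end channel opening onto z-: a 5-voxel sphere cannot
        # enter (no centre positions), though hovering outside it still
        # grazes the pore voxels at the very mouth of the channel.
        data = np.full((12, 11, 11), WALL, np.uint8)
        data[0:8, 4:7, 4:7] = PORE
        g = VoxelGrid(data, 1.0)
        res = accessible_region(g, 5.0, FaceSet.single("z-"))
        assert not res.center_mask.any()
        assert not res.access_mask[1:].any()  # nothing beyond the surface slab
        assert interconnectivity_percent(g, res) < 15.0

    def test_wide_enough_dead_end_is_swept(self):
        data = np.full((12, 13, 13), WALL, np.uint8)
        data[0:8, 3:10, 3:10] = PORE
        g = VoxelGrid(data, 1.0)
        res = accessible_region(g, 5.0, FaceSet.single("z-"))
        assert res.access_mask.any()
        assert (res.center_mask <= res.access_mask).all()

    def test_oversize_diameter_warns_and_empty(self, all_pore):
        with pytest.warns(UserWarning, match="exceeds"):
            res = accessible_region(all_pore, 1000.0, FaceSet.all_open())
        assert not res.access_mask.any()

    def test_masks_nested_in_pore(self):
        for seed in range(4):
            g = random_grid(seed, porosity=0.6)
            res = accessible_region(g, 3.0, FaceSet.all_open())
            assert (res.center_mask <= res.access_mask).all()
            assert (res.access_mask <= g.pore_mask()).all()
            assert res.accessible_volume_um3 == res.access_mask.sum() * g.voxel_volume_um3

    def test_center_nesting_in_d(self):
        for seed in range(4):
            g = random_grid(seed, porosity=0.65)
            faces = FaceSet.single("y-")
            prev = accessible_region(g, 0.0, faces).center_mask
            for d in (2.0, 3.0, 4.0, 5.5):
                cur = accessible_region(g, d, faces).center_mask
                assert (cur <= prev).all()
                prev = cur

    @pytest.mark.parametrize("mode", ["3d", "z-"])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed, mode):
        g = random_grid(seed, shape=(18, 18, 18), porosity=0.62)
        faces = FaceSet.from_spec(mode)
        for d in (2.0, 3.0, 4.0, 5.0):
            res = accessible_region(g, d, faces)
            center, access = brute_force_accessible(g, d, faces, return_center=True)
            np.testing.assert_array_equal(res.center_mask, center)
            np.testing.assert_array_equal(res.access_mask, access)

    def test_26_connectivity_superset(self):
        g = random_grid(11, porosity=0.55)
        res6 = accessible_region(g, 3.0, FaceSet.all_open(), connectivity=6)
        res26 = accessible_region(g, 3.0, FaceSet.all_open(), connectivity=26)
        assert (res6.center_mask <= res26.center_mask).all()


# ---------------------------------------------------------------------------
# interconnectivity
# ---------------------------------------------------------------------------


def _result_from_masks(grid, center, access, d=2.0, faces=None):
    faces = faces or FaceSet.all_open()
    return AccessibilityResult(
        diameter_um=d,
        faces=faces,
        center_mask=center,
        access_mask=access,
        accessible_volume_um3=float(access.sum()) * grid.voxel_volume_um3,
        spacing_um=grid.spacing_um,
    )


class TestInterconnectivityPercent:
    def test_constructed_fixture_75(self):
        # V = 1000 voxels, walls = 200, accessible = 600 of 800 pore:
        # (V - V_s) / (V - V_m) = 600/800 = 75%
        data = np.zeros((10, 10, 10), np.uint8)
        data[:2] = WALL
        g = VoxelGrid(data, 1.0)
        access = np.zeros((10, 10, 10), dtype=bool)
        access[2:8, :, :] = True  # 600 pore voxels
        res = _result_from_masks(g, access.copy(), access)
        assert interconnectivity_percent(g, res) == pytest.approx(75.0)

    def test_full_access_is_100(self, all_pore):
        res = accessible_region(all_pore, 1.0, FaceSet.all_open())
        assert interconnectivity_percent(all_pore, res) == pytest.approx(100.0)

    def test_empty_access_is_0(self, all_pore):
        empty = np.zeros(all_pore.shape, dtype=bool)
        res = _result_from_masks(all_pore, empty.copy(), empty)
        assert interconnectivity_percent(all_pore, res) == 0.0

    def test_shape_mismatch_rejected(self, all_pore):
        g2 = VoxelGrid(np.zeros((5, 5, 5), np.uint8), 1.0)
        res = accessible_region(g2, 1.0, FaceSet.all_open())
        with pytest.raises(VolumeError, match="shape"):
            interconnectivity_percent(all_pore, res)

    def test_no_pore_rejected(self, all_wall):
        empty = np.zeros(all_wall.shape, dtype=bool)
        res = _result_from_masks(all_wall, empty.copy(), empty)
        with pytest.raises(VolumeError, match="no pore"):
            interconnectivity_percent(all_wall, res)

    def test_small_d_matches_flood_fill_when_all_connected(self, channel_grid):
        res = accessible_region(channel_grid, 1.0, FaceSet.single("z-"))
        assert interconnectivity_percent(channel_grid, res) == pytest.approx(100.0)


class TestInterconnectivityCurve:
    def test_all_pore_constant_100(self, all_pore):
        c = interconnectivity_curve(all_pore, [1.0, 2.0, 4.0], FaceSet.all_open())
        assert all(p == pytest.approx(100.0) for _, p in c.points)

    def test_unsorted_rejected(self, all_pore):
        with pytest.raises(VolumeError, match="increasing"):
            interconnectivity_curve(all_pore, [4.0, 2.0], FaceSet.all_open())

    def test_duplicates_rejected(self, all_pore):
        with pytest.raises(VolumeError, match="increasing"):
            interconnectivity_curve(all_pore, [2.0, 2.0, 4.0], FaceSet.all_open())

    def test_too_few_rejected(self, all_pore):
        with pytest.raises(VolumeError):
            interconnectivity_curve(all_pore, [2.0], FaceSet.all_open())

    def test_center_accounting_exactly_monotone(self):
        for seed in range(4):
            g = random_grid(seed, porosity=0.65)
            c = interconnectivity_curve(
                g, [1.0, 2.0, 3.0, 4.5, 6.0], FaceSet.all_open(), accounting="center"
            )
            p = c.percents
            assert (np.diff(p) <= 0).all()
            assert ((p >= 0) & (p <= 100)).all()

    def test_swept_accounting_bounded_and_decreasing_overall(self):
        # swept volume may wobble up by a sweep-radius worth of voxels at
        # small d (centre space shrinks while the ball grows), but the
        # large-diameter end must sit below the small-diameter end
        for seed in range(4):
            g = random_grid(seed, porosity=0.65)
            c = interconnectivity_curve(g, [1.0, 2.0, 3.0, 4.5, 6.0], FaceSet.all_open())
            p = c.percents
            assert ((p >= 0) & (p <= 100)).all()
            assert p[-1] <= p[0] + 1e-9

    def test_3d_dominates_single_face(self):
        for seed in range(3):
            g = random_grid(seed, porosity=0.62)
            ds = [2.0, 3.0, 4.0]
            c3d = interconnectivity_curve(g, ds, FaceSet.all_open())
            for face in ("z-", "x+"):
                cf = interconnectivity_curve(g, ds, FaceSet.single(face))
                assert (c3d.percents >= cf.percents - 1e-9).all()

    def test_throat_lattice_sigmoidal_drop(self):
        g = make_throat_lattice((48, 48, 48), pitch=16, pore_diameter=10, throat_width=6)
        c = interconnectivity_curve(g, [4.0, 6.0, 8.0, 10.0], FaceSet.all_open())
        pct = dict(c.points)
        assert pct[4.0] > 95.0
        assert pct[8.0] < pct[4.0] / 2

    def test_lamellar_z_dominates_x(self):
        g = make_lamellar(
            (40, 40, 40), channel_width=12, wall_thickness=3,
            hole_diameter=5, holes_per_wall=3, seed=0,
        )
        ds = [2.0, 4.0, 7.0, 10.0]
        cz = interconnectivity_curve(g, ds, FaceSet.single("z-"))
        cx = interconnectivity_curve(g, ds, FaceSet.single("x-"))
        assert (cz.percents >= cx.percents - 1e-9).all()
        assert cz.percents[2] > cx.percents[2]  # strict somewhere in the throat range

    def test_csv_export(self, tmp_path, all_pore):
        c = interconnectivity_curve(all_pore, [1.0, 2.0], FaceSet.single("z-"))
        path = tmp_path / "c.csv"
        c.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "diameter_um,interconnectivity_percent,faces"
        assert len(lines) == 3 and lines[1].endswith("z-")
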