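"""Heme frame construction, voxelization and region discarding."""

from __future__ import annotations

import numpy as np
import pytest

import hemevox as hv
from hemevox.atoms import CHANNEL_ELEMENTS
from hemevox.synthetic import random_rotation
from hemevox.voxel import region_keep_mask

from conftest import make_toy_site


def brute_force_voxelize(atoms, frame, edge, voxel):
    """Independent oracle: per-(voxel, atom) containment test on cube bounds."""
    n = int(round(edge / voxel))
    lows = -edge / 2 + np.arange(n) * voxel
    grid = np.zeros((4, n, n, n), dtype=np.uint8)
    coords = frame.to_frame(np.stack([a.coords for a in atoms])) if atoms else np.zeros((0, 3))
    for a, q in zip(atoms, coords):
        if a.element not in CHANNEL_ELEMENTS:
            continue
        ci = CHANNEL_ELEMENTS.index(a.element)
        inside = [(lows <= q[d]) & (q[d] < lows + voxel) for d in range(3)]
        ii, jj, kk = (np.where(m)[0] for m in inside)
        for i in ii:
            for j in jj:
                for k in kk:
                    grid[ci, i, j, k] = 1
    return grid


class TestHemeFrame:
    def test_canonical_pose_gives_identity(self):
        frame = hv.compute_heme_frame(hv.make_porphyrin())
        assert np.allclose(frame.axes, np.eye(3), atol=1e-12)
        assert np.allclose(frame.origin, 0.0, atol=1e-12)

    def test_translation_equivariance(self):
        t = np.array([5.0, -3.0, 2.0])
        frame = hv.compute_heme_frame(hv.make_porphyrin(translation=t))
        assert np.allclose(frame.axes, np.eye(3), atol=1e-12)
        assert np.allclose(frame.origin, t, atol=1e-12)

    def test_rotation_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            R = random_rotation(rng)
            frame = hv.compute_heme_frame(hv.make_porphyrin(R, rng.uniform(-10, 10, 3)))
            assert np.abs(frame.axes @ R - np.eye(3)).max() < 1e-9

    def test_degenerate_methines_raise(self):
        heme = hv.make_porphyrin()
        for i, name in enumerate(("CHA", "CHB", "CHC", "CHD")):
            heme.atom(name).coords[:] = [float(i), 0.0, 0.0]  # collinear
        with pytest.raises(ValueError):
            hv.compute_heme_frame(heme)

    def test_axes_orthonormal_right_handed(self):
        rng = np.random.default_rng(7)
        frame = hv.compute_heme_frame(hv.make_porphyrin(random_rotation(rng)))
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0)


class TestVoxelize:
    def test_empty_input_all_zero(self):
        frame = hv.HemeFrame(np.zeros(3), np.eye(3))
        grid = hv.voxelize_site([], frame)
        assert grid.values.shape == (4, 24, 24, 24)
        assert grid.occupied_count() == 0

    def test_single_carbon_at_origin(self):
        frame = hv.HemeFrame(np.zeros(3), np.eye(3))
        atom = hv.AtomRecord(atom_name="C1", element="C", coords=np.zeros(3))
        grid = hv.voxelize_site([atom], frame)
        assert grid.occupied_count() == 1
        assert grid.values[0].sum() == 1  # C channel only
        assert grid.values[0, 12, 12, 12] == 1

    def test_matches_brute_force_oracle(self):
        site = make_toy_site(seed=9, n_atoms=200, spread=13.0)
        frame = hv.compute_heme_frame(site.heme)
        grid = hv.voxelize_site(site, frame, edge=24.0, voxel=1.0)
        oracle = brute_force_voxelize(site.protein_atoms, frame, 24.0, 1.0)
        assert np.array_equal(grid.values, oracle)

    def test_channel_conservation(self):
        site = make_toy_site(seed=10, n_atoms=150)
        frame = hv.compute_heme_frame(site.heme)
        grid = hv.voxelize_site(site, frame)
        for ci, el in enumerate(CHANNEL_ELEMENTS):
            n_atoms = sum(a.element == el for a in site.protein_atoms)
            assert grid.values[ci].sum() <= n_atoms

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(21)
        site = make_toy_site(seed=21, n_atoms=120)
        frame = hv.compute_heme_frame(site.heme)
        grid = hv.voxelize_site(site, frame)
        R, t = random_rotation(rng), rng.uniform(-15, 15, 3)
        moved = make_toy_site(seed=21, n_atoms=120, rotation=R, translation=t)
        frame2 = hv.compute_heme_frame(moved.heme)
        grid2 = hv.voxelize_site(moved, frame2)
        assert np.array_equal(grid.values, grid2.values)

    def test_vdw_mode_is_superset_of_center_mode(self):
        site = make_toy_site(seed=12, n_atoms=80)
        frame = hv.compute_heme_frame(site.heme)
        center = hv.voxelize_site(site, frame, mode="center")
        vdw = hv.voxelize_site(site, frame, mode="vdw")
        assert np.all(vdw.values >= center.values)
        assert vdw.occupied_count() > center.occupied_count()

    def test_non_channel_elements_dropped(self):
        frame = hv.HemeFrame(np.zeros(3), np.eye(3))
        se = hv.AtomRecord(atom_name="SE", element="Se", coords=np.zeros(3))
        assert hv.voxelize_site([se], frame).occupied_count() == 0


class TestDiscardRegion:
    def _grid(self, fill=1, edge=24.0, voxel=1.0):
        n = int(round(edge / voxel))
        return hv.VoxelGrid(np.full((4, n, n, n), fill, dtype=np.uint8), edge=edge, voxel=voxel)

    def test_r_zero_is_identity_both_modes(self):
        site = make_toy_site(seed=13, n_atoms=100)
        frame = hv.compute_heme_frame(site.heme)
        grid = hv.voxelize_site(site, frame)
        for mode in ("outside", "inside"):
            assert np.array_equal(hv.discard_region(grid, mode, 0.0).values, grid.values)

    def test_outside_r3_keeps_18_cube(self):
        grid = self._grid()
        out = hv.discard_region(grid, "outside", 3.0)
        # surviving voxel centers fill an 18 A cube: 18^3 voxels per channel
        assert out.values[0].sum() == 18**3

    def test_inside_r6_matches_center_count(self):
        grid = self._grid()
        out = hv.discard_region(grid, "inside", 6.0)
        c = grid.voxel_centers_1d()
        cheb = np.maximum.reduce(np.meshgrid(np.abs(c), np.abs(c), np.abs(c), indexing="ij"))
        expected = int((cheb >= 6.0).sum())
        assert out.values[0].sum() == expected == 24**3 - 12**3

    def test_outside_composition_is_max(self):
        rng = np.random.default_rng(5)
        grid = hv.VoxelGrid((rng.random((4, 24, 24, 24)) < 0.3).astype(np.uint8))
        a = hv.discard_region(hv.discard_region(grid, "outside", 2.0), "outside", 5.0)
        b = hv.discard_region(grid, "outside", 5.0)
        assert np.array_equal(a.values, b.values)

    def test_monotone_in_r(self):
        rng = np.random.default_rng(6)
        grid = hv.VoxelGrid((rng.random((4, 24, 24, 24)) < 0.3).astype(np.uint8))
        for mode in ("outside", "inside"):
            counts = [hv.discard_region(grid, mode, r).occupied_count() for r in range(0, 12, 2)]
            assert counts == sorted(counts, reverse=True)

    def test_r_out_of_range_raises(self):
        grid = self._grid()
        for bad in (-0.1, 12.0, 30.0):
            with pytest.raises(ValueError):
                hv.discard_region(grid, "outside", bad)

    def test_seventeen_angstrom_variant(self):
        # the same code path serves smaller inclusion regions
        grid = self._grid(edge=17.0, voxel=1.0)
        out = hv.discard_region(grid, "outside", 2.0)
        assert out.values.shape[1] == 17
        assert out.values[0].sum() == 13**3

    def test_region_keep_mask_modes_are_complementary(self):
        keep_out = region_keep_mask(24, 24.0, 1.0, "outside", 4.0)
        keep_in = region_keep_mask(24, 24.0, 1.0, "inside", 8.0)
        # outside r=4 keeps the 16-cube; inside r=8 removes the 16-cube
        assert np.array_equal(keep_out, ~keep_in)
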