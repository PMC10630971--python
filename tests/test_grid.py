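"""Voxel geometry: margin expansion, mask algebra, targets, shortest distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_grid, mask_from_indices, random_mask
from oracles import brute_force_expand, brute_force_min_distance

from gidose.grid import (
    EmptyStructureError,
    GridGeometry,
    GridMismatchError,
    StructureMask,
    build_targets,
    combine_masks,
    difference,
    expand_margin,
    intersection,
    merge_gastroduodenum,
    shortest_surface_distance,
    union,
)


class TestGridGeometry:
    def test_rejects_nonpositive_spacing_or_shape(self):
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), (1, 0, 1), (5, 5, 5))
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), (1, 1, 1), (5, -5, 5))

    def test_voxel_volume_and_affine(self):
        g = make_grid((4, 4, 4), (1.0, 2.0, 2.5), origin=(1, 2, 3))
        assert g.voxel_volume_cc == pytest.approx(5.0 / 1000)
        assert np.allclose(np.diag(g.affine), (1.0, 2.0, 2.5, 1.0))
        assert np.allclose(g.affine[:3, 3], (1, 2, 3))


class TestExpandMargin:
    def test_zero_margin_is_identity(self, rng):
        grid = make_grid()
        m = random_mask(grid, rng)
        out = expand_margin(m, 0.0)
        assert np.array_equal(out.voxels, m.voxels)

    def test_negative_margin_rejected(self, rng):
        m = random_mask(make_grid(), rng)
        with pytest.raises(ValueError):
            expand_margin(m, -1.0)

    def test_empty_mask_stays_empty(self):
        grid = make_grid()
        m = StructureMask("e", grid, np.zeros(grid.shape, bool))
        assert expand_margin(m, 5.0).is_empty

    @pytest.mark.parametrize(
        "shape,spacing,margin,seed,p",
        [
            ((11, 11, 11), (1.0, 1.0, 1.0), 5.0, 0, 0.0),  # single centre voxel
            ((15, 15, 15), (1.0, 1.0, 2.0), 3.1, 1, 0.05),
            ((12, 10, 14), (2.0, 2.0, 2.0), 5.0, 2, 0.1),
            ((25, 25, 25), (1.0, 1.5, 2.0), 4.0, 3, 0.02),
        ],
    )
    def test_matches_brute_force_dilation(self, shape, spacing, margin, seed, p):
        grid = make_grid(shape, spacing)
        if p == 0.0:
            m = mask_from_indices(grid, [tuple(n // 2 for n in shape)])
        else:
            m = random_mask(grid, np.random.default_rng(seed), p=p)
            if m.is_empty:
                pytest.skip("empty draw")
        out = expand_margin(m, margin)
        expected = brute_force_expand(m.voxels, spacing, margin)
        assert np.array_equal(out.voxels, expected)

    def test_single_voxel_5mm_sphere_count(self):
        # lattice points p with ||p|| <= 5 on a 1 mm isotropic grid
        grid = make_grid((11, 11, 11), (1.0, 1.0, 1.0))
        m = mask_from_indices(grid, [(5, 5, 5)])
        out = expand_margin(m, 5.0)
        pts = np.indices(grid.shape).reshape(3, -1).T - 5
        expected_count = int(((pts**2).sum(axis=1) <= 25).sum())
        assert out.n_voxels == expected_count

    def test_superset_and_monotone(self, rng):
        grid = make_grid((12, 12, 12), (1.0, 1.0, 1.0))
        a = random_mask(grid, rng, p=0.05, label="a")
        b = StructureMask("b", grid, a.voxels | (rng.random(grid.shape) < 0.05))
        ea, eb = expand_margin(a, 2.5), expand_margin(b, 2.5)
        assert (ea.voxels & ~a.voxels).sum() >= 0
        assert np.all(~a.voxels | ea.voxels)  # output superset of input
        assert np.all(~ea.voxels | eb.voxels)  # A <= B implies expand(A) <= expand(B)

    def test_composition_equals_single_expansion_within_one_voxel(self, rng):
        # triangle inequality: expanding twice never reaches beyond the single
        # expansion; the converse holds up to one voxel diagonal of slack
        grid = make_grid((14, 14, 14), (1.0, 1.0, 1.0))
        a = random_mask(grid, rng, p=0.03)
        twice = expand_margin(expand_margin(a, 2.0), 3.0)
        once = expand_margin(a, 5.0)
        assert np.all(~twice.voxels | once.voxels)
        slack = expand_margin(twice, np.sqrt(3.0))
        assert np.all(~once.voxels | slack.voxels)


class TestCombineMasks:
    def test_set_algebra_laws(self, rng):
        grid = make_grid()
        a = random_mask(grid, rng, label="a")
        b = random_mask(grid, rng, label="b")
        assert np.array_equal(union(a, b).voxels, union(b, a).voxels)
        assert np.array_equal(intersection(a, b).voxels, intersection(b, a).voxels)
        # A \ B = A & ~B
        assert np.array_equal(difference(a, b).voxels, a.voxels & ~b.voxels)
        # identity and annihilation
        empty = StructureMask("e", grid, np.zeros(grid.shape, bool))
        assert np.array_equal(union(a, empty).voxels, a.voxels)
        assert difference(a, a).is_empty

    def test_grid_mismatch_rejected(self, rng):
        a = random_mask(make_grid(), rng)
        b = random_mask(make_grid(spacing=(2.0, 1.0, 1.0)), rng)
        with pytest.raises(GridMismatchError):
            combine_masks("union", a, b)

    def test_unknown_operation_rejected(self, rng):
        a = random_mask(make_grid(), rng)
        with pytest.raises(ValueError):
            combine_masks("xor", a, a)

    def test_ptv_mod_against_triple_loop(self, rng):
        grid = make_grid((20, 20, 20), (1.0, 1.0, 1.0))
        ptv = random_mask(grid, rng, p=0.3, label="ptv")
        prvs = [random_mask(grid, rng, p=0.1, label=f"prv{i}") for i in range(4)]
        result = ptv
        for prv in prvs:
            result = difference(result, prv)
        expected = np.zeros(grid.shape, bool)
        for i in range(20):
            for j in range(20):
                for k in range(20):
                    expected[i, j, k] = ptv.voxels[i, j, k] and not any(
                        p.voxels[i, j, k] for p in prvs
                    )
        assert np.array_equal(result.voxels, expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), margin=st.floats(0.0, 6.0))
    def test_distance_zero_iff_overlap_and_dilation_monotone(self, seed, margin):
        rng = np.random.default_rng(seed)
        grid = make_grid((10, 10, 10), (1.0, 1.0, 2.0))
        a = random_mask(grid, rng, p=0.04, label="a")
        b = random_mask(grid, rng, p=0.04, label="b")
        if a.is_empty or b.is_empty:
            return
        d = shortest_surface_distance(a, b)
        assert (d == 0.0) == bool((a.voxels & b.voxels).any())
        assert shortest_surface_distance(expand_margin(a, margin), b) <= d + 1e-9

    def test_volume_conservation(self, rng):
        grid = make_grid(spacing=(1.0, 2.0, 2.0))
        a = random_mask(grid, rng, label="a")
        b = random_mask(grid, rng, label="b")
        assert union(a, b).volume_cc + intersection(a, b).volume_cc == pytest.approx(
            a.volume_cc + b.volume_cc
        )


class TestBuildTargets:
    def test_without_tvi_and_prvs(self, rng):
        grid = make_grid((20, 20, 20), (1.0, 1.0, 1.0))
        gtv = mask_from_indices(grid, [(10, 10, 10)], label="gtv")
        tv = build_targets(gtv, margin_mm=5.0)
        assert np.array_equal(tv.ctv.voxels, gtv.voxels)
        assert np.array_equal(tv.ptv.voxels, expand_margin(gtv, 5.0).voxels)
        assert np.array_equal(tv.ptv_mod.voxels, tv.ptv.voxels)

    def test_missing_gtv_rejected(self):
        grid = make_grid()
        empty = StructureMask("gtv", grid, np.zeros(grid.shape, bool))
        with pytest.raises(EmptyStructureError):
            build_targets(empty)

    def test_spherical_ctv_expands_to_analytic_sphere(self):
        # CTV radius 10 mm -> PTV radius 15 mm within one voxel diagonal
        grid = make_grid((35, 35, 35), (1.0, 1.0, 1.0))
        X, Y, Z = grid.voxel_centers()
        r = np.sqrt(X**2 + Y**2 + Z**2)
        gtv = StructureMask("gtv", grid, r <= 10.0)
        tv = build_targets(gtv, margin_mm=5.0)
        diag = np.sqrt(3.0)
        assert np.all(tv.ptv.voxels[r <= 15.0 - diag])
        assert not np.any(tv.ptv.voxels[r > 15.0 + diag])

    def test_ptv_mod_disjoint_from_prvs(self, rng):
        grid = make_grid((16, 16, 16), (1.5, 1.5, 1.5))
        gtv = mask_from_indices(grid, [(8, 8, 8)], label="gtv")
        prvs = [random_mask(grid, rng, p=0.15, label=f"prv{i}") for i in range(3)]
        tv = build_targets(gtv, gi_prvs=prvs, margin_mm=5.0)
        for prv in prvs:
            assert not (tv.ptv_mod.voxels & prv.voxels).any()
        assert np.all(~tv.ptv_mod.voxels | tv.ptv.voxels)  # ptv_mod inside ptv

    def test_tvi_extends_ctv(self):
        grid = make_grid((25, 25, 25), (1.0, 1.0, 1.0))
        gtv = mask_from_indices(grid, [(12, 12, 12)], label="gtv")
        tvi = mask_from_indices(grid, [(18, 12, 12)], label="tvi")
        tv = build_targets(gtv, tvi=tvi, margin_mm=5.0)
        assert tv.ctv.voxels[12, 12, 12]
        assert tv.ctv.voxels[18, 12, 12]
        assert tv.ctv.voxels[20, 12, 12]  # inside the 5 mm TVI margin
        assert tv.ctv.n_voxels > gtv.n_voxels


class TestMergeGastroduodenum:
    def test_empty_duodenum_keeps_stomach(self, rng):
        grid = make_grid()
        stomach = random_mask(grid, rng, label="stomach")
        duo = StructureMask("duodenum", grid, np.zeros(grid.shape, bool))
        merged = merge_gastroduodenum(stomach, duo)
        assert merged.label == "gastroduodenum"
        assert np.array_equal(merged.voxels, stomach.voxels)

    def test_disjoint_volumes_add(self):
        grid = make_grid()
        s = mask_from_indices(grid, [(1, 1, 1), (2, 2, 2)], label="stomach")
        d = mask_from_indices(grid, [(10, 10, 10)], label="duodenum")
        merged = merge_gastroduodenum(s, d)
        assert merged.volume_cc == pytest.approx(s.volume_cc + d.volume_cc)

    def test_overlap_follows_inclusion_exclusion(self, rng):
        grid = make_grid()
        s = random_mask(grid, rng, p=0.3, label="stomach")
        d = random_mask(grid, rng, p=0.3, label="duodenum")
        merged = merge_gastroduodenum(s, d)
        inter = int((s.voxels & d.voxels).sum())
        assert merged.n_voxels == s.n_voxels + d.n_voxels - inter
        if inter:
            assert merged.volume_cc < s.volume_cc + d.volume_cc


class TestShortestSurfaceDistance:
    def test_overlapping_masks_give_zero(self, rng):
        grid = make_grid()
        a = random_mask(grid, rng, p=0.5, label="a")
        b = StructureMask("b", grid, a.voxels.copy())
        assert shortest_surface_distance(a, b) == 0.0

    def test_two_single_voxels_10mm_apart(self):
        grid = make_grid((11, 11, 11), (2.0, 2.0, 2.0))
        a = mask_from_indices(grid, [(2, 2, 5)], label="a")
        b = mask_from_indices(grid, [(5, 6, 5)], label="b")  # (6, 8, 0) mm offset
        assert shortest_surface_distance(a, b) == pytest.approx(10.0)

    def test_empty_mask_rejected(self, rng):
        grid = make_grid()
        a = random_mask(grid, rng, label="a")
        empty = StructureMask("b", grid, np.zeros(grid.shape, bool))
        with pytest.raises(EmptyStructureError):
            shortest_surface_distance(a, empty)

    def test_abutting_masks_share_boundary_voxel(self):
        # contact configuration behind the cohort's 0 mm medians
        grid = make_grid((10, 10, 10), (2.0, 2.0, 2.0))
        vox_a = np.zeros(grid.shape, bool)
        vox_a[:5] = True
        vox_b = np.zeros(grid.shape, bool)
        vox_b[4:] = True  # shares slab 4 with a
        a = StructureMask("a", grid, vox_a)
        b = StructureMask("b", grid, vox_b)
        assert shortest_surface_distance(a, b) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid((14, 12, 16), (1.0, 2.0, 1.5))
        a = random_mask(grid, rng, p=0.03, label="a")
        b = random_mask(grid, rng, p=0.03, label="b")
        if a.is_empty or b.is_empty:
            pytest.skip("empty draw")
        d_ab = shortest_surface_distance(a, b)
        d_ba = shortest_surface_distance(b, a)
        expected = brute_force_min_distance(a.voxels, b.voxels, grid.spacing)
        assert d_ab == pytest.approx(expected, abs=1e-9)
        assert d_ba == pytest.approx(expected, abs=1e-9)

    def test_never_increases_under_dilation(self, rng):
        grid = make_grid((16, 16, 16), (1.0, 1.0, 1.0))
        a = mask_from_indices(grid, [(2, 2, 2)], label="a")
        b = mask_from_indices(grid, [(13, 13, 13)], label="b")
        d0 = shortest_surface_distance(a, b)
        d1 = shortest_surface_distance(expand_margin(a, 2.0), b)
        d2 = shortest_surface_distance(expand_margin(a, 2.0), expand_margin(b, 2.0))
        assert d1 <= d0
        assert d2 <= d1

    def test_zero_iff_masks_intersect(self, rng):
        grid = make_grid((10, 10, 10), (1.0, 1.0, 1.0))
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = random_mask(grid, r, p=0.1, label="a")
            b = random_mask(grid, r, p=0.1, label="b")
            if a.is_empty or b.is_empty:
                continue
            d = shortest_surface_distance(a, b)
            if (a.voxels & b.voxels).any():
                assert d == 0.0
            else:
                assert d > 0.0
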