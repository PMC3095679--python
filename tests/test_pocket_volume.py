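"""Grid construction, clash detection, pruning, and volume measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pocketdyn.errors import ConfigError, EmptyGridError
from pocketdyn.pocket_volume import (
    InclusionRegion,
    VdwTable,
    VolumeSeries,
    build_grid,
    flag_clashes,
    moving_average,
    pocket_volume,
    prune_isolated,
    volume_histogram,
    volume_series,
)
from pocketdyn.structure_io import Ensemble

from conftest import make_frame


def sphere_region(center=(0.0, 0.0, 0.0), radius=5.0):
    return InclusionRegion.from_centers([center], radius=radius)


# ---------------------------------------------------------------------------
# independent oracles


def lattice_points_in_ball(radius):
    """Integer lattice points with x²+y²+z² ≤ r² (direct enumeration)."""
    span = int(np.ceil(radius))
    pts = []
    for x in range(-span, span + 1):
        for y in range(-span, span + 1):
            for z in range(-span, span + 1):
                if x * x + y * y + z * z <= radius * radius:
                    pts.append((x, y, z))
    return pts


def exhaustive_clash_mask(points, frame, vdw):
    """O(N·M) pairwise clash check, the definitional oracle."""
    occupied = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        for a in range(frame.n_atoms):
            r = vdw.radius(frame.elements[a]) + vdw.probe_radius
            if np.sum((p - frame.coords[a]) ** 2) < r * r:
                occupied[i] = True
                break
    return occupied


def union_find_prune(occupied, lattice_indices, connectivity, min_cluster):
    """Brute-force connected components of free points via union-find."""
    parent = list(range(len(occupied)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    index_of = {tuple(idx): i for i, idx in enumerate(lattice_indices)}
    if connectivity == 6:
        offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    else:
        offsets = [
            (dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) > (0, 0, 0)
        ]
    free = ~occupied
    for i, idx in enumerate(lattice_indices):
        if not free[i]:
            continue
        for off in offsets:
            j = index_of.get(tuple(np.asarray(idx) + off))
            if j is not None and free[j]:
                union(i, j)
    from collections import Counter

    sizes = Counter(find(i) for i in range(len(occupied)) if free[i])
    out = occupied.copy()
    for i in range(len(occupied)):
        if free[i] and sizes[find(i)] < min_cluster:
            out[i] = True
    return out


# ---------------------------------------------------------------------------


class TestBuildGrid:
    def test_sphere_radius_2p4_has_57_points(self):
        grid = build_grid(sphere_region(radius=2.4), spacing=1.0)
        assert grid.n_points == 57
        assert grid.n_points == len(lattice_points_in_ball(2.4))

    def test_half_angstrom_sphere_keeps_only_center(self):
        grid = build_grid(sphere_region(radius=0.5), spacing=1.0)
        assert grid.n_points == 1
        np.testing.assert_allclose(grid.points[0], [0.0, 0.0, 0.0])

    def test_union_of_coincident_spheres_is_idempotent(self):
        one = build_grid(sphere_region(radius=3.0))
        region2 = InclusionRegion.from_centers(
            [(0, 0, 0), (0, 0, 0)], radius=3.0
        )
        two = build_grid(region2)
        np.testing.assert_array_equal(one.points, two.points)

    def test_offcenter_matches_enumeration_oracle(self, rng):
        center = rng.normal(0, 3, 3)
        radius = 3.7
        grid = build_grid(sphere_region(tuple(center), radius))
        # oracle: enumerate around the snapped anchor
        origin = np.round(center)
        count = sum(
            1
            for x in range(-8, 9)
            for y in range(-8, 9)
            for z in range(-8, 9)
            if np.sum((origin + [x, y, z] - center) ** 2) <= radius**2
        )
        assert grid.n_points == count

    def test_deterministic_and_lexicographic(self):
        g1 = build_grid(sphere_region(radius=3.0))
        g2 = build_grid(sphere_region(radius=3.0))
        assert np.array_equal(g1.points, g2.points)
        order = np.lexsort(
            (g1.lattice_indices[:, 2], g1.lattice_indices[:, 1],
             g1.lattice_indices[:, 0])
        )
        assert np.array_equal(order, np.arange(g1.n_points))

    def test_empty_region_raises(self):
        region = InclusionRegion.from_centers([(0.49, 0.49, 0.49)], radius=0.1)
        with pytest.raises(EmptyGridError):
            build_grid(region)

    def test_bad_spacing_raises(self):
        with pytest.raises(ConfigError):
            build_grid(sphere_region(), spacing=0.0)


class TestFlagClashes:
    def test_no_atoms_all_free(self):
        grid = build_grid(sphere_region(radius=3.0))
        frame = make_frame(np.zeros((0, 3)))
        assert not flag_clashes(grid, frame).any()

    def test_single_carbon_removes_93_points(self):
        # carbon 1.70 + probe 1.20 = 2.90 Å reach; strict inequality keeps
        # the 2.9 Å surface, so integer lattice points with d² ≤ 8 clash
        grid = build_grid(sphere_region(radius=6.0))
        frame = make_frame([[0.0, 0.0, 0.0]])
        occupied = flag_clashes(grid, frame)
        assert occupied.sum() == 93

    def test_unknown_element_warns_and_uses_default(self):
        grid = build_grid(sphere_region(radius=3.0))
        frame = make_frame([[0.0, 0.0, 0.0]], elements=np.array(["XX"]))
        with pytest.warns(UserWarning, match="vdW radius"):
            occupied = flag_clashes(grid, frame)
        assert occupied.sum() == 93  # default radius equals carbon's

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = build_grid(sphere_region(radius=4.0))
        elements = rng.choice(["C", "N", "O", "S", "H"], size=20)
        frame = make_frame(rng.normal(0, 4, (20, 3)), elements=elements)
        vdw = VdwTable()
        fast = flag_clashes(grid, frame, vdw)
        slow = exhaustive_clash_mask(grid.points, frame, vdw)
        np.testing.assert_array_equal(fast, slow)


class TestPruneIsolated:
    def test_fully_free_grid_unchanged(self):
        grid = build_grid(sphere_region(radius=3.0))
        occupied = np.zeros(grid.n_points, dtype=bool)
        out = prune_isolated(occupied, grid, 6, 4)
        assert not out.any()

    def test_singleton_free_point_removed(self):
        grid = build_grid(sphere_region(radius=3.0))
        occupied = np.ones(grid.n_points, dtype=bool)
        center = np.all(grid.lattice_indices == 0, axis=1)
        occupied[center] = False
        out = prune_isolated(occupied, grid, 6, min_cluster=2)
        assert out.all()

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        grid = build_grid(sphere_region(radius=4.0))
        occupied = rng.random(grid.n_points) < 0.5
        ours = prune_isolated(occupied, grid, connectivity, min_cluster=4)
        oracle = union_find_prune(occupied, grid.lattice_indices,
                                  connectivity, 4)
        np.testing.assert_array_equal(ours, oracle)


class TestPocketVolume:
    def test_empty_frame_gives_full_grid_volume(self):
        grid = build_grid(sphere_region(radius=3.0))
        frame = make_frame(np.zeros((0, 3)))
        assert pocket_volume(frame, grid) == grid.n_points * 1.0

    def test_adding_atom_never_increases_volume(self, rng):
        grid = build_grid(sphere_region(radius=5.0))
        coords = rng.normal(0, 4, (15, 3))
        for k in range(1, 15):
            v_small = pocket_volume(make_frame(coords[:k]), grid)
            v_big = pocket_volume(make_frame(coords[: k + 1]), grid)
            assert v_big <= v_small

    def test_probe_monotonicity(self, rng):
        grid = build_grid(sphere_region(radius=5.0))
        frame = make_frame(rng.normal(0, 4, (10, 3)))
        vols = [
            pocket_volume(frame, grid, VdwTable(probe_radius=p))
            for p in (0.0, 0.6, 1.2, 1.8)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_rigid_body_invariance(self, rng):
        from pocketdyn.pocket_volume import PocketGrid

        from conftest import random_rotation

        frame = make_frame(rng.normal(0, 3, (25, 3)))
        grid = build_grid(sphere_region(radius=4.0))
        v1 = pocket_volume(frame, grid)
        # one rigid motion applied to the frame, the inclusion centers AND
        # the grid points: the whole configuration is congruent
        R = random_rotation(rng)
        t = rng.normal(0, 10, 3)
        moved = frame.with_coords(frame.coords @ R.T + t)
        center_moved = tuple(np.zeros(3) @ R.T + t)
        grid_moved = PocketGrid(
            grid.points @ R.T + t,
            grid.lattice_indices,
            grid.origin @ R.T + t,
            grid.spacing,
            InclusionRegion.from_centers([center_moved], 4.0),
        )
        v2 = pocket_volume(moved, grid_moved)
        assert v2 == v1


class TestVolumeSeries:
    def test_static_ensemble_constant_series(self, rng):
        frame = make_frame(rng.normal(0, 4, (12, 3)))
        ens = Ensemble(frame, dt=10.0,
                       coords=np.repeat(frame.coords[None], 6, axis=0).copy())
        grid = build_grid(sphere_region(radius=4.0))
        series = volume_series(ens, grid)
        assert len(set(series.volumes)) == 1
        np.testing.assert_allclose(series.times, np.arange(6) * 10.0)

    @pytest.mark.parametrize("stride,expected", [(1, 10), (2, 5), (3, 4), (10, 1)])
    def test_stride_length_contract(self, rng, stride, expected):
        frame = make_frame(rng.normal(0, 4, (5, 3)))
        ens = Ensemble(frame, dt=10.0,
                       coords=np.repeat(frame.coords[None], 10, axis=0).copy())
        grid = build_grid(sphere_region(radius=3.0))
        assert len(volume_series(ens, grid, stride=stride)) == expected

    def test_tsv_roundtrip(self, tmp_path):
        s = VolumeSeries(np.arange(4) * 10.0, [100.0, 200.0, 150.0, 50.0],
                         {"spacing_A": 1.0})
        path = tmp_path / "v.tsv"
        s.to_tsv(path)
        back = VolumeSeries.from_tsv(path)
        np.testing.assert_allclose(back.times, s.times)
        np.testing.assert_allclose(back.volumes, s.volumes)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = VolumeSeries(np.arange(5) * 10.0, np.full(5, 7.0))
        np.testing.assert_allclose(moving_average(s, 30.0).volumes, 7.0)

    def test_hand_boxcar_oracle(self):
        s = VolumeSeries(np.arange(5) * 10.0, [1, 2, 3, 4, 5])
        out = moving_average(s, 30.0)
        np.testing.assert_allclose(out.volumes, [1.5, 2, 3, 4, 4.5])
        np.testing.assert_allclose(out.times, s.times)

    def test_window_spanning_series_gives_global_mean(self):
        s = VolumeSeries(np.arange(5) * 10.0, [1, 2, 3, 4, 5])
        out = moving_average(s, 1000.0)
        assert out.volumes[2] == pytest.approx(3.0)

    def test_subsample_window_rejected(self):
        s = VolumeSeries(np.arange(5) * 10.0, np.ones(5))
        with pytest.raises(ConfigError):
            moving_average(s, 5.0)


class TestVolumeHistogram:
    def test_constant_series_single_bin(self):
        s = VolumeSeries(np.arange(3) * 10.0, np.full(3, 42.0))
        edges, freqs = volume_histogram(s, 25.0)
        assert (freqs > 0).sum() == 1
        assert freqs.sum() == 3

    @given(seed=st.integers(0, 200))
    def test_frequency_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        s = VolumeSeries(np.arange(n) * 10.0, rng.uniform(0, 500, n))
        edges, freqs = volume_histogram(s, 25.0)
        assert freqs.sum() == n
        assert edges[0] <= s.volumes.min()
        assert edges[-1] >= s.volumes.max()
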