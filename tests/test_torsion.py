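"""Trajectory torsion analysis and minimax barriers on 2D-PES grids."""

import itertools

import numpy as np
import pytest

from predkin.conformers import TrieneLabel
from predkin.synthetic import (
    DEFAULT_TORSIONS,
    chain_geometry,
    make_pes_grid,
    make_torsion_trajectory,
    quadrant_well,
)
from predkin.torsion import (
    Histogram2D,
    PESGrid,
    TorsionTrajectory,
    accessibility_report,
    histogram2d,
    minimax_barrier,
    trajectory_torsions,
)

CCm = TrieneLabel.from_string("-c-c")
CCp = TrieneLabel.from_string("+c+c")


class TestTrajectoryTorsions:
    def test_single_frame_matches_conformer(self):
        coords = chain_geometry(54.0, 43.0, 6, seed=1)
        traj = trajectory_torsions([(("C",) * 6, coords)], DEFAULT_TORSIONS)
        assert traj.n_frames == 1
        assert traj.phi1[0] == pytest.approx(54.0, abs=1e-9)
        assert traj.phi2[0] == pytest.approx(43.0, abs=1e-9)

    def test_generator_round_trip(self):
        """Angles recovered from rendered frames equal the walk's series."""
        walk = make_torsion_trajectory(
            quadrant_well("-c-c"), n_steps=200, seed=4
        )
        frames = [
            (("C",) * 6, chain_geometry(p1, p2, 6, seed=0))
            for p1, p2 in zip(walk.phi1, walk.phi2)
        ]
        traj = trajectory_torsions(frames, DEFAULT_TORSIONS)
        assert np.allclose(traj.phi1, walk.phi1, atol=1e-8)
        assert np.allclose(traj.phi2, walk.phi2, atol=1e-8)

    def test_rigid_rotation_invariance(self, rng):
        coords = chain_geometry(-57.0, -46.0, 6, seed=2)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = coords @ q.T + rng.normal(size=3)
        t1 = trajectory_torsions([(("C",) * 6, coords)], DEFAULT_TORSIONS)
        t2 = trajectory_torsions([(("C",) * 6, moved)], DEFAULT_TORSIONS)
        assert t2.phi1[0] == pytest.approx(t1.phi1[0], abs=1e-9)
        assert t2.phi2[0] == pytest.approx(t1.phi2[0], abs=1e-9)

    def test_inconsistent_frames_rejected(self):
        good = (("C",) * 6, chain_geometry(0.1, 0.1, 6, seed=0))
        bad = (("C",) * 7, chain_geometry(0.1, 0.1, 7, seed=0))
        with pytest.raises(ValueError, match="atom count"):
            trajectory_torsions([good, bad], DEFAULT_TORSIONS)


class TestAccessibility:
    def test_confined_trajectory_visits_only_its_quadrant(self):
        traj = TorsionTrajectory(
            np.random.default_rng(0).uniform(-85.0, -5.0, 4000),
            np.random.default_rng(1).uniform(-85.0, -5.0, 4000),
        )
        report = accessibility_report(traj)
        assert {str(lab) for lab in report.visited} == {"-c-c"}
        assert report.occupancy["-c-c"] == 1.0
        assert report.reactive_only

    def test_uniform_angles_visit_all_sixteen_labels(self):
        rng = np.random.default_rng(12345)
        traj = TorsionTrajectory(
            rng.uniform(-179.999, 180.0, 100_000),
            rng.uniform(-179.999, 180.0, 100_000),
        )
        report = accessibility_report(traj)
        assert len(report.visited) == 16
        assert sum(report.occupancy.values()) == pytest.approx(1.0)

    def test_floor_above_max_occupancy_empties_visited(self):
        traj = TorsionTrajectory(np.array([-45.0]), np.array([-45.0]))
        report = accessibility_report(traj, floor=1.5)
        assert report.visited == frozenset()

    def test_occupancy_invariant_to_frame_order(self, rng):
        phi1 = rng.uniform(-179.0, 180.0, 500)
        phi2 = rng.uniform(-179.0, 180.0, 500)
        perm = rng.permutation(500)
        a = accessibility_report(TorsionTrajectory(phi1, phi2)).occupancy
        b = accessibility_report(TorsionTrajectory(phi1[perm], phi2[perm])).occupancy
        assert a == b


class TestHistogram2D:
    def test_single_frame_single_bin(self):
        traj = TorsionTrajectory(np.array([-44.9]), np.array([-44.9]))
        hist = histogram2d(traj, 72)
        assert hist.counts.sum() == 1
        assert hist.counts.max() == 1

    def test_edge_angle_falls_in_right_open_bin(self):
        # -45 is a bin edge of the 72x5-degree grid: it belongs to [-45, -40)
        traj = TorsionTrajectory(np.array([-45.0]), np.array([-45.0]))
        hist = histogram2d(traj, 72)
        i, j = np.argwhere(hist.counts == 1)[0]
        assert hist.edges1[i] == pytest.approx(-45.0)
        assert hist.edges2[j] == pytest.approx(-45.0)

    def test_counts_conserve_frames(self, rng):
        traj = TorsionTrajectory(
            rng.uniform(-179.0, 180.0, 2000), rng.uniform(-179.0, 180.0, 2000)
        )
        assert histogram2d(traj, 36).counts.sum() == 2000

    def test_two_planted_clusters(self):
        rng = np.random.default_rng(7)
        n1, n2 = 300, 700
        # each cluster sits strictly inside one 45-degree bin
        phi1 = np.concatenate(
            [rng.uniform(-85.0, -50.0, n1), rng.uniform(50.0, 85.0, n2)]
        )
        phi2 = np.concatenate(
            [rng.uniform(-85.0, -50.0, n1), rng.uniform(50.0, 85.0, n2)]
        )
        hist = histogram2d(TorsionTrajectory(phi1, phi2), 8)  # 45-degree bins
        occupied = hist.counts[hist.counts > 0]
        assert sorted(occupied.tolist()) == [n1, n2]


def _neighbors(i, j, shape, periodic):
    n1, n2 = shape
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            ii, jj = i + di, j + dj
            if periodic:
                yield ii % n1, jj % n2
            elif 0 <= ii < n1 and 0 <= jj < n2:
                yield ii, jj


def _enumerate_paths_minimax(values, start, ends, periodic):
    """Exhaustive DFS over all simple paths, pruned on the running max."""
    best = np.inf

    def dfs(cell, running_max, seen):
        nonlocal best
        running_max = max(running_max, values[cell])
        if running_max >= best:
            return
        if cell in ends:
            best = running_max
            return
        for nxt in sorted(
            set(_neighbors(*cell, values.shape, periodic)) - seen,
            key=lambda c: values[c],
        ):
            if max(running_max, values[nxt]) < best:
                dfs(nxt, running_max, seen | {nxt})

    dfs(start, -np.inf, {start})
    return best - values[start]


def _threshold_sweep_minimax(values, start, ends, periodic):
    """Independent oracle: smallest energy level t such that start and end
    are BFS-connected through cells with energy <= t (swept exhaustively
    over every candidate level)."""
    from collections import deque

    for t in np.sort(np.unique(values)):
        if values[start] > t:
            continue
        seen = {start}
        queue = deque([start])
        while queue:
            cell = queue.popleft()
            if cell in ends:
                return t - values[start]
            for nxt in _neighbors(*cell, values.shape, periodic):
                if nxt not in seen and values[nxt] <= t:
                    seen.add(nxt)
                    queue.append(nxt)
    return np.inf


class TestMinimaxBarrier:
    def test_flat_grid_zero_barrier(self):
        grid = make_pes_grid(0.0)
        assert minimax_barrier(grid, CCm, CCp) == 0.0

    def test_three_by_three_wall(self):
        values = np.array([[0, 5, 0], [1, 5, 1], [0, 5, 0]], float)
        grid = PESGrid(values, np.arange(3.0), np.arange(3.0), (False, False))
        start = np.zeros((3, 3), bool)
        start[0, 0] = True
        end = np.zeros((3, 3), bool)
        end[0, 2] = True
        assert minimax_barrier(grid, start, end) == 5.0

    def test_gauge_invariance(self, rng):
        values = rng.uniform(0.0, 8.0, (6, 6))
        start = np.zeros((6, 6), bool)
        start[0, 0] = True
        end = np.zeros((6, 6), bool)
        end[4, 5] = True
        g1 = PESGrid(values, np.arange(6.0), np.arange(6.0), (True, True))
        g2 = PESGrid(values + 3.7, np.arange(6.0), np.arange(6.0), (True, True))
        assert minimax_barrier(g1, start, end) == pytest.approx(
            minimax_barrier(g2, start, end), abs=1e-12
        )

    def test_matches_path_enumeration_on_small_grids(self):
        rng = np.random.default_rng(42)
        axes = np.arange(3.0)
        for _ in range(10):
            values = rng.uniform(0.0, 10.0, (3, 3))
            grid = PESGrid(values, axes, axes, (False, False))
            start = np.zeros((3, 3), bool)
            end = np.zeros((3, 3), bool)
            start[0, 0] = True
            end[2, 2] = True
            got = minimax_barrier(grid, start, end)
            want = _enumerate_paths_minimax(grid.values, (0, 0), {(2, 2)}, False)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_threshold_sweep_on_random_grids(self, periodic):
        rng = np.random.default_rng(99)
        axes = np.arange(4.0)
        for _ in range(12):
            values = rng.uniform(0.0, 10.0, (4, 4))
            grid = PESGrid(values, axes, axes, (periodic, periodic))
            start = np.zeros((4, 4), bool)
            end = np.zeros((4, 4), bool)
            si, sj, ei, ej = rng.integers(0, 4, 4)
            if (si, sj) == (ei, ej):
                continue
            start[si, sj] = True
            end[ei, ej] = True
            got = minimax_barrier(grid, start, end)
            want = _threshold_sweep_minimax(
                grid.values, (si, sj), {(ei, ej)}, periodic
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_up_to_basin_minima(self, rng):
        values = rng.uniform(0.0, 10.0, (5, 5))
        grid = PESGrid(values, np.arange(5.0), np.arange(5.0), (True, True))
        a = np.zeros((5, 5), bool)
        b = np.zeros((5, 5), bool)
        a[0, 0] = True
        b[3, 4] = True
        fwd = minimax_barrier(grid, a, b)
        rev = minimax_barrier(grid, b, a)
        e_a = grid.values[0, 0]
        e_b = grid.values[3, 4]
        assert fwd - rev == pytest.approx(e_b - e_a, abs=1e-12)

    def test_planted_barrier_recovered(self):
        grid = make_pes_grid(6.0)
        got = minimax_barrier(grid, CCm, CCp)
        assert got == pytest.approx(6.0, abs=0.1)

    def test_refinement_shrinks_discretization_error(self):
        errors = []
        for spacing in (6.0, 3.0):
            grid = make_pes_grid(6.0, grid_spacing=spacing)
            errors.append(abs(minimax_barrier(grid, CCm, CCp) - 6.0))
        assert errors[1] <= errors[0] / 2.0 + 1e-12


class TestConfinedWalks:
    @pytest.mark.parametrize("temperature", [150.0, 310.15, 1000.0])
    @pytest.mark.parametrize("seed", [0, 17])
    def test_walls_are_inescapable(self, temperature, seed):
        """The computational restatement of the encapsulated MD panel: a
        walk started in -c-c behind infinite walls never leaves it."""
        traj = make_torsion_trajectory(
            quadrant_well("-c-c"), T=temperature, n_steps=3000, seed=seed
        )
        report = accessibility_report(traj)
        assert {str(lab) for lab in report.visited} == {"-c-c"}

    def test_free_walk_covers_every_label(self):
        traj = make_torsion_trajectory(
            lambda a, b: np.zeros_like(np.asarray(a, float)),
            n_steps=100_000,
            step_size=60.0,
            seed=1,
        )
        assert len(accessibility_report(traj).visited) == 16

    def test_cold_walk_concentrates_at_minimum(self):
        grid = make_pes_grid(6.0)
        traj = make_torsion_trajectory(
            grid, T=5.0, n_steps=4000, seed=3, start=(-45.0, -45.0)
        )
        dist = np.hypot(traj.phi1 + 45.0, traj.phi2 + 45.0)
        assert np.mean(dist < 6.0) > 0.9  # pinned to the basin minimum

    def test_start_inside_wall_rejected(self):
        with pytest.raises(ValueError, match="wall"):
            make_torsion_trajectory(
                quadrant_well("-c-c"), n_steps=10, start=(100.0, 100.0)
            )
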