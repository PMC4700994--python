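"""Umbrella windows, WHAM self-consistency, minima and path extraction."""

import itertools

import numpy as np
import pytest

import ionpull as ip
from ionpull.constants import K_B
from ionpull.wham import (
    OverlapWarning,
    PMFGrid,
    UmbrellaWindow,
    classify_pair_configuration,
    find_stationary_points,
    generate_windows,
    harvest_windows,
    minimum_energy_path,
    wham_solve,
)

KT300 = K_B * 300.0


class TestWindows:
    def test_1d_tiling(self):
        centers = generate_windows([(-20.0, -2.0)], 1.0, 2.0)
        assert len(centers) == 19

    def test_2d_tiling(self):
        centers = generate_windows([(0.0, 10.0), (0.0, 10.0)], 1.0, 2.0)
        assert len(centers) == 121

    def test_overlap_warning(self):
        with pytest.warns(OverlapWarning):
            generate_windows([(0.0, 10.0)], 2.0, 10.0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            generate_windows([(5.0, 5.0)], 1.0, 2.0)


class TestHarvest:
    def test_stiff_bias_concentrates_samples(self, sim):
        k_umb = 5.0
        edges = (np.arange(-12.0, -7.9, 0.25),)
        [win] = harvest_windows(
            ip.flat_preset(), [(-10.0,)], k_umb, sim, 4000, edges, stride=10
        )
        centers = 0.5 * (edges[0][1:] + edges[0][:-1])
        width = np.sqrt(KT300 / k_umb)
        inside = np.abs(centers + 10.0) <= 3 * width
        assert win.counts[inside].sum() / win.N > 0.99

    def test_flat_landscape_histogram_matches_bias_weight(self, sim):
        """On a flat landscape the biased histogram is the bias Boltzmann
        weight.  2000 independent single-frame walkers keep the chi-square
        independence assumption honest."""
        from scipy import stats

        k_umb = 2.0
        edges = (np.arange(-13.0, -6.9, 0.5),)
        wins = harvest_windows(
            ip.flat_preset(), [(-10.0,)] * 2000, k_umb, sim, 1, edges, stride=600
        )
        counts = np.sum([w.counts for w in wins], axis=0)
        centers = 0.5 * (edges[0][1:] + edges[0][:-1])
        expected = np.exp(-0.5 * k_umb * (centers + 10.0) ** 2 / KT300)
        expected *= counts.sum() / expected.sum()
        keep = expected > 10
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = 1 - stats.chi2.cdf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_same_seed_identical_histograms(self, sim):
        edges = (np.arange(-12.0, -7.9, 0.5),)
        runs = [
            harvest_windows(ip.flat_preset(), [(-10.0,)], 5.0, sim, 2000, edges)[0]
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].counts, runs[1].counts)


class TestWhamSolve:
    def test_single_unbiased_window_closed_form(self):
        edges = (np.arange(0.0, 5.1, 1.0),)
        counts = np.array([10.0, 40.0, 20.0, 20.0, 10.0])
        win = UmbrellaWindow((0.0,), (1e-9,), counts)
        grid = wham_solve([win], 300.0, edges=edges)
        expect = -KT300 * np.log(counts)
        expect -= expect.min()
        assert np.allclose(grid.values.compressed(), expect, atol=1e-6)

    def test_window_order_invariance(self, sim):
        edges = (np.arange(-14.0, -5.9, 0.5),)
        centers = generate_windows([(-13.0, -7.0)], 1.0, 3.0)
        wins = harvest_windows(
            ip.single_well_preset(), centers, 3.0, sim, 5000, edges, stride=10
        )
        a = wham_solve(wins, 300.0, edges=edges)
        b = wham_solve(wins[::-1], 300.0, edges=edges)
        assert np.allclose(a.values.filled(np.nan), b.values.filled(np.nan),
                           atol=1e-5, equal_nan=True)

    def test_uniform_count_doubling_invariance(self, sim):
        edges = (np.arange(-14.0, -5.9, 0.5),)
        centers = generate_windows([(-13.0, -7.0)], 1.0, 3.0)
        wins = harvest_windows(
            ip.single_well_preset(), centers, 3.0, sim, 5000, edges, stride=10
        )
        doubled = [UmbrellaWindow(w.centers, w.springs, 2 * w.counts) for w in wins]
        a = wham_solve(wins, 300.0, edges=edges)
        b = wham_solve(doubled, 300.0, edges=edges)
        assert np.allclose(a.values.filled(np.nan), b.values.filled(np.nan),
                           atol=1e-5, equal_nan=True)

    def test_non_convergence_flagged(self, sim):
        edges = (np.arange(-14.0, -5.9, 0.5),)
        centers = generate_windows([(-13.0, -7.0)], 1.0, 3.0)
        wins = harvest_windows(
            ip.single_well_preset(), centers, 3.0, sim, 3000, edges, stride=10
        )
        grid = wham_solve(wins, 300.0, tol=1e-12, max_iter=3, edges=edges)
        assert not grid.converged

    def test_double_well_recovery(self):
        """WHAM reconstruction matches the analytic double-well potential
        to < 0.25 kcal/mol RMSE over the sampled interior."""
        dw = ip.double_well_preset()
        sim = ip.SimConfig(seed=5, timestep=0.005, diffusion=0.2)
        zlo, zhi = -16.0, -2.0
        centers = generate_windows([(zlo, zhi)], 0.75, 10.0, 300.0)
        edges = (np.arange(zlo - 0.25, zhi + 0.5, 0.5),)
        wins = harvest_windows(dw, centers, 10.0, sim, 20_000, edges, stride=5)
        grid = wham_solve(wins, 300.0, edges=edges)
        c = grid.centers[0]
        est = grid.values.filled(np.nan)
        m = np.isfinite(est) & (c > zlo + 0.5) & (c < zhi - 0.5)
        diff = est[m] - dw.axial_energy(c[m])
        diff -= diff.mean()
        assert np.sqrt((diff**2).mean()) < 0.25


def grid_from(values, bin_width=1.0):
    values = np.asarray(values, dtype=float)
    edges = tuple(np.arange(0.0, (n + 0.5) * bin_width, bin_width) for n in values.shape)
    return PMFGrid.from_array(edges, values)


class TestMinima:
    def test_single_gaussian_well(self):
        x = np.arange(9.0)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        u = -3.0 * np.exp(-(((xx - 4) ** 2) + (yy - 4) ** 2) / 8.0)
        mins = find_stationary_points(grid_from(u), 0.3)
        assert len(mins) == 1
        assert mins[0].index == (4, 4)
        assert mins[0].is_global

    def test_flat_grid_has_no_minima(self):
        mins = find_stationary_points(grid_from(np.zeros((6, 6))), 0.3)
        assert mins == []

    def test_all_masked_rejected(self):
        g = grid_from(np.zeros((4, 4)))
        g.values.mask = True
        with pytest.raises(ValueError):
            find_stationary_points(g, 0.3)

    def test_shallow_minimum_filtered_by_depth(self):
        u = np.zeros((9, 9))
        u[2, 2] = -2.0
        u[6, 6] = -0.1  # dimple below min_depth
        mins = find_stationary_points(grid_from(u), 0.3)
        assert [m.index for m in mins] == [(2, 2)]


class TestPath:
    def test_flat_grid_zero_barrier(self):
        res = minimum_energy_path(grid_from(np.zeros((5, 5))), (0, 0), (4, 4))
        assert res.barrier == 0.0

    def test_ridge_with_gap_matches_brute_force(self):
        u = np.zeros((5, 5))
        u[:, 2] = 5.0
        u[3, 2] = 0.5  # the gap
        grid = grid_from(u)
        res = minimum_energy_path(grid, (0, 0), (0, 4))
        assert (3, 2) in res.nodes
        # brute force over all simple paths on the tiny grid
        best = np.inf
        nodes = list(itertools.product(range(5), range(5)))

        def neighbors(n):
            i, j = n
            for di, dj in itertools.product((-1, 0, 1), repeat=2):
                if (di, dj) != (0, 0) and 0 <= i + di < 5 and 0 <= j + dj < 5:
                    yield (i + di, j + dj)

        def dfs(node, visited, peak):
            nonlocal best
            if peak >= best:
                return
            if node == (0, 4):
                best = min(best, peak)
                return
            for nb in neighbors(node):
                if nb not in visited:
                    dfs(nb, visited | {nb}, max(peak, u[nb]))

        dfs((0, 0), {(0, 0)}, 0.0)
        assert res.energies.max() == pytest.approx(best)

    def test_two_well_saddle_height(self):
        x = np.linspace(-1, 1, 21)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        # two wells at x = ±0.6 connected through a saddle at the origin
        u = (xx**2 - 0.36) ** 2 * 10 + 2.0 * yy**2
        grid = grid_from(u, bin_width=0.1)
        i_a = (int(np.argmin(np.abs(x + 0.6))), 10)
        i_b = (int(np.argmin(np.abs(x - 0.6))), 10)
        res = minimum_energy_path(grid, i_a, i_b)
        saddle = 0.36**2 * 10  # u at (0, 0)
        bin_range = np.ptp(u) / 20
        assert res.barrier == pytest.approx(saddle, abs=bin_range)

    def test_masked_endpoint_rejected(self):
        g = grid_from(np.zeros((4, 4)))
        g.values[1, 1] = np.ma.masked
        with pytest.raises(ValueError):
            minimum_energy_path(g, (1, 1), (3, 3))

    def test_disconnected_nodes_rejected(self):
        u = np.zeros((5, 5))
        g = grid_from(u)
        g.values[:, 2] = np.ma.masked
        with pytest.raises(ValueError, match="disconnected"):
            minimum_energy_path(g, (0, 0), (0, 4))


class TestClassify:
    def test_same_coordinate_is_pass_by(self):
        assert classify_pair_configuration(-10.0, -10.0, 1.0) == "pass-by"

    def test_three_angstrom_apart_is_knock_on(self):
        assert classify_pair_configuration(-10.0, -13.0, 1.0) == "knock-on"

    def test_boundary_inclusive(self):
        assert classify_pair_configuration(-10.0, -11.0, 1.0) == "pass-by"


class TestGaugeInvariance:
    def test_constant_bias_offset_leaves_pmf_unchanged(self, sim):
        """Adding a constant to every bias energy is a gauge change only."""
        edges = (np.arange(-14.0, -5.9, 0.5),)
        centers = generate_windows([(-13.0, -7.0)], 1.0, 3.0)
        wins = harvest_windows(
            ip.single_well_preset(), centers, 3.0, sim, 5000, edges, stride=10
        )
        grid_a = wham_solve(wins, 300.0, edges=edges)

        class ShiftedWindow(UmbrellaWindow):
            def bias_energy(self, grids):
                return super().bias_energy(grids) + 7.3

        shifted = [ShiftedWindow(w.centers, w.springs, w.counts) for w in wins]
        grid_b = wham_solve(shifted, 300.0, edges=edges)
        assert np.allclose(
            grid_a.values.filled(np.nan), grid_b.values.filled(np.nan),
            atol=1e-5, equal_nan=True,
        )
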