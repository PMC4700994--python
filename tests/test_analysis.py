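"""Trajectory analytics: histograms, pair density, block detection,
shared-solvent counting and the asymmetry summary."""

import numpy as np
import pytest

from ionpull.analysis import (
    PairDensityMap,
    asymmetry_summary,
    axial_histograms,
    detect_block,
    pair_density,
    separation_and_solvent,
)
from ionpull.dynamics import Trajectory
from ionpull.jarzynski import FreeEnergyProfile


def make_traj(zs, n_ions=None, species=None, steps=None):
    zs = np.asarray(zs, dtype=float)
    if zs.ndim == 1:
        zs = zs[:, None]
    t, n = zs.shape
    pos = np.zeros((t, n, 3))
    pos[:, :, 2] = zs
    return Trajectory(
        times=np.arange(1.0, t + 1),
        positions=pos,
        species=species or tuple(f"ion{i}" for i in range(n)),
        step_index=np.asarray(steps) if steps is not None else np.zeros(t, dtype=int),
    )


class TestAxialHistograms:
    def test_constant_position_single_bin(self):
        counts, edges = axial_histograms([make_traj([-10.0] * 20)], 0.5)
        assert counts.shape[0] == 1
        assert counts.max() == 20
        assert (counts > 0).sum() == 1

    def test_counts_conserved(self, rng):
        zs = rng.normal(-10, 2, (500, 2))
        counts, _ = axial_histograms([make_traj(zs)], 0.5)
        assert (counts.sum(axis=1) == 500).all()

    def test_two_gaussian_mixture_peaks(self, rng):
        z = np.concatenate([rng.normal(-13, 0.5, 4000), rng.normal(-5, 0.5, 4000)])
        counts, edges = axial_histograms([make_traj(z)], 0.5)
        centers = 0.5 * (edges[1:] + edges[:-1])
        c = counts[0]
        left = c.copy()
        left[centers > -9] = 0
        right = c.copy()
        right[centers <= -9] = 0
        assert abs(centers[np.argmax(left)] + 13) <= 0.5
        assert abs(centers[np.argmax(right)] + 5) <= 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            axial_histograms([], 0.5)


class TestPairDensity:
    def test_single_frame_single_cell(self):
        pmap = pair_density([make_traj([[-10.0, -12.0]])], 0.5)
        assert pmap.counts.sum() == 1
        assert (pmap.counts == 1).sum() == 1

    def test_total_counts_equal_frames(self, rng):
        zs = rng.normal(-10, 1.5, (300, 2))
        pmap = pair_density([make_traj(zs)], 0.5)
        assert pmap.counts.sum() == 300
        assert pmap.total_frames == 300

    def test_known_gaussian_frequencies(self, rng):
        n = 20_000
        zs = rng.normal(-10, 1.0, (n, 2))
        pmap = pair_density([make_traj(zs)], 0.5, z_range=(-14.0, -6.0))
        c = pmap.centers
        z1, z2 = np.meshgrid(c, c, indexing="ij")
        bw = 0.5
        p = (
            np.exp(-((z1 + 10) ** 2 + (z2 + 10) ** 2) / 2.0)
            * bw**2
            / (2 * np.pi)
        )
        expected = p * n
        big = expected > 50
        # multinomial: |obs − exp| within 4·sqrt(exp) cell-wise on well-filled cells
        assert (np.abs(pmap.counts[big] - expected[big])
                <= 4 * np.sqrt(expected[big])).mean() > 0.95

    def test_fewer_than_two_ions_rejected(self):
        with pytest.raises(ValueError):
            pair_density([make_traj([-10.0, -11.0])], 0.5)

    def test_symmetrized_map_is_symmetric(self, rng):
        zs = rng.normal(-10, 1.5, (200, 2)) + [0.0, -2.0]
        pmap = pair_density([make_traj(zs)], 0.5).symmetrized()
        assert np.array_equal(pmap.counts, pmap.counts.T)


def blob_map(frac_in_blob, blob_lo=-13.5, blob_hi=-10.0, off_diagonal=0.0,
             n_frames=10_000, bin_width=0.5, z_range=(-20.0, -2.0), seed=0):
    """Construct a density map: a uniform diagonal blob plus uniform noise."""
    rng = np.random.default_rng(seed)
    n_blob = int(frac_in_blob * n_frames)
    z1b = rng.uniform(blob_lo, blob_hi, n_blob)
    z2b = z1b + off_diagonal + rng.uniform(-0.2, 0.2, n_blob)
    z1u = rng.uniform(*z_range, n_frames - n_blob)
    z2u = rng.uniform(*z_range, n_frames - n_blob)
    zs = np.column_stack(
        [np.concatenate([z1b, z1u]), np.concatenate([z2b, z2u])]
    )
    return pair_density([make_traj(zs)], bin_width, z_range=z_range)


class TestDetectBlock:
    def test_uniform_map_not_detected(self):
        pmap = blob_map(0.0)
        rep = detect_block(pmap, 1.0, 0.2)
        assert not rep.detected

    def test_diagonal_blob_detected_with_matching_extent(self):
        # 60% of mass concentrated on a 3.5 Å stretch of the diagonal
        pmap = blob_map(0.6)
        rep = detect_block(pmap, 1.0, 0.2)
        assert rep.detected
        assert rep.extent == pytest.approx(3.5, abs=0.5)
        assert -14.0 < rep.z_lo < rep.z_hi < -9.5

    def test_off_diagonal_blob_not_detected(self):
        pmap = blob_map(0.6, off_diagonal=4.0)
        rep = detect_block(pmap, 1.0, 0.2)
        assert not rep.detected

    def test_relabeling_invariance_after_symmetrization(self):
        pmap = blob_map(0.6)
        swapped = PairDensityMap(pmap.edges, pmap.counts.T.copy(), pmap.total_frames)
        a = detect_block(pmap.symmetrized(), 1.0, 0.2)
        b = detect_block(swapped.symmetrized(), 1.0, 0.2)
        assert (a.detected, a.z_lo, a.z_hi) == (b.detected, b.z_lo, b.z_hi)


class TestSharedSolvent:
    def test_midpoint_counts_once(self):
        traj = make_traj([[-10.0, -14.0]])
        pts = [np.array([[0.0, 0.0, -12.0]])]  # 2 Å from each ion, r12 = 4
        series = separation_and_solvent(traj, pts)
        assert series.mean_distance[0] == pytest.approx(4.0)
        assert series.mean_shared_solvent[0] == 1.0

    def test_far_point_not_counted(self):
        traj = make_traj([[-10.0, -14.0]])
        pts = [np.array([[0.0, 0.0, -25.0]])]
        series = separation_and_solvent(traj, pts)
        assert series.mean_shared_solvent[0] == 0.0

    def test_matches_brute_force(self, rng):
        zs = rng.normal(-10, 2, (5, 2))
        traj = make_traj(zs, steps=np.arange(5))
        pts = [rng.uniform(-15, -5, (1000, 3)) for _ in range(5)]
        series = separation_and_solvent(traj, pts, window_fraction=1.0)
        for t in range(5):
            a = traj.positions[t, 0]
            b = traj.positions[t, 1]
            r = np.linalg.norm(a - b)
            n = sum(
                1
                for p in pts[t]
                if np.linalg.norm(p - a) <= r and np.linalg.norm(p - b) <= r
            )
            assert series.mean_shared_solvent[t] == n

    def test_misaligned_solvent_rejected(self):
        traj = make_traj([[-10.0, -14.0], [-10.0, -13.0]])
        with pytest.raises(ValueError, match="aligned"):
            separation_and_solvent(traj, [np.zeros((1, 3))])


def profile(lambdas, dF, err=0.1, direction="inward"):
    lambdas = np.asarray(lambdas, dtype=float)
    return FreeEnergyProfile(
        lambdas, np.asarray(dF, dtype=float), np.full(len(lambdas), err), None, direction
    )


class TestAsymmetrySummary:
    def test_identical_profiles_zero_asymmetry(self):
        lam = np.arange(-20.0, -1.9, 1.0)
        dF = np.clip(lam + 10, 0, None)
        rep = asymmetry_summary(profile(lam, dF), profile(lam[::-1], dF[::-1]))
        assert rep.difference == 0.0

    def test_max_work_difference_is_plain_arithmetic(self):
        lam = np.arange(-20.0, -1.9, 1.0)
        inw = np.interp(lam, [-20, -10, -2], [0, 8, 8])
        out = np.interp(lam, [-20, -10, -2], [3, 3, 0])
        rep = asymmetry_summary(profile(lam, inw), profile(lam[::-1], out[::-1]))
        assert rep.difference == pytest.approx(5.0)

    def test_disjoint_ranges_rejected(self):
        a = profile([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        b = profile([10.0, 11.0, 12.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            asymmetry_summary(a, b)
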