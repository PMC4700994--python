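"""Trajectory analytics: axial histograms, pair densities, block detection,
ion separation / shared-solvent series, and the inward/outward asymmetry
summary.

The central observable is the (z1, z2) pair density of two designated ions
accumulated over a pulling run.  A "block" is a stretch of the same-z
diagonal band that concentrates a large fraction of all frames — the pair
wedged side-by-side in the filter.  Detection is deliberately simple and
threshold-explicit so the same thresholds can be applied to inward and
outward runs when testing direction asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dynamics import Trajectory
from .jarzynski import FreeEnergyProfile

__all__ = [
    "PairDensityMap",
    "BlockReport",
    "SeparationSeries",
    "axial_histograms",
    "pair_density",
    "detect_block",
    "separation_and_solvent",
    "asymmetry_summary",
    "AsymmetryReport",
]


@dataclass
class PairDensityMap:
    """2D counts of (z of ion a, z of ion b) over a set of trajectories."""

    edges: np.ndarray  # shared bin edges for both axes
    counts: np.ndarray  # (nbins, nbins), axis 0 = ion a
    total_frames: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def symmetrized(self) -> "PairDensityMap":
        """Ion-relabelling-invariant map (counts + counts.T)/1, frames ×2."""
        return PairDensityMap(self.edges, self.counts + self.counts.T, 2 * self.total_frames)


@dataclass
class BlockReport:
    detected: bool
    z_lo: float
    z_hi: float
    occupancy: float
    mean_separation: float

    @property
    def extent(self) -> float:
        return self.z_hi - self.z_lo


@dataclass
class SeparationSeries:
    """Per-pulling-step averages of inter-ion distance and shared solvent."""

    steps: np.ndarray
    mean_distance: np.ndarray
    mean_shared_solvent: np.ndarray
    averaging_window: float


def axial_histograms(
    trajectories: Sequence[Trajectory], bin_width: float = 0.5,
    z_range: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion histograms of z over all frames of all trajectories.

    Returns (counts (n_ions, nbins), edges); each ion's counts sum to the
    pooled frame count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not trajectories or all(t.times.size == 0 for t in trajectories):
        raise ValueError("no frames to histogram")
    n_ions = trajectories[0].n_ions
    zs = [np.concatenate([t.z(j) for t in trajectories]) for j in range(n_ions)]
    if z_range is None:
        lo = min(z.min() for z in zs) - bin_width
        hi = max(z.max() for z in zs) + bin_width
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts = np.stack([np.histogram(z, bins=edges)[0] for z in zs])
    return counts, edges


def pair_density(
    trajectories: Sequence[Trajectory],
    bin_width: float = 0.5,
    ions: tuple[int, int] = (0, 1),
    z_range: Optional[tuple[float, float]] = None,
) -> PairDensityMap:
    """2D (z_a, z_b) occupancy map for a designated ordered ion pair."""
    if not trajectories:
        raise ValueError("no trajectories given")
    if trajectories[0].n_ions < 2:
        raise ValueError("pair_density needs at least 2 ions")
    a, b = ions
    za = np.concatenate([t.z(a) for t in trajectories])
    zb = np.concatenate([t.z(b) for t in trajectories])
    if z_range is None:
        lo = min(za.min(), zb.min()) - bin_width
        hi = max(za.max(), zb.max()) + bin_width
    else:
        lo, hi = z_range
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _, _ = np.histogram2d(za, zb, bins=(edges, edges))
    return PairDensityMap(edges=edges, counts=counts, total_frames=za.size)


def detect_block(
    pmap: PairDensityMap,
    delta_diag: float = 1.0,
    theta_occ: float = 0.2,
    peak_fraction: float = 0.1,
) -> BlockReport:
    """Look for a contiguous high-occupancy stretch of the same-z band.

    Counts within the diagonal band |z1 − z2| ≤ delta_diag are pooled per
    diagonal position; the candidate region is the longest contiguous run
    of positions holding at least ``peak_fraction`` of the peak position
    count.  The block is detected when the run's pooled occupancy (fraction
    of all frames) reaches ``theta_occ``.  An undetected block is a valid
    result, reported with the run's statistics.
    """
    centers = pmap.centers
    z1, z2 = np.meshgrid(centers, centers, indexing="ij")
    band = np.abs(z1 - z2) <= delta_diag
    n = len(centers)
    # pool band counts by diagonal position (mean-z bin index)
    diag_counts = np.zeros(n)
    sep_weight = np.zeros(n)
    sep_sum = np.zeros(n)
    for i in range(n):
        for off in range(-n + 1, n):
            j = i + off
            if 0 <= j < n and band[i, j]:
                k = (i + j) // 2
                c = pmap.counts[i, j]
                diag_counts[k] += c
                sep_sum[k] += c * abs(centers[i] - centers[j])
                sep_weight[k] += c
    total = max(pmap.total_frames, 1)
    if diag_counts.max() <= 0:
        return BlockReport(False, np.nan, np.nan, 0.0, np.nan)
    active = diag_counts >= peak_fraction * diag_counts.max()
    # longest contiguous active run
    best_run = (0, 0)
    i = 0
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            if j - i > best_run[1] - best_run[0]:
                best_run = (i, j)
            i = j + 1
        else:
            i += 1
    lo_i, hi_i = best_run
    occ = diag_counts[lo_i : hi_i + 1].sum() / total
    w = sep_weight[lo_i : hi_i + 1].sum()
    mean_sep = sep_sum[lo_i : hi_i + 1].sum() / w if w > 0 else np.nan
    half = 0.5 * (pmap.edges[1] - pmap.edges[0])
    return BlockReport(
        detected=bool(occ >= theta_occ),
        z_lo=float(centers[lo_i] - half),
        z_hi=float(centers[hi_i] + half),
        occupancy=float(occ),
        mean_separation=float(mean_sep),
    )


def separation_and_solvent(
    trajectory: Trajectory,
    solvent_per_frame: Sequence[np.ndarray],
    ions: tuple[int, int] = (0, 1),
    window_fraction: float = 5.0 / 6.0,
) -> SeparationSeries:
    """Per-step averaged ion–ion distance and shared-solvent count.

    A solvent point is shared when its distance to *both* ions is at most
    the instantaneous inter-ion distance r12 — the lens formed by the
    overlap of two spheres of radius r12 centred on the ions.  Averages per
    pulling step use the final ``window_fraction`` of the step's frames
    (the early part of each relaxation window is equilibration).
    """
    if trajectory.step_index is None:
        raise ValueError("trajectory lacks pulling-step labels")
    if len(solvent_per_frame) != trajectory.times.size:
        raise ValueError(
            f"solvent sets ({len(solvent_per_frame)}) not aligned with "
            f"frames ({trajectory.times.size})"
        )
    a, b = ions
    pa = trajectory.positions[:, a]
    pb = trajectory.positions[:, b]
    r12 = np.linalg.norm(pa - pb, axis=1)
    shared = np.zeros(trajectory.times.size)
    for t, pts in enumerate(solvent_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if pts.size == 0:
            continue
        da = np.linalg.norm(pts - pa[t], axis=1)
        db = np.linalg.norm(pts - pb[t], axis=1)
        shared[t] = np.count_nonzero((da <= r12[t]) & (db <= r12[t]))
    steps = np.unique(trajectory.step_index)
    mean_r = np.empty(steps.size)
    mean_s = np.empty(steps.size)
    for s_i, s in enumerate(steps):
        idx = np.flatnonzero(trajectory.step_index == s)
        keep = idx[int(np.floor((1 - window_fraction) * idx.size)):]
        mean_r[s_i] = r12[keep].mean()
        mean_s[s_i] = shared[keep].mean()
    dt = np.median(np.diff(trajectory.times)) if trajectory.times.size > 1 else 0.0
    return SeparationSeries(steps, mean_r, mean_s, averaging_window=window_fraction * dt)


@dataclass
class AsymmetryReport:
    inward_max_work: float
    outward_max_work: float
    difference: float
    inward_escape_work: float
    inward_escape_err: float
    outward_escape_work: float
    outward_escape_err: float

    @property
    def escape_difference(self) -> float:
        return self.inward_escape_work - self.outward_escape_work

    @property
    def escape_joint_err(self) -> float:
        return float(np.hypot(self.inward_escape_err, self.outward_escape_err))


def _escape_work(
    profile: FreeEnergyProfile,
    block_region: tuple[float, float],
    min_prominence: float = 0.75,
) -> tuple[float, float]:
    """Work to leave the block region: rise from the lowest ΔF inside the
    region to the highest ΔF between it and the first later local minimum
    (later = further along the pulling direction).

    A dip only counts as that terminating local minimum when the profile
    rises again by more than ``min_prominence`` afterwards (≈1.25 k_BT at
    300 K by default); smaller wiggles are sampling noise, not metastable
    states.
    """
    lam = profile.lambdas
    inside = (lam >= min(block_region)) & (lam <= max(block_region))
    if not inside.any():
        raise ValueError("profile does not cover the block region")
    idx_in = np.flatnonzero(inside)
    i0 = idx_in[np.argmin(profile.dF[idx_in])]
    dF = profile.dF
    # walk forward (schedule order = pulling direction) to first local min
    j = len(dF) - 1
    for k in range(idx_in[-1] + 1, len(dF) - 1):
        if dF[k] <= dF[k - 1] and dF[k] <= dF[k + 1]:
            later = dF[k + 1 :]
            if later.size and later.max() - dF[k] > min_prominence and dF[k - 1] > dF[k]:
                j = k
                break
    seg = dF[i0 : j + 1]
    k_peak = i0 + int(np.argmax(seg))
    work = float(dF[k_peak] - dF[i0])
    err = float(np.hypot(profile.err[k_peak], profile.err[i0]))
    return work, err


def asymmetry_summary(
    inward: FreeEnergyProfile,
    outward: FreeEnergyProfile,
    filter_span: tuple[float, float] = (-15.0, -5.0),
    block_region: tuple[float, float] = (-15.0, -10.0),
) -> AsymmetryReport:
    """Compare matched inward and outward profiles.

    Reports each direction's maximum cumulative work over the filter span,
    their difference, and the block-escape work per direction (see
    :func:`_escape_work`).  Profiles must overlap in λ.
    """
    lo = max(inward.lambdas.min(), outward.lambdas.min())
    hi = min(inward.lambdas.max(), outward.lambdas.max())
    if hi <= lo:
        raise ValueError("inward and outward λ ranges do not overlap")

    def max_in_span(p: FreeEnergyProfile) -> float:
        m = (p.lambdas >= filter_span[0]) & (p.lambdas <= filter_span[1])
        if not m.any():
            raise ValueError("profile does not cover the filter span")
        return float(p.dF[m].max())

    win, wout = max_in_span(inward), max_in_span(outward)
    ein, ein_err = _escape_work(inward, block_region)
    eout, eout_err = _escape_work(outward, block_region)
    return AsymmetryReport(
        inward_max_work=win,
        outward_max_work=wout,
        difference=win - wout,
        inward_escape_work=ein,
        inward_escape_err=ein_err,
        outward_escape_work=eout,
        outward_escape_err=eout_err,
    )
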