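"""Umbrella sampling and WHAM reconstruction of 1D/2D PMFs.

Overlapping harmonic-bias windows are harvested with the Brownian
simulator; the Weighted Histogram Analysis Method then solves

    P(ξ) ∝ Σ_k h_k(ξ) / Σ_k N_k exp[(f_k − U_k(ξ))/k_BT],
    f_k = −k_BT ln Σ_ξ P(ξ) exp(−U_k(ξ)/k_BT)

self-consistently for the unbiased probability P over the shared grid; the
PMF is −k_BT ln P offset so its sampled minimum is zero.  Bins never
visited stay masked — no extrapolation.

The module also extracts the features the two-ion surfaces are read for:
local minima with a prominence filter (the pass-by minima X and Y), and
bottleneck-optimal ("minimum-energy") paths between grid nodes, which is
how knock-on versus pass-by permeation pathways and their barriers are
quantified.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import K_B
from .dynamics import SimConfig, run_brownian, stream_rng
from .landscape import LandscapeSpec, energy_forces

__all__ = [
    "UmbrellaWindow",
    "PMFGrid",
    "PathResult",
    "Minimum",
    "generate_windows",
    "harvest_window",
    "harvest_windows",
    "wham_solve",
    "find_stationary_points",
    "minimum_energy_path",
    "classify_pair_configuration",
    "OverlapWarning",
]


class OverlapWarning(UserWarning):
    """Neighbouring umbrella windows may not overlap enough."""


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic centers, spring constants, histogram
    ``counts`` over the shared grid, and total sample count N."""

    centers: tuple[float, ...]
    springs: tuple[float, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.centers = tuple(float(c) for c in np.atleast_1d(self.centers))
        self.springs = tuple(float(k) for k in np.atleast_1d(self.springs))
        if len(self.springs) == 1 and len(self.centers) > 1:
            self.springs = self.springs * len(self.centers)
        if any(k <= 0 for k in self.springs):
            raise ValueError("bias spring constants must be > 0")
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    def bias_energy(self, grids: Sequence[np.ndarray]) -> np.ndarray:
        """U_k(ξ) on the shared grid (grids = per-axis bin centers)."""
        mesh = np.meshgrid(*grids, indexing="ij")
        u = np.zeros_like(mesh[0])
        for c, k, m in zip(self.centers, self.springs, mesh):
            u = u + 0.5 * k * (m - c) ** 2
        return u


@dataclass
class PMFGrid:
    """PMF on a regular 1D/2D grid; ``values`` is masked where unsampled.

    Convention: minimum of the unmasked values is 0.
    """

    edges: tuple[np.ndarray, ...]
    values: np.ma.MaskedArray
    temperature: float = 300.0
    converged: bool = True
    iterations: int = 0
    residual: float = 0.0

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    @classmethod
    def from_array(
        cls, edges: Sequence[np.ndarray], values: np.ndarray, **kw
    ) -> "PMFGrid":
        """Wrap a dense (possibly NaN-holed) array, applying the zero-offset
        convention."""
        vals = np.ma.masked_invalid(np.asarray(values, dtype=float))
        vals = vals - vals.min()
        return cls(tuple(np.asarray(e, float) for e in edges), vals, **kw)


@dataclass
class PathResult:
    """Bottleneck-optimal path over a 2D PMF grid."""

    nodes: list[tuple[int, int]]
    energies: np.ndarray
    barrier: float
    label: str


def generate_windows(
    ranges: Sequence[tuple[float, float]],
    spacing: float,
    k_umb: float,
    temperature: float = 300.0,
) -> list[tuple[float, ...]]:
    """Tile the requested 1D or 2D range with window centers.

    Warns (:class:`OverlapWarning`) when the thermal width √(k_BT/k_umb) is
    below half the spacing, the conventional neighbour-overlap criterion.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    axes = []
    for lo, hi in ranges:
        if hi <= lo:
            raise ValueError(f"empty range ({lo}, {hi})")
        axes.append(np.arange(lo, hi + 0.5 * spacing, spacing))
    width = np.sqrt(K_B * temperature / k_umb)
    if width < spacing / 2:
        warnings.warn(
            f"window thermal width {width:.3f} Å < spacing/2 = {spacing / 2:.3f} Å; "
            "histogram overlap may be insufficient",
            OverlapWarning,
            stacklevel=2,
        )
    mesh = np.meshgrid(*axes, indexing="ij")
    return [tuple(float(m[idx]) for m in mesh) for idx in np.ndindex(mesh[0].shape)]


def _grid_edges(
    ranges: Sequence[tuple[float, float]], bin_width: float
) -> tuple[np.ndarray, ...]:
    return tuple(
        np.arange(lo - 0.5 * bin_width, hi + bin_width, bin_width) for lo, hi in ranges
    )


def harvest_window(
    landscape: LandscapeSpec,
    center: Sequence[float],
    k_umb: float,
    config: SimConfig,
    n_frames: int,
    edges: tuple[np.ndarray, ...],
    burn_in: float = 0.1,
    stride: int = 5,
    stream: int = 0,
) -> UmbrellaWindow:
    """Harvest one window (see :func:`harvest_windows` for the batch form)."""
    return harvest_windows(
        landscape, [tuple(center)], k_umb, config, n_frames, edges,
        burn_in=burn_in, stride=stride, stream_offset=stream,
    )[0]


def harvest_windows(
    landscape: LandscapeSpec,
    centers: Sequence[tuple[float, ...]],
    k_umb: float,
    config: SimConfig,
    n_frames: int,
    edges: tuple[np.ndarray, ...],
    burn_in: float = 0.1,
    stride: int = 5,
    stream_offset: int = 0,
) -> list[UmbrellaWindow]:
    """Run biased Brownian sampling in every window (as one walker batch).

    1D windows bias the z coordinate of a single ion; 2D windows bias
    (z1, z2) of a two-ion system.  Returns filled histograms over the
    shared grid defined by ``edges``.
    """
    ndim = len(edges)
    if ndim not in (1, 2):
        raise ValueError("only 1D and 2D umbrella sampling supported")
    config.check_stability(
        k_umb
        + max((abs(f.depth) / f.width**2 for f in landscape.axial_features), default=0.0)
    )
    n_win = len(centers)
    cvec = np.asarray(centers, dtype=float).reshape(n_win, ndim)
    pos = np.zeros((n_win, ndim, 3))
    pos[:, :, 2] = cvec
    if ndim == 2:  # keep the pair from overlapping at start
        pos[:, 0, 0] = 2.0
        pos[:, 1, 0] = -2.0

    def bias(p: np.ndarray) -> np.ndarray:
        f = np.zeros_like(p)
        f[:, :ndim, 2] = -k_umb * (p[:, :ndim, 2] - cvec)
        return f

    rng = stream_rng(config.seed, 1000 + stream_offset)
    n_burn = int(np.ceil(burn_in * n_frames))
    total_steps = (n_frames + n_burn) * stride
    _, rec = run_brownian(
        landscape, config, pos, total_steps, rng, bias_force=bias, record_stride=stride
    )
    assert rec is not None
    zs = rec[n_burn:, :, :ndim, 2]  # (T, W, ndim)
    windows = []
    for w in range(n_win):
        if ndim == 1:
            counts, _ = np.histogram(zs[:, w, 0], bins=edges[0])
        else:
            counts, _, _ = np.histogram2d(zs[:, w, 0], zs[:, w, 1], bins=edges)
        if counts.sum() == 0:
            raise RuntimeError(f"window {centers[w]} produced no accepted frames")
        windows.append(UmbrellaWindow(tuple(cvec[w]), (k_umb,) * ndim, counts))
    return windows


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    temperature: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    edges: Optional[tuple[np.ndarray, ...]] = None,
) -> PMFGrid:
    """Self-consistent WHAM solution over the windows' shared grid.

    ``edges`` must be supplied (the shared grid the histograms were filled
    on).  Iterates until max |Δf_k| < tol (kcal/mol); a result that hits
    ``max_iter`` first is returned flagged ``converged=False``.
    """
    if not windows:
        raise ValueError("need at least one window")
    if edges is None:
        raise ValueError("edges of the shared grid are required")
    kt = K_B * temperature
    grids = tuple(0.5 * (e[1:] + e[:-1]) for e in edges)
    shape = tuple(len(g) for g in grids)
    K = len(windows)
    H = np.stack([w.counts.reshape(-1) for w in windows])  # (K, M)
    N = np.array([w.N for w in windows])
    U = np.stack([w.bias_energy(grids).reshape(-1) for w in windows])  # (K, M)
    h_tot = H.sum(axis=0)
    sampled = h_tot > 0

    logc = -U / kt  # (K, M)
    logf = np.zeros(K)  # log f̂_k = f_k/kT up to sign convention
    logN = np.log(N)
    with np.errstate(divide="ignore"):
        logh = np.where(sampled, np.log(np.where(sampled, h_tot, 1.0)), -np.inf)

    from scipy.special import logsumexp

    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsum_k [logN + logf + logc]
        denom = logsumexp(logN[:, None] + logf[:, None] + logc, axis=0)
        logP = np.where(sampled, logh - denom, -np.inf)
        logP -= logsumexp(logP[sampled])
        new_logf = -logsumexp(logP[None, sampled] + logc[:, sampled], axis=1)
        residual = float(np.max(np.abs(new_logf - logf)) * kt)
        logf = new_logf
        if residual < tol:
            break
    converged = residual < tol

    # disjoint windows: relative free-energy offsets between disconnected
    # sampled regions are undetermined, so the solution is not trustworthy
    if K > 1:
        parent = list(range(K))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        support = [H[k] > 0 for k in range(K)]
        for a in range(K):
            for b in range(a + 1, K):
                if np.any(support[a] & support[b]):
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb
        if len({find(k) for k in range(K)}) > 1:
            converged = False

    pmf = np.full(np.prod(shape), np.nan)
    pmf[sampled] = -kt * logP[sampled]
    pmf = pmf.reshape(shape)
    grid = PMFGrid.from_array(
        edges, pmf, temperature=temperature, converged=converged,
        iterations=it, residual=residual,
    )
    return grid


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass
class Minimum:
    """A local minimum of a 2D PMF grid."""

    index: tuple[int, int]
    coords: tuple[float, float]
    value: float
    prominence: float
    is_global: bool

    @property
    def same_z(self) -> bool:
        return abs(self.coords[0] - self.coords[1]) <= 1.0


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _local_minima(values: np.ma.MaskedArray) -> list[tuple[int, int]]:
    """Bins strictly below all 8 neighbours (ties broken lexicographically).

    A candidate needs its complete 8-neighbourhood present and unmasked:
    grid-boundary bins and bins touching unsampled territory cannot be
    certified as minima and are skipped.
    """
    ni, nj = values.shape
    out = []
    filled = values.filled(np.inf)
    mask = np.ma.getmaskarray(values)
    for i in range(1, ni - 1):
        for j in range(1, nj - 1):
            if mask[i, j]:
                continue
            v = filled[i, j]
            ok = True
            for di, dj in _NEIGHBORS:
                a, b = i + di, j + dj
                if mask[a, b]:
                    ok = False
                    break
                if filled[a, b] < v or (filled[a, b] == v and (a, b) < (i, j)):
                    ok = False
                    break
            if ok:
                out.append((i, j))
    return out


def _bottleneck_value(
    filled: np.ndarray, start: tuple[int, int], targets: set[tuple[int, int]]
) -> float:
    """Minimax (bottleneck) energy from start to the nearest target set."""
    ni, nj = filled.shape
    best = np.full((ni, nj), np.inf)
    h = [(filled[start], start)]
    best[start] = filled[start]
    while h:
        b, (i, j) = heapq.heappop(h)
        if (i, j) in targets:
            return b
        if b > best[i, j]:
            continue
        for di, dj in _NEIGHBORS:
            a, c = i + di, j + dj
            if 0 <= a < ni and 0 <= c < nj and np.isfinite(filled[a, c]):
                nb = max(b, filled[a, c])
                if nb < best[a, c]:
                    best[a, c] = nb
                    heapq.heappush(h, (nb, (a, c)))
    return np.inf


def find_stationary_points(grid: PMFGrid, min_depth: float = 0.3) -> list[Minimum]:
    """Local minima of a 2D PMF, ordered by depth (deepest first).

    A bin is a candidate when it lies below all unmasked 8-neighbours; it is
    retained when its prominence — the bottleneck saddle toward any deeper
    minimum minus its own value — is at least ``min_depth``.  The deepest
    minimum is labelled global and always retained.
    """
    if grid.ndim != 2:
        raise ValueError("find_stationary_points requires a 2D grid")
    values = grid.values
    if np.ma.getmaskarray(values).all():
        raise ValueError("grid is entirely masked")
    cand = _local_minima(values)
    filled = values.filled(np.inf)
    order = sorted(cand, key=lambda ij: filled[ij])
    cx, cy = grid.centers
    out: list[Minimum] = []
    for rank, ij in enumerate(order):
        deeper = {p for p in order if filled[p] < filled[ij]}
        if deeper:
            saddle = _bottleneck_value(filled, ij, deeper)
            prom = saddle - filled[ij]
        else:
            prom = np.inf
        if rank == 0 or prom >= min_depth:
            out.append(
                Minimum(
                    index=ij,
                    coords=(float(cx[ij[0]]), float(cy[ij[1]])),
                    value=float(filled[ij]),
                    prominence=float(prom),
                    is_global=rank == 0,
                )
            )
    return out


def minimum_energy_path(
    grid: PMFGrid, start: tuple[int, int], end: tuple[int, int]
) -> PathResult:
    """Bottleneck-optimal path between two unmasked nodes of a 2D grid.

    Minimizes the maximum energy along the path (8-connected); among
    bottleneck-equal paths the shortest is chosen, then lexicographic node
    order, so the result is deterministic.  ``barrier`` is max(path energy)
    − energy(start).
    """
    if grid.ndim != 2:
        raise ValueError("minimum_energy_path requires a 2D grid")
    filled = grid.values.filled(np.inf)
    for node, name in ((start, "start"), (end, "end")):
        if not np.isfinite(filled[node]):
            raise ValueError(f"{name} node {node} is masked")
    ni, nj = filled.shape
    # Dijkstra on (bottleneck, length) lexicographic cost
    best: dict[tuple[int, int], tuple[float, int]] = {start: (filled[start], 0)}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    h = [(filled[start], 0, start)]
    while h:
        b, length, node = heapq.heappop(h)
        if node == end:
            break
        if (b, length) > best.get(node, (np.inf, 0)):
            continue
        i, j = node
        for di, dj in _NEIGHBORS:
            a, c = i + di, j + dj
            if not (0 <= a < ni and 0 <= c < nj) or not np.isfinite(filled[a, c]):
                continue
            cand = (max(b, filled[a, c]), length + 1)
            if cand < best.get((a, c), (np.inf, 0)):
                best[(a, c)] = cand
                prev[(a, c)] = node
                heapq.heappush(h, (cand[0], cand[1], (a, c)))
    if end not in best:
        raise ValueError(f"nodes {start} and {end} are disconnected")
    nodes = [end]
    while nodes[-1] != start:
        nodes.append(prev[nodes[-1]])
    nodes.reverse()
    energies = np.array([filled[n] for n in nodes])
    barrier = float(energies.max() - energies[0])
    cx, cy = grid.centers
    dz = [abs(cx[i] - cy[j]) for i, j in nodes]
    if all(d <= 1.0 for d in dz):
        label = "pathway-II-like"
    elif all(d > 1.0 for d in dz):
        label = "pathway-I-like knock-on"
    else:
        label = "mixed"
    return PathResult(nodes=nodes, energies=energies, barrier=barrier, label=label)


def classify_pair_configuration(z1: float, z2: float, delta: float = 1.0) -> str:
    """"pass-by" when the two ions share the axial coordinate within
    ``delta`` (boundary inclusive), else "knock-on"."""
    if not np.isfinite(z1) or not np.isfinite(z2):
        raise ValueError("coordinates must be finite")
    return "pass-by" if abs(z1 - z2) <= delta else "knock-on"
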