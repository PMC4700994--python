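"""Overdamped Langevin (Brownian) dynamics of ions on a model landscape.

The integrator is Euler–Maruyama without inertia: each coordinate advances
by (D/k_BT)·F·dt plus, when noise is enabled, a Gaussian increment of
variance 2·D·dt.  Ion motion in a narrow filter is diffusive at the
timescales analysed here, so this is the simplest dynamics whose stationary
distribution is the Boltzmann weight of the landscape — which is exactly
what the free-energy estimators downstream assume.

Randomness follows a counter-based contract: every independent stream
(replica, window, walker set) draws from ``numpy`` ``SeedSequence(master,
spawn_key=(stream,))`` so replica sets are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import K_B
from .landscape import LandscapeSpec, energy_forces

__all__ = [
    "SimConfig",
    "Trajectory",
    "step_overdamped",
    "run_brownian",
    "sample_equilibrium",
    "generate_solvent_points",
    "stream_rng",
]

#: dimensionless stability bound on k_max·D·dt/k_BT
STABILITY_LIMIT = 0.1


class PropagationError(RuntimeError):
    """Raised when a non-finite force would propagate a walker."""


@dataclass(frozen=True)
class SimConfig:
    """Dynamics parameters (Å²/ps, ps, K)."""

    temperature: float = 300.0
    diffusion: float = 0.2
    timestep: float = 0.01
    seed: int = 0
    recording_interval: float = 0.1
    noise_enabled: bool = True
    #: optional reflecting boundaries on z, e.g. (-25.0, 10.0)
    z_bounds: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.recording_interval < self.timestep:
            raise ValueError("recording_interval must be >= timestep")

    @property
    def kT(self) -> float:
        return K_B * self.temperature

    @property
    def mobility(self) -> float:
        """D/k_BT, Å²/(ps·kcal/mol)."""
        return self.diffusion / self.kT

    def check_stability(self, k_max: float) -> None:
        """Abort if the stiffest harmonic term would destabilise the update."""
        q = k_max * self.diffusion * self.timestep / self.kT
        if q >= STABILITY_LIMIT:
            raise ValueError(
                f"stability bound violated: k·D·dt/kBT = {q:.3g} >= {STABILITY_LIMIT} "
                f"(k_max={k_max}, dt={self.timestep})"
            )

    @property
    def record_stride(self) -> int:
        return max(1, int(round(self.recording_interval / self.timestep)))


@dataclass
class Trajectory:
    """Recorded frames for one walker: times (T,), positions (T, N, 3)."""

    times: np.ndarray
    positions: np.ndarray
    species: tuple[str, ...]
    step_index: Optional[np.ndarray] = None  # pulling-step label per frame
    replica: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("positions must be (T, N, 3) matching times")
        if len(self.species) != self.positions.shape[1]:
            raise ValueError("one species tag per ion required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_ions(self) -> int:
        return self.positions.shape[1]

    def z(self, ion: int) -> np.ndarray:
        return self.positions[:, ion, 2]


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for stream ``stream`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _reflect(pos: np.ndarray, bounds: Optional[tuple[float, float]]) -> None:
    if bounds is None:
        return
    lo, hi = bounds
    z = pos[..., 2]
    # a single reflection suffices for steps far smaller than the box
    np.copyto(z, np.where(z < lo, 2 * lo - z, z))
    np.copyto(z, np.where(z > hi, 2 * hi - z, z))


def step_overdamped(
    positions: np.ndarray,
    config: SimConfig,
    forces: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    time: float = 0.0,
) -> np.ndarray:
    """One Euler–Maruyama update of a batch of walkers.

    ``positions`` and ``forces`` have shape (W, N, 3) (or (N, 3)).  With
    noise disabled the update is the deterministic drift (D/k_BT)·F·dt.
    """
    pos = np.array(positions, dtype=float)
    f = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(f)):
        bad = np.argwhere(~np.isfinite(f))
        ion = int(bad[0][-2]) if f.ndim >= 2 else 0
        raise PropagationError(
            f"non-finite force on ion {ion} at t = {time:g} ps"
        )
    pos += config.mobility * f * config.timestep
    if config.noise_enabled:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        pos += rng.normal(0.0, np.sqrt(2 * config.diffusion * config.timestep), pos.shape)
    _reflect(pos, config.z_bounds)
    return pos


def run_brownian(
    spec: LandscapeSpec,
    config: SimConfig,
    positions: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    bias_force: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    record_stride: Optional[int] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Propagate walkers ``n_steps`` steps; optionally record every
    ``record_stride`` steps.

    Returns (final positions (W, N, 3), recorded (T, W, N, 3) or None).
    The bias callback receives positions and returns extra forces, letting
    pulling restraints and umbrella biases reuse the same integrator.
    """
    pos = np.array(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    mob_dt = config.mobility * config.timestep
    sigma = np.sqrt(2 * config.diffusion * config.timestep) if config.noise_enabled else 0.0
    frames = [] if record_stride else None
    for step in range(1, n_steps + 1):
        _, f = energy_forces(spec, pos)
        if bias_force is not None:
            f = f + bias_force(pos)
        if not np.all(np.isfinite(f)):
            raise PropagationError(
                f"non-finite force at step {step} (t = {step * config.timestep:g} ps)"
            )
        pos += mob_dt * f
        if sigma:
            pos += rng.normal(0.0, sigma, pos.shape)
        _reflect(pos, config.z_bounds)
        if frames is not None and step % record_stride == 0:
            frames.append(pos.copy())
    rec = np.array(frames) if frames is not None else None
    return pos, rec


def sample_equilibrium(
    spec: LandscapeSpec,
    config: SimConfig,
    n_frames: int,
    z_range: tuple[float, float],
    bin_width: float = 0.5,
    n_walkers: int = 50,
    burn_in: float = 0.1,
    stride: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased sampling of a single ion; returns an axial histogram.

    ``n_frames`` recorded samples are pooled over ``n_walkers`` independent
    walkers after discarding a ``burn_in`` fraction; −k_BT·ln(histogram)
    reproduces U0(z) up to a constant within sampling error (the Boltzmann
    check of the integrator).

    Returns (counts, bin_edges).
    """
    if n_frames < 1_000:
        raise ValueError(
            f"n_frames = {n_frames} is too small for a meaningful histogram; "
            "use at least 1000 (pooled over walkers)"
        )
    lo, hi = z_range
    cfg = replace(config, z_bounds=(lo, hi))
    rng = stream_rng(cfg.seed, 0)
    per_walker = int(np.ceil(n_frames / n_walkers))
    total_rec = int(np.ceil(per_walker / (1.0 - burn_in)))
    pos0 = np.zeros((n_walkers, 1, 3))
    pos0[:, 0, 2] = rng.uniform(lo, hi, n_walkers)
    _, rec = run_brownian(
        spec, cfg, pos0, n_steps=total_rec * stride, rng=rng, record_stride=stride
    )
    assert rec is not None
    zs = rec[int(burn_in * total_rec):, :, 0, 2].ravel()[:n_frames]
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    counts, edges = np.histogram(zs, bins=edges)
    return counts, edges


def generate_solvent_points(
    radius: float,
    z_range: tuple[float, float],
    density: float,
    seed: int = 0,
    stream: int = 0,
) -> np.ndarray:
    """Uniform "solvent" points in a cylinder around the pore axis.

    The count is Poisson(density·volume); bulk water corresponds to about
    0.033 points/Å³.  Returns an (M, 3) array (possibly empty).
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if density < 0:
        raise ValueError("density must be >= 0")
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("z_range must have positive extent")
    rng = stream_rng(seed, stream)
    volume = np.pi * radius**2 * (hi - lo)
    m = rng.poisson(density * volume)
    r = radius * np.sqrt(rng.uniform(0, 1, m))
    theta = rng.uniform(0, 2 * np.pi, m)
    pts = np.empty((m, 3))
    pts[:, 0] = r * np.cos(theta)
    pts[:, 1] = r * np.sin(theta)
    pts[:, 2] = rng.uniform(lo, hi, m)
    return pts
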