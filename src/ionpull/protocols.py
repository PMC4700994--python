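"""Canonical study protocols: the pulling schedules and simulation settings
used by the shipped analyses.

The inward protocol steps the restraint center from λ = −20 Å to −2 Å in
1.0 Å increments (19 steps); the outward protocol runs from 4.5 Å to
−17.5 Å in −1.0 Å increments (23 steps).  Relaxation times map the
all-atom values (0.5 ns fast / 3 ns slow) onto simulator time through a
single constant of 1/100 — Brownian ions on a smooth model landscape
decorrelate about two orders of magnitude faster than ions in an explicit
filter — giving τ = 5 ps (fast) and 30 ps (slow).
"""

from __future__ import annotations

import numpy as np

from .analysis import AsymmetryReport, asymmetry_summary, detect_block, pair_density
from .dynamics import SimConfig
from .jarzynski import FreeEnergyProfile, profiles_from_result
from .landscape import LandscapeSpec
from .pulling import PullSpec, run_pulling

__all__ = [
    "TIME_MAPPING",
    "TAU_FAST",
    "TAU_SLOW",
    "default_sim_config",
    "inward_pair_spec",
    "outward_pair_spec",
    "run_direction",
    "asymmetry_study",
]

#: simulator time per all-atom nanosecond-scale time (dimensionless factor)
TIME_MAPPING = 0.01
#: fast protocol relaxation (≙ 0.5 ns), ps
TAU_FAST = 5.0
#: slow protocol relaxation (≙ 3 ns), ps
TAU_SLOW = 30.0


def default_sim_config(seed: int = 0) -> SimConfig:
    """Default Brownian dynamics settings for the shipped protocols."""
    return SimConfig(seed=seed, temperature=300.0, diffusion=0.2, timestep=0.01)


def inward_pair_spec(
    seed: int = 0,
    n_replicas: int = 64,
    relaxation_time: float = TAU_SLOW,
    k_axial: float = 0.6,
    k_lateral: float = 0.6,
) -> PullSpec:
    """Two ions pulled inward from the extracellular side (λ: −20 → −2).

    Both ions start at the same extracellular coordinate z = −20 Å, side by
    side across the axis — the configuration a concentration gradient feeds
    toward the filter mouth.
    """
    return PullSpec(
        k_axial=k_axial,
        k_lateral=k_lateral,
        lambda_start=-20.0,
        lambda_increment=1.0,
        n_steps=19,
        relaxation_time=relaxation_time,
        initial_placement=np.array([[1.2, 0.0, -20.0], [-1.2, 0.0, -20.0]]),
        n_replicas=n_replicas,
        recording_interval=0.5,
        seed=seed,
    )


def outward_pair_spec(
    seed: int = 0,
    n_replicas: int = 64,
    relaxation_time: float = TAU_SLOW,
    k_axial: float = 0.6,
    k_lateral: float = 0.6,
) -> PullSpec:
    """Two ions pulled outward from the cavity (λ: 4.5 → −17.5).

    The ions start single file on the cavity side, as a pair arriving from
    the central cavity does.
    """
    return PullSpec(
        k_axial=k_axial,
        k_lateral=k_lateral,
        lambda_start=4.5,
        lambda_increment=-1.0,
        n_steps=23,
        relaxation_time=relaxation_time,
        initial_placement=np.array([[0.0, 0.0, 3.0], [0.0, 0.0, 6.0]]),
        n_replicas=n_replicas,
        recording_interval=0.5,
        seed=seed,
    )


def run_direction(
    landscape: LandscapeSpec,
    direction: str,
    seed: int = 0,
    n_replicas: int = 64,
    relaxation_time: float = TAU_SLOW,
):
    """Run one pulling direction; returns the :class:`PullResult`."""
    maker = {"inward": inward_pair_spec, "outward": outward_pair_spec}[direction]
    spec = maker(seed=seed, n_replicas=n_replicas, relaxation_time=relaxation_time)
    return run_pulling(landscape, spec, default_sim_config(seed))


def asymmetry_study(
    landscape: LandscapeSpec,
    seed: int = 0,
    n_replicas: int = 64,
    relaxation_time: float = TAU_SLOW,
    delta_diag: float = 1.0,
    theta_occ: float = 0.2,
) -> dict:
    """Matched inward/outward pulling with block detection and work summary.

    Returns a dict with per-direction BlockReports, FreeEnergyProfiles and
    the AsymmetryReport — the module-level restatement of the potassium
    block's direction dependence.
    """
    out: dict = {}
    profiles: dict[str, FreeEnergyProfile] = {}
    for direction in ("inward", "outward"):
        result = run_direction(
            landscape, direction, seed=seed, n_replicas=n_replicas,
            relaxation_time=relaxation_time,
        )
        pmap = pair_density(result.trajectories, bin_width=0.5).symmetrized()
        out[f"block_{direction}"] = detect_block(pmap, delta_diag, theta_occ)
        profiles[direction] = profiles_from_result(result, 300.0)
        out[f"profile_{direction}"] = profiles[direction]
    out["asymmetry"] = asymmetry_summary(profiles["inward"], profiles["outward"])
    return out
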