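"""Model free-energy landscapes for ions in a narrow channel.

A :class:`LandscapeSpec` is the ground truth everything downstream is
validated against.  It combines

* an axial potential U0(z): a sum of Gaussian wells/barriers standing in
  for the binding sites of a selectivity filter,
* harmonic lateral confinement toward the pore axis,
* a screened ion–ion repulsion A·exp(−r/ℓ)/r (waters screen the bare
  Coulomb interaction implicitly), soft-core clamped below r = 1 Å, and
* optional "coordination" wells that are active only when two ions sit
  near the same axial coordinate — these create side-by-side ("pass-by")
  pair minima of the kind a hydrogen-bonded glutamate/serine network offers
  to potassium pairs, and are absent for a sodium-like species.

Energies are kcal/mol, lengths Å.  Forces are analytic gradients; the test
suite checks them against central differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AxialFeature",
    "CoordinationFeature",
    "LandscapeSpec",
    "evaluate_landscape",
    "pair_surface",
    "k_like_preset",
    "na_like_preset",
    "flat_preset",
    "single_well_preset",
    "double_well_preset",
]

#: pair distance (Å) below which the screened repulsion is clamped
R_CORE = 1.0


@dataclass(frozen=True)
class AxialFeature:
    """One Gaussian term of U0(z): depth<0 is a well, depth>0 a barrier."""

    center: float
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"feature width must be > 0, got {self.width}")


@dataclass(frozen=True)
class CoordinationFeature:
    """A pair well active when two ions are near the same z.

    The term is depth · exp(−(z̄−z_center)²/2w²) · exp(−Δz²/2t²) with
    z̄ the pair mean coordinate and Δz the axial separation; ``t`` is the
    same-z tolerance.
    """

    z_center: float
    depth: float
    width: float
    same_z_tolerance: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.same_z_tolerance <= 0:
            raise ValueError("coordination width and tolerance must be > 0")


@dataclass(frozen=True)
class LandscapeSpec:
    species_label: str
    axial_features: tuple[AxialFeature, ...] = ()
    lateral_k: float = 0.2
    pair_amplitude: float = 0.0
    pair_screening: float = 3.0
    coordination_features: tuple[CoordinationFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.pair_screening <= 0:
            raise ValueError("pair_screening must be > 0")
        if self.pair_amplitude < 0:
            raise ValueError("pair_amplitude must be >= 0")

    # -- single-ion axial potential -------------------------------------
    def axial_energy(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for f in self.axial_features:
            u += f.depth * np.exp(-((z - f.center) ** 2) / (2.0 * f.width**2))
        return u

    def pair_energy(self, r: np.ndarray) -> np.ndarray:
        """Screened repulsion V(r), clamped to its r = R_CORE value below."""
        r = np.asarray(r, dtype=float)
        rc = np.maximum(r, R_CORE)
        return self.pair_amplitude * np.exp(-rc / self.pair_screening) / rc


class UnsupportedConfigurationError(ValueError):
    """Raised for ion counts the model does not support (must be 1–3)."""


def _check_positions(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    if pos.ndim != 3 or pos.shape[-1] != 3:
        raise ValueError(f"positions must have shape (..., n_ions, 3), got {pos.shape}")
    n_ions = pos.shape[-2]
    if not 1 <= n_ions <= 3:
        raise UnsupportedConfigurationError(
            f"landscape supports 1-3 ions, got {n_ions}"
        )
    return pos


def energy_forces(
    spec: LandscapeSpec, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Total energy and analytic forces for a batch of walkers.

    Parameters
    ----------
    positions : array, shape (W, N, 3) or (N, 3)

    Returns
    -------
    energy : (W,) kcal/mol, forces : (W, N, 3) kcal/mol/Å
    """
    pos = _check_positions(positions)
    w, n, _ = pos.shape
    energy = np.zeros(w)
    forces = np.zeros_like(pos)

    x, y, z = pos[..., 0], pos[..., 1], pos[..., 2]

    # axial Gaussians
    for f in spec.axial_features:
        g = f.depth * np.exp(-((z - f.center) ** 2) / (2.0 * f.width**2))
        energy += g.sum(axis=-1)
        forces[..., 2] += g * (z - f.center) / f.width**2

    # lateral confinement
    energy += 0.5 * spec.lateral_k * (x**2 + y**2).sum(axis=-1)
    forces[..., 0] -= spec.lateral_k * x
    forces[..., 1] -= spec.lateral_k * y

    # pair terms
    for i in range(n):
        for j in range(i + 1, n):
            dvec = pos[:, i] - pos[:, j]
            r = np.linalg.norm(dvec, axis=-1)
            if spec.pair_amplitude > 0:
                rc = np.maximum(r, R_CORE)
                v = spec.pair_amplitude * np.exp(-rc / spec.pair_screening) / rc
                energy += v
                # dV/dr = -V (1/ℓ + 1/r); zero inside the soft core
                dvdr = np.where(
                    r > R_CORE, -v * (1.0 / spec.pair_screening + 1.0 / rc), 0.0
                )
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = np.where(r[:, None] > 0, dvec / np.maximum(r, 1e-12)[:, None], 0.0)
                forces[:, i] -= dvdr[:, None] * unit
                forces[:, j] += dvdr[:, None] * unit
            for c in spec.coordination_features:
                zbar = 0.5 * (z[:, i] + z[:, j])
                dz = z[:, i] - z[:, j]
                u = (
                    c.depth
                    * np.exp(-((zbar - c.z_center) ** 2) / (2.0 * c.width**2))
                    * np.exp(-(dz**2) / (2.0 * c.same_z_tolerance**2))
                )
                energy += u
                du_dzbar = -u * (zbar - c.z_center) / c.width**2
                du_ddz = -u * dz / c.same_z_tolerance**2
                forces[:, i, 2] -= 0.5 * du_dzbar + du_ddz
                forces[:, j, 2] -= 0.5 * du_dzbar - du_ddz

    return energy, forces


def evaluate_landscape(
    spec: LandscapeSpec, positions: np.ndarray
) -> tuple[float, np.ndarray, dict[str, float]]:
    """Energy, force and a per-term breakdown for a single configuration.

    Returns ``(energy, force (N, 3), breakdown)`` where the breakdown maps
    term names (axial / lateral / pair / coordination) to energies whose sum
    equals the total to 1e-10.
    """
    pos = _check_positions(positions)
    if pos.shape[0] != 1:
        raise ValueError("evaluate_landscape expects a single configuration")
    energy, forces = energy_forces(spec, pos)

    x, y, z = pos[0, :, 0], pos[0, :, 1], pos[0, :, 2]
    axial = float(spec.axial_energy(z).sum())
    lateral = float(0.5 * spec.lateral_k * (x**2 + y**2).sum())
    pair = 0.0
    coord = 0.0
    n = pos.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[0, i] - pos[0, j]))
            pair += float(spec.pair_energy(r))
            for c in spec.coordination_features:
                zbar = 0.5 * (z[i] + z[j])
                dz = z[i] - z[j]
                coord += float(
                    c.depth
                    * np.exp(-((zbar - c.z_center) ** 2) / (2.0 * c.width**2))
                    * np.exp(-(dz**2) / (2.0 * c.same_z_tolerance**2))
                )
    breakdown = {"axial": axial, "lateral": lateral, "pair": pair, "coordination": coord}
    return float(energy[0]), forces[0], breakdown


# ---------------------------------------------------------------------------
# reduced two-ion axial surface
# ---------------------------------------------------------------------------

def effective_pair_repulsion(
    spec: LandscapeSpec, dz: np.ndarray, d_max: float = 10.0, n_d: int = 201
) -> np.ndarray:
    """Screened repulsion at axial separation ``dz``, relaxed over the
    lateral separation the confinement allows.

    Two confined ions at the same z can still move apart side-by-side; the
    optimal lateral separation d minimizes V(√(Δz²+d²)) + lateral_k·d²/4
    (each ion displaced d/2 off axis).  This is the repulsion entering the
    reduced (z1, z2) surface.
    """
    dz = np.abs(np.asarray(dz, dtype=float))
    d = np.linspace(0.0, d_max, n_d)
    r = np.sqrt(dz[..., None] ** 2 + d**2)
    total = spec.pair_energy(r) + spec.lateral_k * d**2 / 4.0
    return total.min(axis=-1)


def pair_surface(spec: LandscapeSpec, z_grid: np.ndarray) -> np.ndarray:
    """Reduced two-ion surface U2(z1, z2) on ``z_grid`` × ``z_grid``.

    U2 = U0(z1) + U0(z2) + V_eff(|z1−z2|) + coordination terms.  This is the
    analytic ground truth whose topology (same-z "pass-by" minima vs
    off-diagonal "knock-on" channels) the 2D WHAM reconstruction must
    recover.
    """
    z = np.asarray(z_grid, dtype=float)
    z1, z2 = np.meshgrid(z, z, indexing="ij")
    u = spec.axial_energy(z1) + spec.axial_energy(z2)
    u += effective_pair_repulsion(spec, z1 - z2)
    for c in spec.coordination_features:
        zbar = 0.5 * (z1 + z2)
        dz = z1 - z2
        u += (
            c.depth
            * np.exp(-((zbar - c.z_center) ** 2) / (2.0 * c.width**2))
            * np.exp(-(dz**2) / (2.0 * c.same_z_tolerance**2))
        )
    return u


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def flat_preset(lateral_k: float = 0.2) -> LandscapeSpec:
    """Featureless axial landscape (lateral confinement only)."""
    return LandscapeSpec("flat", (), lateral_k, 0.0, 3.0, ())


def single_well_preset(
    center: float = -10.0, depth: float = -2.0, width: float = 1.5
) -> LandscapeSpec:
    return LandscapeSpec(
        "single-well", (AxialFeature(center, depth, width),), 0.2, 0.0, 3.0, ()
    )


def double_well_preset(
    centers: tuple[float, float] = (-12.0, -6.0),
    depths: tuple[float, float] = (-3.0, -2.0),
    width: float = 1.2,
) -> LandscapeSpec:
    """Asymmetric axial double well with the barrier between the wells."""
    return LandscapeSpec(
        "double-well",
        (
            AxialFeature(centers[0], depths[0], width),
            AxialFeature(centers[1], depths[1], width),
        ),
        0.2,
        0.0,
        3.0,
        (),
    )


#: shared channel skeleton: an extracellular vestibule, a cavity-side
#: "turnstile" binding site that keeps an exiting pair in single file, and a
#: wide cavity well — in a pore narrow enough (lateral_k = 2 kcal/mol/Å²)
#: that two ions at the same z pay several k_BT of screened repulsion.
_VESTIBULE = AxialFeature(-18.0, -3.0, 3.0)
_TURNSTILE = AxialFeature(-5.5, -1.5, 1.2)
_CAVITY = AxialFeature(-1.0, -1.8, 2.5)


def na_like_preset() -> LandscapeSpec:
    """Sodium-like species: an attractive filter with no same-z wells.

    The screened pair repulsion in the narrow pore keeps two ions staggered
    by ~3 Å, so permeation runs through off-diagonal "knock-on" channels
    only; the reduced (z1, z2) surface has no pass-by (same-z) minima and
    no block forms in either pulling direction.
    """
    return LandscapeSpec(
        species_label="Na-like",
        axial_features=(
            AxialFeature(-10.0, -2.0, 3.0),
            AxialFeature(-5.5, -2.2, 1.2),
            _VESTIBULE,
            _CAVITY,
        ),
        lateral_k=2.0,
        pair_amplitude=20.0,
        pair_screening=3.0,
        coordination_features=(),
    )


def k_like_preset() -> LandscapeSpec:
    """Potassium-like species: weak single-ion binding plus same-z pair wells.

    Two coordination wells sit on the pass-by diagonal of the (z1, z2)
    surface: a deep, narrowly gated one in mid-filter (the global pair
    minimum X) and a wide-gated doorway at the filter entrance (the
    shallower, unstable minimum Y).  A pair pulled inward arrives at the
    entrance nearly side by side, drops through the Y doorway and slides
    along the diagonal into X, where it wedges — the block state, held in
    place by the applied force.  A pair approaching from the cavity stays
    staggered (turnstile plus repulsion), cannot cross the narrow X gate,
    and exits over the entrance into the vestibule with little extra work —
    the direction asymmetry of the potassium block.
    """
    return LandscapeSpec(
        species_label="K-like",
        axial_features=(
            AxialFeature(-10.0, -0.5, 3.0),
            _TURNSTILE,
            _VESTIBULE,
            _CAVITY,
        ),
        lateral_k=2.0,
        pair_amplitude=20.0,
        pair_screening=3.0,
        coordination_features=(
            CoordinationFeature(z_center=-10.0, depth=-11.0, width=1.6, same_z_tolerance=0.5),
            CoordinationFeature(z_center=-13.25, depth=-6.5, width=0.9, same_z_tolerance=1.2),
        ),
    )


PRESETS = {
    "flat": flat_preset,
    "single-well": single_well_preset,
    "double-well": double_well_preset,
    "Na-like": na_like_preset,
    "K-like": k_like_preset,
}
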