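"""Physical constants and exact unit conversions.

Working units throughout the package are Å, ps and kcal/mol.  The
conversions here connect pulling work (kcal/mol) to the quantities an
electrophysiologist reads off an I-V plot: membrane potentials (mV, per a
stated number of elementary charges) and mechanical forces (nN).

All conversions are linear and exactly invertible.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/mol/K.
K_B: float = 0.0019872

#: kcal/mol carried by one elementary charge across 1 V.
KCAL_PER_MOL_PER_EV: float = 23.0605

#: pN per kcal/mol/Å.
PN_PER_KCAL_MOL_PER_A: float = 69.48


def thermal_energy(temperature: float, multiple: float = 1) -> float:
    """Return ``multiple * k_B * T`` in kcal/mol.

    At 300 K one k_BT is 0.5962 kcal/mol; a 2 k_BT bias (≈1.2 kcal/mol)
    is the conventional "within thermal fluctuation" scale.
    """
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    return multiple * K_B * temperature


def potential_to_energy(millivolts: float, n_charges: int) -> float:
    """Energy (kcal/mol) gained by ``n_charges`` elementary charges crossing
    a membrane potential of ``millivolts``.  Sign is preserved: −100 mV with
    3 charges gives −6.9 kcal/mol.
    """
    if n_charges < 1:
        raise ValueError(f"n_charges must be >= 1, got {n_charges}")
    return n_charges * (millivolts / 1000.0) * KCAL_PER_MOL_PER_EV


def energy_to_potential(energy_kcal_mol: float, n_charges: int) -> float:
    """Membrane potential (mV) equivalent to ``energy_kcal_mol`` spread over
    ``n_charges`` elementary charges.  Exact inverse of
    :func:`potential_to_energy`.
    """
    if n_charges < 1:
        raise ValueError(f"n_charges must be >= 1, got {n_charges}")
    return 1000.0 * energy_kcal_mol / (n_charges * KCAL_PER_MOL_PER_EV)


def force_to_nN(force_kcal_mol_per_A: float) -> float:
    """Convert a force from kcal/mol/Å to nN (1 kcal/mol/Å = 0.06948 nN)."""
    return force_kcal_mol_per_A * PN_PER_KCAL_MOL_PER_A * 1e-3


def kT(temperature: float) -> float:
    """Shorthand for k_B·T in kcal/mol."""
    return thermal_energy(temperature)
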