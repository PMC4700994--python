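"""Jarzynski free-energy estimation from step-wise pulling work ledgers.

Jarzynski's equality, exp(−ΔF/k_BT) = ⟨exp(−W/k_BT)⟩, converts a
distribution of nonequilibrium work samples into an equilibrium free-energy
change.  Here every λ-switch of the stepped protocol contributes one work
distribution; per-step estimates are accumulated into a "useful work"
profile ΔF(λ) anchored at 0 at the schedule origin.

The exponential average is computed through an overflow-safe
log-sum-exp.  The per-step statistical uncertainty uses the variance
formula  [σ²_W/Q + σ⁴_W (k_BT)⁻² / 2(Q−1)]^{1/2}  (σ_W the work standard
deviation, Q the sample count) and is propagated across steps in
quadrature, ignoring step-to-step correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import K_B

__all__ = [
    "WorkDistribution",
    "FreeEnergyProfile",
    "estimate_delta_F",
    "variance_of_estimate",
    "profile_from_steps",
    "per_ion_step_components",
    "profiles_from_result",
]


@dataclass
class WorkDistribution:
    """Work samples of one pulling step (kcal/mol)."""

    step: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise ValueError("a work distribution needs Q >= 2 samples")

    @property
    def Q(self) -> int:
        return self.samples.size

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sigma(self) -> float:
        return float(self.samples.std(ddof=1))


@dataclass
class FreeEnergyProfile:
    """Cumulative ΔF(λ) with per-point uncertainty and optional per-ion
    components (components sum to the total at every λ)."""

    lambdas: np.ndarray
    dF: np.ndarray
    err: np.ndarray
    per_ion: Optional[np.ndarray] = None  # (n_points, n_ions)
    direction: str = "inward"

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dF = np.asarray(self.dF, dtype=float)
        self.err = np.asarray(self.err, dtype=float)
        if not (len(self.lambdas) == len(self.dF) == len(self.err)):
            raise ValueError("lambdas, dF and err must have equal length")
        if self.per_ion is not None:
            self.per_ion = np.asarray(self.per_ion, dtype=float)
            if self.per_ion.shape[0] != len(self.lambdas):
                raise ValueError("per_ion must have one row per λ")


def variance_of_estimate(sigma_w: float, Q: int, temperature: float) -> float:
    """Statistical uncertainty of a single-step Jarzynski estimate."""
    if Q < 2:
        raise ValueError("Q must be >= 2")
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    kt = K_B * temperature
    return float(np.sqrt(sigma_w**2 / Q + sigma_w**4 / kt**2 / (2 * (Q - 1))))


def estimate_delta_F(
    dist: WorkDistribution | np.ndarray | Sequence[float], temperature: float
) -> tuple[float, float]:
    """ΔF = −k_BT·ln[(1/Q)·Σ exp(−W_q/k_BT)] and its uncertainty.

    Exact property (Jensen): the estimate never exceeds the sample mean.
    """
    if not isinstance(dist, WorkDistribution):
        dist = WorkDistribution(step=0, samples=np.asarray(dist, dtype=float))
    kt = K_B * temperature
    w = dist.samples
    dF = -kt * (logsumexp(-w / kt) - np.log(w.size))
    return float(dF), variance_of_estimate(dist.sigma, dist.Q, temperature)


def profile_from_steps(
    step_dF: Sequence[float],
    step_err: Sequence[float],
    schedule: Sequence[float],
    direction: str = "inward",
    per_ion_steps: Optional[np.ndarray] = None,
) -> FreeEnergyProfile:
    """Accumulate per-step estimates into ΔF(λ) anchored at 0 at λ_0.

    ``step_dF`` has one entry per switch (len(schedule) − 1); uncertainties
    combine in quadrature.
    """
    schedule = np.asarray(schedule, dtype=float)
    step_dF = np.asarray(step_dF, dtype=float)
    step_err = np.asarray(step_err, dtype=float)
    if len(step_dF) != len(schedule) - 1 or len(step_err) != len(step_dF):
        raise ValueError(
            f"expected {len(schedule) - 1} per-step estimates for a "
            f"{len(schedule)}-point schedule, got {len(step_dF)}"
        )
    dF = np.concatenate([[0.0], np.cumsum(step_dF)])
    err = np.sqrt(np.concatenate([[0.0], np.cumsum(step_err**2)]))
    per_ion = None
    if per_ion_steps is not None:
        per_ion_steps = np.asarray(per_ion_steps, dtype=float)
        per_ion = np.vstack(
            [np.zeros(per_ion_steps.shape[1]), np.cumsum(per_ion_steps, axis=0)]
        )
    return FreeEnergyProfile(schedule, dF, err, per_ion, direction)


def per_ion_step_components(
    dW: np.ndarray,
    dW_ion: np.ndarray,
    temperature: float,
    independent: bool = False,
) -> np.ndarray:
    """Decompose one step's ΔF into per-ion components.

    Default weighting: exponential weights w_q ∝ exp(−ΔW_q/k_BT) from the
    *total* work are applied to the per-ion work, and the fluctuation part
    of the total estimate (ΔF − ⟨ΔW⟩_w) is shared equally, so components
    sum to the total estimate exactly:

        ΔF_j = ⟨ΔW_j⟩_w + (ΔF − ⟨ΔW⟩_w)/N.

    With ``independent=True`` each ion gets its own Jarzynski average of its
    own work (does not sum exactly to the total; kept for comparison).
    """
    dW = np.asarray(dW, dtype=float)
    dW_ion = np.asarray(dW_ion, dtype=float)
    if dW_ion.ndim != 2 or dW_ion.shape[0] != dW.size:
        raise ValueError("dW_ion must be (Q, n_ions) aligned with dW")
    kt = K_B * temperature
    if independent:
        return np.array(
            [-kt * (logsumexp(-dW_ion[:, j] / kt) - np.log(dW.size))
             for j in range(dW_ion.shape[1])]
        )
    logw = -dW / kt
    logw -= logsumexp(logw)
    w = np.exp(logw)
    mean_ion = w @ dW_ion
    dF_total = -kt * (logsumexp(-dW / kt) - np.log(dW.size))
    residual = dF_total - w @ dW
    return mean_ion + residual / dW_ion.shape[1]


def profiles_from_result(result, temperature: float) -> FreeEnergyProfile:
    """Full profile (total + per-ion components) from a pulling run.

    ``result`` is a :class:`ionpull.pulling.PullResult`; work increments are
    taken per replica per step (one cumulative work value per replica is the
    default sampling unit).
    """
    inc = result.increment_matrix()  # (R, S-1)
    inc_ion = result.per_ion_increment_matrix()  # (R, S-1, N)
    if inc.shape[0] < 2:
        raise ValueError("need at least 2 replicas to form work distributions")
    n_steps = inc.shape[1]
    step_dF = np.empty(n_steps)
    step_err = np.empty(n_steps)
    per_ion = np.empty((n_steps, inc_ion.shape[2]))
    for s in range(n_steps):
        step_dF[s], step_err[s] = estimate_delta_F(inc[:, s], temperature)
        per_ion[s] = per_ion_step_components(inc[:, s], inc_ion[:, s], temperature)
    direction = "inward" if result.spec.lambda_increment > 0 else "outward"
    return profile_from_steps(step_dF, step_err, result.schedule, direction, per_ion)
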