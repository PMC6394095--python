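"""Steady state and cost-benefit fitness of the one-regulator/one-target network.

The circuit: a regulator ``R`` is produced at a basal rate, converted by an
environmental signal ``S`` into its active form ``R*``, which activates
transcription of a target ``T`` through a dimer (Hill coefficient 2)
response.  Both regulator species are degraded/diluted at a first-order rate
``k_d``, the target at ``k_dT``:

    dR/dt  = bas - k_act*R*S + k_r*R* - k_d*R
    dR*/dt = k_act*R*S - k_r*R* - k_d*R*
    dT/dt  = beta * R*^2 / (K_m^2 + R*^2) - k_dT*T

Fitness is benefit minus cost at steady state:

    B = a*T/(T + b),   C = alpha*(T + R* + R),   F = B - C

The steady state is available in closed form (the R/R* subsystem is linear
and the target equation is explicit in T), so fitness evaluation is pure
arithmetic; numerical integration of the ODEs is provided as an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_KR_RATIO",
    "ParamSet",
    "EnvSignal",
    "SteadyState",
    "FitnessConstants",
    "FitnessComponents",
    "InvalidParameterError",
    "steady_state",
    "integrate_dynamics",
    "fitness",
    "genotype_fitness",
    "batch_fitness",
]

#: The six evolvable parameters, in genotype coordinate order.
PARAM_NAMES = ("bas", "k_act", "k_d", "beta", "K_m", "k_dT")

#: Default coupling of the back-conversion rate to the activation rate:
#: k_r = DEFAULT_KR_RATIO * k_act (the reverse reaction is slow).
DEFAULT_KR_RATIO = 1e-3


class InvalidParameterError(ValueError):
    """Raised when a rate parameter is non-finite or out of its domain."""


@dataclass(frozen=True)
class ParamSet:
    """One point in biochemical parameter space.

    Units follow the nM / minute convention: production rates in nM/min,
    first-order rates in 1/min, ``K_m`` in nM.  ``k_act`` is per signal unit
    per minute.  ``k_r`` is normally slaved to ``k_act`` (see
    :meth:`from_evolvable`) and is not an evolvable coordinate.
    """

    bas: float
    k_act: float
    k_d: float
    beta: float
    K_m: float
    k_dT: float
    k_r: float

    @classmethod
    def from_evolvable(
        cls,
        bas: float,
        k_act: float,
        k_d: float,
        beta: float,
        K_m: float,
        k_dT: float,
        kr_ratio: float = DEFAULT_KR_RATIO,
    ) -> "ParamSet":
        """Build a full parameter set from the six evolvable values."""
        return cls(bas, k_act, k_d, beta, K_m, k_dT, k_r=kr_ratio * k_act)

    def validate(self) -> None:
        vals = (self.bas, self.k_act, self.k_d, self.beta, self.K_m, self.k_dT, self.k_r)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {self}")
        # bas and beta are production rates and may legitimately vanish;
        # the kinetic rates and K_m must be strictly positive.
        if self.bas < 0 or self.beta < 0:
            raise InvalidParameterError("production rates must be >= 0")
        for name in ("k_act", "k_d", "K_m", "k_dT"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.k_r < 0:
            raise InvalidParameterError("k_r must be >= 0")

    def as_array(self) -> np.ndarray:
        """The six evolvable values in :data:`PARAM_NAMES` order."""
        return np.array(
            [self.bas, self.k_act, self.k_d, self.beta, self.K_m, self.k_dT]
        )


@dataclass(frozen=True)
class EnvSignal:
    """Constant environmental signal level activating the regulator."""

    S: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S) and self.S >= 0):
            raise InvalidParameterError("signal level must be finite and >= 0")


@dataclass(frozen=True)
class SteadyState:
    """Fixed point of the network dynamics (concentrations in nM)."""

    R: float
    R_star: float
    T: float


@dataclass(frozen=True)
class FitnessConstants:
    """Constants of the benefit/cost functions.

    ``a`` is the saturating benefit level, ``b`` the target concentration at
    half-maximal benefit, and ``alpha`` the fitness cost per steady-state
    molecule maintained.
    """

    a: float = 1.0
    b: float = 10.0
    alpha: float = 2.5e-5

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.alpha >= 0):
            raise InvalidParameterError("need a > 0, b > 0, alpha >= 0")

    def scaled(self, a_mult: float = 1.0, b_mult: float = 1.0, alpha_mult: float = 1.0
               ) -> "FitnessConstants":
        return FitnessConstants(self.a * a_mult, self.b * b_mult, self.alpha * alpha_mult)


@dataclass(frozen=True)
class FitnessComponents:
    B: float
    C: float
    F: float


def steady_state(p: ParamSet, env: EnvSignal = EnvSignal()) -> SteadyState:
    """Closed-form steady state of the R/R*/T dynamics.

    The regulator subsystem is linear in (R, R*); solving its balance
    equations gives

        R  = bas*(k_r + k_d) / (k_d*(k_r + k_d + k_act*S))
        R* = k_act*R*S / (k_r + k_d)

    and the target equation is then explicit:

        T  = (beta/k_dT) * R*^2 / (K_m^2 + R*^2)
    """
    p.validate()
    S = env.S
    denom = p.k_r + p.k_d
    R = p.bas * denom / (p.k_d * (denom + p.k_act * S))
    R_star = p.k_act * R * S / denom
    T = (p.beta / p.k_dT) * R_star**2 / (p.K_m**2 + R_star**2)
    return SteadyState(R=R, R_star=R_star, T=T)


def dynamics_rhs(t: float, y: Sequence[float], p: ParamSet, S: float) -> list[float]:
    """Right-hand side of the kinetic ODEs (time in minutes)."""
    R, R_star, T = y
    dR = p.bas - p.k_act * R * S + p.k_r * R_star - p.k_d * R
    dRs = p.k_act * R * S - p.k_r * R_star - p.k_d * R_star
    dT = p.beta * R_star**2 / (p.K_m**2 + R_star**2) - p.k_dT * T
    return [dR, dRs, dT]


def integrate_dynamics(
    p: ParamSet,
    env: EnvSignal = EnvSignal(),
    init: tuple[float, float, float] = (0.0, 0.0, 0.0),
    t_end: float | None = None,
    n_points: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the kinetic ODEs from ``init``; the steady-state cross-check.

    By default runs to 40 relaxation times of the slowest first-order sink,
    long enough for the trajectory from the origin to settle at the fixed
    point to well below 1e-6 relative.

    Returns ``(t, Y)`` with ``Y`` of shape ``(n_points, 3)`` holding
    ``(R, R*, T)``.  Raises :class:`RuntimeError` if the integrator fails.
    """
    p.validate()
    if any(v < 0 for v in init):
        raise InvalidParameterError("initial concentrations must be >= 0")
    if t_end is None:
        t_end = 40.0 / min(p.k_d, p.k_dT)
    if not t_end > 0:
        raise InvalidParameterError("t_end must be > 0")
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        dynamics_rhs,
        (0.0, t_end),
        init,
        args=(p, env.S),
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y.T


def fitness(ss: SteadyState, fc: FitnessConstants = FitnessConstants()) -> FitnessComponents:
    """Benefit, cost and fitness of a steady state."""
    B = fc.a * ss.T / (ss.T + fc.b)
    C = fc.alpha * (ss.T + ss.R_star + ss.R)
    return FitnessComponents(B=B, C=C, F=B - C)


def genotype_fitness(
    p: ParamSet,
    env: EnvSignal = EnvSignal(),
    fc: FitnessConstants = FitnessConstants(),
) -> FitnessComponents:
    """Fitness of a parameter set: ``fitness(steady_state(p, env), fc)``."""
    return fitness(steady_state(p, env), fc)


def batch_fitness(
    P: np.ndarray,
    S: float = 1.0,
    fc: FitnessConstants = FitnessConstants(),
    kr_ratio: float = DEFAULT_KR_RATIO,
    components: bool = False,
):
    """Vectorized fitness for an ``(n, 6)`` array of evolvable parameter rows.

    Columns follow :data:`PARAM_NAMES` order.  This is the hot path of the
    adaptive walk (one call evaluates all one-mutant neighbors of a
    genotype); it mirrors :func:`steady_state` + :func:`fitness` exactly but
    skips per-row validation.
    """
    P = np.asarray(P, dtype=float)
    bas, k_act, k_d, beta, K_m, k_dT = (P[..., i] for i in range(6))
    k_r = kr_ratio * k_act
    denom = k_r + k_d
    R = bas * denom / (k_d * (denom + k_act * S))
    R_star = k_act * R * S / denom
    T = (beta / k_dT) * R_star**2 / (K_m**2 + R_star**2)
    B = fc.a * T / (T + fc.b)
    C = fc.alpha * (T + R_star + R)
    F = B - C
    if components:
        return {"R": R, "R_star": R_star, "T": T, "B": B, "C": C, "F": F}
    return F
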