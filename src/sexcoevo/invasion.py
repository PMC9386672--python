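"""Mutant linear systems, invasion fitness and selection gradients.

A rare mutant — a pathogen strain with virulences ``(alpha_f~, alpha_m~)`` or
a host allele with recovery rates ``(gamma_f^, gamma_m^)`` — experiences the
resident endemic equilibrium as a fixed environment, so its lineage dynamics
are linear. Each system is split as ``A = F + T`` into a birth part ``F``
(terms creating new mutant individuals or infections) and a transition part
``T`` (within-lineage moves and removals). Invasion fitness is the
next-generation reduction ``W = rho(F (-T)^{-1})``: the expected number of
new mutant units produced per mutant unit over its lifetime. ``W > 1`` iff
the dominant eigenvalue of ``A`` has positive real part — a property the
tests verify against the direct eigenvalue oracle rather than assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .equilibrium import EndemicEquilibrium
from .model_core import (
    LifeHistoryParams,
    TraitState,
    _birth_pieces,
    birth_rate,
    transmission_rate,
)

__all__ = [
    "MutantLinearSystem",
    "InvasionGradient",
    "mutant_pathogen_system",
    "mutant_host_system",
    "invasion_fitness",
    "selection_gradients",
]


@dataclass(frozen=True)
class MutantLinearSystem:
    """Linearized dynamics of a rare mutant lineage, split birth/transition."""

    birth_part: np.ndarray
    transition_part: np.ndarray
    class_labels: Tuple[str, ...]

    @property
    def dynamics_matrix(self) -> np.ndarray:
        return self.birth_part + self.transition_part

    def dominant_eigenvalue_real_part(self) -> float:
        return float(np.max(np.linalg.eigvals(self.dynamics_matrix).real))


@dataclass(frozen=True)
class InvasionGradient:
    """The four selection-gradient components at a resident."""

    dW_alpha_f: float
    dW_alpha_m: float
    dW_gamma_f: float
    dW_gamma_m: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dW_gamma_f, self.dW_gamma_m, self.dW_alpha_f, self.dW_alpha_m]
        )

    @property
    def max_abs(self) -> float:
        return float(np.max(np.abs(self.as_array())))


def _require_endemic(eq: EndemicEquilibrium) -> None:
    if not eq.endemic:
        raise ValueError("invasion is undefined at a non-endemic equilibrium")


def mutant_pathogen_system(
    mutant_alpha: Sequence[float],
    resident: TraitState,
    eq: EndemicEquilibrium,
    params: LifeHistoryParams,
) -> MutantLinearSystem:
    """2x2 system for the mutant-infection counts ``(I_f~, I_m~)``.

    Births (new mutant infections): vertical transmission from infected
    mutant mothers feeds both sexes' newborns, and horizontal infection of
    resident susceptibles ``S_i beta(alpha_j~)``. Transitions: recovery,
    disease death and natural death of the currently infected.
    """
    _require_endemic(eq)
    a_f, a_m = (float(a) for a in mutant_alpha)
    if a_f < 0 or a_m < 0:
        raise ValueError("mutant virulences must be >= 0")
    S_f, S_m, I_f, I_m = eq.state.as_array()
    N = eq.state.N
    b, w_f, w_m = _birth_pieces(resident, params)
    v = params.v
    vert = b * v * w_f * (S_m + w_m * I_m) / N  # per mutant-infected female
    beta_f = transmission_rate(a_f, params)
    beta_m = transmission_rate(a_m, params)

    F = np.array(
        [
            [vert + S_f * beta_f, S_f * beta_m],
            [vert + S_m * beta_f, S_m * beta_m],
        ]
    )
    muN = params.mu * N
    T = np.diag(
        [
            -(resident.gamma_f + a_f + muN),
            -(resident.gamma_m + a_m + muN),
        ]
    )
    return MutantLinearSystem(F, T, ("I_f_mut", "I_m_mut"))


def mutant_host_system(
    mutant_gamma: Sequence[float],
    resident: TraitState,
    eq: EndemicEquilibrium,
    params: LifeHistoryParams,
) -> MutantLinearSystem:
    """4x4 system for the mutant-host classes ``(S_f^, I_f^, S_m^, I_m^)``.

    The rare mutant is heterozygous and mates only residents, so each birth
    channel (mutant mother, mutant father) carries a factor 1/2 and its own
    birth coefficient — ``b(gamma_f^, gamma_m)`` or ``b(gamma_f, gamma_m^)``.
    Vertical transmission applies to infected-mother contributions only.
    Transitions: recovery of mutant infecteds into mutant susceptibles,
    horizontal infection of mutant susceptibles by *resident* infecteds, and
    removals (natural death everywhere, virulence on infected classes).
    """
    _require_endemic(eq)
    g_f, g_m = (float(g) for g in mutant_gamma)
    if g_f < 0 or g_m < 0:
        raise ValueError("mutant recovery rates must be >= 0")
    S_f, S_m, I_f, I_m = eq.state.as_array()
    N = eq.state.N
    v = params.v
    muN = params.mu * N

    # birth coefficients and infected-parent weights per channel
    if params.cost_mode == "fixed":
        b_mother = birth_rate(g_f, resident.gamma_m, params)  # mutant mother
        b_father = birth_rate(resident.gamma_f, g_m, params)  # mutant father
        w_f = w_m = 1.0  # resident infected-parent weights
        wh_f = wh_m = 1.0  # mutant infected-parent weights
    else:
        b_mother = b_father = params.b_max
        w_f = math.exp(-params.c_f * resident.gamma_f**2)
        w_m = math.exp(-params.c_m * resident.gamma_m**2)
        wh_f = math.exp(-params.c_f * g_f**2)
        wh_m = math.exp(-params.c_m * g_m**2)

    # mutant-mother channel: (1/2) b_mother (S_f^ + (1-v) wh_f I_f^) pool_m / N
    pool_m = S_m + w_m * I_m  # resident male mating pool
    mom_S = 0.5 * b_mother * pool_m / N  # coefficient of S_f^
    mom_SI = mom_S * (1.0 - v) * wh_f  # coefficient of I_f^ (susceptible newborns)
    mom_I = 0.5 * b_mother * v * wh_f * pool_m / N  # infected newborns per I_f^

    # mutant-father channel: (1/2) b_father pool_f (S_m^ + wh_m I_m^) / N
    pool_f_S = S_f + (1.0 - v) * w_f * I_f  # mothers producing susceptibles
    dad_S = 0.5 * b_father * pool_f_S / N  # per unit of (S_m^ + wh_m I_m^)
    dad_I = 0.5 * b_father * v * w_f * I_f / N  # infected newborns

    F = np.zeros((4, 4))
    # rows: S_f^, I_f^, S_m^, I_m^ — newborn sexes are produced equally
    for r in (0, 2):  # susceptible newborns of either sex
        F[r, 0] = mom_S
        F[r, 1] = mom_SI
        F[r, 2] = dad_S
        F[r, 3] = dad_S * wh_m
    for r in (1, 3):  # vertically infected newborns of either sex
        F[r, 1] = mom_I
        F[r, 2] = dad_I
        F[r, 3] = dad_I * wh_m

    beta_f = transmission_rate(resident.alpha_f, params)
    beta_m = transmission_rate(resident.alpha_m, params)
    force_f = beta_f * I_f + beta_m * I_m  # force of infection on females
    force_m = beta_f * I_f + beta_m * I_m  # same force on males (beta_ij = beta(alpha_j))

    T = np.zeros((4, 4))
    T[0, 0] = -(force_f + muN)
    T[0, 1] = g_f
    T[1, 0] = force_f
    T[1, 1] = -(g_f + resident.alpha_f + muN)
    T[2, 2] = -(force_m + muN)
    T[2, 3] = g_m
    T[3, 2] = force_m
    T[3, 3] = -(g_m + resident.alpha_m + muN)
    return MutantLinearSystem(F, T, ("S_f_mut", "I_f_mut", "S_m_mut", "I_m_mut"))


def invasion_fitness(system: MutantLinearSystem) -> float:
    """Next-generation invasion fitness ``W = rho(F (-T)^{-1})``.

    The threshold is at 1: the mutant invades iff ``W > 1``, equivalently iff
    the dominant eigenvalue of ``F + T`` has positive real part.
    """
    T = system.transition_part
    try:
        M = np.linalg.solve(-T.T, system.birth_part.T).T  # F @ (-T)^{-1}
    except np.linalg.LinAlgError as exc:
        raise ValueError("transition part is singular") from exc
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def _fd_derivative(f, x0: float, h: float) -> float:
    """Central difference, falling back to one-sided near the zero boundary."""
    if x0 - h < 0.0:
        return (f(x0 + h) - f(x0)) / h
    return (f(x0 + h) - f(x0 - h)) / (2.0 * h)


def selection_gradients(
    resident: TraitState,
    eq: EndemicEquilibrium,
    params: LifeHistoryParams,
    h: float = 1e-4,
) -> InvasionGradient:
    """Finite-difference selection gradients at the resident traits.

    Partials of the pathogen fitness ``W_alpha`` in each mutant virulence and
    of the host fitness ``W_gamma`` in each mutant recovery rate, holding the
    resident equilibrium fixed (the mutant is rare: its environment does not
    move). Step ``h`` is scaled per trait as ``h * max(1, |trait|)``.
    """
    _require_endemic(eq)
    if h <= 0:
        raise ValueError("h must be > 0")

    def W_alpha(a_f, a_m):
        return invasion_fitness(
            mutant_pathogen_system((a_f, a_m), resident, eq, params)
        )

    def W_gamma(g_f, g_m):
        return invasion_fitness(
            mutant_host_system((g_f, g_m), resident, eq, params)
        )

    a_f, a_m = resident.alpha_f, resident.alpha_m
    g_f, g_m = resident.gamma_f, resident.gamma_m
    return InvasionGradient(
        dW_alpha_f=_fd_derivative(
            lambda x: W_alpha(x, a_m), a_f, h * max(1.0, abs(a_f))
        ),
        dW_alpha_m=_fd_derivative(
            lambda x: W_alpha(a_f, x), a_m, h * max(1.0, abs(a_m))
        ),
        dW_gamma_f=_fd_derivative(
            lambda x: W_gamma(x, g_m), g_f, h * max(1.0, abs(g_f))
        ),
        dW_gamma_m=_fd_derivative(
            lambda x: W_gamma(g_f, x), g_m, h * max(1.0, abs(g_m))
        ),
    )
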