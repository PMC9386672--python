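"""Adaptive-dynamics loop: equilibrium -> gradients -> trait steps -> outcome.

Each iteration (i) locates the stable endemic equilibrium of the current
resident, (ii) computes the four selection-gradient components, and (iii)
moves every trait by a signed step following its gradient sign. All four
traits move simultaneously from the same equilibrium. Per-trait steps halve
whenever that component's gradient reverses sign and floor at a small value,
so the walk settles geometrically onto the convergence-stable outcome; the
loop stops when every gradient is within tolerance of zero. Two-dimensional
evolutionary stability of the outcome is verified separately on a lattice of
mutant trait pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .equilibrium import (
    EndemicEquilibrium,
    SolverOptions,
    find_endemic_equilibrium,
)
from .invasion import (
    InvasionGradient,
    invasion_fitness,
    mutant_host_system,
    mutant_pathogen_system,
    selection_gradients,
)
from .model_core import LifeHistoryParams, TraitState

__all__ = [
    "CoevolutionOptions",
    "CoevolutionOutcome",
    "solve_coevolution",
    "verify_ess",
    "continue_in_parameter",
]

DEFAULT_INIT = TraitState(gamma_f=0.5, gamma_m=0.5, alpha_f=2.0, alpha_m=2.0)


@dataclass(frozen=True)
class CoevolutionOptions:
    """Step and tolerance settings for the trait-iteration loop."""

    step_init: float = 0.01
    step_floor: float = 1e-6
    step_grow: float = 1.3
    grad_tol: float = 1e-6
    fd_step: float = 1e-4
    max_iter: int = 20000
    record_trajectory: bool = False
    solver: SolverOptions = field(default_factory=SolverOptions)


@dataclass(frozen=True)
class CoevolutionOutcome:
    """Converged trait values with stability flags and final equilibrium."""

    traits_star: TraitState
    converged: bool
    iterations: int
    max_abs_gradient: float
    equilibrium_star: Optional[EndemicEquilibrium]
    ess_pathogen: Optional[bool] = None
    ess_host: Optional[bool] = None
    message: str = ""
    trajectory: Optional[List[dict]] = None

    def to_dict(self) -> dict:
        d = self.traits_star.to_dict()
        d.update(
            converged=self.converged,
            iterations=self.iterations,
            max_abs_gradient=self.max_abs_gradient,
            ess_pathogen=self.ess_pathogen,
            ess_host=self.ess_host,
            message=self.message,
        )
        if self.equilibrium_star is not None:
            d["equilibrium"] = self.equilibrium_star.to_dict()
        return d


def solve_coevolution(
    params: LifeHistoryParams,
    init: TraitState = DEFAULT_INIT,
    options: Optional[CoevolutionOptions] = None,
) -> CoevolutionOutcome:
    """Iterate the adaptive-dynamics update to a convergence-stable outcome.

    Returns a :class:`CoevolutionOutcome`; ``converged`` is True only if all
    four gradient components fell below ``options.grad_tol``. Pathogen
    extinction or equilibrium failure along the way yields a flagged,
    not-converged outcome rather than an exception.
    """
    options = options or CoevolutionOptions()
    traits = np.array(init.as_array())  # order: g_f, g_m, a_f, a_m
    steps = np.full(4, options.step_init)
    prev_sign = np.zeros(4)
    warm: Optional[np.ndarray] = None
    trajectory: Optional[List[dict]] = [] if options.record_trajectory else None
    eq = None
    grad_max = np.inf

    for it in range(1, options.max_iter + 1):
        ts = TraitState.from_array(traits)
        eq = find_endemic_equilibrium(ts, params, options.solver, x0=warm)
        if not eq.converged:
            return CoevolutionOutcome(
                ts, False, it, grad_max, eq,
                message=f"equilibrium failure: {eq.message}",
                trajectory=trajectory,
            )
        if not eq.endemic:
            return CoevolutionOutcome(
                ts, False, it, grad_max, eq,
                message="pathogen extinct at current traits; co-evolution undefined",
                trajectory=trajectory,
            )
        if not eq.locally_stable:
            return CoevolutionOutcome(
                ts, False, it, grad_max, eq,
                message="endemic equilibrium not locally stable",
                trajectory=trajectory,
            )
        warm = eq.state.as_array()

        grad = selection_gradients(ts, eq, params, h=options.fd_step)
        g = grad.as_array()
        grad_max = float(np.max(np.abs(g)))
        if trajectory is not None:
            trajectory.append(
                dict(
                    iteration=it,
                    gamma_f=traits[0], gamma_m=traits[1],
                    alpha_f=traits[2], alpha_m=traits[3],
                    dW_gamma_f=g[0], dW_gamma_m=g[1],
                    dW_alpha_f=g[2], dW_alpha_m=g[3],
                )
            )
        if grad_max < options.grad_tol:
            return CoevolutionOutcome(
                ts, True, it, grad_max, eq, trajectory=trajectory
            )

        sign = np.sign(g)
        reversed_ = (sign * prev_sign) < 0
        persisted = (sign * prev_sign) > 0
        steps[reversed_] = np.maximum(steps[reversed_] * 0.5, options.step_floor)
        # regrow after persistent same-sign moves so a transient early
        # reversal cannot strand a trait creeping at the step floor
        steps[persisted] = np.minimum(
            steps[persisted] * options.step_grow, options.step_init
        )
        prev_sign = np.where(sign != 0, sign, prev_sign)
        traits = np.maximum(traits + sign * steps, 0.0)

    return CoevolutionOutcome(
        TraitState.from_array(traits), False, options.max_iter, grad_max, eq,
        message="iteration budget exhausted", trajectory=trajectory,
    )


def verify_ess(
    outcome: CoevolutionOutcome,
    params: LifeHistoryParams,
    radius: float = 0.1,
    n_grid: int = 11,
    slack: float = 1e-7,
) -> Tuple[bool, bool]:
    """Two-dimensional ESS check for pathogen and host at the outcome.

    Evaluates the pathogen fitness on an ``n_grid x n_grid`` lattice of
    mutant virulence pairs in a box of half-width ``radius`` around
    ``(alpha_f*, alpha_m*)`` (clipped at zero) and requires ``W <= 1 +
    slack`` everywhere; same for the host fitness over mutant recovery
    pairs. Returns ``(ess_pathogen, ess_host)``.
    """
    if not outcome.converged:
        raise ValueError("ESS verification requires a converged outcome")
    eq = outcome.equilibrium_star
    star = outcome.traits_star

    def lattice(center: float) -> np.ndarray:
        return np.maximum(np.linspace(center - radius, center + radius, n_grid), 0.0)

    ess_path = True
    for a_f in lattice(star.alpha_f):
        for a_m in lattice(star.alpha_m):
            W = invasion_fitness(
                mutant_pathogen_system((a_f, a_m), star, eq, params)
            )
            if W > 1.0 + slack:
                ess_path = False
                break
        if not ess_path:
            break

    ess_host = True
    for g_f in lattice(star.gamma_f):
        for g_m in lattice(star.gamma_m):
            W = invasion_fitness(
                mutant_host_system((g_f, g_m), star, eq, params)
            )
            if W > 1.0 + slack:
                ess_host = False
                break
        if not ess_host:
            break
    return ess_path, ess_host


def continue_in_parameter(
    params_list: Sequence[LifeHistoryParams],
    init: TraitState = DEFAULT_INIT,
    options: Optional[CoevolutionOptions] = None,
) -> List[CoevolutionOutcome]:
    """Solve an ordered path of parameter sets, warm-starting each point.

    Each solve is seeded from the previous converged outcome; on a failed
    point the next one falls back to the cold initial traits. Per-point
    failures are recorded in the returned outcomes, not raised.
    """
    outcomes: List[CoevolutionOutcome] = []
    seed = init
    for params in params_list:
        out = solve_coevolution(params, seed, options)
        if not out.converged and seed is not init:
            out = solve_coevolution(params, init, options)
        outcomes.append(out)
        if out.converged:
            seed = out.traits_star
    return outcomes
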