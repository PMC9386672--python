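"""Reported quantities: case metrics, sex-difference regions, parameter sweeps.

Converged co-evolutionary outcomes are re-expressed as the quantities a
medical record would show — case mortality ``chi_i`` (probability an
infection ends in disease death) and case recovery ``eta_i`` (probability it
ends in recovery) — and classified by the signs of the female-minus-male
differences into qualitative co-evolutionary patterns. Two-dimensional
sweeps over vertical transmission ``v`` and cost disparity ``delta_c``
map those patterns across parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coevolution import (
    DEFAULT_INIT,
    CoevolutionOptions,
    CoevolutionOutcome,
    solve_coevolution,
)
from .model_core import LifeHistoryParams, TraitState

__all__ = [
    "OutcomeMetrics",
    "RegionLabel",
    "case_metrics",
    "classify_region",
    "sweep_phase_plane",
    "compare_cost_modes",
    "SWEEP_COLUMNS",
]


class RegionLabel(str, Enum):
    """Qualitative co-evolutionary pattern by sign of the sex differences."""

    FEMALE_DEFENDED_FEMALE_VIRULENT = "FEMALE_DEFENDED_FEMALE_VIRULENT"
    MALE_DEFENDED_MALE_VIRULENT = "MALE_DEFENDED_MALE_VIRULENT"
    FEMALE_DEFENDED_MALE_VIRULENT = "FEMALE_DEFENDED_MALE_VIRULENT"
    OTHER = "OTHER"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class OutcomeMetrics:
    """Case metrics and sex differences at a co-evolved outcome.

    ``chi_i + eta_i <= 1``; the remainder is the probability of natural
    death while infected.
    """

    chi_f: float
    chi_m: float
    eta_f: float
    eta_m: float
    diff_gamma: float
    diff_alpha: float
    diff_chi: float
    diff_eta: float

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def case_metrics(
    outcome: CoevolutionOutcome, params: LifeHistoryParams
) -> OutcomeMetrics:
    """Competing-risk exit probabilities from the infected state.

    With constant hazards — recovery ``gamma_i*``, disease death
    ``alpha_i*`` and natural death ``mu N_bar`` — an infection ends in
    disease death with probability ``chi_i = alpha_i* / (gamma_i* +
    alpha_i* + mu N_bar)`` and in recovery with probability ``eta_i =
    gamma_i* / (gamma_i* + alpha_i* + mu N_bar)``.
    """
    if not outcome.converged or outcome.equilibrium_star is None:
        raise ValueError("case metrics require a converged outcome")
    t = outcome.traits_star
    muN = params.mu * outcome.equilibrium_star.N
    tot_f = t.gamma_f + t.alpha_f + muN
    tot_m = t.gamma_m + t.alpha_m + muN
    if tot_f <= 0 or tot_m <= 0:
        raise ValueError("total exit hazard must be positive")
    chi_f = t.alpha_f / tot_f
    chi_m = t.alpha_m / tot_m
    eta_f = t.gamma_f / tot_f
    eta_m = t.gamma_m / tot_m
    return OutcomeMetrics(
        chi_f=chi_f,
        chi_m=chi_m,
        eta_f=eta_f,
        eta_m=eta_m,
        diff_gamma=t.gamma_f - t.gamma_m,
        diff_alpha=t.alpha_f - t.alpha_m,
        diff_chi=chi_f - chi_m,
        diff_eta=eta_f - eta_m,
    )


def classify_region(
    metrics: OutcomeMetrics,
    tie_tol: float = 1e-4,
    basis: str = "rates",
) -> RegionLabel:
    """Label the qualitative pattern from the signs of the sex differences.

    ``basis="rates"`` uses ``(diff_gamma, diff_alpha)``; ``basis=
    "case_metrics"`` applies the same sign table to ``(diff_eta,
    diff_chi)``. Sign table (defence difference, virulence difference):
    (+,+) female-defended & female-virulent; (-,-) male-defended &
    male-virulent; (+,-) female-defended & male-virulent; (-,+) OTHER;
    a difference within ``tie_tol`` of zero is UNRESOLVED.
    """
    if basis == "rates":
        dx, dy = metrics.diff_gamma, metrics.diff_alpha
    elif basis == "case_metrics":
        dx, dy = metrics.diff_eta, metrics.diff_chi
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if abs(dx) <= tie_tol or abs(dy) <= tie_tol:
        return RegionLabel.UNRESOLVED
    if dx > 0 and dy > 0:
        return RegionLabel.FEMALE_DEFENDED_FEMALE_VIRULENT
    if dx < 0 and dy < 0:
        return RegionLabel.MALE_DEFENDED_MALE_VIRULENT
    if dx > 0 and dy < 0:
        return RegionLabel.FEMALE_DEFENDED_MALE_VIRULENT
    return RegionLabel.OTHER


SWEEP_COLUMNS = [
    "v",
    "delta_c",
    "c_0",
    "gamma_f_star",
    "gamma_m_star",
    "alpha_f_star",
    "alpha_m_star",
    "chi_f",
    "chi_m",
    "eta_f",
    "eta_m",
    "region_rates",
    "region_case",
    "converged",
]


def sweep_phase_plane(
    v_grid: Sequence[float],
    delta_c_grid: Sequence[float],
    c_0: float,
    params_base: LifeHistoryParams,
    options: Optional[CoevolutionOptions] = None,
    init: TraitState = DEFAULT_INIT,
    tie_tol: float = 1e-4,
) -> pd.DataFrame:
    """Solve co-evolution on the ``(v, delta_c)`` grid and classify each cell.

    Rows are solved in order of increasing ``v`` with each row warm-started
    from the previous cell along ``delta_c`` (falling back to the cold
    initial traits on failure). Returns a ``DataFrame`` with columns
    ``SWEEP_COLUMNS``: one row per grid point.
    """
    v_grid = list(v_grid)
    delta_c_grid = list(delta_c_grid)
    if not v_grid or not delta_c_grid:
        raise ValueError("grids must be non-empty")
    if c_0 - max(abs(d) for d in delta_c_grid) / 2.0 < 0:
        raise ValueError("delta_c grid exceeds the admissible range for c_0")

    rows = []
    for v in v_grid:
        seed = init
        for dc in delta_c_grid:
            params = LifeHistoryParams.from_midpoint(
                c_0,
                dc,
                b_max=params_base.b_max,
                beta_max=params_base.beta_max,
                d=params_base.d,
                mu=params_base.mu,
                v=v,
                cost_mode=params_base.cost_mode,
            )
            out = solve_coevolution(params, seed, options)
            if not out.converged and seed is not init:
                out = solve_coevolution(params, init, options)
            row = dict(v=v, delta_c=dc, c_0=c_0, converged=out.converged)
            if out.converged:
                seed = out.traits_star
                m = case_metrics(out, params)
                t = out.traits_star
                row.update(
                    gamma_f_star=t.gamma_f,
                    gamma_m_star=t.gamma_m,
                    alpha_f_star=t.alpha_f,
                    alpha_m_star=t.alpha_m,
                    chi_f=m.chi_f,
                    chi_m=m.chi_m,
                    eta_f=m.eta_f,
                    eta_m=m.eta_m,
                    region_rates=classify_region(m, tie_tol, "rates").value,
                    region_case=classify_region(m, tie_tol, "case_metrics").value,
                )
            else:
                row.update(
                    gamma_f_star=np.nan,
                    gamma_m_star=np.nan,
                    alpha_f_star=np.nan,
                    alpha_m_star=np.nan,
                    chi_f=np.nan,
                    chi_m=np.nan,
                    eta_f=np.nan,
                    eta_m=np.nan,
                    region_rates=None,
                    region_case=None,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def compare_cost_modes(
    sweep_fixed: pd.DataFrame, sweep_variable: pd.DataFrame
) -> pd.DataFrame:
    """Per-region cell counts for fixed vs variable immunity costs.

    Both sweeps must share the same ``(v, delta_c)`` grid. Returns a frame
    indexed by region label with columns ``fixed``, ``variable`` and
    ``difference`` (variable minus fixed), for the rates basis.
    """
    key_f = sweep_fixed[["v", "delta_c"]].round(12)
    key_v = sweep_variable[["v", "delta_c"]].round(12)
    if len(key_f) != len(key_v) or not (key_f.values == key_v.values).all():
        raise ValueError("sweeps were run on different grids")
    labels = [r.value for r in RegionLabel]
    counts = {}
    for name, df in (("fixed", sweep_fixed), ("variable", sweep_variable)):
        sub = df[df["converged"].astype(bool)]
        counts[name] = sub["region_rates"].value_counts().reindex(labels, fill_value=0)
    result = pd.DataFrame(counts)
    result["difference"] = result["variable"] - result["fixed"]
    result.index.name = "region"
    return result
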