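"""Core model: parameters, traits, trade-offs and resident SIS dynamics.

The ecological model tracks a two-sex host population structured by disease
status (susceptible/infectious), with harmonic-mean mating, density-dependent
natural mortality ``mu * N`` per capita, horizontal transmission whose rate is
tied to virulence through a saturating trade-off, and vertical (mother-to-
child) transmission with probability ``v``.

Two trade-offs couple ecology to evolution:

* pathogen: horizontal transmissibility ``beta(alpha) = beta_max * alpha /
  (alpha + d)`` rises with the disease-induced mortality ``alpha`` it inflicts;
* host: the pair birth coefficient ``b(gamma_f, gamma_m) = b_max *
  exp(-c_f gamma_f^2) * exp(-c_m gamma_m^2)`` falls as either sex invests in
  recovery.

``cost_mode`` selects whether the fertility cost of immunity is paid always
("fixed", a maintenance/innate-like cost) or only while infected ("variable",
an activation/adaptive-like cost).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "LifeHistoryParams",
    "TraitState",
    "PopulationState",
    "transmission_rate",
    "birth_rate",
    "resident_rhs",
]

COST_MODES = ("fixed", "variable")

PARAM_KEYS = ("b_max", "beta_max", "d", "mu", "c_f", "c_m", "v", "cost_mode")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Fixed ecological and evolutionary parameters of hosts and pathogen.

    Parameters
    ----------
    b_max : float
        Maximal per-pairing birth-rate coefficient (per unit time).
    beta_max : float
        Saturation level of horizontal transmissibility (per host per unit
        time).
    d : float
        Virulence half-saturation constant of the transmission trade-off
        (same scale as alpha).
    mu : float
        Density-dependent natural-mortality coefficient (per host per unit
        time); every host dies at per-capita rate ``mu * N``.
    c_f, c_m : float
        Sex-specific fertility costs of recovery (coefficients on gamma^2).
    v : float
        Vertical-transmission probability in [0, 1].
    cost_mode : str
        ``"fixed"`` (cost paid regardless of infection status) or
        ``"variable"`` (cost paid only by infected hosts).
    """

    b_max: float
    beta_max: float
    d: float
    mu: float
    c_f: float
    c_m: float
    v: float = 0.0
    cost_mode: str = "fixed"

    def __post_init__(self) -> None:
        for name in ("b_max", "beta_max", "d", "mu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("c_f", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.v <= 1.0:
            raise ValueError(f"v must lie in [0, 1], got {self.v!r}")
        if self.cost_mode not in COST_MODES:
            raise ValueError(
                f"cost_mode must be one of {COST_MODES}, got {self.cost_mode!r}"
            )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_midpoint(
        cls,
        c_0: float,
        delta_c: float = 0.0,
        **kwargs,
    ) -> "LifeHistoryParams":
        """Build from the midpoint cost parameterization.

        ``c_f = c_0 - delta_c / 2`` and ``c_m = c_0 + delta_c / 2`` so the
        midpoint ``(c_f + c_m) / 2 = c_0`` stays fixed while ``delta_c =
        c_m - c_f`` controls the disparity; ``delta_c > 0`` means costlier
        male immunity.
        """
        return cls(c_f=c_0 - delta_c / 2.0, c_m=c_0 + delta_c / 2.0, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "LifeHistoryParams":
        unknown = set(data) - set(PARAM_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "LifeHistoryParams":
        """Read a flat YAML/JSON config with keys exactly ``PARAM_KEYS``."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            import yaml

            data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **changes) -> "LifeHistoryParams":
        return replace(self, **changes)

    @property
    def delta_c(self) -> float:
        return self.c_m - self.c_f

    @property
    def c_0(self) -> float:
        return 0.5 * (self.c_f + self.c_m)


@dataclass(frozen=True)
class TraitState:
    """The four co-evolving phenotypes.

    ``gamma_f, gamma_m`` are sex-specific recovery rates (host
    immunocompetence); ``alpha_f, alpha_m`` are sex-specific disease-induced
    mortality rates (pathogen virulence). All per unit time, all >= 0.
    """

    gamma_f: float
    gamma_m: float
    alpha_f: float
    alpha_m: float

    def __post_init__(self) -> None:
        for name in ("gamma_f", "gamma_m", "alpha_f", "alpha_m"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {val!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma_f, self.gamma_m, self.alpha_f, self.alpha_m])

    @classmethod
    def from_array(cls, arr) -> "TraitState":
        g_f, g_m, a_f, a_m = (float(x) for x in arr)
        return cls(g_f, g_m, a_f, a_m)

    def swapped(self) -> "TraitState":
        """Exchange female and male labels."""
        return TraitState(self.gamma_m, self.gamma_f, self.alpha_m, self.alpha_f)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PopulationState:
    """Resident compartment counts by sex and disease status."""

    S_f: float
    S_m: float
    I_f: float
    I_m: float

    def __post_init__(self) -> None:
        for name in ("S_f", "S_m", "I_f", "I_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")

    @property
    def N(self) -> float:
        return self.S_f + self.S_m + self.I_f + self.I_m

    def as_array(self) -> np.ndarray:
        return np.array([self.S_f, self.S_m, self.I_f, self.I_m])

    @classmethod
    def from_array(cls, arr) -> "PopulationState":
        return cls(*(float(x) for x in arr))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["N"] = self.N
        return d


# -- trade-off functions ------------------------------------------------------


def transmission_rate(alpha: float, params: LifeHistoryParams) -> float:
    """Horizontal transmissibility of a pathogen with virulence ``alpha``.

    ``beta(alpha) = beta_max * alpha / (alpha + d)``: strictly increasing and
    concave in alpha, saturating at beta_max, independent of recipient sex.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha!r}")
    return params.beta_max * alpha / (alpha + params.d)


def birth_rate(gamma_f: float, gamma_m: float, params: LifeHistoryParams) -> float:
    """Pair birth coefficient ``b_max * exp(-c_f g_f^2) * exp(-c_m g_m^2)``.

    Used as-is in fixed cost mode; in variable mode the per-parent cost
    factors are applied selectively inside the birth terms instead (see
    :func:`_birth_pieces`).
    """
    if gamma_f < 0 or gamma_m < 0:
        raise ValueError("recovery rates must be >= 0")
    return (
        params.b_max
        * math.exp(-params.c_f * gamma_f**2)
        * math.exp(-params.c_m * gamma_m**2)
    )


def _birth_pieces(traits: TraitState, params: LifeHistoryParams):
    """Return ``(b_coef, w_f, w_m)`` for the resident birth terms.

    Fixed mode: ``b_coef = b(gamma_f, gamma_m)`` and unit mating weights.
    Variable mode: ``b_coef = b_max`` and the fertility-cost factor
    ``exp(-c_i gamma_i^2)`` weights only the *infected* parent of sex i in the
    mating pool (the cost is paid only while infected).
    """
    if params.cost_mode == "fixed":
        return birth_rate(traits.gamma_f, traits.gamma_m, params), 1.0, 1.0
    w_f = math.exp(-params.c_f * traits.gamma_f**2)
    w_m = math.exp(-params.c_m * traits.gamma_m**2)
    return params.b_max, w_f, w_m


def resident_rhs(
    state: Union[PopulationState, np.ndarray],
    traits: TraitState,
    params: LifeHistoryParams,
) -> np.ndarray:
    """Time-derivatives ``(dS_f, dS_m, dI_f, dI_m)`` of the resident system.

    Birth inflow ``b (S_f + (1-v) I_f)(S_m + I_m) / N`` feeds each susceptible
    class and ``b v I_f (S_m + I_m) / N`` feeds each infected class (one-to-one
    birth sex ratio; only infected mothers transmit vertically). Infected
    hosts recover at ``gamma_i``, susceptibles acquire infection at
    ``S_i beta(alpha_j) I_j``, every host dies at ``mu N`` per capita and
    infected hosts additionally at ``alpha_i``.

    An empty population (N == 0) is absorbing: all derivatives are zero.
    """
    if isinstance(state, PopulationState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (4,):
            raise ValueError("state must have four compartments")
        if np.any(y < 0):
            raise ValueError("compartments must be >= 0")
    S_f, S_m, I_f, I_m = y
    N = S_f + S_m + I_f + I_m
    if N == 0.0:
        return np.zeros(4)

    b, w_f, w_m = _birth_pieces(traits, params)
    v = params.v
    males = S_m + w_m * I_m
    birth_S = b * (S_f + (1.0 - v) * w_f * I_f) * males / N
    birth_I = b * v * w_f * I_f * males / N

    beta_f = transmission_rate(traits.alpha_f, params)  # from infected females
    beta_m = transmission_rate(traits.alpha_m, params)  # from infected males
    inf_f = S_f * (beta_f * I_f + beta_m * I_m)
    inf_m = S_m * (beta_f * I_f + beta_m * I_m)
    muN = params.mu * N

    dS_f = birth_S + traits.gamma_f * I_f - inf_f - muN * S_f
    dS_m = birth_S + traits.gamma_m * I_m - inf_m - muN * S_m
    dI_f = birth_I + inf_f - (traits.gamma_f + traits.alpha_f + muN) * I_f
    dI_m = birth_I + inf_m - (traits.gamma_m + traits.alpha_m + muN) * I_m
    return np.array([dS_f, dS_m, dI_f, dI_m])
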