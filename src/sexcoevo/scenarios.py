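"""Named and randomized parameter scenarios.

Every analysis in the package is purely model-based, so the test surface is
driven by parameter scenarios rather than data files: four named benchmark
sets spanning the regimes the analysis targets, plus a seeded
random-scenario generator used by the property-test suites (neutrality,
exchange symmetry, eigenvalue-oracle equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model_core import LifeHistoryParams, TraitState

__all__ = ["Scenario", "paper_scenarios", "random_scenario", "DEFAULT_RANGES"]


@dataclass(frozen=True)
class Scenario:
    """A parameter set plus initial traits, with provenance and seed."""

    name: str
    params: LifeHistoryParams
    init_traits: TraitState
    seed: Optional[int] = None
    provenance: str = ""

    def to_dict(self) -> dict:
        return dict(
            name=self.name,
            params=self.params.to_dict(),
            init_traits=self.init_traits.to_dict(),
            seed=self.seed,
            provenance=self.provenance,
        )


_DEFAULT_INIT = TraitState(gamma_f=0.5, gamma_m=0.5, alpha_f=2.0, alpha_m=2.0)


def paper_scenarios() -> List[Scenario]:
    """The four named benchmark parameterizations.

    FIG3: symmetric-cost baseline, c_0 = 0.01, with v swept over [0, 0.9].
    FIG4 / FIG6: phase-plane sweeps at c_0 = 0.1.
    FIG5: cost-mode comparison at c_0 = 0.5 with a more fecund host and a
    more transmissible pathogen (b_max = 3.5, beta_max = 3.1).
    All share d = 4 and mu = 0.1.
    """
    common = dict(d=4.0, mu=0.1, v=0.0, cost_mode="fixed")
    return [
        Scenario(
            "FIG3",
            LifeHistoryParams.from_midpoint(
                0.01, 0.0, b_max=2.0, beta_max=1.1, **common
            ),
            _DEFAULT_INIT,
            provenance="baseline trajectories; v ranges between 0 and 0.9",
        ),
        Scenario(
            "FIG4",
            LifeHistoryParams.from_midpoint(
                0.1, 0.0, b_max=2.0, beta_max=1.1, **common
            ),
            _DEFAULT_INIT,
            provenance="phase-plane sweep, c_0 = 0.1",
        ),
        Scenario(
            "FIG5",
            LifeHistoryParams.from_midpoint(
                0.5, 0.0, b_max=3.5, beta_max=3.1, **common
            ),
            _DEFAULT_INIT,
            provenance="cost-mode comparison, c_0 = 0.5",
        ),
        Scenario(
            "FIG6",
            LifeHistoryParams.from_midpoint(
                0.1, 0.0, b_max=2.0, beta_max=1.1, **common
            ),
            _DEFAULT_INIT,
            provenance="case-metric reclassification, c_0 = 0.1",
        ),
    ]


DEFAULT_RANGES = dict(
    b_max=(1.0, 4.0),
    beta_max=(0.5, 3.5),
    d=(1.0, 8.0),
    mu=(0.02, 0.3),
    c_0=(0.005, 0.6),
    delta_c_rel=1.6,  # |delta_c| <= delta_c_rel * c_0
    v=(0.0, 0.9),
)


def random_scenario(
    seed: int,
    ranges: Optional[dict] = None,
    symmetric: bool = False,
) -> Scenario:
    """Deterministic-in-seed random scenario for property testing.

    Parameters are drawn uniformly on the default bounds, log-uniformly for
    ``mu`` and ``c_0`` (each spans an order of magnitude), with
    ``|delta_c| <= 1.6 c_0``. ``symmetric=True`` forces ``delta_c = 0`` and
    ``v = 0`` for the exchange-symmetry suites. Initial traits are interior.
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for key in ("b_max", "beta_max", "d", "mu", "c_0", "v"):
        lo, hi = r[key]
        if not (hi > lo >= 0):
            raise ValueError(f"degenerate range for {key}: {(lo, hi)}")
    rng = np.random.default_rng(seed)

    def unif(key):
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    def logunif(key):
        lo, hi = r[key]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    c_0 = logunif("c_0")
    delta_c = 0.0 if symmetric else float(
        rng.uniform(-r["delta_c_rel"] * c_0, r["delta_c_rel"] * c_0)
    )
    params = LifeHistoryParams.from_midpoint(
        c_0,
        delta_c,
        b_max=unif("b_max"),
        beta_max=unif("beta_max"),
        d=unif("d"),
        mu=logunif("mu"),
        v=0.0 if symmetric else unif("v"),
        cost_mode="fixed",
    )
    init = TraitState(
        gamma_f=float(rng.uniform(0.1, 1.5)),
        gamma_m=float(rng.uniform(0.1, 1.5)),
        alpha_f=float(rng.uniform(0.5, 4.0)),
        alpha_m=float(rng.uniform(0.5, 4.0)),
    )
    return Scenario(
        name=f"random-{seed}", params=params, init_traits=init, seed=seed
    )
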