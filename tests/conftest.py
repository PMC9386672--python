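"""Shared fixtures: named parameter sets and solved baseline outcomes."""

import numpy as np
import pytest

from sexcoevo import (
    LifeHistoryParams,
    TraitState,
    find_endemic_equilibrium,
    solve_coevolution,
)

BASE = dict(b_max=2.0, beta_max=1.1, d=4.0, mu=0.1)


@pytest.fixture(scope="session")
def baseline_params() -> LifeHistoryParams:
    """Symmetric-cost baseline: c_f = c_m = 0.01, no vertical transmission."""
    return LifeHistoryParams(c_f=0.01, c_m=0.01, v=0.0, **BASE)


@pytest.fixture(scope="session")
def baseline_traits() -> TraitState:
    """Interior, pathogen-viable resident traits at the baseline."""
    return TraitState(gamma_f=0.5, gamma_m=0.5, alpha_f=2.0, alpha_m=2.0)


@pytest.fixture(scope="session")
def baseline_eq(baseline_traits, baseline_params):
    eq = find_endemic_equilibrium(baseline_traits, baseline_params)
    assert eq.converged and eq.endemic and eq.locally_stable
    return eq


@pytest.fixture(scope="session")
def asymmetric_params() -> LifeHistoryParams:
    """Vertical transmission v = 0.3 over the symmetric-cost baseline."""
    return LifeHistoryParams(c_f=0.01, c_m=0.01, v=0.3, **BASE)


@pytest.fixture(scope="session")
def asymmetric_eq(baseline_traits, asymmetric_params):
    eq = find_endemic_equilibrium(baseline_traits, asymmetric_params)
    assert eq.converged and eq.endemic and eq.locally_stable
    return eq


@pytest.fixture(scope="session")
def baseline_outcome(baseline_params):
    """Converged symmetric co-evolutionary outcome (Fig. 3A-style setting)."""
    out = solve_coevolution(baseline_params)
    assert out.converged
    return out


@pytest.fixture(scope="session")
def vertical_outcome(asymmetric_params):
    """Converged outcome with vertical transmission only (v = 0.3)."""
    out = solve_coevolution(asymmetric_params)
    assert out.converged
    return out


def endemic_random_cases(n, start_seed=0, max_seeds=5000, symmetric=False):
    """Deterministic stream of (scenario, equilibrium) pairs that are endemic."""
    from sexcoevo.scenarios import random_scenario

    cases = []
    seed = start_seed
    while len(cases) < n and seed < start_seed + max_seeds:
        sc = random_scenario(seed, symmetric=symmetric)
        eq = find_endemic_equilibrium(sc.init_traits, sc.params)
        if eq.converged and eq.endemic and eq.locally_stable:
            cases.append((sc, eq))
        seed += 1
    assert len(cases) == n, "random-scenario stream exhausted"
    return cases
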