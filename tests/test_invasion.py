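"""Mutant linear systems, invasion fitness, and selection gradients."""

import numpy as np
import pytest

from sexcoevo import (
    LifeHistoryParams,
    TraitState,
    find_endemic_equilibrium,
    invasion_fitness,
    mutant_host_system,
    mutant_pathogen_system,
    selection_gradients,
)
from conftest import endemic_random_cases


class TestMutantSystems:
    def test_birth_transition_split_invariants(self, baseline_traits, asymmetric_eq, asymmetric_params):
        for sys_ in (
            mutant_pathogen_system((1.8, 2.3), baseline_traits, asymmetric_eq, asymmetric_params),
            mutant_host_system((0.4, 0.7), baseline_traits, asymmetric_eq, asymmetric_params),
        ):
            assert np.all(sys_.birth_part >= 0)
            assert np.all(sys_.transition_part.sum(axis=0) <= 1e-12)
            assert np.allclose(
                sys_.dynamics_matrix, sys_.birth_part + sys_.transition_part
            )

    def test_pathogen_no_vertical_column_structure(
        self, baseline_traits, baseline_eq, baseline_params
    ):
        """With v=0 the mutant-female column of the birth part is purely
        horizontal: S_i * beta(alpha_f~)."""
        from sexcoevo import transmission_rate

        sys_ = mutant_pathogen_system(
            (1.7, 2.4), baseline_traits, baseline_eq, baseline_params
        )
        s = baseline_eq.state
        bf = transmission_rate(1.7, baseline_params)
        assert sys_.birth_part[0, 0] == pytest.approx(s.S_f * bf, rel=1e-12)
        assert sys_.birth_part[1, 0] == pytest.approx(s.S_m * bf, rel=1e-12)

    def test_avirulent_mutant_transmits_nothing(
        self, baseline_traits, asymmetric_eq, asymmetric_params
    ):
        sys_ = mutant_pathogen_system(
            (0.0, 0.0), baseline_traits, asymmetric_eq, asymmetric_params
        )
        # only the vertical-transmission entries (column I_f~) survive
        assert np.all(sys_.birth_part[:, 1] == 0.0)
        assert np.all(sys_.birth_part[:, 0] > 0.0)

    def test_host_no_vertical_means_no_infected_birth(
        self, baseline_traits, baseline_eq, baseline_params
    ):
        sys_ = mutant_host_system(
            (0.3, 0.9), baseline_traits, baseline_eq, baseline_params
        )
        assert np.all(sys_.birth_part[1, :] == 0.0)
        assert np.all(sys_.birth_part[3, :] == 0.0)

    def test_host_costless_birth_independent_of_mutant_trait(
        self, baseline_traits, baseline_params
    ):
        free = baseline_params.replace(c_f=0.0, c_m=0.0)
        eq = find_endemic_equilibrium(baseline_traits, free)
        s1 = mutant_host_system((0.2, 0.2), baseline_traits, eq, free)
        s2 = mutant_host_system((1.4, 0.8), baseline_traits, eq, free)
        assert np.allclose(s1.birth_part, s2.birth_part)

    @pytest.mark.parametrize("which", ["pathogen", "host"])
    def test_neutral_mutant_annihilates_resident_state(
        self, which, baseline_traits, asymmetric_eq, asymmetric_params
    ):
        """The neutral mutant's dynamics matrix has the resident equilibrium
        in its kernel — the mutant system degenerates to the resident one."""
        s = asymmetric_eq.state
        if which == "pathogen":
            sys_ = mutant_pathogen_system(
                (baseline_traits.alpha_f, baseline_traits.alpha_m),
                baseline_traits, asymmetric_eq, asymmetric_params,
            )
            vec = np.array([s.I_f, s.I_m])
        else:
            sys_ = mutant_host_system(
                (baseline_traits.gamma_f, baseline_traits.gamma_m),
                baseline_traits, asymmetric_eq, asymmetric_params,
            )
            vec = np.array([s.S_f, s.I_f, s.S_m, s.I_m])
        assert np.max(np.abs(sys_.dynamics_matrix @ vec)) < 1e-10

    def test_invasion_undefined_without_endemic_resident(self, baseline_params):
        traits = TraitState(0.5, 0.5, 50.0, 50.0)
        eq = find_endemic_equilibrium(traits, baseline_params)
        assert not eq.endemic
        with pytest.raises(ValueError):
            mutant_pathogen_system((2.0, 2.0), traits, eq, baseline_params)


class TestInvasionFitness:
    def test_neutrality_both_parties(self):
        """W = 1 to 1e-8 for neutral mutants at every certified equilibrium."""
        for sc, eq in endemic_random_cases(30, start_seed=100):
            t = sc.init_traits
            Wp = invasion_fitness(
                mutant_pathogen_system((t.alpha_f, t.alpha_m), t, eq, sc.params)
            )
            Wh = invasion_fitness(
                mutant_host_system((t.gamma_f, t.gamma_m), t, eq, sc.params)
            )
            assert abs(Wp - 1.0) < 1e-8
            assert abs(Wh - 1.0) < 1e-8

    def test_threshold_matches_eigenvalue_oracle(self):
        """sign(W - 1) equals the sign of the dominant eigenvalue real part
        of the full mutant dynamics matrix (split-independent oracle)."""
        rng = np.random.default_rng(11)
        for sc, eq in endemic_random_cases(40, start_seed=500):
            t = sc.init_traits
            ma = np.maximum(
                np.array([t.alpha_f, t.alpha_m]) + rng.normal(0, 0.5, 2), 0.0
            )
            mg = np.maximum(
                np.array([t.gamma_f, t.gamma_m]) + rng.normal(0, 0.3, 2), 0.0
            )
            for sys_ in (
                mutant_pathogen_system(ma, t, eq, sc.params),
                mutant_host_system(mg, t, eq, sc.params),
            ):
                W = invasion_fitness(sys_)
                lam = sys_.dominant_eigenvalue_real_part()
                if abs(W - 1.0) > 1e-7:
                    assert np.sign(W - 1.0) == np.sign(lam)


class TestSelectionGradients:
    def test_symmetric_resident_symmetric_gradient(
        self, baseline_traits, baseline_eq, baseline_params
    ):
        g = selection_gradients(baseline_traits, baseline_eq, baseline_params)
        assert g.dW_alpha_f == pytest.approx(g.dW_alpha_m, abs=1e-8)
        assert g.dW_gamma_f == pytest.approx(g.dW_gamma_m, abs=1e-8)

    def test_low_recovery_selects_for_more(self, baseline_params):
        """At a very low resident recovery rate, host fitness increases with
        the mutant recovery rate (oracle: coarse mutant grid)."""
        traits = TraitState(0.05, 0.05, 2.0, 2.0)
        eq = find_endemic_equilibrium(traits, baseline_params)
        assert eq.endemic
        g = selection_gradients(traits, eq, baseline_params)
        assert g.dW_gamma_f > 0 and g.dW_gamma_m > 0
        # grid oracle: W_gamma increases away from the resident value
        grid = [0.05, 0.10, 0.15, 0.20]
        W = [
            invasion_fitness(
                mutant_host_system((x, 0.05), traits, eq, baseline_params)
            )
            for x in grid
        ]
        assert np.all(np.diff(W) > 0)

    def test_sex_swap_swaps_gradients(self):
        """Relabeling the sexes in a v=0 scenario swaps gradient components."""
        for sc, eq in endemic_random_cases(10, start_seed=900, symmetric=True):
            t = sc.init_traits
            g = selection_gradients(t, eq, sc.params)
            eq_sw = find_endemic_equilibrium(t.swapped(), sc.params)
            g_sw = selection_gradients(t.swapped(), eq_sw, sc.params)
            assert g.dW_alpha_f == pytest.approx(g_sw.dW_alpha_m, abs=1e-9)
            assert g.dW_gamma_f == pytest.approx(g_sw.dW_gamma_m, abs=1e-9)

    def test_step_halving_second_order(self, baseline_traits, asymmetric_eq, asymmetric_params):
        """Central differences: halving h shrinks the Richardson error ~4x."""
        g4 = selection_gradients(baseline_traits, asymmetric_eq, asymmetric_params, h=4e-3)
        g2 = selection_gradients(baseline_traits, asymmetric_eq, asymmetric_params, h=2e-3)
        g1 = selection_gradients(baseline_traits, asymmetric_eq, asymmetric_params, h=1e-3)
        for comp in ("dW_alpha_f", "dW_alpha_m", "dW_gamma_f", "dW_gamma_m"):
            e42 = abs(getattr(g4, comp) - getattr(g2, comp))
            e21 = abs(getattr(g2, comp) - getattr(g1, comp))
            if e42 > 1e-12:
                assert e21 < 0.5 * e42  # at least halving; ~quartering expected

    def test_invalid_step_rejected(self, baseline_traits, baseline_eq, baseline_params):
        with pytest.raises(ValueError):
            selection_gradients(baseline_traits, baseline_eq, baseline_params, h=0.0)
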