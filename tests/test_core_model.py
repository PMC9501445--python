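"""Core model: Gibbs-energy propagation, linkage, enthalpies, speciation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4phase.core_model import (
    Conditions,
    DomainError,
    R_KCAL,
    ReferenceConditions,
    SiteThermo,
    SystemModel,
    TransitionThermo,
    composite_transition,
    equilibrium_constant,
    folding_fractions,
    gibbs_energy,
    solve_speciation,
    species_enthalpies,
)

from conftest import brute_force_speciation, random_conditions


class TestGibbsEnergy:
    def test_reference_state_identity(self, model):
        assert gibbs_energy(model.ui, 298.15, 0.1) == pytest.approx(-4.7, abs=1e-12)
        assert gibbs_energy(model.iq, 298.15, 0.1) == pytest.approx(-1.0, abs=1e-12)

    def test_identity_with_zero_cp_and_equal_h_g(self):
        t = TransitionThermo("U->I", dG0=-3.0, dH0=-3.0, dCp=0.0, n=0.0)
        for T in (280.0, 298.15, 360.0):
            assert gibbs_energy(t, T, 0.1) == pytest.approx(-3.0, abs=1e-12)

    def test_ion_linkage_at_reference_temperature(self, model):
        # hand evaluation: -4.7 + (-1.3)*R*298.15*ln(0.001/0.1) = -1.153
        got = gibbs_energy(model.ui, 298.15, 0.001)
        assert got == pytest.approx(-1.1530, abs=1e-3)

    def test_gibbs_helmholtz_plus_linkage_at_20C_1mM(self, model):
        # hand evaluation of the closed form with dS0 = (dH0 - dG0)/T0
        assert gibbs_energy(model.ui, 293.15, 0.001) == pytest.approx(-1.6945, abs=1e-3)
        assert gibbs_energy(model.iq, 293.15, 0.001) == pytest.approx(-0.2749, abs=1e-3)

    def test_binding_sites_carry_no_ion_linkage(self, model):
        g_high = gibbs_energy(model.site1, 298.15, 0.1)
        g_low = gibbs_energy(model.site1, 298.15, 0.001)
        assert g_high == g_low == pytest.approx(-9.6, abs=1e-12)

    def test_domain_errors_name_the_field(self, model):
        with pytest.raises(DomainError, match="T"):
            gibbs_energy(model.ui, -1.0, 0.1)
        with pytest.raises(DomainError, match="cK"):
            gibbs_energy(model.ui, 298.15, 0.0)

    def test_linkage_identity(self, model):
        """d(dG)/d(ln cK) of a folding step equals n*R*T."""
        T = 310.0
        for t in model.transitions:
            eps = 1e-6
            g1 = gibbs_energy(t, T, 0.01 * math.exp(eps))
            g0 = gibbs_energy(t, T, 0.01 * math.exp(-eps))
            deriv = (g1 - g0) / (2 * eps)
            assert deriv == pytest.approx(t.n * R_KCAL * T, abs=1e-6)

    def test_vant_hoff_identity(self, model):
        """-R * dlnK/d(1/T) equals dH(T), dCp nonzero case."""
        T = 320.0
        h = 1e-7
        for t in model.transitions:
            lnK = lambda Ti: -gibbs_energy(t, Ti, 0.1) / (R_KCAL * Ti)
            inv = 1.0 / T
            dlnK = (lnK(1 / (inv + h)) - lnK(1 / (inv - h))) / (2 * h)
            dH_expected = t.dH0 + t.dCp * (T - 298.15)
            assert -R_KCAL * dlnK == pytest.approx(dH_expected, abs=1e-3)


class TestEquilibriumConstant:
    @pytest.mark.parametrize("dG, T, expected, rel", [
        (0.0, 298.15, 1.0, 1e-12),
        (-9.6, 298.15, 1.089e7, 1e-3),   # ~1.1e7 M^-1, upper end of affinity range
        (-8.7, 298.15, 2.383e6, 1e-3),   # ~2.4e6 M^-1
    ])
    def test_values(self, dG, T, expected, rel):
        assert equilibrium_constant(dG, T) == pytest.approx(expected, rel=rel)

    def test_monotone_decreasing_in_dG(self):
        gs = np.linspace(-10, 10, 50)
        ks = [equilibrium_constant(g, 300.0) for g in gs]
        assert all(a > b > 0 for a, b in zip(ks, ks[1:]))


class TestSpeciesEnthalpies:
    def test_reference_values(self, model):
        H = species_enthalpies(model, 298.15)
        assert H["U"] == 0.0
        assert H["I"] == pytest.approx(-34.0)
        assert H["Q"] == pytest.approx(-56.0)
        assert H["LIL"] == pytest.approx(-72.0)  # -34 - 18 - 20

    def test_path_independence_of_lil(self, model):
        """LIL enthalpy via IL (site1 last) equals via LI (site2 last)."""
        for T in (280.0, 298.15, 350.0):
            H = species_enthalpies(model, T)
            via_il = H["IL"] + (model.site1.dH0 + model.site1.dCp * (T - 298.15))
            via_li = H["LI"] + (model.site2.dH0 + model.site2.dCp * (T - 298.15))
            assert H["LIL"] == pytest.approx(via_il, abs=1e-12)
            assert H["LIL"] == pytest.approx(via_li, abs=1e-12)

    def test_temperature_independent_when_cp_zero(self, model):
        m = model.with_updates(**{"UI.dCp": 0.0, "IQ.dCp": 0.0,
                                  "site1.dCp": 0.0, "site2.dCp": 0.0})
        H1 = species_enthalpies(m, 280.0)
        H2 = species_enthalpies(m, 360.0)
        for s in m.species:
            assert H1[s] == pytest.approx(H2[s], abs=1e-12)


class TestHessAdditivity:
    def test_composite_u_to_q(self, model):
        comp = composite_transition(model)
        assert comp.dG0 == pytest.approx(model.ui.dG0 + model.iq.dG0)
        # additivity must hold at every (T, cK), not just at reference
        for T in (278.0, 310.0, 365.0):
            for cK in (1e-4, 1e-2, 0.1):
                total = gibbs_energy(model.ui, T, cK) + gibbs_energy(model.iq, T, cK)
                assert gibbs_energy(comp, T, cK) == pytest.approx(total, abs=1e-10)


class TestSpeciation:
    def test_ligand_free_three_state_reference(self, model):
        # Boltzmann weights 1 : K_UI : K_UI*K_IQ at 25 °C, 100 mM
        sp = solve_speciation(model, Conditions(T=298.15, cK=0.1, cDNA=1e-5))
        assert sp["U"] == pytest.approx(5.6e-5, rel=0.02)
        assert sp["I"] == pytest.approx(0.156, abs=0.002)
        assert sp["Q"] == pytest.approx(0.844, abs=0.002)
        assert sp.free_ligand == 0.0

    def test_q_i_coexistence_at_20C_1mM(self, model):
        """At 20 °C and 1 mM K+ the folded and intermediate forms coexist
        at roughly 60/40."""
        sp = solve_speciation(model, Conditions(T=293.15, cK=0.001, cDNA=1e-5))
        assert sp["Q"] == pytest.approx(0.60, abs=0.05)
        assert sp["I"] == pytest.approx(0.40, abs=0.05)

    def test_binding_disabled_gives_free_ligand_only(self, model):
        m = model.with_updates(**{"site1.dG0": 50.0, "site2.dG0": 50.0})
        cond = Conditions(T=298.15, cK=0.1, cDNA=1e-5, cL=3e-5)
        sp = solve_speciation(m, cond)
        for s in ("QL", "IL", "LI", "LIL"):
            assert sp[s] == pytest.approx(0.0, abs=1e-12)
        assert sp.free_ligand == pytest.approx(cond.cL, rel=1e-9)

    def test_mass_action_relations_hold(self, model):
        from g4phase.core_model import equilibrium_constants
        cond = Conditions(T=300.0, cK=0.05, cDNA=2e-5, cL=4e-5)
        sp = solve_speciation(model, cond)
        K_ui, K_iq, K1, K2 = equilibrium_constants(model, cond.T, cond.cK)
        L = sp.free_ligand
        assert sp["I"] == pytest.approx(K_ui * sp["U"], rel=1e-9)
        assert sp["Q"] == pytest.approx(K_iq * sp["I"], rel=1e-9)
        assert sp["QL"] == pytest.approx(K2 * sp["Q"] * L, rel=1e-9)
        assert sp["IL"] == pytest.approx(K2 * sp["I"] * L, rel=1e-9)
        assert sp["LI"] == pytest.approx(K1 * sp["I"] * L, rel=1e-9)
        assert sp["LIL"] == pytest.approx(K1 * K2 * sp["I"] * L * L, rel=1e-9)

    def test_thermodynamic_cycle_independence(self, model):
        """[LIL] computed through the IL path equals the LI path to 1e-12."""
        from g4phase.core_model import equilibrium_constants
        cond = Conditions(T=305.0, cK=0.1, cDNA=1e-5, cL=2e-5)
        sp = solve_speciation(model, cond)
        K_ui, K_iq, K1, K2 = equilibrium_constants(model, cond.T, cond.cK)
        L = sp.free_ligand
        via_li = K2 * sp["LI"] * L
        via_il = K1 * sp["IL"] * L
        assert abs(via_li - via_il) <= 1e-12 * max(via_li, 1e-30)

    def test_fraction_sums_over_many_random_conditions(self, model):
        """Fractions sum to 1 within 1e-9 over 10^4 random valid conditions."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            cond = random_conditions(rng)
            sp = solve_speciation(model, cond)
            total = sum(sp.fractions.values())
            assert abs(total - 1.0) < 1e-9
            assert 0.0 <= sp.free_ligand <= cond.cL + 1e-15

    def test_ligand_mass_balance(self, model):
        rng = np.random.default_rng(11)
        for _ in range(200):
            cond = random_conditions(rng)
            if cond.cL == 0.0:
                continue
            sp = solve_speciation(model, cond)
            bound = cond.cDNA * (sp["QL"] + sp["IL"] + sp["LI"] + 2 * sp["LIL"])
            assert sp.free_ligand + bound == pytest.approx(cond.cL, rel=1e-8)

    def test_matches_brute_force_grid_oracle(self, model):
        rng = np.random.default_rng(3)
        for _ in range(25):
            cond = random_conditions(rng)
            sp = solve_speciation(model, cond)
            oracle = brute_force_speciation(model, cond)
            for s in model.species:
                assert abs(sp[s] - oracle[s]) < 1e-6

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(T=st.floats(278.0, 368.0), log_cK=st.floats(-4.0, -1.0),
           r=st.floats(0.0, 3.0))
    def test_fractions_valid_property(self, T, log_cK, r):
        model = SystemModel.default()
        cond = Conditions(T=T, cK=10.0 ** log_cK, cDNA=1e-5, cL=r * 1e-5)
        sp = solve_speciation(model, cond)
        assert all(-1e-12 <= f <= 1 + 1e-12 for f in sp.fractions.values())
        assert sum(sp.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestVectorisedFoldingFractions:
    def test_matches_pointwise_solution(self, model):
        T = np.linspace(278, 368, 37)
        a_u, a_i, a_q = folding_fractions(model, T, 0.01)
        for j, Tj in enumerate(T):
            sp = solve_speciation(model, Conditions(T=float(Tj), cK=0.01, cDNA=1e-5))
            assert a_u[j] == pytest.approx(sp["U"], abs=1e-12)
            assert a_q[j] == pytest.approx(sp["Q"], abs=1e-12)


class TestValidation:
    def test_transition_name_restricted(self):
        with pytest.raises(ValueError):
            TransitionThermo("Q->U", -1.0, -1.0, 0.0, 0.0)

    def test_site_label_restricted(self):
        with pytest.raises(ValueError):
            SiteThermo(3, -1.0, -1.0, 0.0)

    def test_reference_conditions_positive(self):
        with pytest.raises(DomainError):
            ReferenceConditions(T0=-1.0)

    def test_conditions_temperature_window(self):
        with pytest.raises(DomainError):
            Conditions(T=500.0, cK=0.1)

    def test_tds_is_derived(self, model):
        assert model.ui.TdS0 == pytest.approx(model.ui.dH0 - model.ui.dG0)
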