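"""Multigroup next-generation analysis and vaccine allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import waningvax as wv
from waningvax import multigroup as mg
from waningvax import pde


@pytest.fixture(scope="module")
def shared_laws():
    inf = wv.constant_infectiousness(0.5, wv.exponential(0.25))
    sus = wv.step_sigma(wv.exponential(0.125))
    return inf, sus


class TestContactMatrix:
    def test_well_mixed(self):
        np.testing.assert_allclose(mg.two_group_contact_matrix(0.3, 1.0),
                                   np.ones((2, 2)))

    def test_disconnected_equal_groups(self):
        np.testing.assert_allclose(mg.two_group_contact_matrix(0.5, 0.0),
                                   np.diag([2.0, 2.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.05, 0.95), st.floats(0.0, 1.0))
    def test_equal_activity_constraint(self, p1, u):
        alpha = u * min(1 / p1, 1 / (1 - p1))
        g = mg.two_group_contact_matrix(p1, alpha)
        p = np.array([p1, 1 - p1])
        np.testing.assert_allclose(g @ p, [1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(g, g.T)

    def test_out_of_range_alpha(self):
        with pytest.raises(ValueError):
            mg.two_group_contact_matrix(0.2, 6.0)


class TestNextGeneration:
    def test_equal_sigmas_rho_independent_of_alpha(self, shared_laws):
        inf, sus = shared_laws
        vac = wv.gamma_law(4.0, 7.5)
        rhos = []
        for alpha in (0.2, 0.7, 1.0, 1.5):
            gm = mg.GroupModel([0.4, 0.6], mg.two_group_contact_matrix(0.4, alpha),
                               [vac, vac], inf, sus)
            rhos.append(mg.next_generation(gm).rho)
        sig = wv.stationary_susceptibility(sus, vac)
        np.testing.assert_allclose(rhos, sig, rtol=1e-12)

    def test_well_mixed_rho_is_weighted_mean(self, shared_laws):
        inf, sus = shared_laws
        gm = mg.GroupModel([0.3, 0.7], mg.two_group_contact_matrix(0.3, 1.0),
                           [wv.gamma_law(4.0, 7.5), wv.gamma_law(4.0, 2.0)],
                           inf, sus)
        res = mg.next_generation(gm)
        expect = 0.3 * res.sigmas[0] + 0.7 * res.sigmas[1]
        assert res.rho == pytest.approx(expect, rel=1e-12)

    def test_isolated_groups_rho_is_max(self, shared_laws):
        inf, sus = shared_laws
        gm = mg.GroupModel([0.5, 0.5], mg.two_group_contact_matrix(0.5, 0.0),
                           [wv.gamma_law(4.0, 7.5), wv.gamma_law(4.0, 2.0)],
                           inf, sus)
        with pytest.raises(ValueError):
            mg.next_generation(gm)
        res = mg.next_generation(gm, require_irreducible=False)
        assert res.rho == pytest.approx(np.max(res.sigmas), rel=1e-10)


class TestRhoOfAlpha:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 0.9), st.floats(0.05, 1.0), st.floats(0.05, 1.0),
           st.floats(0.0, 1.0))
    def test_closed_form_matches_power_iteration(self, p1, s1, s2, u):
        alpha = u * min(1 / p1, 1 / (1 - p1))
        m = mg.two_group_contact_matrix(p1, alpha) * \
            (np.array([p1, 1 - p1]) * np.array([s1, s2]))[None, :]
        assert mg.rho_of_alpha(p1, s1, s2, alpha) == pytest.approx(
            mg._power_iteration(m), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 0.9), st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_nonincreasing_convex_in_alpha(self, p1, s1, s2):
        a_max = min(1 / p1, 1 / (1 - p1))
        alphas = np.linspace(0, a_max, 100)
        rho = np.array([mg.rho_of_alpha(p1, s1, s2, a) for a in alphas])
        assert np.all(np.diff(rho) <= 1e-12)
        assert np.all(np.diff(rho, 2) >= -1e-9)

    def test_constant_when_sigmas_equal(self):
        vals = [mg.rho_of_alpha(0.4, 0.6, 0.6, a) for a in (0, 0.5, 1, 2)]
        np.testing.assert_allclose(vals, 0.6, rtol=1e-12)


class TestCriticalFraction:
    def test_perfect_vaccine_classic(self):
        assert mg.critical_vaccination_fraction(2.0, 0.0) == pytest.approx(0.5)

    def test_subcritical_needs_no_vaccination(self):
        assert mg.critical_vaccination_fraction(0.8, 0.3) <= 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(1.05, 6.0), st.floats(0.0, 0.9))
    def test_threshold_equivalence(self, r0, sigma):
        """R_0 rho(p1) crosses 1 exactly at p1 = p_c, with
        rho = 1 - (1 - Sigma) p1 (vaccine-hesitancy setting)."""
        pc = mg.critical_vaccination_fraction(r0, sigma)
        g = lambda p1: r0 * (1 - (1 - sigma) * p1) - 1.0
        assert abs(g(pc)) < 1e-10
        assert g(pc - 1e-6) > 0 > g(pc + 1e-6)

    def test_useless_vaccine_rejected(self):
        with pytest.raises(ValueError):
            mg.critical_vaccination_fraction(2.0, 1.0)


class TestFairAllocation:
    def test_even_split_identity(self):
        t = wv.gamma_law(4.0, 7.5)
        al = mg.fair_allocation(t, 0.0, 0.4)
        assert al.law1.mean == pytest.approx(t.mean)
        assert al.law2.mean == pytest.approx(t.mean)

    def test_endpoint_unvaccinated_group(self):
        t = wv.gamma_law(4.0, 7.5)
        al = mg.fair_allocation(t, 1 / 0.4, 0.4)  # all doses to group 1
        assert al.law2.is_infinite
        assert al.law1.mean == pytest.approx(0.4 * t.mean)

    def test_dose_budget_identity(self):
        t = wv.gamma_law(4.0, 7.5)
        p1 = 0.35
        m = t.mean
        for beta in np.linspace(-1 / 0.65 + 1e-9, 1 / 0.35 - 1e-9, 23):
            al = mg.fair_allocation(t, beta, p1)
            budget = p1 / al.law1.mean + (1 - p1) / al.law2.mean
            assert budget == pytest.approx(1 / m, abs=1e-12)

    def test_fair_split_minimizes_rho(self, shared_laws):
        inf, sus = shared_laws
        t = wv.gamma_law(4.0, 7.5)
        betas = np.linspace(-2, 2, 41)
        for alpha in (0.0, 0.5, 1.0):
            rhos = [mg.allocation_next_generation(t, b, 0.5, alpha, sus, inf).rho
                    for b in betas]
            assert betas[int(np.argmin(rhos))] == pytest.approx(0.0)

    def test_symmetric_under_group_swap(self, shared_laws):
        inf, sus = shared_laws
        t = wv.gamma_law(4.0, 7.5)
        for b in (0.3, 0.9, 1.6):
            r1 = mg.allocation_next_generation(t, b, 0.5, 0.5, sus, inf).rho
            r2 = mg.allocation_next_generation(t, -b, 0.5, 0.5, sus, inf).rho
            assert r1 == pytest.approx(r2, rel=1e-10)


class TestMultigroupVolterra:
    def test_identical_groups_collapse_to_homogeneous(self, shared_laws,
                                                      vaccinated_spec):
        inf, sus = shared_laws
        vac = wv.gamma_law(4.0, 7.5)
        hom = pde.solve_volterra(vaccinated_spec, dt=0.05, t_max=40.0,
                                 k_sigma=16)
        gm = mg.GroupModel([0.4, 0.6], mg.two_group_contact_matrix(0.4, 1.0),
                           [vac, vac], inf, sus)
        sols = mg.solve_multigroup_volterra(gm, 0.1, vaccinated_spec.h_i,
                                            vaccinated_spec.h_s, dt=0.05,
                                            t_max=40.0, k_sigma=16)
        np.testing.assert_allclose(sols[0].prevalence + sols[1].prevalence,
                                   hom.prevalence, atol=1e-9)
        np.testing.assert_allclose(sols[0].prevalence, 0.4 * hom.prevalence,
                                   atol=1e-9)

    def test_isolated_groups_conserve_group_mass(self, shared_laws,
                                                 vaccinated_spec):
        inf, sus = shared_laws
        gm = mg.GroupModel([0.5, 0.5], mg.two_group_contact_matrix(0.5, 0.0),
                           [wv.gamma_law(4.0, 7.5), wv.gamma_law(4.0, 2.0)],
                           inf, sus)
        sols = mg.solve_multigroup_volterra(gm, 0.1, vaccinated_spec.h_i,
                                            vaccinated_spec.h_s, dt=0.05,
                                            t_max=30.0, k_sigma=16)
        for s in sols:
            assert np.max(np.abs(s.prevalence + s.susceptible_mass - 0.5)) < 1e-3

    def test_threshold_predicts_long_time_multigroup_prevalence(self,
                                                                shared_laws,
                                                                vaccinated_spec):
        """Total prevalence survives at t -> infinity iff R_0 rho > 1."""
        inf, sus = shared_laws
        vacs = [wv.gamma_law(4.0, 7.5), wv.gamma_law(4.0, 15.0)]
        gm = mg.GroupModel([0.5, 0.5], mg.two_group_contact_matrix(0.5, 0.8),
                           vacs, inf, sus)
        rho = mg.next_generation(gm).rho
        for rel, expect_endemic in ((0.75, False), (1.5, True)):
            r0 = rel / rho
            gm2 = mg.GroupModel(gm.p, gm.gamma, vacs,
                                inf.rescaled(r0 / wv.basic_reproduction_number(inf)),
                                sus)
            sols = mg.solve_multigroup_volterra(
                gm2, 0.1, vaccinated_spec.h_i, vaccinated_spec.h_s,
                dt=0.05, t_max=250.0, k_sigma=16)
            total = sum(s.prevalence[-1] for s in sols)
            assert (total > 1e-3) == expect_endemic
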