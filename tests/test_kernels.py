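"""Duration/curve laws and the scalar functionals built from them."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import waningvax as wv
from waningvax.kernels import PointMassHazardError

# -- duration-law strategies -------------------------------------------------

duration_laws = st.one_of(
    st.floats(0.05, 5.0).map(wv.exponential),
    st.tuples(st.floats(0.5, 8.0), st.floats(0.2, 10.0)).map(
        lambda t: wv.gamma_law(*t)),
    st.tuples(st.floats(0.0, 3.0), st.floats(0.1, 5.0)).map(
        lambda t: wv.uniform_law(t[0], t[0] + t[1])),
)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(duration_laws)
def test_density_normalization_and_hazard_identity(law):
    """Densities integrate to 1 and hazard * survival = density pointwise."""
    hi = law.upper(1e-12)
    mass, _ = integrate.quad(lambda a: float(law.density(a)), 0.0, hi,
                             points=[p for p in law.kinks() if 0 < p < hi] or None,
                             limit=200)
    assert mass == pytest.approx(1.0, abs=1e-6)
    ages = np.linspace(0.01, law.quantile(0.99), 7)
    np.testing.assert_allclose(law.hazard(ages) * law.survival(ages),
                               law.density(ages), rtol=1e-10)
    assert law.survival(0.0) == pytest.approx(1.0)
    s = law.survival(np.linspace(0, hi, 50))
    assert np.all(np.diff(s) <= 1e-12)


def test_hazard_examples():
    assert wv.hazard(wv.exponential(0.7), 3.1) == pytest.approx(0.7)
    assert wv.hazard(wv.uniform_law(0.0, 1.0), 0.5) == pytest.approx(2.0)
    with pytest.raises(PointMassHazardError):
        wv.hazard(wv.fixed(2.0), 1.0)
    with pytest.raises(ValueError):
        wv.hazard(wv.uniform_law(0.0, 1.0), 1.5)  # beyond the support


def test_scaled_laws_preserve_family_and_mean():
    for law in (wv.exponential(0.5), wv.gamma_law(3, 2), wv.uniform_law(1, 3),
                wv.fixed(4.0), wv.two_point(1.0, 5.0, 0.25)):
        s = law.scaled(2.5)
        assert s.mean == pytest.approx(2.5 * law.mean)
        assert s.family == law.family


def test_basic_reproduction_number():
    # lambda = beta on Exp(gamma) period: R0 = beta/gamma
    law = wv.constant_infectiousness(0.6, wv.exponential(0.2))
    assert wv.basic_reproduction_number(law) == pytest.approx(3.0, rel=1e-8)
    # zero infectiousness
    z = wv.constant_infectiousness(0.0, wv.exponential(0.2))
    assert wv.basic_reproduction_number(z) == 0.0
    # fixed duration: beta * d
    f = wv.constant_infectiousness(2.0, wv.fixed(1.5))
    assert wv.basic_reproduction_number(f) == pytest.approx(3.0, rel=1e-8)


def test_r0_profile_family_quadrature_vs_oracle():
    """Hump-shaped profile on an exponential period against direct
    quadrature of the zero-extended mean curve."""
    prof = lambda a: 1.2 * np.asarray(a) * np.exp(-0.5 * np.asarray(a))
    law = wv.profile_infectiousness(prof, wv.exponential(0.3))
    oracle, _ = integrate.quad(lambda a: prof(a) * np.exp(-0.3 * a), 0, 300)
    assert wv.basic_reproduction_number(law) == pytest.approx(oracle, rel=1e-6)


class TestStationarySusceptibility:
    def test_step_fixed_durations(self):
        # sigma = 1{a>=1}, T_V = 2: Sigma = (2-1)/2
        sig = wv.step_sigma(wv.fixed(1.0))
        assert wv.stationary_susceptibility(sig, wv.fixed(2.0)) == pytest.approx(0.5)

    def test_no_immunity_gives_one(self):
        sig = wv.constant_sigma(1.0)
        for vac in (wv.fixed(3.0), wv.exponential(0.2), wv.gamma_law(2, 5)):
            assert wv.stationary_susceptibility(sig, vac) == pytest.approx(1.0)

    def test_exponential_pair_monte_carlo_oracle(self):
        # T_R ~ Exp(3), T_V ~ Exp(1): Sigma = E[(T_V - T_R)+]/E[T_V]
        sig = wv.step_sigma(wv.exponential(3.0))
        val = wv.stationary_susceptibility(sig, wv.exponential(1.0))
        rng = np.random.default_rng(12345)
        n = 2_000_000
        mc = np.maximum(rng.exponential(1.0, n) - rng.exponential(1 / 3, n),
                        0.0).mean()
        se = 3.0 / np.sqrt(n)  # generous bound on the MC s.e.
        assert abs(val - mc) < 4 * se
        assert val == pytest.approx(0.75, rel=1e-6)  # analytic omega/(omega+nu)

    def test_infinite_vaccination_returns_waning_limit(self):
        sig = wv.step_sigma(wv.exponential(0.5))
        with pytest.warns(UserWarning):
            assert wv.stationary_susceptibility(sig, wv.never()) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(duration_laws, st.floats(0.05, 2.0))
    def test_sigma_in_unit_interval(self, vac, rate):
        sig = wv.step_sigma(wv.exponential(rate))
        val = wv.stationary_susceptibility(sig, vac)
        assert 0.0 <= val <= 1.0

    def test_scale_monotonicity(self):
        """Sigma(m * T_V) is non-decreasing in the scale m (vaccinating less
        often can only raise the stationary susceptibility)."""
        sig = wv.gamma_cdf_sigma(3.0, 5.0)
        base = wv.gamma_law(2.0, 4.0)
        vals = [wv.stationary_susceptibility(sig, base.scaled(m))
                for m in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(vals) >= -1e-12)


class TestMeanCumulativeSusceptibility:
    def test_examples(self):
        sig = wv.step_sigma(wv.fixed(1.0))
        assert wv.mean_cumulative_susceptibility(sig, 0.0) == 0.0
        assert wv.mean_cumulative_susceptibility(sig, 2.0) == pytest.approx(1.0)
        full = wv.constant_sigma(1.0)
        assert wv.mean_cumulative_susceptibility(full, 3.0) == pytest.approx(3.0)

    def test_phi_convex_nondecreasing(self):
        sig = wv.step_sigma(wv.gamma_law(2.0, 3.0))
        ts = np.linspace(0, 25, 60)
        phi = np.array([sig.phi(t) for t in ts])
        assert np.all(np.diff(phi) >= -1e-12)
        assert np.all(np.diff(phi, 2) >= -1e-9)


class TestConvexOrderCompare:
    def test_point_mass_dominates_at_equal_mean(self):
        sig = wv.step_sigma(wv.fixed(1.0))
        rec = wv.convex_order_compare(wv.fixed(2.0), wv.exponential(0.5), sig)
        assert rec.sigma1 == pytest.approx(0.5)
        assert rec.sigma1 <= rec.sigma2 + 1e-12

    def test_identical_laws(self):
        sig = wv.step_sigma(wv.exponential(1.0))
        rec = wv.convex_order_compare(wv.gamma_law(2, 1), wv.gamma_law(2, 1), sig)
        assert rec.sign == 0

    def test_lower_dispersion_gamma_is_better(self):
        sig = wv.gamma_cdf_sigma(3.0, 1.0)
        rec = wv.convex_order_compare(wv.gamma_law(4.0, 0.5),
                                      wv.gamma_law(1.0, 2.0), sig)
        assert rec.sigma1 <= rec.sigma2 + 1e-12

    def test_unequal_means_rejected(self):
        sig = wv.step_sigma(wv.fixed(1.0))
        with pytest.raises(ValueError):
            wv.convex_order_compare(wv.fixed(2.0), wv.fixed(3.0), sig)


def test_model_spec_rescaling_invariants(vaccinated_spec):
    """Rescaling infectiousness by c multiplies R_0 by c and leaves the
    stationary susceptibility unchanged."""
    r0 = vaccinated_spec.r0
    sig = vaccinated_spec.sigma_stationary
    scaled = vaccinated_spec.with_r0(3.7)
    assert scaled.r0 == pytest.approx(3.7, rel=1e-8)
    assert scaled.sigma_stationary == pytest.approx(sig, rel=1e-12)
    assert r0 == pytest.approx(2.0, rel=1e-8)


def test_age_density_nodes_and_sampling():
    law = wv.gamma_law(3.0, 2.0)
    dens = wv.AgeDensity.stationary(law)
    ages, w = dens.nodes(128)
    assert w.sum() == pytest.approx(1.0)
    # mean of the stationary age distribution: E[T^2]/(2 E[T])
    m2 = law.expect(lambda t: t * t)
    assert np.dot(ages, w) == pytest.approx(m2 / (2 * law.mean), rel=1e-2)
    rng = np.random.default_rng(0)
    samp = dens.sample(rng, 200_000)
    assert samp.mean() == pytest.approx(m2 / (2 * law.mean), rel=2e-2)


def test_panel_sigma_curves_nondecreasing_unit_range():
    panel = wv.panel_sigma(k=32, seed=4)
    ages = np.linspace(0, 300, 400)
    for c in panel.panel[:8]:
        v = c(ages)
        assert np.all(np.diff(v) >= -1e-12)
        assert np.all((v >= 0) & (v <= 1))
    m = panel.mean(ages)
    assert np.all((m >= 0) & (m <= 1))
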