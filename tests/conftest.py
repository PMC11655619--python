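import pytest

import waningvax as wv


def make_sirs_spec(beta=0.5, gamma=0.25, omega=0.125, i0=0.1):
    """Classical SIRS as a special case: constant infectiousness on an
    exponential infectious period, step susceptibility with exponential
    immune period, no vaccination."""
    return wv.ModelSpec(
        infectiousness=wv.constant_infectiousness(beta, wv.exponential(gamma)),
        susceptibility=wv.step_sigma(wv.exponential(omega)),
        vaccination=wv.never(),
        i0=i0,
        h_i=wv.AgeDensity.stationary(wv.exponential(gamma)),
        h_s=wv.AgeDensity.stationary(wv.exponential(omega)))


def sirs_ode_prevalence(beta, gamma, omega, i0, r_init, t_eval):
    """Independent SIRS ODE oracle (S' = omega R - beta S I, ...)."""
    from scipy.integrate import solve_ivp

    def rhs(t, u):
        s, i, r = u
        return [omega * r - beta * s * i, beta * s * i - gamma * i,
                gamma * i - omega * r]

    out = solve_ivp(rhs, (float(t_eval[0]), float(t_eval[-1])),
                    [1.0 - i0 - r_init, i0, r_init], t_eval=t_eval,
                    rtol=1e-11, atol=1e-13)
    return out.y[1]


@pytest.fixture(scope="session")
def sis_spec():
    """SIS limit: full susceptibility at all ages, no vaccination,
    unit-mean exponential infectious period, R_0 = 2."""
    return wv.ModelSpec(
        infectiousness=wv.constant_infectiousness(2.0, wv.exponential(1.0)),
        susceptibility=wv.constant_sigma(1.0),
        vaccination=wv.never(),
        i0=0.1,
        h_i=wv.AgeDensity.stationary(wv.exponential(1.0)),
        h_s=wv.AgeDensity.point_mass(0.0))


@pytest.fixture(scope="session")
def vaccinated_spec():
    """Day-scale spec with waning (step) immunity and recurrent gamma-
    distributed boosters; R_0 Sigma > 1."""
    vac = wv.gamma_law(4.0, 7.5)
    return wv.ModelSpec(
        infectiousness=wv.constant_infectiousness(0.5, wv.exponential(0.25)),
        susceptibility=wv.step_sigma(wv.exponential(0.125)),
        vaccination=vac,
        i0=0.1,
        h_i=wv.AgeDensity.stationary(wv.exponential(0.25)),
        h_s=wv.AgeDensity.stationary(vac))


@pytest.fixture(scope="session")
def smooth_waning_spec():
    """Deterministic Gamma-CDF susceptibility (plateau then loss) with
    recurrent vaccination."""
    vac = wv.gamma_law(4.0, 15.0)
    return wv.ModelSpec(
        infectiousness=wv.constant_infectiousness(1.0, wv.exponential(0.25)),
        susceptibility=wv.gamma_cdf_sigma(3.0, 10.0),
        vaccination=vac,
        i0=0.1,
        h_i=wv.AgeDensity.stationary(wv.exponential(0.25)),
        h_s=wv.AgeDensity.stationary(vac)).with_r0(2.5)
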