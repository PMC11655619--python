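"""Stochastic individual-based simulator."""

import numpy as np
import pytest
from scipy import integrate, stats

import waningvax as wv
from waningvax import ibm, pde
from conftest import make_sirs_spec, sirs_ode_prevalence


def test_seeded_initialization_is_reproducible(vaccinated_spec):
    a = ibm.init_population(vaccinated_spec, 50, seed=11)
    b = ibm.init_population(vaccinated_spec, 50, seed=11)
    assert np.array_equal(a.state, b.state)
    assert np.array_equal(a.tau, b.tau)
    assert np.array_equal(a.r_imm, b.r_imm)


def test_initial_infected_count_is_binomial(vaccinated_spec):
    """Mean number of initially infected over replicates within 3 binomial
    standard errors of N * I_0."""
    n, i0, reps = 100, vaccinated_spec.i0, 2000
    counts = [int(np.sum(ibm.init_population(vaccinated_spec, n, seed=s).state))
              for s in range(reps)]
    se = np.sqrt(n * i0 * (1 - i0) / reps)
    assert abs(np.mean(counts) - n * i0) < 3 * se


def test_age_zero_point_mass_gives_unconditioned_curves(vaccinated_spec):
    spec = wv.ModelSpec(vaccinated_spec.infectiousness,
                        vaccinated_spec.susceptibility,
                        vaccinated_spec.vaccination, 0.5,
                        wv.AgeDensity.point_mass(0.0),
                        wv.AgeDensity.point_mass(0.0))
    st = ibm.init_population(spec, 200, seed=3)
    assert np.all(st.tau == 0.0)


def test_event_log_bit_identical_and_population_conserved(vaccinated_spec):
    runs = []
    for _ in range(2):
        st = ibm.init_population(vaccinated_spec, 300, seed=42)
        tr = ibm.simulate(st, 30.0, record_events=True)
        runs.append((tr.events, st))
    assert runs[0][0] == runs[1][0]
    st = runs[0][1]
    assert len(st.state) == 300
    assert np.sum(st.state == 1) + np.sum(st.state == 0) == 300
    # incrementally maintained force cache matches exact recomputation
    assert abs(st.sum_lam - st.total_infectiousness(st.time)) < 1e-9


def test_permanent_immunity_epidemic_dies_out():
    """sigma == 0: zero infections after t=0, prevalence decays as the
    initial infections recover."""
    spec = wv.ModelSpec(
        wv.constant_infectiousness(0.8, wv.exponential(0.5)),
        wv.step_sigma(wv.never()), wv.never(), 0.3,
        wv.AgeDensity.point_mass(0.0), wv.AgeDensity.point_mass(0.0))
    st = ibm.init_population(spec, 400, seed=5)
    tr = ibm.simulate(st, 40.0, record_events=True)
    assert all(kind != "infect" for _, _, kind in tr.events)
    assert tr.prevalence[-1] < 0.02
    assert tr.incidence[-1] == 0.0


def test_single_individual_recovers_then_only_vaccinations():
    spec = wv.ModelSpec(
        wv.constant_infectiousness(0.5, wv.exponential(1.0)),
        wv.step_sigma(wv.never()), wv.gamma_law(2.0, 1.0), 0.999,
        wv.AgeDensity.point_mass(0.0), wv.AgeDensity.point_mass(0.0))
    st = ibm.init_population(spec, 1, seed=2)
    assert st.state[0] == 1
    tr = ibm.simulate(st, 50.0, record_events=True)
    kinds = [k for _, _, k in tr.events]
    assert kinds[0] == "recover"
    assert set(kinds[1:]) == {"vaccinate"}


def test_thinning_reproduces_analytic_infection_law():
    """One susceptible facing a constant external force: infection times
    follow exp(-Lambda * int_0^a sigma) (Kolmogorov-Smirnov at 1%)."""
    lam_bar = 0.35
    sig = wv.gamma_cdf_sigma(2.0, 2.0)
    # individual 0: permanently infectious with lambda = 2*lam_bar so that
    # Lambda^N = lam_bar for N = 2; individual 1: fresh susceptible
    spec = wv.ModelSpec(
        wv.constant_infectiousness(2 * lam_bar, wv.fixed(1e9)),
        sig, wv.never(), 0.5,
        wv.AgeDensity.point_mass(0.0), wv.AgeDensity.point_mass(0.0))
    times = []
    seed = 0
    while len(times) < 10_000:
        st = ibm.init_population(spec, 2, seed=seed)
        seed += 1
        if not (st.state[0] == 1 and st.state[1] == 0):
            continue
        tr = ibm.simulate(st, 80.0, grid_dt=80.0, record_events=True)
        inf_ev = [e for e in tr.events if e[2] == "infect"]
        times.append(inf_ev[0][0] if inf_ev else np.inf)
    times = np.asarray(times)
    assert np.mean(~np.isfinite(times)) < 1e-3
    grid = np.linspace(0, 80, 8001)
    phi = integrate.cumulative_trapezoid(sig.curve(grid), grid, initial=0.0)
    cdf = lambda a: 1.0 - np.exp(-lam_bar * np.interp(a, grid, phi))
    res = stats.kstest(times[np.isfinite(times)], cdf)
    assert res.pvalue > 0.01


def test_sirs_replicate_mean_matches_ode():
    """SIRS parameterization: replicate-mean prevalence within 3 Monte Carlo
    standard errors of the independently integrated SIRS ODE."""
    beta, gamma, omega, i0 = 0.5, 0.25, 0.125, 0.1
    spec = make_sirs_spec(beta, gamma, omega, i0)
    n, reps = 2000, 8
    paths = []
    for s in range(reps):
        st = ibm.init_population(spec, n, seed=1000 + s)
        tr = ibm.simulate(st, 30.0, grid_dt=1.0)
        paths.append(tr.prevalence)
    paths = np.array(paths)
    t = np.arange(0.0, 30.0 + 0.5, 1.0)
    oracle = sirs_ode_prevalence(beta, gamma, omega, i0, (1 - i0) * 0.5, t)
    mean = paths.mean(axis=0)
    se = np.maximum(paths.std(axis=0, ddof=1), 1e-4) / np.sqrt(reps)
    # pointwise 3-sigma check away from t=0 (which is exact by construction)
    assert np.all(np.abs(mean - oracle)[1:] < 3.5 * se[1:] + 2e-3)


def test_empirical_age_measures():
    spec = wv.ModelSpec(
        wv.constant_infectiousness(0.5, wv.exponential(0.25)),
        wv.step_sigma(wv.exponential(0.2)), wv.never(), 0.5,
        wv.AgeDensity.point_mass(0.0), wv.AgeDensity.point_mass(0.0))
    st = ibm.init_population(spec, 2, seed=9)
    st.tau = np.array([-0.2, -1.7])
    st.state = np.array([1, 0], dtype=np.int8)
    edges, hi, hs = ibm.empirical_age_measures(st, 1.0)
    assert hi[0] == pytest.approx(0.5)       # infected, age 0.2 in [0,1)
    assert hs[1] == pytest.approx(0.5)       # susceptible, age 1.7 in [1,2)
    assert hi.sum() + hs.sum() == pytest.approx(1.0)


def test_age_histograms_converge_to_limit_densities(vaccinated_spec):
    """At moderate N the empirical age histogram is close to the limit
    densities I(t, .), S(t, .)."""
    t_end, bw = 25.0, 2.0
    sol = pde.solve_volterra(vaccinated_spec, dt=0.02, t_max=t_end, k_sigma=16)
    ages, dI, dS = pde.reconstruct_age_densities(sol, t=t_end, age_stride=2)
    reps, n = 6, 2000
    acc_i = acc_s = None
    for s in range(reps):
        st = ibm.init_population(vaccinated_spec, n, seed=300 + s)
        ibm.simulate(st, t_end, grid_dt=5.0)
        edges, hi, hs = ibm.empirical_age_measures(st, bw)
        k = min(len(hi), 12)
        hi, hs = hi[:k], hs[:k]
        if acc_i is None:
            acc_i, acc_s = np.zeros((reps, k)), np.zeros((reps, k))
        acc_i[s, :len(hi)] = hi
        acc_s[s, :len(hs)] = hs
    # limit-model bin masses
    k = acc_i.shape[1]
    bin_i = [np.trapezoid(dI[(ages >= m * bw) & (ages < (m + 1) * bw)],
                          ages[(ages >= m * bw) & (ages < (m + 1) * bw)])
             for m in range(k)]
    se_i = acc_i.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(acc_i.mean(axis=0) - bin_i) < 4 * se_i + 3e-3)


def test_fixed_step_scheme_agrees_roughly(vaccinated_spec):
    """The Bernoulli fixed-step fallback tracks the exact thinning scheme."""
    n, reps = 800, 4
    finals = {"thinning": [], "fixed_step": []}
    for scheme in finals:
        for s in range(reps):
            st = ibm.init_population(vaccinated_spec, n, seed=50 + s)
            tr = ibm.simulate(st, 25.0, grid_dt=1.0, scheme=scheme)
            finals[scheme].append(tr.prevalence[-1])
    assert abs(np.mean(finals["thinning"]) - np.mean(finals["fixed_step"])) < 0.05


def test_simulate_time_validation(vaccinated_spec):
    st = ibm.init_population(vaccinated_spec, 10, seed=0)
    ibm.simulate(st, 1.0)
    with pytest.raises(ValueError):
        ibm.simulate(st, 0.5)
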