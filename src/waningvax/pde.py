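"""Deterministic large-population limit of the epidemic.

As the population size grows, the empirical age structure of infected and
susceptible individuals converges to densities ``I(t,a)``, ``S(t,a)``
solving a pair of transport (age-structured) equations with boundary
renewal terms.  Along characteristics the system reduces to a set of
Volterra integral equations for the boundary fluxes

    x(t) = I(t, 0)   (incidence),
    y(t) = S(t, 0)   (flux of newly recovered / vaccinated),

coupled through the force of infection ``L(t) = int E[lambda(a)] x(t-a) da``.
The susceptible side carries a conditioning term: a susceptible of age ``a``
at time ``t`` has escaped infection since ``t-a``, which biases its random
susceptibility curve downwards.  This survives in the limit as the factor
``E[exp(-int_0^a L(t-a+u) sigma(u) du)]`` attached to each cohort.

The solver discretizes time on a uniform grid, applies the product
trapezoidal rule to every convolution, and resolves the per-step implicit
system by Picard iteration.  Expectations over the random susceptibility
curve are carried by a finite set of representatives (the single curve for
deterministic laws, quantile nodes of the immune period ``T_R`` for step
laws, the fixed panel otherwise); each cohort's exposure integral is
maintained incrementally, giving an O(n^2 K) total cost over n time steps.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy import integrate

from .kernels import (AgeDensity, DurationLaw, InfectiousnessLaw, ModelSpec,
                      SusceptibilityLaw)

__all__ = ["LimitSolution", "solve_volterra", "solve_volterra_groups",
           "exposure_weighted_susceptibility", "force_of_infection",
           "reconstruct_age_densities"]


@dataclasses.dataclass
class LimitSolution:
    """Discretized limit solution for one group.

    ``x``, ``y`` are the boundary fluxes, ``lam`` the group's own force of
    infection Lambda, ``force`` the total infection pressure felt by the
    group (equal to ``lam`` in the homogeneous model), ``prevalence`` and
    ``susceptible_mass`` the compartment masses (summing to the group
    weight ``p``).
    """

    t: np.ndarray
    dt: float
    x: np.ndarray
    y: np.ndarray
    lam: np.ndarray
    force: np.ndarray
    prevalence: np.ndarray
    susceptible_mass: np.ndarray
    p: float
    i0: float
    infectiousness: InfectiousnessLaw
    susceptibility: SusceptibilityLaw
    vaccination: DurationLaw
    h_i: AgeDensity
    h_s: AgeDensity
    k_sigma: int

    @property
    def conservation_drift(self) -> np.ndarray:
        return self.prevalence + self.susceptible_mass - self.p

    @property
    def max_conservation_drift(self) -> float:
        return float(np.max(np.abs(self.conservation_drift)))


def _tabulate(fn, idx_times):
    return np.asarray(fn(idx_times), dtype=float)


def _snap_nodes(density: AgeDensity, dt: float, n_nodes: int):
    ages, w = density.nodes(n_nodes)
    idx = np.rint(np.asarray(ages) / dt).astype(int)
    return idx, np.asarray(w, float)


def solve_volterra(spec: ModelSpec, dt: float, t_max: float,
                   k_sigma: int = 16, n_init: int = 64,
                   picard_tol: float = 1e-10, max_picard: int = 100,
                   mass_tol: float = 0.02) -> LimitSolution:
    """Solve the homogeneous limit equations on [0, t_max] with step dt."""
    sols = solve_volterra_groups(
        infectiousness=spec.infectiousness, susceptibility=spec.susceptibility,
        vaccinations=[spec.vaccination], p=[1.0], gamma=np.array([[1.0]]),
        i0=spec.i0, h_i=spec.h_i, h_s=spec.h_s, dt=dt, t_max=t_max,
        k_sigma=k_sigma, n_init=n_init, picard_tol=picard_tol,
        max_picard=max_picard, mass_tol=mass_tol)
    sol = sols[0]
    # a-priori bound of the limit system: x(t) <= L(t) <= I_0 lam_max e^{lam_max t}
    lm = spec.infectiousness.lam_max
    expo = lm * sol.t
    ok = expo < 700
    bound = spec.i0 * lm * np.exp(expo[ok])
    slack = 1e-9 + 1e-6 * np.maximum(bound, 1.0)
    if np.any(sol.x[ok] > sol.lam[ok] + 1e-9) or np.any(sol.lam[ok] > bound + slack):
        raise RuntimeError("a-priori bound x <= L <= I0*lam_max*exp(lam_max t) "
                           "violated: numerical scheme inconsistent")
    return sol


def solve_volterra_groups(infectiousness: InfectiousnessLaw,
                          susceptibility: SusceptibilityLaw,
                          vaccinations: Sequence[DurationLaw],
                          p: Sequence[float], gamma: np.ndarray,
                          i0: float, h_i: AgeDensity, h_s: AgeDensity,
                          dt: float, t_max: float, k_sigma: int = 16,
                          n_init: int = 64, picard_tol: float = 1e-10,
                          max_picard: int = 100,
                          mass_tol: float = 0.02) -> List[LimitSolution]:
    """Coupled Volterra system for L groups sharing the infectiousness and
    susceptibility laws, with per-group vaccination laws and symmetric
    contact matrix ``gamma``; within each group a fraction ``i0`` starts
    infected with age density ``h_i`` (susceptibles: ``h_s``)."""
    L = len(vaccinations)
    p = np.asarray(p, float)
    gamma = np.asarray(gamma, float)
    if gamma.shape != (L, L) or np.any(gamma < 0):
        raise ValueError("contact matrix must be LxL and non-negative")
    if not np.allclose(gamma, gamma.T):
        raise ValueError("contact matrix must be symmetric")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("group weights must sum to 1")
    if not 0 < i0 < 1:
        raise ValueError("i0 must be in (0, 1)")
    if t_max <= 0 or dt <= 0:
        raise ValueError("need t_max > 0 and dt > 0")
    lam_max = infectiousness.lam_max
    if lam_max * dt >= 0.1:
        raise ValueError(f"dt too large: need lam_max*dt < 0.1, got {lam_max * dt:.3g}")
    if not infectiousness.duration.has_density:
        raise ValueError("the infectious period must have a density")
    for v in vaccinations:
        if not (v.has_density or v.is_infinite):
            raise ValueError("vaccination laws must have a density or be the "
                             "infinite (no-vaccination) sentinel")

    n = int(round(t_max / dt))
    t = np.arange(n + 1) * dt

    qidx_i, wq_i = _snap_nodes(h_i, dt, n_init)
    qidx_s, wq_s = _snap_nodes(h_s, dt, n_init)
    m_ext = n + int(max(qidx_i.max(), qidx_s.max())) + 2
    a_ext = np.arange(m_ext) * dt

    elam = _tabulate(infectiousness.mean_curve, a_ext)
    s_i = _tabulate(infectiousness.duration.survival, a_ext)
    f_i = _tabulate(infectiousness.duration.density, a_ext)
    if np.any(s_i[qidx_i] <= 0):
        raise ValueError("h_I places mass beyond the support of T_I: cannot "
                         "condition the initial infectiousness curves")

    s_v, f_v = [], []
    for v in vaccinations:
        if v.is_infinite:
            s_v.append(np.ones(m_ext))
            f_v.append(np.zeros(m_ext))
        else:
            s_v.append(_tabulate(v.survival, a_ext))
            f_v.append(_tabulate(v.density, a_ext))
        if np.any(s_v[-1][qidx_s] <= 0):
            raise ValueError("h_S places mass beyond the support of T_V")

    wk, curves, step_rs = susceptibility.representatives(k_sigma)
    K = len(wk)
    sig = np.column_stack([np.clip(np.asarray(c(a_ext), float), 0.0, 1.0)
                           for c in curves])  # (m_ext, K)
    binary = step_rs is not None

    half = 0.5 * dt

    # histories
    X = np.zeros((L, n + 1))
    Y = np.zeros((L, n + 1))
    LAM = np.zeros((L, n + 1))
    FORCE = np.zeros((L, n + 1))
    PREV = np.zeros((L, n + 1))
    SMASS = np.zeros((L, n + 1))

    # exposure state: exp(-int F sigma) per cohort (rows) and representative
    W = [np.ones((n + 1, K)) for _ in range(L)]
    Winit = [np.ones((len(qidx_s), K)) for _ in range(L)]

    # per-step gathers from the initial-age nodes
    def init_i_force(j):
        return float(np.dot(wq_i, elam[qidx_i + j] / s_i[qidx_i]))

    def init_i_flux(j):
        return float(np.dot(wq_i, f_i[qidx_i + j] / s_i[qidx_i]))

    def init_i_mass(j):
        return float(np.dot(wq_i, s_i[qidx_i + j] / s_i[qidx_i]))

    def _trap(arr, hist, j):
        # product-trapezoid of arr[c]*hist[c] over cohorts c = 0..j
        s = float(np.dot(arr, hist))
        return dt * (s - 0.5 * arr[0] * hist[0] - 0.5 * arr[j] * hist[j])

    # ---- step 0: everything determined by the initial ages -----------------
    lam0 = i0 * p * init_i_force(0)
    f0 = gamma @ lam0
    sig_init0 = sig[qidx_s, :]                      # (Q, K)
    for l in range(L):
        mσ = float(np.dot(wq_s, sig_init0 @ wk))
        X[l, 0] = f0[l] * (1 - i0) * p[l] * mσ
        Y[l, 0] = (i0 * p[l] * init_i_flux(0)
                   + (1 - i0) * p[l] * float(np.dot(wq_s, f_v[l][qidx_s] / s_v[l][qidx_s])))
        LAM[l, 0] = lam0[l]
        FORCE[l, 0] = f0[l]
        PREV[l, 0] = i0 * p[l]
        SMASS[l, 0] = (1 - i0) * p[l]

    # ---- time stepping ------------------------------------------------------
    for j in range(1, n + 1):
        f_prev = FORCE[:, j - 1]
        sig_prev_rev = sig[j - 1::-1, :]            # cohorts 0..j-1 at t_{j-1}
        sig_old_rev = sig[j:0:-1, :]                # cohorts 0..j-1 at t_j
        sig_init_prev = sig[qidx_s + (j - 1), :]
        sig_init_cur = sig[qidx_s + j, :]
        sig0 = float(sig[0] @ wk)                   # mean sigma at age 0

        elam_rev = elam[j::-1]
        fi_rev = f_i[j::-1]
        si_rev = s_i[j::-1]

        B0 = [None] * L
        B1 = [None] * L
        for l in range(L):
            # fold the F_{j-1} half-increment of the exposure into W
            if binary:
                sp = np.exp(-half * f_prev[l])
                W[l][0:j] *= 1.0 + (sp - 1.0) * sig_prev_rev
            else:
                W[l][0:j] *= np.exp(-half * f_prev[l] * sig_prev_rev)
            Winit[l] *= np.exp(-half * f_prev[l] * sig_init_prev)
            if binary:
                A = W[l][0:j]
                B1[l] = (sig_old_rev * A) @ wk
                B0[l] = A @ wk

        initIL = init_i_force(j)
        initIy = init_i_flux(j)

        # Picard iteration for (x_j, y_j, F_j)
        xj = X[:, j - 1].copy()
        yj = Y[:, j - 1].copy()
        num1_final = [None] * L
        for it in range(max_picard):
            X[:, j] = xj
            Y[:, j] = yj
            lam_j = np.empty(L)
            for l in range(L):
                lam_j[l] = _trap(elam_rev, X[l, 0:j + 1], j) + i0 * p[l] * initIL
            f_j = gamma @ lam_j
            x_new = np.empty(L)
            y_new = np.empty(L)
            for l in range(L):
                sv_rev = s_v[l][j::-1]
                fv_rev = f_v[l][j::-1]
                num_sig = np.empty(j + 1)
                num_one = np.empty(j + 1)
                # the cohort born at t_j has zero exposure
                num_sig[j] = sig0
                num_one[j] = 1.0
                if binary:
                    s = np.exp(-half * f_j[l])
                    num_sig[:j] = s * B1[l]
                    num_one[:j] = B0[l] + (s - 1.0) * B1[l]
                else:
                    Wt = W[l][0:j] * np.exp(-half * f_j[l] * sig_old_rev)
                    num_sig[:j] = (sig_old_rev * Wt) @ wk
                    num_one[:j] = Wt @ wk
                num1_final[l] = num_one
                Wti = Winit[l] * np.exp(-half * f_j[l] * sig_init_cur)
                svr = s_v[l][qidx_s + j] / s_v[l][qidx_s]
                fvr = f_v[l][qidx_s + j] / s_v[l][qidx_s]
                init_sig = float(np.dot(wq_s * svr, (sig_init_cur * Wti) @ wk))
                init_one = float(np.dot(wq_s * fvr, Wti @ wk))
                x_new[l] = f_j[l] * (_trap(sv_rev * num_sig, Y[l, 0:j + 1], j)
                                     + (1 - i0) * p[l] * init_sig)
                y_new[l] = (_trap(fi_rev, X[l, 0:j + 1], j)
                            + i0 * p[l] * initIy
                            + _trap(fv_rev * num_one, Y[l, 0:j + 1], j)
                            + (1 - i0) * p[l] * init_one)
            err = max(np.max(np.abs(x_new - xj)), np.max(np.abs(y_new - yj)))
            scale = max(1.0, float(np.max(np.abs(x_new))), float(np.max(np.abs(y_new))))
            xj, yj = x_new, y_new
            if err < picard_tol * scale:
                break
        else:
            raise RuntimeError(f"Picard iteration did not converge at t={j * dt:.3f}; "
                               "reduce dt")
        X[:, j] = xj
        Y[:, j] = yj
        LAM[:, j] = lam_j
        FORCE[:, j] = f_j

        # commit the F_j half-increment (pre-existing cohorts only) and
        # record masses
        for l in range(L):
            if binary:
                s = np.exp(-half * f_j[l])
                W[l][0:j] *= 1.0 + (s - 1.0) * sig_old_rev
            else:
                W[l][0:j] *= np.exp(-half * f_j[l] * sig_old_rev)
            Winit[l] *= np.exp(-half * f_j[l] * sig_init_cur)
            sv_rev = s_v[l][j::-1]
            num_one = np.empty(j + 1)
            num_one[:j] = W[l][0:j] @ wk
            num_one[j] = 1.0
            svr = s_v[l][qidx_s + j] / s_v[l][qidx_s]
            PREV[l, j] = (_trap(si_rev, X[l, 0:j + 1], j)
                          + i0 * p[l] * init_i_mass(j))
            SMASS[l, j] = (_trap(sv_rev * num_one, Y[l, 0:j + 1], j)
                           + (1 - i0) * p[l] * float(np.dot(wq_s * svr, Winit[l] @ wk)))

    drift = np.abs(PREV.sum(axis=0) + SMASS.sum(axis=0) - 1.0)
    if np.max(drift) > mass_tol:
        raise RuntimeError(f"mass conservation drift {np.max(drift):.3g} exceeds "
                           f"tolerance {mass_tol}; reduce dt")
    if np.any(X < -1e-9) or np.any(Y < -1e-9) or np.any(LAM < -1e-9):
        raise RuntimeError("negative boundary values: numerical instability")

    return [LimitSolution(t=t, dt=dt, x=X[l], y=Y[l], lam=LAM[l], force=FORCE[l],
                          prevalence=PREV[l], susceptible_mass=SMASS[l], p=float(p[l]),
                          i0=i0, infectiousness=infectiousness,
                          susceptibility=susceptibility,
                          vaccination=vaccinations[l], h_i=h_i, h_s=h_s,
                          k_sigma=k_sigma)
            for l in range(L)]


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def force_of_infection(solution: LimitSolution, t: float) -> float:
    """Lambda(t) = int E[lambda(a)|T_I>a] I(t,a) da, cached by the solver."""
    j = int(round(t / solution.dt))
    if not 0 <= j < len(solution.t) or abs(solution.t[j] - t) > 1e-9:
        raise ValueError(f"t={t} is not on the solution grid")
    return float(solution.lam[j])


def exposure_weighted_susceptibility(sus: SusceptibilityLaw,
                                     lam_history: Callable,
                                     a: float, n_grid: int = 2049,
                                     k_sigma: int = 64) -> float:
    """Expected susceptibility of a susceptible of age ``a`` conditioned on
    having escaped infection, under the force-of-infection history
    ``lam_history(u) = Lambda(t - a + u)`` for u in [0, a]:

        E[ sigma(a) e^{-int_0^a Lam sigma} ] / E[ e^{-int_0^a Lam sigma} ].

    For a deterministic curve the conditioning bias vanishes and sigma(a) is
    returned exactly.
    """
    if a < 0:
        raise ValueError("age must be non-negative")
    if sus.kind == "deterministic":
        return float(sus.curve(a))
    u = np.linspace(0.0, a, n_grid)
    lam = np.clip(np.asarray(lam_history(u), float), 0.0, None)
    cum = integrate.cumulative_trapezoid(lam, u, initial=0.0)

    if sus.kind == "step":
        rec = sus.recovery
        # exposure for immune period r: cum(a) - cum(r) for r < a, else 0
        def num_den(r):
            if r >= a:
                return 0.0, 1.0
            e = cum[-1] - float(np.interp(r, u, cum))
            w = np.exp(-e)
            return w, w
        if rec.is_infinite:
            return 0.0
        if rec._atoms is not None:
            num = sum(p * num_den(r)[0] for r, p in rec._atoms)
            den = sum(p * num_den(r)[1] for r, p in rec._atoms)
        else:
            num = rec.expect(lambda r: num_den(r)[0], extra_points=(a,))
            den = rec.expect(lambda r: num_den(r)[1], extra_points=(a,))
        if den <= 0:
            raise ValueError("degenerate conditioning (zero escape probability)")
        return float(num / den)

    if not sus.panel:
        raise ValueError("empty susceptibility panel")
    num = den = 0.0
    for c in sus.panel:
        sv = np.asarray(c(u), float)
        e = np.exp(-np.trapezoid(lam * sv, u))
        num += sv[-1] * e
        den += e
    return float(num / den)


def reconstruct_age_densities(solution: LimitSolution,
                              t: Optional[float] = None,
                              age_stride: int = 1,
                              max_age: Optional[float] = None):
    """Rebuild the age densities I(t, .), S(t, .) from the boundary fluxes.

    Along characteristics, for a <= t:

        I(t,a) = x(t-a) * P(T_I > a),
        S(t,a) = y(t-a) * P(T_V > a) * E[e^{-int_0^a F(t-a+u) sigma(u) du}],

    while cohorts older than t descend from the initial condition.  Returns
    (ages, I_density, S_density).
    """
    dt = solution.dt
    if t is None:
        t = float(solution.t[-1])
    j = int(round(t / dt))
    if not 0 <= j < len(solution.t):
        raise ValueError("t outside the solved horizon")
    inf, sus, vac = (solution.infectiousness, solution.susceptibility,
                     solution.vaccination)
    if max_age is None:
        up_v = vac.upper() if not vac.is_infinite else 0.0
        max_age = float(min(t + max(solution.h_i.upper(), solution.h_s.upper()),
                            t + max(inf.duration.upper(), up_v, 1.0)))
    idx = np.arange(0, int(round(max_age / dt)) + 1, age_stride)
    ages = idx * dt
    wk, curves, _ = sus.representatives(solution.k_sigma)
    sig_tab = np.column_stack([np.clip(np.asarray(c(ages), float), 0, 1)
                               for c in curves])

    s_i = inf.duration.survival(ages)
    s_v = np.ones_like(ages) if vac.is_infinite else vac.survival(ages)
    F = solution.force

    I = np.zeros_like(ages)
    S = np.zeros_like(ages)
    for m, i in enumerate(idx):
        a = ages[m]
        if i <= j:
            # exposure of the cohort born at t - a, per representative
            tt = solution.t[j - i:j + 1]
            esc = np.empty(len(wk))
            for k, c in enumerate(curves):
                sv = np.asarray(c(tt - tt[0]), float)
                esc[k] = np.exp(-np.trapezoid(F[j - i:j + 1] * sv, tt))
            I[m] = solution.x[j - i] * s_i[m]
            S[m] = solution.y[j - i] * s_v[m] * float(np.dot(wk, esc))
        else:
            b = a - t
            if solution.h_i.kind != "point":
                sib = float(inf.duration.survival(b))
                if sib > 0:
                    I[m] = solution.i0 * solution.p * solution.h_i.density(b) * s_i[m] / sib
            if solution.h_s.kind != "point":
                svb = 1.0 if vac.is_infinite else float(vac.survival(b))
                if svb > 0:
                    tt = solution.t[:j + 1]
                    esc = np.empty(len(wk))
                    for k, c in enumerate(curves):
                        sv = np.asarray(c(b + tt), float)
                        esc[k] = np.exp(-np.trapezoid(F[:j + 1] * sv, tt)) if j > 0 else 1.0
                    S[m] = ((1 - solution.i0) * solution.p * solution.h_s.density(b)
                            * s_v[m] / svb * float(np.dot(wk, esc)))
    return ages, I, S
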