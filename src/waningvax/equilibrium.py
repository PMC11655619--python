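"""Equilibrium analysis of the homogeneous limit equations.

The limit system always admits a disease-free equilibrium: the stationary
age distribution of the vaccination renewal process,
``S(a) = P(T_V > a) / E[T_V]``.  Endemic equilibria are in one-to-one
correspondence with the positive roots of ``F_e(x) = R_0`` where

    F_e(x) = x E[T_I]
           + x E[ int_0^{T_V} e^{-x phi(a)} da ] / E[ 1 - e^{-x phi(T_V)} ],

``phi(a) = int_0^a sigma(u) du`` being the per-realization cumulative
susceptibility.  ``F_e`` tends to ``1/Sigma`` as ``x -> 0`` (with ``Sigma``
the mean susceptibility at the disease-free equilibrium), is increasing for
deterministic and step susceptibility curves, and hence a unique endemic
equilibrium exists in those families iff ``R_0 * Sigma > 1``.  Given a root
``x``, the equilibrium has incidence ``I(0) = x / R_0``, prevalence
``x E[T_I] / R_0`` (the endemic level) and explicit exponential age
profiles.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import numpy as np
from scipy import integrate, optimize

from .kernels import (DurationLaw, ModelSpec, SusceptibilityLaw,
                      stationary_susceptibility)

__all__ = ["EndemicEquilibrium", "disease_free_equilibrium",
           "endemic_function", "endemic_function_limit0",
           "find_endemic_equilibria", "endemic_threshold"]


@dataclasses.dataclass
class EndemicEquilibrium:
    x: float                 # root of F_e(x) = R_0, equal to Lambda at equilibrium
    r0: float
    i_boundary: float        # I(0) = x / R_0
    s_boundary: float
    ages: np.ndarray
    i_profile: np.ndarray
    s_profile: np.ndarray
    prevalence: float        # int I(a) da = x E[T_I] / R_0 (the endemic level)

    @property
    def endemic_level(self) -> float:
        return self.prevalence


def disease_free_equilibrium(vac: DurationLaw, ages) -> np.ndarray:
    """Stationary age density of the vaccination renewal process,
    S(a) = exp(-int_0^a mu_V) / E[T_V]."""
    if vac.is_infinite or not np.isfinite(vac.mean):
        raise ValueError("disease-free equilibrium needs a finite-mean "
                         "vaccination law")
    return vac.survival(np.asarray(ages, float)) / vac.mean


# ---------------------------------------------------------------------------
# The endemic function
# ---------------------------------------------------------------------------


def _phi_representatives(sus: SusceptibilityLaw, k_sigma: int, a_max: float):
    """Per-representative cumulative susceptibility phi_k as callables."""
    wk, curves, step_rs = sus.representatives(k_sigma)
    if step_rs is not None:
        phis = [(lambda a, r=r: np.maximum(np.asarray(a, float) - r, 0.0))
                for r in step_rs]
        return wk, curves, phis
    grid = np.linspace(0.0, max(a_max, 1.0), 16385)
    phis = []
    for c in curves:
        vals = np.clip(np.asarray(c(grid), float), 0.0, 1.0)
        cum = integrate.cumulative_trapezoid(vals, grid, initial=0.0)
        slope = vals[-1]  # linear extension beyond the tabulated range
        phis.append(lambda a, g=grid, cc=cum, s=slope:
                    np.where(np.asarray(a, float) <= g[-1],
                             np.interp(a, g, cc),
                             cc[-1] + s * (np.asarray(a, float) - g[-1])))
    return wk, curves, phis


def _fe_terms_step(x: float, rec: DurationLaw, vac: DurationLaw):
    """Step-susceptibility terms, integrating adaptively over T_R.

    With sigma(a) = 1{a >= r}, phi(a) = (a - r)_+ and

        E[int_0^{T_V} e^{-x phi}]        = E[T_V ^ T_R] + E[h_x(T_R)],
        E[int_0^{T_V} sigma e^{-x phi}]  = E[h_x(T_R)],

    where h_x(r) = int_r^inf e^{-x(a-r)} P(T_V > a) da.
    """
    if rec.is_infinite:  # permanent immunity: no reinfection at any x
        return np.inf, 0.0
    if vac.is_infinite:
        # P(T_V > a) = 1: E[T_V ^ T_R] = E[T_R], h_x(r) = 1/x
        if not np.isfinite(rec.mean):
            return np.inf, 0.0
        return rec.mean + 1.0 / x, 1.0 / x
    a_hi = vac.upper(1e-12)
    vkinks = vac.kinks()

    def h(r):
        if r >= a_hi:
            return 0.0
        pts = [p for p in vkinks if r < p < a_hi]
        v, _ = integrate.quad(
            lambda a: np.exp(-x * (a - r)) * float(vac.survival(a)),
            r, a_hi, points=pts or None, limit=300)
        return v

    # E[T_V ^ T_R] = int_0^inf P(T_V > a) P(T_R > a) da
    pts = [p for p in (*vkinks, *rec.kinks()) if 0 < p < a_hi]
    e_min, _ = integrate.quad(
        lambda a: float(vac.survival(a)) * float(rec.survival(a)),
        0.0, a_hi, points=pts or None, limit=300)
    if rec._atoms is not None:
        eh = sum(p * h(r) for r, p in rec._atoms)
    else:
        eh = rec.expect(h, extra_points=(a_hi,))
    return e_min + eh, eh


def _fe_terms(x: float, sus: SusceptibilityLaw, vac: DurationLaw,
              k_sigma: int):
    """Numerator E[int_0^{T_V} e^{-x phi}] and the susceptibility-weighted
    denominator E[int_0^{T_V} sigma e^{-x phi}] (equal to
    E[1 - e^{-x phi(T_V)}]/x)."""
    if sus.kind == "step":
        return _fe_terms_step(x, sus.recovery, vac)
    a_hi = None if vac.is_infinite else vac.upper(1e-12)
    wk, curves, phis = _phi_representatives(
        sus, k_sigma, a_hi if a_hi is not None else _damping_range(sus, x))
    num = den = 0.0
    for w, c, phi in zip(wk, curves, phis):
        if a_hi is None:
            hi = _rep_range(phi, x)
            sfun = lambda a: 1.0
            kinks = ()
        else:
            hi = a_hi
            sfun = vac.survival
            kinks = vac.kinks()
        pts = [p for p in (*kinks, *sus.mean_kinks()) if 0 < p < hi]
        nv, _ = integrate.quad(
            lambda a: float(sfun(a)) * np.exp(-x * float(phi(a))),
            0.0, hi, points=pts or None, limit=300)
        dv, _ = integrate.quad(
            lambda a: float(sfun(a)) * float(c(a)) * np.exp(-x * float(phi(a))),
            0.0, hi, points=pts or None, limit=300)
        if a_hi is None:
            # tail of the numerator beyond hi: e^{-x phi} with phi ~ linear
            s_inf = max(float(c(hi)), 1e-12)
            nv += np.exp(-x * float(phi(hi))) / (x * s_inf)
            dv += np.exp(-x * float(phi(hi))) / x
        num += w * nv
        den += w * dv
    return num, den


def _damping_range(sus: SusceptibilityLaw, x: float) -> float:
    hi = 1.0
    while x * sus.phi(hi) < 50 and hi < 1e7:
        hi *= 2
    return hi


def _rep_range(phi, x: float) -> float:
    hi = 1.0
    while x * float(phi(hi)) < 50 and hi < 1e7:
        hi *= 2
    return hi


def endemic_function(x: float, spec: ModelSpec, k_sigma: int = 64,
                     method: str = "auto") -> float:
    """Evaluate F_e(x) for x > 0.

    ``method='closed_form'`` uses the step-susceptibility reduction
    F_e(x) = x E[T_I] + 1 + E[T_V ^ T_R] / E[int_0^{(T_V-T_R)+} e^{-xa} da];
    ``method='quadrature'`` uses the generic representative average.  The
    two agree for step curves and serve as mutual checks.
    """
    if x <= 0:
        raise ValueError("x must be positive; the x->0 limit is "
                         "endemic_function_limit0 (= 1/Sigma)")
    e_ti = spec.infectiousness.duration.mean
    sus, vac = spec.susceptibility, spec.vaccination
    if method == "auto":
        method = "closed_form" if (sus.kind == "step"
                                   and not vac.is_infinite) else "quadrature"
    if method == "closed_form":
        if sus.kind != "step" or vac.is_infinite:
            raise ValueError("closed form requires a step susceptibility law "
                             "and a finite vaccination law")
        rec = sus.recovery
        if rec.is_infinite:
            return np.inf

        # expectations taken against the densities / atoms of T_R and T_V
        # (the generic route integrates against survival functions instead)
        def e_tv(g, r):
            return vac.expect(lambda t: g(t, r), extra_points=(r,))

        e_min = rec.expect(lambda r: e_tv(lambda t, r: min(t, r), r))
        # E[ int_0^{(T_V - T_R)+} e^{-xa} da ] = E[ (1 - e^{-x (T_V-T_R)+}) / x ]
        eh = rec.expect(
            lambda r: e_tv(lambda t, r: -np.expm1(-x * max(t - r, 0.0)) / x, r))
        if eh <= 0:
            return np.inf
        return x * e_ti + 1.0 + e_min / eh

    num, den = _fe_terms(x, sus, vac, k_sigma)
    if den <= 0:
        return np.inf
    return x * e_ti + num / den


def endemic_function_limit0(spec: ModelSpec) -> float:
    """lim_{x->0+} F_e(x) = 1/Sigma (infinite when immunity never wanes)."""
    s = stationary_susceptibility(spec.susceptibility, spec.vaccination)
    return np.inf if s <= 0 else 1.0 / s


def endemic_threshold(spec: ModelSpec) -> float:
    """The value 1/Sigma of R_0 above which an endemic equilibrium exists."""
    return endemic_function_limit0(spec)


# ---------------------------------------------------------------------------
# Fast cached evaluator (used by the root scan)
# ---------------------------------------------------------------------------


def _density_nodes(law: DurationLaw, n_seg: int = 64, n_per: int = 16):
    """Composite Gauss-Legendre nodes/weights for E[g(T)] against a
    continuous duration law (atoms returned directly).  Quantile segments
    are refined geometrically in the tail so that light-tailed laws are
    integrated accurately."""
    if law._atoms is not None:
        return (np.array([v for v, _ in law._atoms]),
                np.array([p for _, p in law._atoms]))
    qs = np.concatenate([np.linspace(0.0, 0.9, n_seg + 1),
                         1.0 - 10.0 ** (-np.arange(2, 13, 0.5))])
    qs = np.unique(qs)
    edges = np.array([law.quantile(max(q, 1e-13)) for q in qs]
                     + [law.upper(1e-13)])
    xg, wg = np.polynomial.legendre.leggauss(n_per)
    nodes, weights = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
        r = mid + half * xg
        nodes.append(r)
        weights.append(half * wg * law.density(r))
    nodes = np.concatenate(nodes)
    weights = np.concatenate(weights)
    return nodes, weights / weights.sum()


class FeEvaluator:
    """Cached evaluator of F_e on which a dense root scan is affordable.

    All x-independent structure (survival tables, per-representative
    cumulative susceptibilities, the overshoot kernel
    G(a) = P(T_V - T_R > a) for step curves) is tabulated once; each
    evaluation is then a vectorized quadrature.
    """

    def __init__(self, spec: ModelSpec, k_sigma: int = 64,
                 n_grid: int = 16385):
        sus, vac = spec.susceptibility, spec.vaccination
        self.e_ti = spec.infectiousness.duration.mean
        self.mode = None
        if sus.kind == "step":
            rec = sus.recovery
            if rec.is_infinite:
                self.mode = "immune"         # sigma == 0: F_e = inf
            elif vac.is_infinite:
                self.mode = "step_novacc"    # num = E[T_R] + 1/x, den = 1/x
                self.e_tr = rec.mean
            else:
                self.mode = "step"
                a_hi = vac.upper(1e-12)
                self.a = np.linspace(0.0, a_hi, n_grid)
                sv = vac.survival(self.a)
                rs, ws = _density_nodes(rec)
                # overshoot kernel G(a) = E_r[ P(T_V > a + r) ]
                self.g = np.zeros(n_grid)
                for r, w in zip(rs, ws):
                    self.g += w * vac.survival(self.a + r)
                self.e_min = float(np.trapezoid(sv * rec.survival(self.a), self.a))
        if self.mode is None:
            # deterministic or panel curves: tabulated sigma_k and phi_k
            wk, curves, _ = sus.representatives(k_sigma)
            self.wk = np.asarray(wk)
            if vac.is_infinite:
                self.mode = "curves_novacc"
                self.s_inf = sus.limit()
                a_hi = 1.0
                while (sus.limit() - float(np.min([np.asarray(c(a_hi), float)
                                                   for c in curves]))) > 1e-9 \
                        and a_hi < 1e7:
                    a_hi *= 2
                self.sv = None
            else:
                self.mode = "curves"
                a_hi = vac.upper(1e-12)
            self.a = np.linspace(0.0, a_hi, n_grid)
            self.sig = np.column_stack(
                [np.clip(np.asarray(c(self.a), float), 0.0, 1.0) for c in curves])
            self.phi = integrate.cumulative_trapezoid(self.sig, self.a,
                                                      axis=0, initial=0.0)
            if self.mode == "curves":
                self.sv = vac.survival(self.a)

    def terms(self, x: float):
        """(numerator, denominator) of the renewal part of F_e."""
        if self.mode == "immune":
            return np.inf, 0.0
        if self.mode == "step_novacc":
            return self.e_tr + 1.0 / x, 1.0 / x
        if self.mode == "step":
            damp = np.exp(-x * self.a)
            eh = float(np.trapezoid(damp * self.g, self.a))
            return self.e_min + eh, eh
        damp = np.exp(-x * self.phi)
        if self.mode == "curves":
            num = float(self.wk @ np.trapezoid(self.sv[:, None] * damp,
                                               self.a, axis=0))
            den = float(self.wk @ np.trapezoid(self.sv[:, None] * self.sig * damp,
                                               self.a, axis=0))
            return num, den
        # no vaccination: analytic constant-sigma tail beyond the table
        num = np.trapezoid(damp, self.a, axis=0)
        den = np.trapezoid(self.sig * damp, self.a, axis=0)
        tail_sig = np.clip(self.sig[-1], 1e-300, None)
        num = num + damp[-1] / (x * tail_sig)
        den = den + damp[-1] / x
        return float(self.wk @ num), float(self.wk @ den)

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise ValueError("x must be positive")
        num, den = self.terms(x)
        if not np.isfinite(num) or den <= 0:
            return np.inf
        return x * self.e_ti + num / den


# ---------------------------------------------------------------------------
# Root finding and equilibrium profiles
# ---------------------------------------------------------------------------


def find_endemic_equilibria(r0: float, spec: ModelSpec, n_scan: int = 400,
                            k_sigma: int = 64, ages: Optional[np.ndarray] = None,
                            xtol: float = 1e-12) -> List[EndemicEquilibrium]:
    """All roots of F_e(x) = R_0 found on a logarithmic scan of
    (0, R_0/E[T_I]], each refined by bracketed root polishing; an empty list
    means no endemic equilibrium (e.g. R_0 Sigma <= 1 in the monotone
    families)."""
    if r0 <= 0:
        raise ValueError("R_0 must be positive")
    e_ti = spec.infectiousness.duration.mean
    fe_fun = FeEvaluator(spec, k_sigma=k_sigma)
    x_max = r0 / e_ti
    xs = np.geomspace(1e-8 * x_max, x_max, n_scan)
    fe = np.array([fe_fun(x) for x in xs])
    g = fe - r0
    roots = []
    for i in range(len(xs) - 1):
        if np.isfinite(g[i]) and np.isfinite(g[i + 1]) and g[i] * g[i + 1] < 0:
            r = optimize.brentq(lambda x: fe_fun(x) - r0,
                                xs[i], xs[i + 1], xtol=xtol, rtol=8.9e-16)
            roots.append(r)
    return [_build_equilibrium(x, r0, spec, k_sigma, ages, fe_fun)
            for x in roots]


def _build_equilibrium(x: float, r0: float, spec: ModelSpec, k_sigma: int,
                       ages: Optional[np.ndarray],
                       fe_fun: Optional[FeEvaluator] = None) -> EndemicEquilibrium:
    sus, vac = spec.susceptibility, spec.vaccination
    inf = spec.infectiousness
    i0b = x / r0
    if fe_fun is not None:
        num, den = fe_fun.terms(x)
    else:
        num, den = _fe_terms(x, sus, vac, k_sigma)
    # E[1 - e^{-x phi(T_V)}] = x * E[int_0^{T_V} sigma e^{-x phi}]
    s0 = i0b / (x * den)
    if ages is None:
        hi_v = vac.upper(1e-12) if not vac.is_infinite else _damping_range(sus, x)
        hi = max(inf.duration.upper(1e-12), hi_v)
        ages = np.linspace(0.0, hi, 16385)
    ages = np.asarray(ages, float)
    esc = np.zeros_like(ages, dtype=float)
    if sus.kind == "step" and not sus.recovery.is_infinite:
        rs, ws = _density_nodes(sus.recovery)
        for r, w in zip(rs, ws):
            esc += w * np.exp(-x * np.maximum(ages - r, 0.0))
    else:
        wk, curves, phis = _phi_representatives(sus, k_sigma, float(ages[-1]))
        for w, phi in zip(wk, phis):
            esc += w * np.exp(-x * np.asarray(phi(ages), float))
    sv = np.ones_like(ages) if vac.is_infinite else vac.survival(ages)
    i_prof = i0b * inf.duration.survival(ages)
    s_prof = s0 * sv * esc
    return EndemicEquilibrium(x=float(x), r0=r0, i_boundary=float(i0b),
                              s_boundary=float(s0), ages=np.asarray(ages, float),
                              i_profile=i_prof, s_profile=s_prof,
                              prevalence=float(i0b * inf.duration.mean))
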