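"""Heterogeneous vaccination across population groups.

The population is split into L groups with weights ``p_l`` (summing to 1), a
symmetric non-negative irreducible contact matrix ``Gamma`` and per-group
vaccination laws ``T_l``; infectiousness and susceptibility laws are shared.
A single infected of group ``l`` placed at the disease-free equilibrium
generates on average ``R_0 m_{l,l'}`` secondary cases in group ``l'`` with

    m_{l,l'} = p_{l'} * gamma_{l,l'} * Sigma_{l'},

``Sigma_l`` being the stationary susceptibility of group ``l``.  An endemic
equilibrium exists iff ``R_0 * rho > 1`` where ``rho`` is the spectral
radius of ``M = (m_{l,l'})`` (a multi-type branching-process survival
criterion).

For two groups with equal activity (each individual makes contacts at unit
rate), all symmetric contact matrices are parametrized by a single contact
parameter ``alpha`` (assortative below 1, well-mixed at 1), ``rho(alpha)``
has a closed form and is non-increasing and convex in ``alpha``.  The module
also provides the critical recurrently-vaccinated fraction
``p_c = (1 - 1/R_0) / (1 - Sigma)`` and the fairness-parametrized dose
allocations ``T_1(beta) = T/(1+beta*p_2)``, ``T_2(beta) = T/(1-beta*p_1)``
for which the even split ``beta = 0`` minimizes ``rho``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import pde
from .kernels import (AgeDensity, DurationLaw, InfectiousnessLaw,
                      SusceptibilityLaw, never, stationary_susceptibility)

__all__ = ["GroupModel", "NextGenResult", "two_group_contact_matrix",
           "next_generation", "rho_of_alpha", "critical_vaccination_fraction",
           "fair_allocation", "FairAllocation", "solve_multigroup_volterra"]


def _group_sigma(sus: SusceptibilityLaw, vac: DurationLaw) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # infinite sentinel -> large-T_V limit
        return stationary_susceptibility(sus, vac)


@dataclasses.dataclass
class GroupModel:
    p: np.ndarray
    gamma: np.ndarray
    vaccinations: List[DurationLaw]
    infectiousness: InfectiousnessLaw
    susceptibility: SusceptibilityLaw

    def __post_init__(self):
        self.p = np.asarray(self.p, float)
        self.gamma = np.asarray(self.gamma, float)
        L = len(self.p)
        if abs(self.p.sum() - 1.0) > 1e-9 or np.any(self.p <= 0):
            raise ValueError("group weights must be positive and sum to 1")
        if self.gamma.shape != (L, L) or np.any(self.gamma < 0):
            raise ValueError("contact matrix must be LxL non-negative")
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        if len(self.vaccinations) != L:
            raise ValueError("one vaccination law per group required")

    @property
    def n_groups(self) -> int:
        return len(self.p)

    def is_irreducible(self) -> bool:
        n, _ = connected_components(csr_matrix(self.gamma > 0), directed=False)
        return n == 1

    def has_equal_activity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.gamma @ self.p, 1.0, atol=atol))

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([_group_sigma(self.susceptibility, v)
                         for v in self.vaccinations])


@dataclasses.dataclass
class NextGenResult:
    matrix: np.ndarray
    rho: float
    sigmas: np.ndarray

    def endemic(self, r0: float) -> bool:
        """Endemicity verdict R_0 * rho > 1."""
        return r0 * self.rho > 1.0


def two_group_contact_matrix(p1: float, alpha: float) -> np.ndarray:
    """All symmetric equal-activity two-group contact matrices:
    Gamma = [[(1-p2*a)/p1, a], [a, (1-p1*a)/p2]]."""
    if not 0 < p1 < 1:
        raise ValueError("p1 must be in (0, 1)")
    p2 = 1.0 - p1
    a_max = min(1.0 / p1, 1.0 / p2)
    if not 0 <= alpha <= a_max:
        raise ValueError(f"contact parameter must lie in [0, {a_max:.6g}]")
    return np.array([[(1 - p2 * alpha) / p1, alpha],
                     [alpha, (1 - p1 * alpha) / p2]])


def _power_iteration(m: np.ndarray, tol: float = 1e-14,
                     max_iter: int = 100_000) -> float:
    L = m.shape[0]
    v = np.full(L, 1.0 / L)
    lam = 0.0
    for _ in range(max_iter):
        w = m @ v
        norm = np.linalg.norm(w, 1)
        if norm == 0.0:
            return 0.0
        lam_new = norm / np.linalg.norm(v, 1)
        w = w / norm
        if abs(lam_new - lam) <= tol * max(lam_new, 1e-300) and \
                np.linalg.norm(w - v, 1) <= 10 * tol:
            return float(lam_new)
        v, lam = w, lam_new
    return float(lam)


def next_generation(groups: GroupModel,
                    require_irreducible: bool = True) -> NextGenResult:
    """Next-generation matrix m_{l,l'} = p_{l'} gamma_{l,l'} Sigma_{l'} and
    its leading eigenvalue by power iteration.

    The endemicity criterion is derived for irreducible contact matrices;
    ``require_irreducible=False`` allows boundary cases such as fully
    assortative two-group scans (alpha = 0), where the spectral radius is
    the limit of the irreducible criterion.
    """
    if require_irreducible and not groups.is_irreducible():
        raise ValueError("contact matrix is reducible: the endemicity "
                         "criterion requires an irreducible Gamma")
    s = groups.sigmas
    m = groups.gamma * (groups.p * s)[None, :]
    return NextGenResult(matrix=m, rho=_power_iteration(m), sigmas=s)


def rho_of_alpha(p1: float, sigma1: float, sigma2: float,
                 alpha: float) -> float:
    """Closed-form leading eigenvalue for two equal-activity groups:
    largest root of rho^2 - ((1-p1 a)S2 + (1-p2 a)S1) rho + (1-a) S1 S2 = 0.
    Non-increasing and convex in alpha; constant when Sigma1 = Sigma2."""
    p2 = 1.0 - p1
    b = (1 - p2 * alpha) * sigma1 + (1 - p1 * alpha) * sigma2
    disc = b * b - 4.0 * (1.0 - alpha) * sigma1 * sigma2
    return 0.5 * (b + np.sqrt(max(disc, 0.0)))


def critical_vaccination_fraction(r0: float, sigma: float) -> float:
    """Critical fraction of the population that must follow the recurrent
    vaccination policy (the rest unvaccinated, well-mixed contacts):
    p_c = (1 - 1/R_0) / (1 - Sigma).  Negative values mean no vaccination is
    needed (R_0 <= 1)."""
    if r0 <= 0:
        raise ValueError("R_0 must be positive")
    if not 0 <= sigma < 1:
        raise ValueError("requires 0 <= Sigma < 1: a vaccine that blocks no "
                         "transmission (Sigma >= 1) cannot eradicate")
    return (1.0 - 1.0 / r0) / (1.0 - sigma)


@dataclasses.dataclass
class FairAllocation:
    beta: float
    law1: DurationLaw
    law2: DurationLaw

    @property
    def dose_budget(self) -> tuple:
        return (self.law1.mean, self.law2.mean)


def fair_allocation(t_law: DurationLaw, beta: float, p1: float) -> FairAllocation:
    """Dose split with fairness parameter beta: T_1 = T/(1 + beta p2),
    T_2 = T/(1 - beta p1); the per-capita dose budget
    p1/E[T_1] + p2/E[T_2] = 1/E[T] is preserved exactly.  At the endpoints
    one group is unvaccinated (infinite sentinel)."""
    if not 0 < p1 < 1:
        raise ValueError("p1 must be in (0, 1)")
    if not np.isfinite(t_law.mean):
        raise ValueError("the base allocation law must have a finite mean")
    p2 = 1.0 - p1
    if not -1.0 / p2 - 1e-12 <= beta <= 1.0 / p1 + 1e-12:
        raise ValueError(f"beta must lie in [{-1 / p2:.6g}, {1 / p1:.6g}]")
    c1 = 1.0 + beta * p2
    c2 = 1.0 - beta * p1
    law1 = never() if c1 <= 1e-12 else t_law.scaled(1.0 / c1)
    law2 = never() if c2 <= 1e-12 else t_law.scaled(1.0 / c2)
    return FairAllocation(beta=beta, law1=law1, law2=law2)


def allocation_next_generation(t_law: DurationLaw, beta: float, p1: float,
                               alpha: float, sus: SusceptibilityLaw,
                               infectiousness: InfectiousnessLaw) -> NextGenResult:
    """Next-generation analysis of the (alpha, beta) allocation."""
    alloc = fair_allocation(t_law, beta, p1)
    gm = GroupModel(p=[p1, 1 - p1], gamma=two_group_contact_matrix(p1, alpha),
                    vaccinations=[alloc.law1, alloc.law2],
                    infectiousness=infectiousness, susceptibility=sus)
    return next_generation(gm, require_irreducible=alpha > 0)


def solve_multigroup_volterra(groups: GroupModel, i0: float,
                              h_i: AgeDensity, h_s: AgeDensity,
                              dt: float, t_max: float,
                              **kwargs) -> List[pde.LimitSolution]:
    """Coupled per-group limit equations; each group starts with a fraction
    i0 infected so that group masses p_l are conserved."""
    return pde.solve_volterra_groups(
        infectiousness=groups.infectiousness,
        susceptibility=groups.susceptibility,
        vaccinations=list(groups.vaccinations), p=groups.p,
        gamma=groups.gamma, i0=i0, h_i=h_i, h_s=h_s, dt=dt, t_max=t_max,
        **kwargs)
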