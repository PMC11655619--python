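"""Experiment drivers producing tidy tables.

These orchestrate the simulator, the limit solver and the equilibrium
toolkit into the standard analyses: finite-N vs limit comparison, bifurcation
sweeps of the terminal prevalence against the endemic threshold, and
two-group vaccine-allocation scans.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ibm, pde
from .equilibrium import endemic_threshold
from .kernels import DurationLaw, InfectiousnessLaw, ModelSpec, SusceptibilityLaw
from .multigroup import allocation_next_generation

__all__ = ["run_compare_limits", "run_bifurcation", "run_allocation_scan",
           "EXTINCTION_PREVALENCE"]

#: terminal prevalence below which the epidemic is declared extinct
EXTINCTION_PREVALENCE = 1e-6


def run_compare_limits(spec: ModelSpec, n_values: Sequence[int],
                       replicates: int, t_max: float, seed: int,
                       grid_dt: float = 0.5, dt_pde: float = 0.01,
                       k_sigma: int = 16) -> pd.DataFrame:
    """Replicate IBM trajectories against the limit solution on a common
    grid.  Returns a tidy table (source, n, replicate, t, prevalence, lam,
    incidence); the limit rows have source='pde', n=0, replicate=-1."""
    sol = pde.solve_volterra(spec, dt=dt_pde, t_max=t_max, k_sigma=k_sigma)
    stride = max(1, int(round(grid_dt / dt_pde)))
    rows = [pd.DataFrame({
        "source": "pde", "n": 0, "replicate": -1,
        "t": sol.t[::stride], "prevalence": sol.prevalence[::stride],
        "lam": sol.lam[::stride],
        "incidence": np.nan})]
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(len(n_values) * replicates) % (2 ** 31)
    k = 0
    for n in n_values:
        for rep in range(replicates):
            st = ibm.init_population(spec, n, int(rep_seeds[k]))
            k += 1
            traj = ibm.simulate(st, t_max, grid_dt=grid_dt)
            rows.append(pd.DataFrame({
                "source": "ibm", "n": n, "replicate": rep, "t": traj.t,
                "prevalence": traj.prevalence, "lam": traj.lam,
                "incidence": traj.incidence}))
    return pd.concat(rows, ignore_index=True)


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(n, t) replicate mean and standard error of the IBM prevalence."""
    g = (table[table.source == "ibm"]
         .groupby(["n", "t"])["prevalence"]
         .agg(["mean", "std", "count"])
         .reset_index())
    g["se"] = g["std"] / np.sqrt(g["count"])
    return g


def run_bifurcation(spec: ModelSpec, r0_values: Sequence[float],
                    t_max: float = 300.0, dt: float = 0.05,
                    theta_sigma_values: Optional[Sequence[float]] = None,
                    sigma_factory=None, k_sigma: int = 16) -> pd.DataFrame:
    """Terminal prevalence of the limit equations over a sweep of R_0 (and
    optionally of a susceptibility scale parameter via ``sigma_factory``),
    with the analytic threshold 1/Sigma reported alongside."""
    records = []
    theta_list = [None] if theta_sigma_values is None else list(theta_sigma_values)
    for theta in theta_list:
        s = spec
        if theta is not None:
            if sigma_factory is None:
                raise ValueError("theta sweep requires a sigma_factory")
            s = ModelSpec(spec.infectiousness, sigma_factory(theta),
                          spec.vaccination, spec.i0, spec.h_i, spec.h_s)
        thr = endemic_threshold(s)
        for r0 in r0_values:
            sol = pde.solve_volterra(s.with_r0(float(r0)), dt=dt, t_max=t_max,
                                     k_sigma=k_sigma)
            rec = {"r0": float(r0), "terminal_prevalence": float(sol.prevalence[-1]),
                   "threshold": thr,
                   "extinct": bool(sol.prevalence[-1] < EXTINCTION_PREVALENCE)}
            if theta is not None:
                rec["theta_sigma"] = float(theta)
            records.append(rec)
    return pd.DataFrame.from_records(records)


def run_allocation_scan(t_law: DurationLaw, p1: float,
                        alphas: Sequence[float], n_beta: int,
                        sus: SusceptibilityLaw,
                        infectiousness: InfectiousnessLaw) -> pd.DataFrame:
    """1/rho over an (alpha, beta) grid of two-group dose allocations."""
    p2 = 1.0 - p1
    betas = np.linspace(-1.0 / p2, 1.0 / p1, int(n_beta))
    records = []
    for alpha in alphas:
        for beta in betas:
            res = allocation_next_generation(t_law, float(beta), p1, float(alpha),
                                             sus, infectiousness)
            records.append({"alpha": float(alpha), "beta": float(beta),
                            "rho": res.rho,
                            "inv_rho": np.inf if res.rho == 0 else 1.0 / res.rho,
                            "sigma1": res.sigmas[0], "sigma2": res.sigmas[1]})
    return pd.DataFrame.from_records(records)
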