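"""Stochastic individual-based model (finite population of size N).

Each individual alternates between an infectious state I (carrying a sampled
infectiousness curve ``lambda`` on ``[0, T_I)``) and a susceptible state S
(carrying a sampled susceptibility curve ``sigma``).  Susceptibles are
re-vaccinated according to a renewal process with inter-dose law ``T_V``;
each vaccination resets the susceptibility curve.  Individual ``i`` is
infected at time ``t`` at rate ``sigma_i(t) * Lambda(t)`` where
``Lambda(t) = (1/N) sum_i lambda_i(t)`` is the force of infection.

Infections are simulated *exactly* by thinning: candidate contact points are
generated at the bounding rate ``N * lambda_max``, a uniformly chosen target
individual is infected with probability ``sigma_i(t) Lambda(t) / lambda_max``
(valid because ``sigma <= 1`` and ``Lambda <= lambda_max``).  Recoveries and
vaccinations occur at their pre-scheduled times.  Simultaneous events (only
possible under point-mass duration laws) are resolved in the order
recovery < vaccination < infection, then by individual index, so that runs
replay bit-identically from a seed.

A fixed-step Bernoulli scheme is also exposed (``scheme="fixed_step"``) for
susceptibility laws whose pointwise evaluation is expensive; it is first
order in the step and not exact.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import List, Optional

import numpy as np

from .kernels import ModelSpec

__all__ = ["PopulationState", "Trajectory", "init_population", "simulate",
           "empirical_age_measures"]

_RECOVER, _VACCINATE, _INFECT = 0, 1, 2
_EVENT_NAMES = {_RECOVER: "recover", _VACCINATE: "vaccinate", _INFECT: "infect"}

_I, _S = 1, 0


@dataclasses.dataclass
class Trajectory:
    """Sampled output of one simulation run."""

    t: np.ndarray
    prevalence: np.ndarray
    lam: np.ndarray          # force of infection Lambda^N
    incidence: np.ndarray    # cumulative infections per capita (t > 0)
    n: int
    events: Optional[List[tuple]] = None
    snapshots: Optional[list] = None


class PopulationState:
    """Per-individual state plus the global clock and RNG streams.

    One independent RNG substream per individual (curve and duration draws)
    plus one for the thinning process, all spawned from the user seed.
    """

    def __init__(self, spec: ModelSpec, n: int, seed: int):
        self.spec = spec
        self.n = n
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(n + 1)
        self.rngs = [np.random.default_rng(c) for c in children[:n]]
        self.thin_rng = np.random.default_rng(children[n])
        self.time = 0.0

        self.state = np.zeros(n, dtype=np.int8)
        self.tau = np.zeros(n)            # time of last event
        self.beta = np.zeros(n)           # amplitude of the active lambda curve
        self.t_infectious_end = np.full(n, np.inf)
        self.r_imm = np.zeros(n)          # step sigma: immune-period length
        self.panel_idx = np.zeros(n, dtype=np.int64)
        self.seq = np.zeros(n, dtype=np.int64)   # event counter (heap invalidation)
        self.heap: list = []
        self.sum_lam = 0.0                # N * Lambda^N, constant-curve cache
        self.cum_infections = 0

        inf_law = spec.infectiousness
        self._constant_curves = inf_law.family == "constant"
        sus = spec.susceptibility
        self._sus_kind = sus.kind

    # ------------------------------------------------------------------
    def _draw_sigma(self, i: int):
        sus = self.spec.susceptibility
        if sus.kind == "step":
            self.r_imm[i] = sus.recovery.sample(self.rngs[i])
        elif sus.kind == "panel":
            self.panel_idx[i] = self.rngs[i].integers(len(sus.panel))

    def sigma_at(self, i: int, t: float) -> float:
        if self.state[i] != _S:
            return 0.0
        age = t - self.tau[i]
        sus = self.spec.susceptibility
        if sus.kind == "step":
            return 1.0 if age >= self.r_imm[i] else 0.0
        if sus.kind == "deterministic":
            return float(sus.curve(age))
        return float(sus.panel[self.panel_idx[i]](age))

    def lambda_at(self, i: int, t: float) -> float:
        if self.state[i] != _I:
            return 0.0
        age = t - self.tau[i]
        if age >= self.t_infectious_end[i] - self.tau[i]:
            return 0.0
        if self._constant_curves:
            return float(self.beta[i])
        return float(self.spec.infectiousness.profile(age))

    def total_infectiousness(self, t: float) -> float:
        """N * Lambda^N(t), recomputed exactly."""
        if self._constant_curves:
            return float(np.sum(self.beta[(self.state == _I)]))
        idx = np.nonzero(self.state == _I)[0]
        if len(idx) == 0:
            return 0.0
        ages = t - self.tau[idx]
        return float(np.sum(self.spec.infectiousness.profile(ages)))

    # ------------------------------------------------------------------
    def _schedule(self, t: float, kind: int, i: int):
        if np.isfinite(t):
            heapq.heappush(self.heap, (t, kind, i, self.seq[i]))

    def enter_infected(self, i: int, t: float):
        rng = self.rngs[i]
        t_i = self.spec.infectiousness.duration.sample(rng)
        self.state[i] = _I
        self.tau[i] = t
        self.seq[i] += 1
        self.beta[i] = (self.spec.infectiousness.beta
                        if self._constant_curves else 0.0)
        self.t_infectious_end[i] = t + t_i
        if self._constant_curves:
            self.sum_lam += self.beta[i]
        self._schedule(t + t_i, _RECOVER, i)

    def enter_susceptible(self, i: int, t: float):
        rng = self.rngs[i]
        if self.state[i] == _I and self._constant_curves:
            self.sum_lam -= self.beta[i]
        self.state[i] = _S
        self.tau[i] = t
        self.seq[i] += 1
        self.beta[i] = 0.0
        self._draw_sigma(i)
        t_v = self.spec.vaccination.sample(rng)
        self._schedule(t + t_v, _VACCINATE, i)


def init_population(spec: ModelSpec, n: int, seed: int) -> PopulationState:
    """Draw the initial population: each individual is infected with
    probability I_0; ages come from h_I / h_S; the active infectiousness
    curve is conditioned on T_I exceeding the age and the residual
    vaccination time on T_V exceeding the age (exact inverse-CDF
    conditioning; valid because the curve shape is independent of the
    duration in the built-in families)."""
    if n < 1:
        raise ValueError("need N >= 1")
    st = PopulationState(spec, n, seed)
    inf_law = spec.infectiousness
    vac = spec.vaccination
    for i in range(n):
        rng = st.rngs[i]
        infected = rng.random() < spec.i0
        if infected:
            age = float(spec.h_i.sample(rng, 1)[0])
            try:
                t_i = inf_law.duration.sample_exceeding(age, rng)
            except RuntimeError as e:
                raise RuntimeError(f"initial infected age {age:.4g}: {e}") from e
            st.state[i] = _I
            st.tau[i] = -age
            st.beta[i] = inf_law.beta if st._constant_curves else 0.0
            st.t_infectious_end[i] = t_i - age
            st._schedule(t_i - age, _RECOVER, i)
        else:
            age = float(spec.h_s.sample(rng, 1)[0])
            st.state[i] = _S
            st.tau[i] = -age
            st._draw_sigma(i)
            try:
                t_v = vac.sample_exceeding(age, rng)
            except RuntimeError as e:
                raise RuntimeError(f"initial susceptible age {age:.4g}: {e}") from e
            st._schedule(t_v - age, _VACCINATE, i)
    st.sum_lam = st.total_infectiousness(0.0)
    return st


def simulate(state: PopulationState, t_max: float, grid_dt: float = 0.5,
             record_events: bool = False, scheme: str = "thinning",
             fixed_step: float = 1e-2, snapshot_times: Optional[list] = None,
             bin_width: float = 1.0) -> Trajectory:
    """Run the epidemic until ``t_max`` and sample the trajectory on a grid."""
    if t_max <= state.time:
        raise ValueError("t_max must exceed the current simulation time")
    if scheme == "fixed_step":
        return _simulate_fixed_step(state, t_max, grid_dt, fixed_step,
                                    record_events)
    if scheme != "thinning":
        raise ValueError(f"unknown scheme {scheme!r}")
    lam_max = state.spec.infectiousness.lam_max
    n = state.n
    thin = state.thin_rng
    events = [] if record_events else None
    snap_iter = sorted(snapshot_times) if snapshot_times else []
    snaps = [] if snapshot_times else None

    grid = np.arange(state.time, t_max + grid_dt * 0.5, grid_dt)
    prev = np.empty(len(grid))
    lam_out = np.empty(len(grid))
    inc_out = np.empty(len(grid))
    gi = 0

    n_inf = int(np.sum(state.state == _I))
    t = state.time
    cand_rate = n * lam_max
    next_cand = (t + thin.exponential(1.0 / cand_rate)) if cand_rate > 0 else np.inf
    heap = state.heap

    def record_until(up_to):
        nonlocal gi
        while gi < len(grid) and grid[gi] <= up_to + 1e-12:
            prev[gi] = n_inf / n
            lam_out[gi] = state.sum_lam / n if state._constant_curves \
                else state.total_infectiousness(grid[gi]) / n
            inc_out[gi] = state.cum_infections / n
            gi += 1

    def take_snaps(up_to):
        nonlocal snap_iter
        while snap_iter and snap_iter[0] <= up_to + 1e-12:
            ts = snap_iter.pop(0)
            snaps.append((ts,) + empirical_age_measures(state, bin_width, at_time=ts))

    while True:
        # next valid scheduled event
        while heap and heap[0][3] != state.seq[heap[0][2]]:
            heapq.heappop(heap)
        t_sched = heap[0][0] if heap else np.inf
        t_next = min(t_sched, next_cand)
        if t_next > t_max:
            break
        record_until(t_next)
        if snaps is not None:
            take_snaps(t_next)
        t = t_next
        state.time = t
        if t_sched <= next_cand:
            _, kind, i, _ = heapq.heappop(heap)
            if kind == _RECOVER:
                state.enter_susceptible(i, t)
                n_inf -= 1
                if record_events:
                    events.append((t, i, "recover"))
            else:
                state.enter_susceptible(i, t)  # vaccination resets sigma
                if record_events:
                    events.append((t, i, "vaccinate"))
        else:
            next_cand = t + thin.exponential(1.0 / cand_rate)
            i = int(thin.integers(n))
            u = thin.random()
            if state.state[i] == _S:
                lam_now = (state.sum_lam / n if state._constant_curves
                           else state.total_infectiousness(t) / n)
                p_acc = state.sigma_at(i, t) * lam_now / lam_max
                if p_acc > 1.0 + 1e-12:
                    raise RuntimeError("thinning acceptance probability exceeds 1: "
                                       "inconsistent lam_max bound")
                if u < p_acc:
                    state.enter_infected(i, t)
                    n_inf += 1
                    state.cum_infections += 1
                    if record_events:
                        events.append((t, i, "infect"))

    state.time = t_max
    record_until(t_max)
    if snaps is not None:
        take_snaps(t_max)
    return Trajectory(t=grid, prevalence=prev, lam=lam_out, incidence=inc_out,
                      n=n, events=events, snapshots=snaps)


def _simulate_fixed_step(state: PopulationState, t_max: float, grid_dt: float,
                         dt: float, record_events: bool) -> Trajectory:
    """First-order Bernoulli scheme: per step each susceptible is infected
    with probability 1 - exp(-sigma_i Lambda dt); scheduled events are
    processed when the clock passes them."""
    n = state.n
    thin = state.thin_rng
    events = [] if record_events else None
    grid = np.arange(state.time, t_max + grid_dt * 0.5, grid_dt)
    prev, lam_out, inc_out = (np.empty(len(grid)) for _ in range(3))
    gi = 0
    heap = state.heap
    t = state.time
    while gi < len(grid):
        # scheduled events up to t + dt
        while heap:
            while heap and heap[0][3] != state.seq[heap[0][2]]:
                heapq.heappop(heap)
            if not heap or heap[0][0] > t + dt:
                break
            te, kind, i, _ = heapq.heappop(heap)
            state.enter_susceptible(i, te)
            if record_events:
                events.append((te, i, _EVENT_NAMES[kind]))
        lam_now = state.total_infectiousness(t) / n
        if state._constant_curves:
            state.sum_lam = lam_now * n
        sus_idx = np.nonzero(state.state == _S)[0]
        if lam_now > 0 and len(sus_idx):
            sig = np.array([state.sigma_at(i, t) for i in sus_idx])
            p = -np.expm1(-sig * lam_now * dt)
            hits = sus_idx[thin.random(len(sus_idx)) < p]
            for i in hits:
                state.enter_infected(int(i), t + dt)
                state.cum_infections += 1
                if record_events:
                    events.append((t + dt, int(i), "infect"))
        t += dt
        state.time = t
        while gi < len(grid) and grid[gi] <= t + 1e-12:
            n_inf = int(np.sum(state.state == _I))
            prev[gi] = n_inf / n
            lam_out[gi] = state.total_infectiousness(grid[gi]) / n
            inc_out[gi] = state.cum_infections / n
            gi += 1
    return Trajectory(t=grid, prevalence=prev, lam=lam_out, incidence=inc_out,
                      n=n, events=events)


def empirical_age_measures(state: PopulationState, bin_width: float,
                           at_time: Optional[float] = None):
    """Per-compartment histograms of class ages, masses (#I/N, #S/N)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    t = state.time if at_time is None else at_time
    ages = t - state.tau
    amax = float(ages.max()) if len(ages) else bin_width
    edges = np.arange(0.0, amax + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    hist_i, _ = np.histogram(ages[state.state == _I], bins=edges)
    hist_s, _ = np.histogram(ages[state.state == _S], bins=edges)
    return edges, hist_i / state.n, hist_s / state.n
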