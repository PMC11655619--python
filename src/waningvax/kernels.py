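"""Parametric laws for infectiousness, susceptibility and vaccination.

The epidemic model is driven by three distributions attached to each
individual:

* an *infectiousness curve* ``lambda(a)`` defined on a random infectious
  period ``[0, T_I)`` -- the rate at which an infected individual of
  infection-age ``a`` transmits;
* a non-decreasing *susceptibility curve* ``sigma(a)`` in ``[0, 1]`` -- the
  probability of reinfection upon infectious contact, ``a`` units of time
  after the last recovery or vaccination (waning immunity);
* a *vaccination-interval law* ``T_V`` -- the waiting time between
  consecutive booster doses of one individual (a renewal process).

This module provides parametric families for these objects and the scalar
functionals built from them: age-dependent hazards, the basic reproduction
number ``R_0 = int E[lambda(a)] da``, the mean cumulative susceptibility
``Phi(t) = int_0^t E[sigma(a)] da`` and the stationary susceptibility at the
disease-free equilibrium,

    Sigma = E[ int_0^{T_V} sigma(a) da ] / E[T_V] = E[Phi(T_V)] / E[T_V],

which controls the endemic threshold ``1/Sigma``.

Everywhere in this package ``lambda(a)`` is taken to be 0 for ``a >= T_I``,
so that ``E[lambda(a)]`` already contains the survival factor
``P(T_I > a)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, special, stats

#: infinite age integrals are truncated at the 1 - TAIL quantile
TAIL = 1e-8


class PointMassHazardError(ValueError):
    """Raised when an age-dependent hazard is requested from a law without a
    density; callers should schedule the (deterministic) event time instead."""


# ---------------------------------------------------------------------------
# Duration laws
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DurationLaw:
    """A distribution over non-negative durations (T_I, T_V, T_R ...).

    Exposes density / survival / hazard / sampling and expectation helpers.
    Continuous families wrap a frozen scipy distribution; point masses and
    finite mixtures of atoms are stored explicitly.  The ``never`` sentinel
    (infinite duration, e.g. "no vaccination") has ``is_infinite=True``.
    """

    family: str
    params: dict
    mean: float
    has_density: bool
    is_point_mass: bool = False
    is_infinite: bool = False
    _dist: object = None
    _atoms: Optional[tuple] = None  # ((value, prob), ...)

    # -- basic functions ----------------------------------------------------
    def density(self, a):
        if not self.has_density:
            raise PointMassHazardError(f"{self.family} law has no density")
        return self._dist.pdf(np.asarray(a, dtype=float))

    def cdf(self, a):
        a = np.asarray(a, dtype=float)
        if self.is_infinite:
            return np.zeros_like(a)
        if self._atoms is not None:
            out = np.zeros_like(a)
            for v, p in self._atoms:
                out = out + p * (a >= v)
            return out
        return self._dist.cdf(a)

    def survival(self, a):
        a = np.asarray(a, dtype=float)
        if self.is_infinite:
            return np.ones_like(a)
        if self._atoms is not None:
            return 1.0 - self.cdf(a)
        return self._dist.sf(a)

    def hazard(self, a):
        """density(a) / survival(a); errors on laws without a density or
        beyond the support."""
        if not self.has_density:
            raise PointMassHazardError(
                f"{self.family} law has no density: use the scheduled event "
                "time directly instead of an age-dependent hazard")
        a = np.asarray(a, dtype=float)
        s = self.survival(a)
        if np.any(s <= 0):
            raise ValueError(
                f"hazard undefined at age beyond the support of {self.family}"
                f" (survival is 0)")
        return self.density(a) / s

    # -- sampling and quantiles --------------------------------------------
    def sample(self, rng: np.random.Generator, size=None):
        if self.is_infinite:
            return np.inf if size is None else np.full(size, np.inf)
        if self.is_point_mass:
            v = self.params["value"]
            return v if size is None else np.full(size, float(v))
        if self._atoms is not None:
            vals = np.array([v for v, _ in self._atoms])
            probs = np.array([p for _, p in self._atoms])
            out = rng.choice(vals, size=size if size is not None else (), p=probs)
            return float(out) if size is None else out
        out = self._dist.rvs(size=size if size is not None else 1,
                             random_state=rng)
        return float(out[0]) if size is None else out

    def sample_exceeding(self, age: float, rng: np.random.Generator) -> float:
        """Sample T conditional on T > age by inverse-CDF (exact; robust in
        the far tail where rejection sampling would stall)."""
        if self.is_infinite:
            return np.inf
        if age <= 0:
            return float(self.sample(rng))
        if self._atoms is not None:
            cand = [(v, p) for v, p in self._atoms if v > age]
            tot = sum(p for _, p in cand)
            if tot <= 0:
                raise RuntimeError(f"cannot condition {self.family} law on "
                                   f"exceeding age {age:.6g}: no support there")
            vals = np.array([v for v, _ in cand])
            probs = np.array([p / tot for _, p in cand])
            return float(rng.choice(vals, p=probs))
        c = float(self.cdf(age))
        if c >= 1.0 - 1e-14:
            raise RuntimeError(f"cannot condition {self.family} law on "
                               f"exceeding age {age:.6g}: survival underflows")
        return float(self._dist.ppf(rng.uniform(c, 1.0)))

    def quantile(self, q):
        if self.is_infinite:
            return np.inf
        if self.is_point_mass:
            return float(self.params["value"])
        if self._atoms is not None:
            vals = np.array(sorted(v for v, _ in self._atoms))
            cum = np.cumsum([p for v, p in sorted(self._atoms)])
            return float(vals[np.searchsorted(cum, q, side="left").clip(0, len(vals) - 1)])
        return float(self._dist.ppf(q))

    def upper(self, tail: float = TAIL) -> float:
        """Truncation point for age integrals (the 1 - tail quantile)."""
        if self.is_infinite:
            return np.inf
        return self.quantile(1.0 - tail)

    def kinks(self) -> tuple:
        """Breakpoints of the survival function, passed to quadrature."""
        if self.is_point_mass:
            return (float(self.params["value"]),)
        if self._atoms is not None:
            return tuple(float(v) for v, _ in self._atoms)
        if self.family == "uniform":
            return (self.params["low"], self.params["high"])
        if "shift" in self.params and self.params["shift"] > 0:
            return (self.params["shift"],)
        return ()

    # -- expectations -------------------------------------------------------
    def expect(self, f: Callable[[float], float], extra_points: Sequence[float] = ()) -> float:
        """E[f(T)] by atom summation or adaptive quadrature."""
        if self.is_infinite:
            raise ValueError("expectation against the infinite sentinel law")
        if self.is_point_mass:
            return float(f(self.params["value"]))
        if self._atoms is not None:
            return float(sum(p * f(v) for v, p in self._atoms))
        lo = self.quantile(1e-13)
        hi = self.upper(1e-12)
        pts = [p for p in (*self.kinks(), *extra_points) if lo < p < hi]
        val, _ = integrate.quad(lambda t: f(t) * float(self.density(t)),
                                lo, hi, points=pts or None, limit=200)
        return float(val)

    def survival_integral(self, g: Callable, upper: Optional[float] = None,
                          extra_points: Sequence[float] = ()) -> float:
        """int_0^inf g(a) * P(T > a) da, i.e. E[ int_0^T g(a) da ]."""
        hi = self.upper(1e-12) if upper is None else upper
        if not np.isfinite(hi):
            raise ValueError("survival integral over the infinite sentinel "
                             "needs an explicit upper limit")
        pts = [p for p in (*self.kinks(), *extra_points) if 0.0 < p < hi]
        val, _ = integrate.quad(lambda a: float(g(a)) * float(self.survival(a)),
                                0.0, hi, points=pts or None, limit=200)
        return float(val)

    def scaled(self, c: float) -> "DurationLaw":
        """The law of c*T (scale transform used by vaccine-allocation scans)."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        if self.is_infinite:
            return never()
        f, p = self.family, self.params
        if f == "exponential":
            return exponential(p["rate"] / c)
        if f == "gamma":
            return gamma_law(p["shape"], p["scale"] * c, shift=p["shift"] * c)
        if f == "uniform":
            return uniform_law(p["low"] * c, p["high"] * c)
        if f == "point_mass":
            return fixed(p["value"] * c)
        if f == "two_point":
            return two_point(p["low"] * c, p["high"] * c, p["p_low"])
        raise ValueError(f"cannot scale family {f!r}")


def exponential(rate: float) -> DurationLaw:
    if rate <= 0:
        raise ValueError("rate must be positive")
    return DurationLaw("exponential", {"rate": rate}, mean=1.0 / rate,
                       has_density=True, _dist=stats.expon(scale=1.0 / rate))


def gamma_law(shape: float, scale: float, shift: float = 0.0) -> DurationLaw:
    if shape <= 0 or scale <= 0 or shift < 0:
        raise ValueError("shape and scale must be positive, shift >= 0")
    return DurationLaw("gamma", {"shape": shape, "scale": scale, "shift": shift},
                       mean=shape * scale + shift, has_density=True,
                       _dist=stats.gamma(shape, loc=shift, scale=scale))


def uniform_law(low: float, high: float) -> DurationLaw:
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    return DurationLaw("uniform", {"low": low, "high": high},
                       mean=0.5 * (low + high), has_density=True,
                       _dist=stats.uniform(loc=low, scale=high - low))


def fixed(value: float) -> DurationLaw:
    """Point mass: the duration equals ``value`` almost surely."""
    if value < 0:
        raise ValueError("duration must be non-negative")
    return DurationLaw("point_mass", {"value": float(value)}, mean=float(value),
                       has_density=False, is_point_mass=True,
                       _atoms=((float(value), 1.0),))


def two_point(low: float, high: float, p_low: float = 0.5) -> DurationLaw:
    """Mixture of two atoms; handy for convex-ordering experiments."""
    if not (0 <= low <= high) or not (0 < p_low < 1):
        raise ValueError("need 0 <= low <= high and 0 < p_low < 1")
    m = p_low * low + (1 - p_low) * high
    return DurationLaw("two_point", {"low": low, "high": high, "p_low": p_low},
                       mean=m, has_density=False,
                       _atoms=((float(low), p_low), (float(high), 1 - p_low)))


def never() -> DurationLaw:
    """Infinite sentinel: the event never happens (no vaccination)."""
    return DurationLaw("never", {}, mean=np.inf, has_density=False,
                       is_infinite=True)


# ---------------------------------------------------------------------------
# Infectiousness laws
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InfectiousnessLaw:
    """Law of the random pair (lambda, T_I).

    Two families are provided:

    * ``constant`` -- lambda(a) = beta on [0, T_I), the classical
      constant-rate transmission of SIR-type models;
    * ``profile`` -- lambda(a) = g(a) on [0, T_I) for a deterministic shape
      ``g`` (e.g. a viral-load-like hump), the duration remaining random.
    """

    duration: DurationLaw
    family: str
    beta: float = 0.0
    profile: Optional[Callable] = None
    lam_max: float = 0.0

    def __post_init__(self):
        if self.duration.is_infinite:
            raise ValueError("infectious period must be almost surely finite")
        if not np.isfinite(self.lam_max) or self.lam_max < 0:
            raise ValueError("lam_max must be finite and non-negative")

    def mean_curve(self, a):
        """E[lambda(a)] with the zero-extension convention (a >= T_I -> 0)."""
        a = np.asarray(a, dtype=float)
        amp = self.beta if self.family == "constant" else self.profile(a)
        return amp * self.duration.survival(a)

    def conditional_mean_curve(self, a):
        """E[lambda(a) | T_I > a]."""
        a = np.asarray(a, dtype=float)
        return self.beta if self.family == "constant" else self.profile(a)

    def sample(self, rng: np.random.Generator):
        """Draw one realization: (T_I, curve) with curve(a) valid on [0,T_I)."""
        t_i = self.duration.sample(rng)
        if self.family == "constant":
            b = self.beta
            return t_i, (lambda a, b=b: np.where(np.asarray(a) < t_i, b, 0.0))
        g = self.profile
        return t_i, (lambda a, g=g: np.where(np.asarray(a) < t_i, g(np.asarray(a)), 0.0))

    def rescaled(self, c: float) -> "InfectiousnessLaw":
        """Multiply the infectiousness (hence R_0) by c."""
        if self.family == "constant":
            return InfectiousnessLaw(self.duration, "constant",
                                     beta=self.beta * c, lam_max=self.lam_max * c)
        g = self.profile
        return InfectiousnessLaw(self.duration, "profile",
                                 profile=(lambda a, g=g: c * g(a)),
                                 lam_max=self.lam_max * c)


def constant_infectiousness(beta: float, duration: DurationLaw) -> InfectiousnessLaw:
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return InfectiousnessLaw(duration, "constant", beta=beta, lam_max=beta)


def profile_infectiousness(profile: Callable, duration: DurationLaw,
                           lam_max: Optional[float] = None) -> InfectiousnessLaw:
    if lam_max is None:
        grid = np.linspace(0.0, duration.upper(1e-12), 4097)
        lam_max = float(np.max(profile(grid)))
    return InfectiousnessLaw(duration, "profile", profile=profile,
                             lam_max=float(lam_max))


def basic_reproduction_number(law: InfectiousnessLaw) -> float:
    """R_0 = int_0^inf E[lambda(a)] da, by adaptive quadrature."""
    hi = law.duration.upper(1e-12)
    pts = [p for p in law.duration.kinks() if 0 < p < hi]
    val, _ = integrate.quad(lambda a: float(law.mean_curve(a)), 0.0, hi,
                            points=pts or None, limit=200)
    # truncation diagnostic: the mean curve must be negligible at the cut
    tail = float(law.mean_curve(hi)) * hi
    if not np.isfinite(val) or (val > 0 and tail > 1e-6 * val):
        raise ValueError("mean infectiousness curve does not appear integrable "
                         "over the truncated age range")
    return float(val)


# ---------------------------------------------------------------------------
# Susceptibility laws
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SigmaRealization:
    """One sampled susceptibility curve."""
    curve: Callable
    #: immune-period length for step curves (np.inf = permanent immunity)
    r: Optional[float] = None

    def __call__(self, a):
        return self.curve(a)


@dataclasses.dataclass
class SusceptibilityLaw:
    """Law of the random non-decreasing susceptibility curve sigma.

    Three kinds:

    * ``deterministic`` -- a single curve shared by everyone (e.g. a
      Gamma-CDF shape: plateau of protection, then loss around a typical
      time);
    * ``step`` -- sigma(a) = 1{a >= T_R} for a random immune period T_R
      (the SIR/SIS/SIRS mechanism, with a general T_R law);
    * ``panel`` -- a fixed, seeded panel of K sampled curves, reused across
      evaluations so that functionals (Sigma, F_e) are smooth in their
      arguments (common random numbers).
    """

    kind: str
    curve: Optional[Callable] = None
    description: str = ""
    recovery: Optional[DurationLaw] = None
    panel: Optional[list] = None       # list of vectorized curves
    panel_seed: int = 0
    _kinks: tuple = ()
    _limit: Optional[float] = None

    # -- mean curve and functionals ----------------------------------------
    def mean(self, a):
        """E[sigma(a)]."""
        a = np.asarray(a, dtype=float)
        if self.kind == "deterministic":
            return self.curve(a)
        if self.kind == "step":
            return self.recovery.cdf(a)
        return np.mean([c(a) for c in self.panel], axis=0)

    def mean_kinks(self) -> tuple:
        if self.kind == "step":
            return self.recovery.kinks()
        return self._kinks

    def phi(self, t: float) -> float:
        """Phi(t) = int_0^t E[sigma(a)] da (convex, non-decreasing)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return 0.0
        pts = [p for p in self.mean_kinks() if 0 < p < t]
        val, _ = integrate.quad(lambda a: float(self.mean(a)), 0.0, t,
                                points=pts or None, limit=200)
        return float(val)

    def limit(self) -> float:
        """lim_{a -> inf} E[sigma(a)] (full-waning laws have limit 1)."""
        if self._limit is not None:
            return self._limit
        if self.kind == "step":
            return 0.0 if self.recovery.is_infinite else 1.0
        big = 1e9
        return float(self.mean(big))

    # -- representatives for quadrature over the sigma randomness -----------
    def representatives(self, k: int = 16):
        """(weights, curves, step_times) triplet for averaging over sigma.

        ``step_times`` is an array of immune-period lengths when every
        representative is a step curve (enabling closed-form handling), and
        None otherwise.
        """
        if self.kind == "deterministic":
            return np.array([1.0]), [self.curve], None
        if self.kind == "step":
            rec = self.recovery
            if rec.is_infinite:
                return np.array([1.0]), [lambda a: np.zeros_like(np.asarray(a, float))], np.array([np.inf])
            if rec._atoms is not None:
                rs = np.array([v for v, _ in rec._atoms])
                ws = np.array([p for _, p in rec._atoms])
            else:
                qs = (np.arange(k) + 0.5) / k
                rs = np.array([rec.quantile(q) for q in qs])
                ws = np.full(k, 1.0 / k)
            curves = [(lambda a, r=r: (np.asarray(a, float) >= r).astype(float))
                      for r in rs]
            return ws, curves, rs
        n = len(self.panel)
        return np.full(n, 1.0 / n), list(self.panel), None

    def sample(self, rng: np.random.Generator) -> SigmaRealization:
        if self.kind == "deterministic":
            return SigmaRealization(self.curve)
        if self.kind == "step":
            r = self.recovery.sample(rng)
            return SigmaRealization(
                lambda a, r=r: (np.asarray(a, float) >= r).astype(float), r=r)
        c = self.panel[rng.integers(len(self.panel))]
        return SigmaRealization(c)


def deterministic_sigma(curve: Callable, description: str = "custom",
                        limit: Optional[float] = None,
                        kinks: Sequence[float] = ()) -> SusceptibilityLaw:
    return SusceptibilityLaw("deterministic", curve=curve,
                             description=description, _kinks=tuple(kinks),
                             _limit=limit)


def gamma_cdf_sigma(shape: float, scale: float) -> SusceptibilityLaw:
    """Deterministic sigma(a) = GammaCDF(a; shape, scale): immunity plateaus
    and is then lost around the typical age shape*scale."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    return SusceptibilityLaw(
        "deterministic",
        curve=lambda a: special.gammainc(shape, np.asarray(a, float) / scale),
        description=f"gamma_cdf(shape={shape}, scale={scale})", _limit=1.0)


def constant_sigma(value: float = 1.0) -> SusceptibilityLaw:
    if not 0 <= value <= 1:
        raise ValueError("sigma must take values in [0, 1]")
    return SusceptibilityLaw(
        "deterministic",
        curve=lambda a, v=value: np.full_like(np.asarray(a, float), v),
        description=f"constant({value})", _limit=float(value))


def step_sigma(recovery: DurationLaw) -> SusceptibilityLaw:
    """sigma(a) = 1{a >= T_R} with random immune period T_R."""
    return SusceptibilityLaw("step", recovery=recovery,
                             description=f"step(T_R ~ {recovery.family})")


def panel_sigma(k: int = 512, seed: int = 0,
                shape_range=(2.0, 6.0), scale_range=(10.0, 60.0)) -> SusceptibilityLaw:
    """Seeded fixed panel of Gamma-CDF curves with random shape/scale."""
    rng = np.random.default_rng(seed)
    shapes = rng.uniform(*shape_range, size=k)
    scales = np.exp(rng.uniform(np.log(scale_range[0]), np.log(scale_range[1]), size=k))
    panel = [(lambda a, s=s, t=t: special.gammainc(s, np.asarray(a, float) / t))
             for s, t in zip(shapes, scales)]
    return SusceptibilityLaw("panel", panel=panel, panel_seed=seed,
                             description=f"panel(k={k}, seed={seed})", _limit=1.0)


# ---------------------------------------------------------------------------
# Scalar functionals
# ---------------------------------------------------------------------------


def hazard(law: DurationLaw, a):
    """Age-dependent event rate density(a)/survival(a) (recovery or
    vaccination rate of the transport equations)."""
    return law.hazard(a)


def mean_cumulative_susceptibility(sus: SusceptibilityLaw, t: float) -> float:
    """Phi(t) = int_0^t E[sigma(a)] da."""
    return sus.phi(t)


def stationary_susceptibility(sus: SusceptibilityLaw, vac: DurationLaw) -> float:
    """Mean susceptibility at the disease-free equilibrium,

        Sigma = E[ int_0^{T_V} sigma(a) da ] / E[T_V]
              = int_0^inf E[sigma(a)] P(T_V > a) da / E[T_V],

    the second form using the independence of sigma and T_V.  For the
    infinite sentinel (no vaccination) the large-T_V limit
    lim_a E[sigma(a)] is returned with a warning.
    """
    if vac.is_infinite:
        warnings.warn("infinite-mean vaccination law: returning the "
                      "large-T_V limit of the mean susceptibility")
        return sus.limit()
    if not np.isfinite(vac.mean) or vac.mean <= 0:
        raise ValueError("vaccination law must have a positive finite mean")
    num = vac.survival_integral(sus.mean, extra_points=sus.mean_kinks())
    val = num / vac.mean
    return float(min(max(val, 0.0), 1.0))


@dataclasses.dataclass
class ConvexOrderComparison:
    sigma1: float
    sigma2: float

    @property
    def sign(self) -> int:
        d = self.sigma1 - self.sigma2
        return 0 if abs(d) < 1e-12 else (1 if d > 0 else -1)


def convex_order_compare(vac1: DurationLaw, vac2: DurationLaw,
                         sus: SusceptibilityLaw,
                         rtol: float = 1e-8) -> ConvexOrderComparison:
    """Compare the stationary susceptibilities of two vaccination laws with
    the same mean (same dose budget 1/E[T_V]).

    If ``vac1`` is smaller in convex order than ``vac2`` (e.g. a point mass
    at the common mean), Jensen's inequality forces Sigma_1 <= Sigma_2:
    evenly spaced boosters dominate irregular ones at equal cost.
    """
    if not (np.isfinite(vac1.mean) and np.isfinite(vac2.mean)):
        raise ValueError("convex-order comparison needs finite means")
    if abs(vac1.mean - vac2.mean) > rtol * max(vac1.mean, vac2.mean):
        raise ValueError(
            f"the comparison is only meaningful at fixed cost: means differ "
            f"({vac1.mean} vs {vac2.mean})")
    return ConvexOrderComparison(stationary_susceptibility(sus, vac1),
                                 stationary_susceptibility(sus, vac2))


# ---------------------------------------------------------------------------
# Initial age densities and the full model specification
# ---------------------------------------------------------------------------


class AgeDensity:
    """A probability density of class ages at time 0 (h_I or h_S).

    Supports densities given by a duration law, the stationary age
    distribution of a renewal process with given inter-event law, an
    explicit tabulated profile, or a point mass (everyone has age a0).
    """

    def __init__(self, kind, law=None, grid=None, pdf=None, atom=None):
        self.kind = kind
        self.law = law
        self.atom = atom
        if kind == "tabulated":
            grid = np.asarray(grid, float)
            pdf = np.clip(np.asarray(pdf, float), 0.0, None)
            mass = np.trapezoid(pdf, grid)
            if mass <= 0:
                raise ValueError("tabulated age density has zero mass")
            self.grid = grid
            self.pdf = pdf / mass
            cdf = integrate.cumulative_trapezoid(self.pdf, grid, initial=0.0)
            self.cdf_vals = cdf / cdf[-1]

    @classmethod
    def from_law(cls, law: DurationLaw) -> "AgeDensity":
        if law.is_infinite:
            raise ValueError("age density cannot be the infinite sentinel")
        if law.is_point_mass:
            return cls("point", atom=float(law.params["value"]))
        return cls("law", law=law)

    @classmethod
    def point_mass(cls, age: float = 0.0) -> "AgeDensity":
        return cls("point", atom=float(age))

    @classmethod
    def stationary(cls, law: DurationLaw, n: int = 8192) -> "AgeDensity":
        """Stationary age of a renewal process with inter-event law ``law``:
        density survival(a)/mean."""
        if law.is_infinite or not np.isfinite(law.mean):
            raise ValueError("stationary age density needs a finite mean law")
        hi = law.upper(1e-12)
        grid = np.linspace(0.0, hi, n)
        return cls("tabulated", grid=grid, pdf=law.survival(grid) / law.mean)

    @classmethod
    def from_profile(cls, ages, values) -> "AgeDensity":
        return cls("tabulated", grid=ages, pdf=values)

    # -----------------------------------------------------------------
    def density(self, a):
        a = np.asarray(a, float)
        if self.kind == "law":
            return self.law.density(a)
        if self.kind == "tabulated":
            return np.interp(a, self.grid, self.pdf, left=0.0, right=0.0)
        raise ValueError("point-mass age density has no density function")

    def upper(self) -> float:
        if self.kind == "point":
            return self.atom
        if self.kind == "law":
            return self.law.upper(1e-12)
        return float(self.grid[-1])

    def nodes(self, n: int = 64):
        """Quantile-midpoint quadrature nodes (ages, weights), sum w = 1."""
        if self.kind == "point":
            return np.array([self.atom]), np.array([1.0])
        qs = (np.arange(n) + 0.5) / n
        if self.kind == "law":
            if self.law._atoms is not None:
                ages = np.array([v for v, _ in self.law._atoms])
                ws = np.array([p for _, p in self.law._atoms])
                return ages, ws
            ages = np.array([self.law.quantile(q) for q in qs])
        else:
            ages = np.interp(qs, self.cdf_vals, self.grid)
        return ages, np.full(n, 1.0 / n)

    def sample(self, rng: np.random.Generator, size: int):
        if self.kind == "point":
            return np.full(size, self.atom)
        if self.kind == "law":
            return self.law.sample(rng, size=size)
        u = rng.uniform(size=size)
        return np.interp(u, self.cdf_vals, self.grid)


@dataclasses.dataclass
class ModelSpec:
    """Full specification of the homogeneous model."""

    infectiousness: InfectiousnessLaw
    susceptibility: SusceptibilityLaw
    vaccination: DurationLaw
    i0: float
    h_i: AgeDensity
    h_s: AgeDensity

    def __post_init__(self):
        if not 0.0 < self.i0 < 1.0:
            raise ValueError("initial infected fraction must be in (0, 1)")

    @property
    def r0(self) -> float:
        return basic_reproduction_number(self.infectiousness)

    @property
    def sigma_stationary(self) -> float:
        return stationary_susceptibility(self.susceptibility, self.vaccination)

    def with_r0(self, r0: float) -> "ModelSpec":
        """Rescale the infectiousness so that the basic reproduction number
        equals ``r0`` (leaves Sigma unchanged)."""
        cur = self.r0
        if cur <= 0:
            raise ValueError("cannot rescale a zero infectiousness law")
        return dataclasses.replace(
            self, infectiousness=self.infectiousness.rescaled(r0 / cur))
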