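# Methods

## Model

`waningvax` implements a closed-population epidemic model in which immunity
is a continuously varying, individually stochastic quantity rather than a
compartment label.  Each of the N individuals alternates between two states:

* **Infected (I).** Upon infection the individual samples a random
  infectiousness curve `lambda(a) >= 0` on a random infectious period
  `[0, T_I)`; `a` is the time since infection ("class age").  While
  infected the individual cannot be reinfected.
* **Susceptible (S).** Upon recovery (or vaccination) the individual samples
  a random non-decreasing susceptibility curve `sigma(a) in [0, 1]`: the
  probability that an infectious contact at class age `a` causes
  reinfection.  Waning immunity is precisely the fact that `sigma` is
  non-decreasing.

Susceptible individuals are re-vaccinated at the renewal times of a law
`T_V`; a vaccination resets the susceptibility curve exactly as a recovery
does.  Individual `i` is infected at rate `sigma_i(t) * Lambda(t)` where
`Lambda(t) = (1/N) sum_i lambda_i(t)` is the force of infection.  Choosing
`lambda = beta` on an exponential period and `sigma(a) = 1{a >= T_R}`
recovers the stochastic SIR (`T_R = inf`), SIS (`T_R = 0`) and SIRS
(`T_R ~ Exp`) models.

All random elements of one individual are resampled independently at each
event: the model is a renewal-type structure with no memory of past
infections beyond the current curve.  The susceptibility curve after an
infection is independent of the infectiousness curve during it.

## Large-population limit

As `N -> inf` the empirical class-age measures of the I and S populations
converge to densities `I(t,a)`, `S(t,a)` solving transport equations with
removal rates `mu_I`, `mu_V` (the hazards of `T_I`, `T_V`) and renewal
boundary fluxes.  A distinctive feature survives the limit: a susceptible of
age `a` at time `t` is conditioned on having escaped infection since
`t - a`, which biases its random `sigma` downwards.  The susceptible density
therefore carries the factor `E[exp(-int_0^a Lambda(t-a+u) sigma(u) du)]`
and new infections are produced at rate
`Lambda(t) * E_{t,a}[sigma(a)] * S(t,a)` with the exposure-weighted mean

    E_{t,a}[sigma(a)] = E[sigma(a) e^{-int Lam sigma}] / E[e^{-int Lam sigma}].

For deterministic curves the bias cancels.

Along characteristics the PDE system is equivalent to Volterra integral
equations for the boundary fluxes `x(t) = I(t,0)` (incidence) and
`y(t) = S(t,0)` (recovery + vaccination flux), with
`L(t) = int E[lambda(a)] x(t-a) da` (zero-extension convention:
`lambda(a) = 0` for `a >= T_I`, so `E[lambda]` carries the survival factor).
One modelling detail: following the individual-level initial condition, the
curves of initially infected individuals are conditioned on `T_I` exceeding
their initial age, so the initial-cohort contribution to the force of
infection carries the factor `1/P(T_I > b)`; for exponential infectious
periods this is exactly the memoryless renewal term.

## Numerical scheme for the limit equations

* Uniform time grid with step `dt`; product trapezoidal rule for every
  convolution; the per-step implicit system for `(x_j, y_j, L_j)` is solved
  by Picard iteration to a relative tolerance of `1e-10` (cap 100
  iterations, with an informative error suggesting a smaller step).
* Expectations over the random susceptibility curve use a finite set of
  *representatives*: the single curve (deterministic laws), `k_sigma`
  quantile nodes of the immune period `T_R` (step laws, default 16), or the
  fixed seeded panel (panel laws).  Each cohort (and each initial-age node)
  carries one exposure integral per representative, updated incrementally by
  the trapezoidal rule; memory is `O((T/dt) * k_sigma)` and total work
  `O((T/dt)^2 * k_sigma)`.  For step curves the exposure exponentials reduce
  to scalar powers (the indicator takes values 0/1), which removes almost
  all transcendental-function cost.
* A newly created cohort has exactly zero exposure at its birth time; the
  half-leg of the trapezoidal increment belonging to the birth step is
  applied only to pre-existing cohorts.  (Getting this boundary wrong
  produces a first-order mass leak whenever `sigma(0) > 0`.)
* Initial age densities `h_I`, `h_S` are reduced to quantile-midpoint nodes
  snapped to the time grid (default 64 nodes); age integrals are truncated
  at the `1 - 1e-12` quantile of the relevant law.
* The infinite-`T_V` sentinel (no vaccination) sets `mu_V = 0` and drops the
  vaccination flux, giving the SIR/SIS/SIRS limits.
* Diagnostics on every solve: mass conservation
  `int I + int S = 1` (hard error beyond `mass_tol`, default 2e-2; the
  measured drift is exposed on the solution object) and the a-priori bound
  `x(t) <= L(t) <= I_0 lam_max e^{lam_max t}`.

The scheme is first-order in `dt` overall.  Measured behaviour: for
day-scale parameterizations (rates well below 1/day) the conservation drift
at `dt = 0.01` over `t in [0, 100]` is below `1e-5`; the sharp SIS
parameterization (`beta = 2`, `gamma = 1`) is the worst case at about
`4e-4`.  Solver cost at `dt = 0.01`, `t = 100`, `k_sigma = 16` is roughly
ten seconds on one core.

The multigroup solver is the same core vectorized over groups, with
per-group forces coupled through the symmetric contact matrix and per-group
vaccination laws; two identical groups collapse onto the homogeneous
solution to machine precision, which is used as a test oracle.

## Stochastic simulation

The individual-based model is simulated exactly by Ogata-style thinning:
candidate contact events arrive at the bounding rate `N * lambda_max`, a
uniformly chosen individual is infected with probability
`sigma_i(t) Lambda(t) / lambda_max` (valid since `sigma <= 1` and
`Lambda <= lambda_max`).  Recoveries and vaccinations are pre-scheduled in a
priority queue; simultaneous events (possible only under point-mass laws)
resolve as recovery < vaccination < infection, then individual index, so a
seeded run replays bit-identically.  One RNG substream per individual plus
one for the thinning process are spawned from the user seed.  Because
thinning realizes the inhomogeneous first-passage construction directly, no
exposure integral needs to be tracked; the distribution of infection times
is validated against the closed-form escape probability by a
Kolmogorov-Smirnov test.  Conditioning of initial curves on the initial age
uses exact inverse-CDF sampling (valid because the curve shape is
independent of the duration in the built-in families); this is robust in the
far tail where rejection sampling stalls.

For the constant-amplitude infectiousness family the total force of
infection is maintained incrementally in O(1) per event and checked against
exact recomputation; time-varying profiles fall back to exact O(#infected)
recomputation.  A first-order fixed-step Bernoulli scheme is also exposed
for susceptibility laws whose pointwise evaluation is expensive.

## Equilibria and thresholds

The disease-free equilibrium is the stationary age distribution of the
vaccination renewal process, `S(a) = P(T_V > a)/E[T_V]`.  Endemic equilibria
correspond to roots of `F_e(x) = R_0`,

    F_e(x) = x E[T_I] + x E[int_0^{T_V} e^{-x phi(a)} da]
                        / E[1 - e^{-x phi(T_V)}],

with `phi(a) = int_0^a sigma(u) du` per realization.  `F_e -> 1/Sigma` as
`x -> 0`, where `Sigma = E[phi(T_V)]/E[T_V]` is the mean susceptibility at
the disease-free equilibrium, so an endemic equilibrium exists whenever
`R_0 Sigma > 1`; for deterministic and step curves `F_e` is increasing and
the equilibrium is unique exactly when `R_0 Sigma > 1`.  Root finding scans
`F_e` on 400 log-spaced points of `(0, R_0/E[T_I]]` and refines every
bracketed sign change; all roots are reported (monotonicity of `F_e` is not
guaranteed for general random curves).  The scan runs on a cached evaluator
that tabulates all x-independent structure (survival tables,
per-representative `phi`, and for step curves the overshoot kernel
`G(a) = P(T_V - T_R > a)` built with composite Gauss-Legendre nodes over the
`T_R` density, with geometrically refined tail segments); high-accuracy
point evaluations use adaptive quadrature, and for step curves a second,
independently assembled closed form
`F_e(x) = x E[T_I] + 1 + E[T_V ^ T_R] / E[int_0^{(T_V-T_R)_+} e^{-xa} da]`
is used as a cross-check (agreement ~1e-12).

Given a root, the equilibrium profiles are explicit:
`I(a) = (x/R_0) P(T_I > a)` and
`S(a) = S(0) P(T_V > a) E[e^{-x phi(a)}]`; the prevalence (endemic level) is
`x E[T_I]/R_0`.  The `x -> 0` limit is exposed as a dedicated function
(`endemic_function_limit0`) because the generic formula suffers cancellation
there.

Stationarity caveat: the limit solver assigns *fresh unconditioned*
susceptibility curves to initially susceptible individuals, per the model's
initial condition.  Initializing at an endemic equilibrium is therefore
exactly stationary only for deterministic susceptibility curves (where the
escape-conditioning bias factorizes); the stationarity test uses the
Gamma-CDF family for this reason.

## Vaccination policy analysis

`Sigma` is the policy-efficiency indicator and `1/E[T_V]` the dose cost.
Since `Phi(t) = E[phi(t)]` is convex, Jensen's inequality gives
`Sigma = E[Phi(T_V)]/E[T_V] >= Phi(m)/m` at fixed mean `m`: evenly spaced
boosters dominate, and more generally laws smaller in convex order give
smaller `Sigma` (`convex_order_compare` enforces equal means before
comparing).  `Sigma(m T_V)` is non-decreasing in the scale `m`.

The multigroup criterion is `R_0 * rho > 1` with `rho` the spectral radius
of `M = (p_l' gamma_{l,l'} Sigma_{l'})`, computed by power iteration
(relative tolerance 1e-14).  For two equal-activity groups the contact
matrix is parametrized by the assortativity `alpha` and `rho(alpha)` has a
closed quadratic-root form, non-increasing and convex; the two routes agree
to 1e-12 and are tested against each other.  The irreducibility requirement
is relaxed (explicit flag) only for boundary scans such as `alpha = 0`,
where the spectral radius is the limit of the irreducible criterion.
Vaccine hesitancy (`Sigma_2 = 1`, well-mixed) yields the critical adherent
fraction `p_c = (1 - 1/R_0)/(1 - Sigma)`; fixed-budget dose splits are
parametrized by a fairness parameter `beta` via
`T_1 = T/(1 + beta p_2)`, `T_2 = T/(1 - beta p_1)` (budget preserved to
machine precision), and the even split `beta = 0` minimizes `rho` for all
`alpha <= 1`.  At the endpoints one group is unvaccinated: its `Sigma` is
the large-`T_V` limit `lim_a E[sigma(a)]` (1 under full waning).

## Default parameter families and study conditions

Durations are in days.  Built-in duration families: exponential, gamma
(optional shift), uniform, point mass, two-point mixture, and the infinite
"never" sentinel.  Susceptibility families: deterministic Gamma-CDF curves
`sigma(a) = GammaCDF(a; kappa, theta)` (immunity plateaus, then is lost
around `kappa * theta` days — the scale `theta` is the natural waning-speed
sweep parameter), step curves with a random immune period, and a seeded
panel (default 512 curves) reused across evaluations so that functionals are
smooth in their arguments (common random numbers).  Infectiousness:
constant-amplitude curves (with an `R_0` override that rescales the
amplitude and leaves `Sigma` untouched) and deterministic hump profiles on a
random duration.

Where a concrete study condition was needed the package uses: infectious
periods of 2-8 days, reproduction numbers 1.2-2.8, immune periods of 5-20
days (step) or Gamma-CDF waning over 10-60 days, and booster intervals of
15-60 days — magnitudes typical of fast-waning respiratory pathogens under
aggressive boosting.  The test and verification problem sizes are: limit
solver at `dt = 0.01-0.05` over horizons 100-300; stochastic runs at
`N = 500-8000` with up to 20 replicates; these were chosen so each check
carries clear statistical power on a single core.

## What the synthetic data does and does not show

All verification inputs are generated by the model itself (there is no
external data).  Passing tests demonstrate internal consistency
(stochastic model <-> limit equations <-> equilibrium formulas <->
closed-form special cases), not fit to any real epidemic: the model assumes
a closed population (no demography), no pathogen evolution, no behavioural
feedback, group-independent curve laws and equal-activity contacts in the
two-group analyses, and complete loss of memory at each immunity reset.

## Known limitations

* The limit solver is first order in `dt`; sharp-rate parameterizations
  (rates of order 1/day) need `dt <= 0.01` for 1e-3-level accuracy.
* `F_e` monotonicity — hence uniqueness of the endemic equilibrium — is
  only guaranteed for deterministic and step susceptibility laws; the root
  scan reports all roots it brackets.
* Panel susceptibility laws make the limit solver considerably slower
  (general exponential path instead of the binary step shortcut).
* Stability of equilibria is probed numerically (long-horizon solves), not
  proved.
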