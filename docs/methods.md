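# Methods

## Model

`sleepdyn` implements a structured-population model of the evolutionary value
of sleep.  A population of organisms is described by a density
`n(t, tau, x)` over time `t`, time since last feeding `tau`, and age `x`.
Both structure variables advance at unit speed, giving the hyperbolic
transport equation

    dn/dt + dn/dtau + dn/dx = -( gamma(t) f(s)(t) + alpha(t) s(t) ) n

with two renewal boundaries: organisms that forage successfully (rate
`alpha(t) s(t)`) are moved to `tau = 0`,

    n(t, 0, x) = alpha(t) s(t) * Int_0^d n(t, tau, x) dtau,

and newborns enter at age zero, inheriting the parental feeding structure,

    n(t, tau, 0) = beta(t) s(t) * Int_0^m n(t, tau, x) dx.

`d` is the starvation horizon (no one survives `d` without food) and `m` the
maximum lifespan; the density vanishes at both.  `beta`, `gamma`, `alpha` are
basal periodic birth, mortality and foraging rates, and `s(t)` is the sleep
strategy: a nonnegative periodic activity schedule with period-mean exactly 1,
so that every strategy spends the same total activity per cycle and strategies
differ only in *when* they are active.  `s == 1` is the waking baseline;
`s(t) = 1 + sigma cos(t - phase)` with depth `sigma in (0, 1]` is a sleeper.

Mortality is weighted by an exposure model `f(s)`:

* **neutral** `f = 1`: sleep does not affect mortality;
* **safe** `f = s`: sleeping is protective (sheltered or social sleep);
* **vulnerable** `f = max s - s`: sleeping is dangerous (open, solitary
  sleep), so exposure peaks when activity is lowest.

Integrating the transport equation over the `(tau, x)` rectangle, the
foraging terms cancel (feeding only moves organisms in `tau`) and the total
population `N(t)` obeys

    dN/dt = ( beta(t) s(t) - gamma(t) f(s)(t) ) N,

so the Malthusian fitness of a strategy is
`r(t) = Int_0^t (beta s - gamma f(s))`.  For single-harmonic rates and
strategies `r(t)` splits exactly into a *secular* part `lambda * t` plus a
bounded oscillation; the secular coefficient `lambda` is the long-run growth
rate and decides every comparison: whichever strategy has the larger
coefficient is ahead at all sufficiently large times, with the crossover time
computable from the oscillation bounds.  The interesting results:

* constant `beta`, `gamma`: sleeping is selectively **neutral**
  (`lambda = B - Gamma` for every depth `sigma`);
* oscillating births, constant mortality: full-depth in-phase sleep gains
  `B/2` in the secular coefficient;
* constant births (decoupled from activity), oscillating mortality: sleep
  gains `Gamma/2` in both exposure modes, and the safe strategy
  (`s = 1 - cos`) and vulnerable strategy (`s = 1 + cos`) have *identical*
  fitness functions;
* both oscillating with birth peak offset by `g`: choosing the sleep phase
  `pi/2` when `sin g >= 0` and `3 pi/2` otherwise guarantees an advantage of
  `(B/2)|sin g|` in both exposure modes, for every offset `g`.  The numerical
  optimizer (`optimize_phase`) closes the gap between this prescription and
  the true optimum `atan2((B/2) sin g, (B/2) cos g -/+ Gamma/2)`.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `B` | basal birth rate (per unit time) | 5.0 | reference magnitude used throughout the comparisons |
| `Gamma` | basal mortality rate | 2.5 | keeps the waking population growing (`B > Gamma`) |
| `period` | cycle length | `2 pi` | phases are then plain radians; the cycle need not be a day |
| `sigma` | sleep depth | 1.0 | full-depth sleep, activity touching zero once per cycle |
| `g` | birth-peak offset from mortality peak | scenario input | `pi/3` in the worked examples |
| `alpha` | basal foraging success rate | 2.0 (solver) | frequent feeding keeps the starvation-edge flux `< 1e-4 N` at `d = 6` |
| `d`, `m` | starvation horizon, lifespan | 6, 8 time units | small enough for fine grids, large enough that the absorbing edges stay empty over `t_end = 5` |
| `delta` | common grid step for `t, tau, x` | 0.01 (0.005 in verification runs) | see accuracy discussion |

Birth coupling: effective births are `beta * s` by default (mating requires
activity).  The constant-birth/oscillating-mortality scenarios decouple
births from activity (`beta` alone), matching their closed forms; the
`EnvironmentSpec.birth_coupled_to_activity` flag makes the convention
explicit.

Waking baseline convention: the waking strategy is always paired with
*neutral* exposure.  Applying the vulnerable weighting `max s - s` to
constant activity would abolish mortality entirely — a degenerate limit no
comparison intends.  Relatedly, for `sigma < 1` the vulnerable weighting
`sigma (1 - cos)` has period-mean `sigma != 1`, so sleepers and wakers face
different mean exposure; the package computes this faithfully, which is why
the secular advantage is linear in `sigma` only for the activity-coupled and
safe-exposure terms (it is affine in `sigma` in the vulnerable mode).

## Numerical choices

**Closed forms.**  Every analytic fitness is assembled from the exact
antiderivative of `c (1 + a1 cos(rho - p1))(1 + a2 cos(rho - p2))`
(`harmonic_product_integral`) rather than transcribed: births minus deaths,
with the vulnerable weighting rewritten as the harmonic
`sigma (1 + cos(rho - phase - pi))`.  A unit test pins the fully modulated
case to the printed expressions.

**Quadrature.**  Smooth harmonic inputs go through adaptive quadrature
(`scipy.integrate.quad`, default relative tolerance 1e-10 — headroom for the
1e-8 closed-form comparisons).  Tabulated rates are piecewise linear, whose
kinks stall an adaptive subdivider at these tolerances; they are integrated
by composite Gauss-Legendre panels aligned with the kinks (order 12, error
estimated against order 7, failure raised as `QuadratureError`).

**Secular extraction for general inputs.**  For tabulated inputs the exact
term split does not exist; `secular_slope_numeric` uses `r(KP)/(KP)` over
`K = 100` whole periods, where the oscillatory remainder cancels identically.

**The PDE scheme.**  Exact characteristic tracing with one common step
`delta` for `t`, `tau`, `x`; per step each interior node moves one cell
diagonally and is multiplied by `exp(-(gamma f + alpha s) delta)` evaluated
at the step midpoint.  The feeding row (`tau = 0`) is written before the
birth column (`x = 0`), which then includes the just-fed row; the corner
takes the birth value.  Both renewal rows absorb their own trapezoid weight
implicitly (`rate / (1 - rate delta / 2)`): written explicitly, each renewal
carries a per-step mass drift of order `(rate * delta)^2 / 4`, which at
effective birth rates of up to 20 per unit time accumulates to tens of
percent over five time units.

Because the initial density must vanish near the boundaries while the
renewal conditions are positive from `t = 0+`, the exact solution is
discontinuous across the generation fronts `tau = t` and `x = t`.  Exact
transport keeps these fronts on known lattice diagonals, and every line
integral (renewals and `N`) adds a half-panel jump correction there,
extrapolating the renewal-side limit from its neighbour.  Untreated, the
front gives the trapezoid rule a standing relative error of about
`rate * delta / 2` per boundary — several percent at `delta = 0.005` for the
oscillating-birth scenario.  With the correction, the measured growth-law
error is about 0.1% (constant rates) and 0.9% (oscillating births) at
`delta = 0.005`, `t_end = 5`.

*Accuracy versus nominal order.*  A scheme of this family is formally
first-order, and without the front correction it converges with factor ~2
per halving of `delta` — but with a constant so large (the front error) that
percent-level accuracy is out of reach at practical steps.  With the
correction the remaining error is second-order dominated on these problems
(measured halving factor ~4).  The package ships the corrected scheme: the
accuracy is the scientific point, and the convergence diagnostics
(`growth_law_convergence`) report the measured factor rather than assuming
the nominal order.

**Leakage.**  Mass reaching `tau = d` (starvation) or `x = m` (lifespan) is
recorded per step, never silently dropped: the growth-law reduction assumes
those edges are empty, so `verify_growth_law` flags the comparison invalid
when cumulative leakage exceeds `1e-3` of the current population.  With the
default horizons the observed fractions are below `1e-4`.

**Optimization.**  Phase optimization is a 1e-3 grid search over
`[0, 2 pi)` (ties to the smaller phase) refined by bounded scalar
minimization to 1e-6.  The objective is a single sinusoid in the phase, so
the grid stage alone already brackets the global optimum.

## Synthetic data

The generators emulate the study conditions: truncated harmonic series for
rates (2 harmonics by default) with the *sum* of relative amplitudes capped
at 1, which guarantees nonnegativity without clipping (clipping would bias
the period-mean); birth bases in [1, 2], mortality in [0.2, 0.8], foraging
in [0.3, 1.0], so synthetic populations grow on average; sleep depth uniform
on [0, 1] and phase uniform on the cycle; initial densities are smooth
compact mollifier bumps supported in `tau < d/2`, `x < m/4`, keeping the
absorbing edges empty over the solver horizon.  All draws come from
`numpy.random.default_rng((seed, salt))` with a fixed salt per generator:
the same seed reproduces every object bit for bit.

What the generators do *not* emulate: non-harmonic (e.g. square-wave or
multi-bout) activity patterns as optimized objects, rates varying on
multiple timescales, density dependence, and age- or hunger-dependent vital
rates.  Passing tests therefore demonstrate correctness of the model's
mathematics under periodic forcing, not realism of any particular organism's
schedule.

## Problem sizes

Verification runs use `d = 6`, `m = 8`, `t_end = 5` at `delta = 0.005`
(about 1.9 million grid nodes, 1000 steps) with one refinement to
`delta = 0.0025` for the convergence factor; quadrature cross-checks use 20
random times per scenario and 10^6-step Riemann sums.  These sizes keep a
full verification pass in the low minutes on a single core while leaving the
measured errors far from their tolerances (except the convergence-factor
diagnostic discussed above).

## Known limitations

* The closed-form suite covers the single-harmonic family only; general
  periodic inputs are handled numerically (tabulated contract).
* The vulnerable exposure model for partial sleep depth (`sigma < 1`)
  implies unequal mean exposure between strategies (see above); comparisons
  at `sigma < 1` in that mode should be interpreted accordingly.
* The solver assumes rates depend on time only; age- or hunger-dependent
  rates would break the exact total-population reduction that the growth-law
  verification relies on.
* At `sin g = 0` with `B cos g = Gamma`, the best single-harmonic safe-mode
  strategy has zero secular advantage; whether richer strategy families
  break that tie is outside the scope of this package.
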