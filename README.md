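# bindingsir

Deterministic solvers and stochastic simulators for SIR epidemics on
configuration-type contact networks in which each individual has a fixed
number `n` of *binding sites* (partnership slots). Three nested models are
covered:

- **Static network** (`bindingsir.static_net`) — partnerships are fixed for
  all time. Four equivalent formulations are implemented: the binding-site
  ODE system, the scalar (Volz-type) ODE, the renewal equation driven by an
  arbitrary escape kernel, and a closed phase-type system. Includes
  R0, the Malthusian parameter `r`, final size, and the individual-level
  (multinomial) state bookkeeping.
- **Dynamic partnerships** (`bindingsir.dynamic_net`) — partnerships form at
  rate `rho F` per free site and dissolve at rate `sigma`; a closed six-ODE
  system plus integral-representation cross-checks, thresholds and final size.
- **Demographic turnover** (`bindingsir.demo_net`) — individuals additionally
  die at rate `mu` and are replaced by partner-free susceptibles. An
  age-structured cohort solver, a 2x2 next-generation kernel (R0, `r`), and
  the endemic fixed point of the environmental map.

A finite-population oracle (`bindingsir.stochastic`) provides an exact
event-driven simulator on configuration graphs and a Gillespie simulator
with explicit partnership dynamics. `bindingsir.cli_io` exposes everything
on the command line.

## Worked example

```python
from bindingsir.static_net import StaticParams, summary_static

params = StaticParams(beta=2.0, gamma=1.0, n=3)
print(summary_static(params))
```

prints (up to floating-point formatting)

```
{'R0': 1.3333333333333335, 'r': 1.0, 'r_status': 'ok',
 'xbar_inf': 0.5, 'final_size': 0.875}
```

i.e. at transmission rate `beta = 2`, recovery rate `gamma = 1` and three
binding sites per individual, the epidemic threshold quantity is
`R0 = beta (n-1) / (beta + gamma) = 4/3`, the early exponential growth rate
is exactly `r = 1`, and the final-size equation factorizes so that the
probability a binding site never transmits is `1/2` and a fraction
`1 - (1/2)^3 = 0.875` of the population is ultimately infected.

The same scenario from the command line:

```sh
bindingsir run --beta 2 --gamma 1 --n 3 --out results/
bindingsir r0 --case dynamic --rho 2 --sigma 1     # prints R0 = 7/6
bindingsir endemic --case demography --beta 3 --gamma 0.5 --mu 0.2
bindingsir simulate --case static --seed 1 --out sim/
```

Each run echoes the fully-resolved configuration (all defaults filled in)
next to its outputs, writes trajectories as CSV at 17 significant digits
(lossless round trip for double precision) and a `summary.json`.

## Epidemic seeding (the `eps` policy)

All deterministic solvers start from an epidemiologically small but strictly
positive perturbation of the disease-free state, controlled by `eps`
(default `1e-6`):

- static/dynamic ODEs: a fraction `eps` of binding sites of susceptible
  individuals is transferred to the "partner infectious" state;
- renewal/scalar formulations: the history `xbar = 1 - eps` (the scalar ODE
  rescales to `eps' = 1 - (1-eps)^{1/(n-1)}` so that the consistency relation
  `x1 = xbar^{n-1}` holds at `t = 0`);
- cohort solver: each age cohort moves a fraction `eps` of its
  susceptible-partner probability to infectious-partner status at `t = 0`.

Because the formulations seed with slightly different effective amplitudes,
trajectories agree only after aligning them on a common epidemic phase (a
time translation); the test suite does exactly this. Final sizes in the
supercritical regime depend on `eps` only at `O(eps)`.

## Numerical choices

- ODE systems: `scipy.integrate.solve_ivp` (LSODA) at `rtol 1e-10`,
  `atol 1e-12`; outputs on a uniform grid of step `dt` (default `0.01`).
- Renewal equation: product integration (the kernel increment `F(tau_i) -
  F(tau_{i+1})` is applied to the trapezoid of the nonlinearity), which makes
  the disease-free state an exact equilibrium of the discrete scheme; plain
  trapezoid quadrature would bias the equilibrium at `O(dt^2)` and corrupt
  invasion dynamics at small `eps`.
- Cohort solver (case III): method of characteristics on a shared age/time
  step with a Heun (predictor-corrector) update of the environments; memory
  integrals carried by per-cohort exponential accumulators. The age cutoff
  defaults to `10/mu` (truncation error below `e^{-10}`); the step is guarded
  by a CFL-type check and defaults to at most `0.01`.
- Root finding (thresholds, final sizes, Malthusian parameters):
  `scipy.optimize.brentq` at `xtol 1e-13` with bracket expansion; searches
  respect the Laplace abscissa of the kernel and report `"no real root"`
  instead of guessing.
- Endemic state: damped fixed-point iteration (`omega = 0.5`) on the
  three-dimensional environmental map, each evaluation an accurate
  age-integration (`rtol 1e-12`); iterates are projected to the admissible
  set.
- Stochastic static SIR: the percolation representation (per-node infectious
  periods, per-directed-edge transmission delays, Dijkstra from the seeds),
  which samples the exact continuous-time process in
  `O((N + E) log N)` per replicate. Dynamic simulation uses a direct
  Gillespie scheme with an aggregate pair-formation rate
  `rho B(B-1)/(2 n N)`; the partnership process is burnt in to stationarity
  before seeding.
- Determinism: every stochastic entry point takes a `seed`; replicate seeds
  are derived by a fixed stride, and reruns are byte-for-byte identical.

Default problem sizes (`N = 10^4`, 10 replicates, `t_end = 40`) are package
choices made so the CLI answers in seconds; the test suite exercises
`N = 10^5` with 200 replicates.

## Limitations

- The binding-site and partnership ODE paths assume a uniform number of
  binding sites; general degree distributions are served by the renewal
  formulation (case I only).
- Case III (demographic turnover) has no exact finite-population simulator;
  `simulate_dynamic_sir(..., mu > 0)` implements a deliberately minimal
  death-and-replacement probe whose results are reported descriptively.
- The Gillespie pair-formation step draws uniform stub pairs and rejects
  same-owner pairs, while the aggregate rate counts all pairs; this is an
  `O(1/N)` bias relative to the mean field.
- Fixed-point iteration for the endemic state is damped but not globally
  guaranteed; convergence from random admissible starts is verified in the
  tests for the documented parameter sets, not proved.
- The `eps -> 0` limit is singular (the disease-free state is an
  equilibrium); quantitative trajectory comparisons require the time-shift
  alignment described above.

See `docs/methods.md` for derivations, discretization details and the exact
formulas implemented.
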