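# Methods

Notation: each individual carries `n` binding sites. A site of a susceptible
individual is classified by its partner: `x1` (partner susceptible), `x2`
(partner infectious), `x3` (partner recovered); in the dynamic models `x0`
(free). `xbar = x0 + x1 + x2 + x3` (no `x0` term in the static case) is the
probability that a site has not yet transmitted to its owner, and
`s(t) = xbar^n` is the fraction still susceptible. Transmission acts per
infectious partnership at rate `beta`, recovery at rate `gamma`, partnership
formation at rate `rho F` per free site (`F` the stationary free fraction),
separation at rate `sigma`, and death/replacement at rate `mu`.

## Escape kernels (`kernels`)

The renewal formulation needs only the *escape kernel* `F(tau)`: the
probability that a susceptible partner of an individual infected `tau` ago
has not received infection across that partnership.

- Markovian SIR: `F(tau) = gamma/(beta+gamma) + beta/(beta+gamma)
  e^{-(beta+gamma) tau}`, `F(inf) = gamma/(beta+gamma)`.
- Phase-type infectiousness (stages `Sigma`, per-stage transmission rates
  `beta_vec`, initial-stage distribution `V`):
  `F(tau) = 1 - int_0^tau beta_vec . e^{eta (Sigma - diag beta_vec)} V d eta`,
  evaluated with `scipy.linalg.expm`. The Laplace transform of the
  infection-time density `-F'` is available in closed form from the resolvent
  `(lam I - A)^{-1}` with `A = Sigma - diag beta_vec`.

Degree distributions enter through the size-biased generating function
`g(x) = sum_n n p_n x^{n-1} / sum_m m p_m` and the mean excess degree
`g'(1) = E[n(n-1)]/E[n]`.

## Case I: static network (`static_net`)

Formulations (all seeded by `eps`, see README):

1. **Binding-site ODE.** `x1' = -beta (n-1) (x2/xbar) x1`,
   `x2' = beta (n-1)(x2/xbar) x1 - (beta+gamma) x2`, `x3' = gamma x2` from
   `(1-eps, eps, 0)`. Summing gives the leakage law `xbar' = -beta x2`.
2. **Scalar ODE (Volz-type).** `xbar' = beta g(xbar) - (beta+gamma) xbar +
   gamma` (uniform degree: `g(x) = x^{n-1}`).
3. **Renewal equation.** `xbar(t) = F(inf) - int_0^inf g(xbar(t-tau))
   F'(tau) d tau` with history `xbar = 1 - eps` for `t <= 0`.
4. **Phase-type closure.** For phase-type kernels, `dQ/dt = A Q + g(xbar) V`
   with `xbar = F(inf) + beta_vec . Q`; the disease-free state is
   `Q* = -A^{-1} V`.

Thresholds: `R0 = g'(1)(1 - F(inf))` (for Markovian SIR and uniform degree,
`beta (n-1)/(beta+gamma)`); the Malthusian parameter `r` solves the
Euler-Lotka equation `1 = g'(1) int_0^inf e^{-r tau} (-F'(tau)) d tau`.
Final size: `xbar(inf)` is the root in `(0,1)` of
`x = F(inf) + (1 - F(inf)) g(x)` when `R0 > 1`, and the final size is
`1 - sum_n p_n xbar(inf)^n`. At the benchmark `beta=2, gamma=1, n=3` the
final-size cubic factorizes, giving `xbar(inf) = 1/2`, final size `7/8`,
`R0 = 4/3` and `r = 1` exactly.

**Renewal discretization.** With grid step `dt`, write the convolution as a
sum of kernel increments `dF_i = F(tau_i) - F(tau_{i+1})` applied to the
trapezoid average of `g(xbar)` over the matching interval (product
integration), plus a tail term `g(1-eps)(F(tau_m) - F(inf))` for the
pre-seeding history. Because `sum_i dF_i + F(inf) = 1` exactly, `xbar = 1`
is an exact equilibrium of the discrete scheme; this matters because the
interesting initial data are `O(eps)` perturbations of that equilibrium.
The implicit diagonal term is resolved by a scalar fixed-point iteration per
step.

**Individual-level bookkeeping.** The susceptible labels are the multinomial
lift `p_(-,k) = C(n;k) x1^{k1} x2^{k2} x3^{k3}`; summing over `k` gives
`xbar^n` identically. A population-level ODE for the `p_(-,k)` (closing the
environment through the labels themselves) provides an independent
cross-check. After the owner's infection (at `t_+`) or recovery (at `t_*`),
the remaining sites follow linear time-inhomogeneous systems driven by the
environments `Lambda_+ = 1 + Lambda_-` and `Lambda_* = (n-1) x3/xbar`; these
are lower triangular and are integrated by cumulative quadrature of the
integrating-factor representation on the trajectory grid. The exceptional
(transmitting) site is `(0, e^{-gamma (t-t_+)}, 1 - e^{-gamma (t-t_+)})`.
Weighting by incidence and integrating reconstructs the infectious and
recovered label distributions; `S + I + R` then totals one up to the
quadrature error of the reconstruction (second order in `dt`).

## Case II: dynamic partnerships without demography (`dynamic_net`)

The stationary free fraction solves `rho F^2 + sigma F - sigma = 0`
(positive root); a site free for duration `xi` since a reference time has
re-partnered with a (then-susceptible) partner with probability
`phi1(xi) = F (1 - e^{-theta xi})`, `theta = rho F + sigma`.

Closed system (states `x0..x3` for a susceptible's site, plus prevalence `I`
and free-infectious-site fraction `F_+`):

```
x0' = -rho F x0 + sigma (x1 + x2 + x3)
x1' =  rho x0^2 xbar^{n-1}         - (sigma + beta(n-1) x2/xbar) x1
x2' =  rho F_+ x0 + beta(n-1)(x2/xbar) x1 - (sigma + beta + gamma) x2
x3' =  rho F_* x0 + gamma x2 - sigma x3
I'  =  beta n x2 xbar^{n-1} - gamma I
F_+' = beta(n-1) x0 x2 xbar^{n-2} - (rho F + gamma) F_+ + sigma (I - F_+)
```

with `F_- = x0 xbar^{n-1}` (free sites owned by susceptibles) and
`F_* = F - F_- - F_+` (free sites of recovered owners); the split
`F_- + F_+ + F_* = F` is conserved exactly. Initial data:
`(F, 1-F-eps, eps, 0)`, `I = eps`, `F_+ = F eps`.

Cross-checks: `F_+` and `I` satisfy integral (renewal) representations over
the incidence history,

```
F_+(t) = eps F e^{-gamma t} + int_0^t e^{-gamma(t-s)} beta x2 xbar^{n-1}(s)
         [ n phi1(t-s) + (n-1)(x0/xbar)(s) e^{-theta(t-s)} ] ds,
```

evaluated by trapezoid quadrature on the solution grid (error `O(dt^2)`).

Thresholds: the linearized infection process has a scalar kernel whose
Laplace transform is, with `s = sigma + beta + gamma`,

```
K^(lam) = beta/(lam+s) { (n-1)(1-F)
          + rho F [ F (1/(lam+gamma) - 1/(lam+gamma+theta))
                    + (n-1) F/(lam+gamma) ] },
```

`R0 = K^(0)` (equal to `7/6` at `beta=2, gamma=1, rho=2, sigma=1, n=3`) and
`r` solves `K^(r) = 1` (abscissa `-gamma`). `sigma -> 0` gives `F = 0` and
the system collapses to case I.

Final size integrates the ODE to quiescence (`max |RHS| < 1e-12` over ten
consecutive steps), doubling the horizon as needed.

## Case III: demographic turnover (`demo_net`)

`F` solves `rho F^2 + (sigma + 2 mu) F - (sigma + 2 mu) = 0` (each member of
a partnership dies at rate `mu`, hence `2 mu`). With
`theta = rho F + sigma + mu`, `c_inf = (sigma+mu)/theta`,
`c_rho = rho F / theta`:

- `phi0(a) = c_inf + c_rho e^{-theta a}` (site of an age-`a` individual is
  free), `phi1(a) = c_inf (1 - e^{-theta a})`;
- link-age densities `pi0(a) = mu e^{-mu a} phi0(a)/F` (links born by pairing)
  and `pi1(a) = mu e^{-mu a}(1 - phi0(a))/(1 - F)` (partner side of an
  existing link);
- the stationarity identity `int mu e^{-mu a} phi0(a) da = F` holds in
  closed form and is verified by quadrature in the tests.

**Cohort solver.** Along characteristics (age = time since birth), a cohort's
sites obey a linear system driven by the aggregate environments
`E = (F_+, F_*, Lambda_-)`; environments are age-averages against
`mu e^{-mu a}` of cohort quantities. The solver advances all cohorts and the
environments on a shared step (Heun predictor-corrector), carrying the
memory integrals needed for `F_+` as per-cohort exponential accumulators
`J_kappa[s](a) = int_0^a e^{-kappa(a-u)} s(u) du` updated by one-step
recursions. Newborns enter partner-free, so the age-0 boundary is
`x(0) = (1, 0, 0, 0)`.

**Next-generation kernel.** Linearizing about the disease-free state yields
a 2x2 renewal kernel over the two birth types of susceptible-infectious
links (type 0: born by pairing of free sites; type 1: born by infection of
the partner of an existing link). With `s = sigma + 2 mu + beta + gamma`,
`d = mu + gamma`, and the exponential moments `A0, A1` of `e^{-theta a}`
against `pi0, pi1`, the rows are

```
K_0j(tau) = beta rho F [ (c_inf + (n-1)(c_inf + c_rho A_j e^{-theta tau}))
            E(s, d; tau) - c_inf E(s, d + theta; tau) ]
K_1j(tau) = beta (n-1) c_rho e^{-s tau} (1 - A_j e^{-theta tau})
```

where `E(p, q; tau) = (e^{-q tau} - e^{-p tau})/(p - q)` is the exponential
convolution. *Derivation note:* the type-0 row is the convolution of the
transmission-delay density `e^{-s xi}` with the post-infection factor,
because the renewal delay is the **sum** of the transmission delay and the
post-infection time. Carrying the delay only through the second factor (a
product instead of a convolution) leaves the integrated kernel — hence R0 —
unchanged but distorts the Laplace transform; the package uses the
convolution form, which is validated three ways in the test suite (nested
quadrature of the defining double integral, the early-phase slope of the
nonlinear cohort solver, and the `mu -> 0` limit against case II).

`R0` is the dominant eigenvalue of `int K`; `r` solves
`rho(K^(lam)) = 1` (abscissa `-(mu+gamma)`). The unscaled kernel acting on
`(F_+ hat, Lambda_- hat)` is similar to `K` under
`C = diag(rho F n, beta n (1-F))`, so both share their spectrum.

**Endemic state.** A constant environment `E = (F_+, F_*, Lambda_-)` is
endemic iff it is a fixed point of the map `G` that (i) integrates the
cohort system under constant `E` over age, and (ii) recomputes the
age-averaged environments. `G` is evaluated by a single high-accuracy
`solve_ivp` run over an 11-dimensional augmented state (cohort states,
memory accumulators, and the age-average accumulators). The fixed point is
found by damped iteration `E <- (1-omega) E + omega G(E)` (`omega = 0.5`,
tolerance `1e-10`) with projection onto the admissible set
(`F_+, F_* >= 0`, `F_+ + F_* <= F`, `0 <= Lambda_- <= n-1`). Subcritical
parameters drive the iteration to the extinction state `(0, 0, 0)`.

## Stochastic oracle (`stochastic`)

- **Configuration graphs**: degrees sampled i.i.d. from the target pmf (one
  degree resampled to fix parity; if the support cannot fix parity, one stub
  is dropped), uniform stub matching, then up to 100 rounds of rematching
  confined to defective (self-loop/duplicate) edges, erasing whatever
  remains. For the sizes used here the erased fraction is `O(1/N)`.
- **Static SIR**: percolation representation. Draw infectious periods
  `Exp(gamma)` per node and a transmission delay `Exp(beta)` per directed
  edge at expansion time; an edge transmits iff its delay is shorter than
  the source's infectious period. Infection times are the Dijkstra
  distances from the seed set. This reproduces the exact law of the
  continuous-time Markov process.
- **Dynamic SIR**: direct Gillespie. Free stubs are paired at aggregate rate
  `rho B(B-1)/(2 n N)` (uniform pair, same-owner pairs rejected — an
  `O(1/N)` bias versus the mean field), partnerships separate at `sigma`,
  susceptible-infectious partnerships transmit at `beta`, infectious
  individuals recover at `gamma`, and (optionally) individuals die at `mu`
  and are replaced by partner-free susceptible newborns. The pure
  partnership process is burnt in (default `30/(rho F + sigma)`) before the
  epidemic is seeded.
- **Growth estimation**: least-squares slope of `log` incidence on a time
  window; nonpositive values inside the window are an error.
- Seeding: replicate `i` uses `seed + i * 1000003 (mod 2^31 - 1)`; all
  results are byte-for-byte reproducible.

## File formats (`cli_io`)

Flat dotted-key configs (`model.beta = 2.0`) or JSON with the same keys;
unknown keys are rejected naming the nearest valid key. Trajectory CSVs are
written at 17 significant digits (exact round trip) with fixed column
orders:

- static: `t,x1,x2,x3,xbar,s_frac,incidence,lambda_minus,lambda_plus,lambda_star`
- dynamic: `t,x0,x1,x2,x3,I,F_plus,F_minus,F_star,s_frac,incidence`
- demography: `t,Lambda_minus,F_minus,F_plus,F_star,prevalence,incidence`
- replicate summaries: `replicate,final_size,major_outbreak,peak_incidence`

Summaries: `{R0, r, xbar_inf, final_size, params, kernel}` (static),
`{F, R0, r, final_size}` (dynamic),
`{F, R0, r, endemic: {F_plus, F_star, Lambda_minus, residual, converged}}`
(demography).
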