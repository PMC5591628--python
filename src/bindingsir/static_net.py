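"""SIR on a static configuration network (binding-site / edge-based model).

A susceptible individual with partnership capacity ``n`` is a bundle of ``n``
conditionally independent binding sites.  The probability vector
``x = (x1, x2, x3)`` tracks a single susceptible binding site whose partner is
susceptible / infectious / recovered, conditional on the owner not being
infected through its other ``n - 1`` sites; ``xbar = x1 + x2 + x3`` is the
Volz variable (the probability that no transmission has occurred along the
site), and ``xbar**n`` is the fraction of susceptible individuals.

Four equivalent formulations are implemented:

* the three-dimensional binding-site ODE (``solve_static_binding_site``),
* the decoupled scalar ODE for ``xbar`` (``solve_scalar_volz``),
* the nonlinear renewal equation driven by a general escape kernel and degree
  distribution (``solve_renewal_volz``),
* the closed ODE representation for phase-type kernels
  (``phase_type_closed_solve``).

On top of these sit the calculators for R0, the Malthusian parameter r and
the final epidemic size, plus the reconstruction of individual-level state
distributions for susceptible, infectious and recovered individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import factorial

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import brentq

from .kernels import (
    DegreeDistribution,
    InfectiousnessKernel,
    MarkovianSIRSpec,
    PhaseTypeSpec,
    degree_generating,
    gprime_at_one,
    markovian_kernel,
    phase_type_kernel,
)

__all__ = [
    "StaticParams",
    "BindingSiteTrajectory",
    "ScalarTrajectory",
    "RootResult",
    "StateDistribution",
    "PostSusceptibleState",
    "solve_static_binding_site",
    "solve_scalar_volz",
    "solve_renewal_volz",
    "r0_static",
    "malthusian_static",
    "final_size_static",
    "ilevel_susceptible",
    "post_susceptible_distributions",
    "phase_type_closed_solve",
    "solve_plevel_susceptible",
    "compositions",
]

_ODE_RTOL = 1e-10
_ODE_ATOL = 1e-12
_XBAR_FLOOR = 1e-14


@dataclass(frozen=True)
class StaticParams:
    """Parameters of the static-network Markovian SIR model.

    ``eps`` is the size of the initial perturbation replacing the formal
    "infection introduced in the far past" limit: at t = 0 a fraction eps of
    partners of susceptibles is infectious.  Solutions for different eps agree
    up to a time translation.
    """

    beta: float
    gamma: float
    n: int
    eps: float = 1e-6
    t_end: float = 40.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.n < 2:
            raise ValueError("partnership capacity n must be >= 2")
        if not 0.0 < self.eps < 0.1:
            raise ValueError("eps must lie in (0, 0.1)")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")

    def kernel(self) -> InfectiousnessKernel:
        return markovian_kernel(MarkovianSIRSpec(self.beta, self.gamma))

    def degree(self) -> DegreeDistribution:
        return DegreeDistribution.uniform(self.n)


@dataclass
class BindingSiteTrajectory:
    """Time-gridded solution of the susceptible binding-site system."""

    times: np.ndarray
    x: np.ndarray  # shape (3, K): rows x1, x2, x3
    lambda_minus: np.ndarray
    lambda_plus: np.ndarray
    lambda_star: np.ndarray
    s_frac: np.ndarray
    incidence: np.ndarray
    status: str = "ok"

    @property
    def xbar(self) -> np.ndarray:
        return self.x.sum(axis=0)


@dataclass
class ScalarTrajectory:
    times: np.ndarray
    xbar: np.ndarray
    status: str = "ok"


@dataclass(frozen=True)
class RootResult:
    """Result of a characteristic-equation root search."""

    value: float
    status: str = "ok"  # "ok" | "no real root"

    def __float__(self) -> float:
        return self.value


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with the convention 0/0 = 0 (both vanish at the absorbing state)."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    mask = np.abs(den) > 1e-300
    out[mask] = (num / np.where(mask, den, 1.0))[mask]
    return out


def _fill_environment(traj: BindingSiteTrajectory, params: StaticParams) -> None:
    n, beta = params.n, params.beta
    x1, x2, x3 = traj.x
    xbar = traj.xbar
    traj.lambda_minus = (n - 1) * _ratio(x2, xbar)
    traj.lambda_plus = 1.0 + traj.lambda_minus
    traj.lambda_star = (n - 1) * _ratio(x3, xbar)
    traj.s_frac = xbar**n
    traj.incidence = beta * n * x2 * xbar ** (n - 1)


def solve_static_binding_site(params: StaticParams) -> BindingSiteTrajectory:
    """Integrate x1' = -b(n-1)(x2/xbar)x1, x2' = ... from (1-eps, eps, 0)."""
    beta, gamma, n = params.beta, params.gamma, params.n

    def rhs(_t, x):
        x1, x2, _x3 = x
        xbar = x.sum()
        ratio = 0.0 if x2 < 1e-300 else x2 / xbar
        foi = beta * (n - 1) * ratio
        return [-foi * x1, foi * x1 - (beta + gamma) * x2, gamma * x2]

    def absorbing(_t, x):
        return float(np.sum(x)) - _XBAR_FLOOR

    absorbing.terminal = True
    absorbing.direction = -1

    times = np.arange(0.0, params.t_end + 0.5 * params.dt, params.dt)
    sol = solve_ivp(
        rhs,
        (0.0, params.t_end),
        [1.0 - params.eps, params.eps, 0.0],
        method="LSODA",
        t_eval=times,
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
        events=absorbing,
        max_step=np.inf,
    )
    status = "ok" if not sol.t_events[0].size else "absorbing state reached"
    traj = BindingSiteTrajectory(
        times=sol.t,
        x=sol.y,
        lambda_minus=None,
        lambda_plus=None,
        lambda_star=None,
        s_frac=None,
        incidence=None,
        status=status,
    )
    _fill_environment(traj, params)
    return traj


def _g_polynomial(degree: DegreeDistribution) -> np.polynomial.Polynomial:
    ns = degree.degrees()
    ps = degree.probabilities()
    mean = float(np.dot(ns, ps))
    coefs = np.zeros(int(ns.max()))
    for n, p in zip(ns, ps):
        if n >= 1:
            coefs[n - 1] += n * p / mean
    return np.polynomial.Polynomial(coefs)


def solve_scalar_volz(
    params: StaticParams, degree: DegreeDistribution | None = None
) -> ScalarTrajectory:
    """Integrate the decoupled Volz equation xbar' = beta g(xbar) - (beta+gamma) xbar + gamma.

    The initial value 1 - eps' is chosen so that the consistency relation
    x1 = xbar**(n-1) maps the binding-site initial condition x1(0) = 1 - eps:
    eps' = 1 - (1 - eps)**(1/(n-1)) ~ eps/(n-1).  The two formulations then
    agree up to an O(eps) time translation.
    """
    degree = degree or params.degree()
    g = _g_polynomial(degree)
    beta, gamma = params.beta, params.gamma
    eps_prime = 1.0 - (1.0 - params.eps) ** (1.0 / (params.n - 1))

    def rhs(_t, y):
        xb = min(max(y[0], 0.0), 1.0)
        return [beta * g(xb) - (beta + gamma) * xb + gamma]

    times = np.arange(0.0, params.t_end + 0.5 * params.dt, params.dt)
    sol = solve_ivp(
        rhs,
        (0.0, params.t_end),
        [1.0 - eps_prime],
        method="LSODA",
        t_eval=times,
        rtol=_ODE_RTOL,
        atol=_ODE_ATOL,
    )
    return ScalarTrajectory(times=sol.t, xbar=sol.y[0])


def solve_renewal_volz(
    kernel: InfectiousnessKernel,
    degree: DegreeDistribution,
    eps: float = 1e-6,
    t_end: float = 40.0,
    dt: float = 0.01,
) -> ScalarTrajectory:
    """Time-step the renewal equation xbar(t) = F(inf) - int g(xbar(t-tau)) F'(tau) dtau.

    History is xbar = 1 - eps on (-inf, 0]; its contribution is carried as the
    analytic tail g(1-eps) (F(inf) - F(t)) rather than by quadrature, and the
    kernel memory is truncated where |F(tau) - F(inf)| < 1e-10.
    """
    g = _g_polynomial(degree)
    Finf = kernel.escape_limit
    status = "ok"
    if 1.0 - Finf <= 1e-10:
        t_hist = 2 * dt  # kernel (essentially) constant: no transmission
    else:
        # memory truncation: F is monotone, find tau with F - Finf < 1e-10
        hi = 1.0
        while kernel(hi) - Finf > 1e-10 and hi < 1e6:
            hi *= 2.0
        t_hist = hi if hi >= 1e6 else brentq(
            lambda tau: float(kernel(tau)) - Finf - 1e-10, 0.0, hi
        )
        half_level = Finf + 0.5 * (1.0 - Finf)
        t_half = brentq(lambda tau: float(kernel(tau)) - half_level, 0.0, t_hist)
        if t_half / dt < 4:
            status = "warning: dt too coarse for kernel half-life"

    L = max(int(np.ceil(t_hist / dt)), 2)
    tau = np.arange(L + 1) * dt
    F_tau = np.asarray(kernel(tau), dtype=float)
    # product-integration weights: dF[i] = F(tau_i) - F(tau_{i+1}) is the exact
    # transmission mass of interval i+1; g is treated as piecewise linear in tau.
    # Plain trapezoid of g * F' would bias the quadrature mass by O(dt^2), which
    # shifts the discrete disease-free equilibrium off xbar = 1 by more than eps
    # and corrupts the invasion dynamics; with product integration a constant g
    # is integrated exactly, so the disease-free state is an exact equilibrium.
    dF = F_tau[:-1] - F_tau[1:]

    K = int(round(t_end / dt))
    times = np.arange(K + 1) * dt
    xb = np.empty(K + 1)
    g_hist = g(1.0 - eps)
    gx = np.empty(K + 1)  # cached g(xb)

    for j in range(K + 1):
        m = min(j, L)
        # sum over intervals i=1..m: dF[i-1] * (g_{j-i+1} + g_{j-i}) / 2,
        # with g_j (the i=1 left endpoint) handled implicitly below
        if m >= 1:
            idx = np.arange(1, m + 1)
            known = 0.5 * float(np.dot(dF[:m], gx[j - idx]))
            if m >= 2:
                known += 0.5 * float(np.dot(dF[1:m], gx[j - idx[1:] + 1]))
        else:
            known = 0.0
        # analytic tail for tau > m dt (pre-t=0 history constant at 1 - eps)
        tail = g_hist * (F_tau[m] - Finf) if j <= L else 0.0
        const = Finf + known + tail
        c0 = 0.5 * dF[0] if m >= 1 else 0.0
        # implicit in g(xb[j]); fixed point converges since |c0 g'| << 1
        x_new = xb[j - 1] if j else 1.0 - eps
        for _ in range(80):
            x_next = const + c0 * g(x_new)
            if abs(x_next - x_new) < 1e-15:
                x_new = x_next
                break
            x_new = x_next
        xb[j] = x_new
        gx[j] = g(xb[j])

    return ScalarTrajectory(times=times, xbar=xb, status=status)


def r0_static(kernel: InfectiousnessKernel, degree: DegreeDistribution) -> float:
    """R0 = g'(1) (1 - F(inf)): mean excess degree times transmission probability."""
    return gprime_at_one(degree) * (1.0 - kernel.escape_limit)


def malthusian_static(
    kernel: InfectiousnessKernel, degree: DegreeDistribution
) -> RootResult:
    """Real root of the Euler-Lotka equation 1 = -g'(1) int e^{-lam tau} F'(tau) dtau."""
    gp = gprime_at_one(degree)

    def L(lam: float) -> float:
        return gp * kernel.escape_deriv_laplace(lam)

    r0 = L(0.0)
    if abs(r0 - 1.0) < 1e-14:
        return RootResult(0.0)
    if r0 > 1.0:
        hi = 1.0
        while L(hi) > 1.0:
            hi *= 2.0
        return RootResult(brentq(lambda lam: L(lam) - 1.0, 0.0, hi, xtol=1e-13))
    # subcritical: search in (abscissa, 0)
    absc = kernel.laplace_abscissa
    lo = None
    for k in range(1, 60):
        cand = absc + (0.0 - absc) * 0.5**k
        val = L(cand)
        if val > 1.0:
            lo = cand
            break
    if lo is None:
        return RootResult(float("nan"), status="no real root")
    return RootResult(brentq(lambda lam: L(lam) - 1.0, lo, 0.0, xtol=1e-13))


def final_size_static(
    kernel: InfectiousnessKernel, degree: DegreeDistribution
) -> tuple[float, float]:
    """Solve xbar = F(inf) + (1 - F(inf)) g(xbar); return (xbar_inf, final size).

    Final size is 1 - sum_n p_n xbar_inf**n.  For R0 <= 1 the only root in
    [0, 1] is 1 and the final size is 0.
    """
    if r0_static(kernel, degree) <= 1.0:
        return 1.0, 0.0
    g = _g_polynomial(degree)
    Finf = kernel.escape_limit

    def h(x: float) -> float:
        return Finf + (1.0 - Finf) * g(x) - x

    # h(0) = Finf >= 0 (with equality only if Finf=0 and g(0)=0); root in (0, 1)
    hi = 1.0 - 1e-12
    xbar_inf = brentq(h, 0.0, hi, xtol=1e-13, rtol=8.9e-16)
    ns = degree.degrees()
    ps = degree.probabilities()
    final_size = 1.0 - float(np.dot(ps, xbar_inf ** ns.astype(float)))
    return float(xbar_inf), final_size


# ---------------------------------------------------------------------------
# individual-level state distributions
# ---------------------------------------------------------------------------


def compositions(n: int, parts: int = 3) -> list[tuple[int, ...]]:
    """All k with nonnegative entries summing to n, lexicographic order."""
    if parts == 1:
        return [(n,)]
    out = []
    for k1 in range(n + 1):
        for rest in compositions(n - k1, parts - 1):
            out.append((k1, *rest))
    return out


@dataclass
class StateDistribution:
    """Probabilities of individual-level labels (d, k) with k summing to n."""

    probs: dict[tuple[str, tuple[int, ...]], float]

    def total(self, d: str | None = None) -> float:
        return float(
            sum(p for (dd, _k), p in self.probs.items() if d is None or dd == d)
        )


def _multinomial_coeff(k: tuple[int, ...]) -> float:
    num = factorial(sum(k))
    for ki in k:
        num //= factorial(ki)
    return float(num)


def ilevel_susceptible(x: np.ndarray, n: int) -> StateDistribution:
    """Multinomial i-level probabilities p_(-,k) = C(n;k) x1^k1 x2^k2 x3^k3."""
    x1, x2, x3 = (float(v) for v in x)
    probs = {}
    for k in compositions(n, 3):
        probs[("-", k)] = _multinomial_coeff(k) * x1 ** k[0] * x2 ** k[1] * x3 ** k[2]
    return StateDistribution(probs)


@dataclass
class PostSusceptibleState:
    """Binding-site probabilities after the owner's infection (case I).

    ``y``/``y_e`` are (3, J+1) arrays over conditioning times t_plus on the
    trajectory grid (states 1..3); ``z``/``z_e`` are (3, J+1, J+1) over
    (t_plus, t_star) pairs with t_plus <= t_star.  Entries outside the
    admissible triangle are zero.
    """

    t: float
    t_grid: np.ndarray
    y: np.ndarray
    y_e: np.ndarray
    z: np.ndarray
    z_e: np.ndarray
    dist_plus: StateDistribution
    dist_star: StateDistribution


def post_susceptible_distributions(
    traj: BindingSiteTrajectory, params: StaticParams, t: float
) -> PostSusceptibleState:
    """Reconstruct infectious/recovered i-level distributions at time t.

    The non-exceptional site systems under M+(Lambda+) and M*(Lambda*) are
    lower triangular, so they are solved by cumulative quadrature of the
    integrating-factor representation on the trajectory grid; the exceptional
    site has the closed form (0, e^{-gamma (t - t_+)}, 1 - e^{-gamma (t-t_+)}).
    """
    times = traj.times
    J = int(np.searchsorted(times, t + 1e-12) - 1)
    if J < 1 or t > times[-1] + 1e-9:
        raise ValueError("t outside trajectory grid")
    t = times[J]  # snap to grid
    n, beta, gamma = params.n, params.beta, params.gamma

    tg = times[: J + 1]
    x = traj.x[:, : J + 1]
    xbar = x.sum(axis=0)
    inc = traj.incidence[: J + 1]
    lam_plus = traj.lambda_plus[: J + 1]
    lam_star = traj.lambda_star[: J + 1]

    def _propagators(lam):
        G = np.concatenate([[0.0], cumulative_trapezoid(beta * lam, tg)])
        E = np.exp(-G)
        C = np.concatenate(
            [[0.0], cumulative_trapezoid(np.exp(gamma * tg) * beta * lam * E, tg)]
        )
        return G, C

    Gp, Cp = _propagators(lam_plus)
    Gs, Cs = _propagators(lam_star)

    yb = x / np.maximum(xbar, 1e-300)  # boundary y(t_+|t_+), shape (3, J+1)

    # non-exceptional infectious sites at time t for every t_+
    y1 = yb[0] * np.exp(-(Gp[J] - Gp))
    y2 = np.exp(-gamma * t) * (
        np.exp(gamma * tg) * yb[1] + yb[0] * np.exp(Gp) * (Cp[J] - Cp)
    )
    y3 = 1.0 - y1 - y2
    y = np.vstack([y1, y2, y3])
    ye2 = np.exp(-gamma * (t - tg))
    y_e = np.vstack([np.zeros(J + 1), ye2, 1.0 - ye2])

    # infectious individual distribution p_(+,k)(t)
    dist_plus: dict[tuple[str, tuple[int, ...]], float] = {}
    weight_plus = np.exp(-gamma * (t - tg)) * inc
    for k in compositions(n, 3):
        k1, k2, k3 = k
        coef = _multinomial_coeff(k)
        phi = np.zeros(J + 1)
        if k2 >= 1:
            phi += (k2 / n) * y_e[1] * y1**k1 * y2 ** (k2 - 1) * y3**k3
        if k3 >= 1:
            phi += (k3 / n) * y_e[2] * y1**k1 * y2**k2 * y3 ** (k3 - 1)
        dist_plus[("+", k)] = float(np.trapezoid(weight_plus * coef * phi, tg))

    # recovered sites: boundary at t_* (index m) from y(t_m | t_j)
    expGp = np.exp(Gp)
    y1_jm = yb[0][None, :] * np.exp(-(Gp[:, None] - Gp[None, :]))  # [m, j]
    y2_jm = np.exp(-gamma * tg)[:, None] * (
        np.exp(gamma * tg)[None, :] * yb[1][None, :]
        + yb[0][None, :] * expGp[None, :] * (Cp[:, None] - Cp[None, :])
    )
    tri = tg[:, None] >= tg[None, :] - 1e-15  # t_m >= t_j
    y1_jm = np.where(tri, y1_jm, 0.0)
    y2_jm = np.where(tri, y2_jm, 0.0)
    y3_jm = np.where(tri, 1.0 - y1_jm - y2_jm, 0.0)

    # evolve from t_m to t under Lambda_*
    decay1 = np.exp(-(Gs[J] - Gs))  # over m
    z1 = y1_jm * decay1[:, None]
    z2 = np.exp(-gamma * t) * (
        np.exp(gamma * tg)[:, None] * y2_jm
        + y1_jm * (np.exp(Gs) * (Cs[J] - Cs))[:, None]
    )
    z3 = np.where(tri, 1.0 - z1 - z2, 0.0)
    z = np.stack([z1, z2, z3])

    # exceptional recovered site: z_e = (0, e^{-gamma(t - t_j)}, ...) for t_j <= t_m
    ze2 = np.where(tri, np.exp(-gamma * (t - tg))[None, :] * np.ones((J + 1, 1)), 0.0)
    z_e = np.stack([np.zeros_like(ze2), ze2, np.where(tri, 1.0 - ze2, 0.0)])

    # double integral over t_j <= t_m <= t
    w_jm = np.where(tri, gamma * np.exp(-gamma * (tg[:, None] - tg[None, :])) * inc[None, :], 0.0)
    dist_star: dict[tuple[str, tuple[int, ...]], float] = {}
    for k in compositions(n, 3):
        k1, k2, k3 = k
        coef = _multinomial_coeff(k)
        psi = np.zeros((J + 1, J + 1))
        if k2 >= 1:
            psi += (k2 / n) * z_e[1] * z1**k1 * z2 ** (k2 - 1) * z3**k3
        if k3 >= 1:
            psi += (k3 / n) * z_e[2] * z1**k1 * z2**k2 * z3 ** (k3 - 1)
        inner = np.trapezoid(w_jm * coef * psi, tg, axis=1)  # over t_j
        dist_star[("*", k)] = float(np.trapezoid(inner, tg))  # over t_m

    return PostSusceptibleState(
        t=t,
        t_grid=tg,
        y=y,
        y_e=y_e,
        z=z,
        z_e=z_e,
        dist_plus=StateDistribution(dist_plus),
        dist_star=StateDistribution(dist_star),
    )


# ---------------------------------------------------------------------------
# phase-type closed system and the p-level ODE cross-check
# ---------------------------------------------------------------------------


@dataclass
class PhaseTypeClosedTrajectory:
    times: np.ndarray
    xbar: np.ndarray
    Q: np.ndarray  # shape (m, K)


def phase_type_closed_solve(
    spec: PhaseTypeSpec,
    degree: DegreeDistribution,
    eps: float = 1e-6,
    t_end: float = 40.0,
    dt: float = 0.01,
) -> PhaseTypeClosedTrajectory:
    """Closed ODE for the phase-type renewal equation.

    dQ/dt = (Sigma - diag beta) Q + g(xbar) V with xbar = F(inf) + beta . Q;
    the disease-free state is Q* = -(Sigma - diag beta)^{-1} V (xbar = 1) and
    the initial condition scales Q* so that xbar(0) = 1 - eps.
    """
    kern = phase_type_kernel(spec)
    g = _g_polynomial(degree)
    b = spec.beta_vec
    A = spec.Sigma - np.diag(b)
    V = spec.V
    Finf = kern.escape_limit
    Q_star = -np.linalg.solve(A, V)
    Q0 = Q_star * (1.0 - eps / (1.0 - Finf))

    def rhs(_t, Q):
        xbar = min(max(Finf + float(b @ Q), 0.0), 1.0)
        return A @ Q + g(xbar) * V

    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs, (0.0, t_end), Q0, method="LSODA", t_eval=times,
        rtol=_ODE_RTOL, atol=_ODE_ATOL,
    )
    xbar = np.clip(Finf + b @ sol.y, 0.0, 1.0)
    return PhaseTypeClosedTrajectory(times=sol.t, xbar=xbar, Q=sol.y)


def solve_plevel_susceptible(params: StaticParams):
    """Population-level ODE for the susceptible labels P_(-,k) (closed system).

    The environment Lambda- is computed from the P themselves,
    Lambda- = sum m2 m1 P_m / sum k1 P_k, so this solver is independent of the
    binding-site system and serves as a cross-check on the multinomial lift.
    Returns (times, list of k labels, P array of shape (len(labels), K)).
    """
    n, beta, gamma = params.n, params.beta, params.gamma
    labels = compositions(n, 3)
    index = {k: i for i, k in enumerate(labels)}
    x0 = np.array([1.0 - params.eps, params.eps, 0.0])
    P0 = np.array([ilevel_susceptible(x0, n).probs[("-", k)] for k in labels])

    m1 = np.array([k[0] for k in labels], dtype=float)
    m2 = np.array([k[1] for k in labels], dtype=float)

    def rhs(_t, P):
        denom = float(np.dot(m1, P))
        lam = float(np.dot(m2 * m1, P)) / denom if denom > 1e-300 else 0.0
        dP = np.zeros_like(P)
        for i, (k1, k2, k3) in enumerate(labels):
            dP[i] -= (beta * k2 + gamma * k2 + beta * lam * k1) * P[i]
            if k3 >= 1:
                dP[i] += gamma * (k2 + 1) * P[index[(k1, k2 + 1, k3 - 1)]]
            if k2 >= 1:
                dP[i] += beta * lam * (k1 + 1) * P[index[(k1 + 1, k2 - 1, k3)]]
        return dP

    times = np.arange(0.0, params.t_end + 0.5 * params.dt, params.dt)
    sol = solve_ivp(
        rhs, (0.0, params.t_end), P0, method="LSODA", t_eval=times,
        rtol=_ODE_RTOL, atol=_ODE_ATOL,
    )
    return sol.t, labels, sol.y


def summary_static(params: StaticParams) -> dict:
    """R0, r, xbar_inf and final size for a Markovian static-network epidemic."""
    kern = params.kernel()
    deg = params.degree()
    r = malthusian_static(kern, deg)
    xbar_inf, fs = final_size_static(kern, deg)
    return {
        "R0": r0_static(kern, deg),
        "r": r.value if r.status == "ok" else None,
        "r_status": r.status,
        "xbar_inf": xbar_inf,
        "final_size": fs,
    }
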