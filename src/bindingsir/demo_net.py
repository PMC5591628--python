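"""Case III: dynamic partnership network with demographic turnover.

Individuals die at rate mu and are replaced by partner-free newborns, so age
structure matters: the susceptible binding-site probabilities x(a | t_b) are
solved per birth cohort along characteristics, and the environmental
variables (Lambda_minus, F_minus, F_plus, F_star) are age averages against
the stationary age density mu e^{-mu a}.  The invasion threshold reduces to
a 2x2 next-generation kernel over the two birth-types of susceptible-
infectious links (type 0: pairing of free binding sites, age density pi0;
type 1: partner of an existing link got infected, age density pi1).  The
endemic steady state is the fixed point of a three-dimensional map
E = G(E) with E = (F_plus, F_star, Lambda_minus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .static_net import RootResult

__all__ = [
    "DemoParams",
    "AgeKernels",
    "NGMKernel",
    "EndemicState",
    "EnvTrajectoryDemo",
    "CohortField",
    "age_kernels",
    "ngm_kernel",
    "r0_demo",
    "malthusian_demo",
    "solve_demo_system",
    "endemic_fixed_point",
]

_XBAR_FLOOR = 1e-300


@dataclass(frozen=True)
class DemoParams:
    """Parameters of the demographic-turnover model."""

    beta: float
    gamma: float
    rho: float
    sigma: float
    mu: float
    n: int
    eps: float = 1e-6
    t_end: float = 100.0
    a_max: float | None = None
    da: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive (use dynamic_net for mu = 0)")
        if self.beta < 0 or self.gamma < 0 or self.rho < 0 or self.sigma < 0:
            raise ValueError("rates must be nonnegative")
        if self.n < 2:
            raise ValueError("partnership capacity n must be at least 2")
        if not 0.0 <= self.eps < 1.0:
            raise ValueError("eps must be in [0, 1)")
        if self.a_max is not None and np.exp(-self.mu * self.a_max) > 1e-4:
            raise ValueError(
                f"a_max={self.a_max} truncates too much mass: need "
                f"exp(-mu a_max) < 1e-4, i.e. a_max > {np.log(1e4) / self.mu:.3f}"
            )

    @property
    def age_cutoff(self) -> float:
        return self.a_max if self.a_max is not None else 10.0 / self.mu

    def age_step(self, F: float) -> float:
        if self.da is not None:
            return self.da
        rate = self.rho * F + self.sigma + self.mu + self.beta + self.gamma
        return min(0.01, 0.1 / rate)


def demo_free_fraction(rho: float, sigma: float, mu: float) -> float:
    """Stationary free fraction: positive root of rho F^2 + (sigma+2mu) F - (sigma+2mu) = 0."""
    s2 = sigma + 2.0 * mu
    if rho == 0:
        return 1.0
    return (-s2 + np.sqrt(s2 * s2 + 4.0 * rho * s2)) / (2.0 * rho)


@dataclass(frozen=True)
class AgeKernels:
    """Stationary partnership quantities of the demographic model.

    theta = rho F + sigma + mu, c_inf = (sigma+mu)/theta, c_rho = rho F/theta:
    phi0(a) = c_inf + c_rho e^{-theta a}, phi1(a) = c_inf (1 - e^{-theta a}),
    pi0(a) = mu e^{-mu a} phi0(a)/F, pi1(a) = mu e^{-mu a}(1-phi0(a))/(1-F).
    """

    F: float
    theta: float
    c_inf: float
    c_rho: float
    mu: float

    def phi0(self, a):
        a = np.asarray(a, dtype=float)
        out = self.c_inf + self.c_rho * np.exp(-self.theta * a)
        return float(out) if out.ndim == 0 else out

    def phi1(self, a):
        a = np.asarray(a, dtype=float)
        out = self.c_inf * (1.0 - np.exp(-self.theta * a))
        return float(out) if out.ndim == 0 else out

    def pi0(self, a):
        a = np.asarray(a, dtype=float)
        out = self.mu * np.exp(-self.mu * a) * (
            self.c_inf + self.c_rho * np.exp(-self.theta * a)
        ) / self.F
        return float(out) if out.ndim == 0 else out

    def pi1(self, a):
        a = np.asarray(a, dtype=float)
        out = self.mu * np.exp(-self.mu * a) * self.c_rho * (
            1.0 - np.exp(-self.theta * a)
        ) / (1.0 - self.F)
        return float(out) if out.ndim == 0 else out

    # exponential moments of the age densities against e^{-theta a}
    @property
    def A0(self) -> float:
        mu, th = self.mu, self.theta
        return (self.c_inf * mu / (mu + th) + self.c_rho * mu / (mu + 2 * th)) / self.F

    @property
    def A1(self) -> float:
        mu, th = self.mu, self.theta
        return self.c_rho * mu * th / ((mu + th) * (mu + 2 * th) * (1.0 - self.F))


def age_kernels(params: DemoParams) -> AgeKernels:
    F = demo_free_fraction(params.rho, params.sigma, params.mu)
    theta = params.rho * F + params.sigma + params.mu
    return AgeKernels(
        F=F,
        theta=theta,
        c_inf=(params.sigma + params.mu) / theta,
        c_rho=params.rho * F / theta,
        mu=params.mu,
    )


@dataclass
class NGMKernel:
    """2x2 next-generation kernel K(tau) over birth-types of -+ links.

    Index 0: links born by pairing of free binding sites (age density pi0);
    index 1: links born by infection of the partner of an existing link
    (age density pi1).  K is the scaled kernel; K_tilde the unscaled one
    acting on (F_plus_hat, Lambda_minus_hat), related by the similarity
    C K C^{-1} with C = diag(c0, c1), c0 = rho F n, c1 = beta n (1-F).
    """

    K: Callable[[float], np.ndarray]
    K_int: np.ndarray
    K_laplace: Callable[[float], np.ndarray]
    K_tilde: Callable[[float], np.ndarray]
    K_tilde_int: np.ndarray
    c0: float
    c1: float
    laplace_abscissa: float
    quadrature: Callable[[float], np.ndarray]


def ngm_kernel(params: DemoParams) -> NGMKernel:
    """Closed-form next-generation kernel; a quadrature evaluator is attached for testing.

    The kernel is derived from the pre-convolution linearized system: a -+
    link born at t - tau with the susceptible side of age alpha transmits
    after a further delay xi (density e^{-(sigma+2mu+beta+gamma) xi}); the
    type-0 row then accumulates re-pairings over the remaining infectious
    lifetime.  In the type-0 row the renewal delay is the *sum* of the
    transmission delay xi and the post-infection time, so the row is a
    convolution of the two exponentials (the printed product form carries
    the delay only in the second factor, which leaves the integrated kernel
    -- and hence R0 -- unchanged but would distort the Laplace transform).
    """
    ak = age_kernels(params)
    beta, gamma, rho, sigma, mu, n = (
        params.beta, params.gamma, params.rho, params.sigma, params.mu, params.n,
    )
    F, th, ci, cr = ak.F, ak.theta, ak.c_inf, ak.c_rho
    s = sigma + 2.0 * mu + beta + gamma
    d = mu + gamma
    A0, A1 = ak.A0, ak.A1

    def conv_exp(p, q, tau):
        # int_0^tau e^{-p xi} e^{-q (tau-xi)} dxi
        if abs(p - q) < 1e-12:
            return tau * np.exp(-p * tau)
        return (np.exp(-q * tau) - np.exp(-p * tau)) / (p - q)

    def row0(tau, A):
        # beta rho F int_0^tau e^{-s xi} e^{-d (tau-xi)}
        #   [phi1(tau-xi) + (n-1)(c_inf + c_rho A e^{-theta tau})] dxi
        const = ci + (n - 1) * (ci + cr * A * np.exp(-th * tau))
        return beta * rho * F * (
            const * conv_exp(s, d, tau) - ci * conv_exp(s, d + th, tau)
        )

    def row1(tau, A):
        return beta * (n - 1) * cr * np.exp(-s * tau) * (1.0 - A * np.exp(-th * tau))

    def K(tau):
        return np.array(
            [[row0(tau, A0), row0(tau, A1)], [row1(tau, A0), row1(tau, A1)]]
        )

    def K_laplace(lam):
        def hat0(A):
            return beta * rho * F * (
                ci * (1.0 / (lam + d) - 1.0 / (lam + d + th)) / (lam + s)
                + (n - 1) * (
                    ci / ((lam + s) * (lam + d))
                    + cr * A / ((lam + s + th) * (lam + d + th))
                )
            )

        def hat1(A):
            return beta * (n - 1) * cr * (1.0 / (lam + s) - A / (lam + s + th))

        return np.array([[hat0(A0), hat0(A1)], [hat1(A0), hat1(A1)]])

    c0 = rho * F * n
    c1 = beta * n * (1.0 - F)

    def K_tilde(tau):
        # built directly from the pre-scaling renewal equations for
        # (F_plus_hat, Lambda_minus_hat); similar to K under C = diag(c0, c1)
        def t0(coef, A):
            const = ci + (n - 1) * (ci + cr * A * np.exp(-th * tau))
            return coef * (const * conv_exp(s, d, tau) - ci * conv_exp(s, d + th, tau))

        def t1(coef, A):
            return coef * (n - 1) * cr * np.exp(-s * tau) * (1.0 - A * np.exp(-th * tau))

        return np.array(
            [
                [t0(beta * rho * F, A0), t0(beta * beta * (1.0 - F), A1)],
                [t1(rho * F / (1.0 - F), A0), t1(beta, A1)],
            ]
        )

    def quadrature(tau):
        # nested quadrature of the alpha- and xi-integrals (xi in [0, tau]
        # for the type-0 row: the renewal delay tau is xi plus the
        # post-infection time)
        from scipy.integrate import quad

        cut = 40.0 / min(mu, s, th)

        def inner0(pi):
            def ig(xi):
                val, _ = quad(
                    lambda al: pi(al) * ak.phi0(tau + al), 0.0, cut, limit=200
                )
                return (
                    np.exp(-s * xi)
                    * np.exp(-d * (tau - xi))
                    * (ak.phi1(tau - xi) + (n - 1) * val)
                )

            val, _ = quad(ig, 0.0, tau, limit=200)
            return beta * rho * F * val

        def inner1(pi):
            val, _ = quad(
                lambda al: pi(al) * (1.0 - ak.phi0(tau + al)), 0.0, cut, limit=200
            )
            return beta * (n - 1) * np.exp(-s * tau) * val

        return np.array(
            [[inner0(ak.pi0), inner0(ak.pi1)], [inner1(ak.pi0), inner1(ak.pi1)]]
        )

    return NGMKernel(
        K=K,
        K_int=K_laplace(0.0),
        K_laplace=K_laplace,
        K_tilde=K_tilde,
        K_tilde_int=np.array(
            [
                [K_laplace(0.0)[0, 0], K_laplace(0.0)[0, 1] * c0 / c1],
                [K_laplace(0.0)[1, 0] * c1 / c0, K_laplace(0.0)[1, 1]],
            ]
        ),
        c0=c0,
        c1=c1,
        laplace_abscissa=-d,
        quadrature=quadrature,
    )


def _dominant_eig_2x2(M: np.ndarray) -> float:
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    disc = tr * tr - 4.0 * det
    # nonnegative matrices: disc >= 0 by Perron-Frobenius
    return 0.5 * (tr + np.sqrt(max(disc, 0.0)))


def r0_demo(params: DemoParams) -> float:
    """Dominant eigenvalue of the integrated next-generation kernel."""
    return _dominant_eig_2x2(ngm_kernel(params).K_int)


def malthusian_demo(params: DemoParams) -> RootResult:
    """Real lambda at which the spectral radius of the Laplace-transformed kernel is 1."""
    ngm = ngm_kernel(params)
    f = lambda lam: _dominant_eig_2x2(ngm.K_laplace(lam)) - 1.0
    r0 = _dominant_eig_2x2(ngm.K_int)
    if abs(r0 - 1.0) < 1e-14:
        return RootResult(0.0)
    abscissa = ngm.laplace_abscissa
    if r0 > 1.0:
        hi = 1.0
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                return RootResult(np.nan, "no real root")
        return RootResult(brentq(f, 0.0, hi, xtol=1e-13))
    lo = abscissa + 0.75 * (0.0 - abscissa)
    while f(lo) < 0.0:
        lo = abscissa + 0.5 * (lo - abscissa)
        if lo - abscissa < 1e-13:
            return RootResult(np.nan, "no real root")
    return RootResult(brentq(f, lo, 0.0, xtol=1e-13))


@dataclass
class CohortField:
    """Per-age record of the susceptible binding-site probabilities at one time."""

    ages: np.ndarray
    x: np.ndarray          # shape (4, Na+1): x(a | t - a) by age
    J: np.ndarray          # shape (3, Na+1): exponential incidence accumulators


@dataclass
class EnvTrajectoryDemo:
    """Environmental variables of the demographic model on a time grid."""

    times: np.ndarray
    Lambda_minus: np.ndarray
    F_minus: np.ndarray
    F_plus: np.ndarray
    F_star: np.ndarray
    prevalence: np.ndarray
    incidence: np.ndarray
    F: float
    status: str = "ok"


def _age_weights(mu: float, ages: np.ndarray) -> np.ndarray:
    """Trapezoid weights for int_0^amax mu e^{-mu a} (.) da on the age grid."""
    w = np.full(ages.size, ages[1] - ages[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return w * mu * np.exp(-mu * ages)


def solve_demo_system(
    params: DemoParams,
) -> tuple[CohortField, EnvTrajectoryDemo]:
    """Method-of-characteristics solver on a shared age/time grid.

    Cohorts advance diagonally (age and time share one step), newborns enter
    partner-free; the F_plus memory integrals are carried per cohort by
    exponential accumulators (one-step recursions), so each time step costs
    O(number of ages).  The epidemic is seeded at t = 0 by transferring a
    fraction eps of each cohort's susceptible-partner probability to
    infectious-partner status.
    """
    ak = age_kernels(params)
    F = ak.F
    beta, gamma, rho, sigma, mu, n = (
        params.beta, params.gamma, params.rho, params.sigma, params.mu, params.n,
    )
    da = params.age_step(F)
    rate = rho * F + sigma + mu + beta + gamma
    if rate * da > 0.2:
        raise ValueError(
            f"age step too coarse: need da < {0.2 / rate:.5f}, got {da}"
        )
    a_max = params.age_cutoff
    Na = int(np.ceil(a_max / da))
    ages = np.arange(Na + 1) * da
    K = int(round(params.t_end / da))
    times = np.arange(K + 1) * da
    w = _age_weights(mu, ages)
    th = ak.theta
    ci = ak.c_inf

    # disease-free age profile, seeded with eps in x2
    phi0 = ak.phi0(ages)
    x = np.zeros((4, Na + 1))
    x[0] = phi0
    x[1] = (1.0 - params.eps) * (1.0 - phi0)
    x[2] = params.eps * (1.0 - phi0)
    # J rows: J_gamma[s1], J_{gamma+theta}[s1], J_{gamma+theta}[s2]
    J = np.zeros((3, Na + 1))
    decay = np.array([gamma, gamma + th, gamma + th])
    efac = np.exp(-decay * da)

    env = {
        "Lambda_minus": np.empty(K + 1),
        "F_minus": np.empty(K + 1),
        "F_plus": np.empty(K + 1),
        "F_star": np.empty(K + 1),
        "prevalence": np.empty(K + 1),
        "incidence": np.empty(K + 1),
    }

    def environments(x, J):
        xbar = x.sum(axis=0)
        xb1 = xbar ** (n - 1)
        xb2 = xbar ** (n - 2)
        den = float(w @ (x[1] * xb1))
        num = float(w @ (x[1] * x[2] * xb2))
        lam = (n - 1) * num / den if den > _XBAR_FLOOR else 0.0
        fmin = float(w @ (x[0] * xb1))
        h = beta * (n * ci * (J[0] - J[1]) + (n - 1) * J[2])
        fplus = float(w @ h)
        prev = float(w @ (beta * n * J[0]))
        inc = float(w @ (beta * n * x[2] * xb1))
        return lam, fmin, fplus, prev, inc

    def rhs(x, lam, fmin, fplus, fstar):
        xbar = x.sum(axis=0)
        dx = np.empty_like(x)
        dx[0] = -rho * F * x[0] + (sigma + mu) * (x[1] + x[2] + x[3])
        dx[1] = rho * fmin * x[0] - (beta * lam + sigma + mu) * x[1]
        dx[2] = rho * fplus * x[0] + beta * lam * x[1] - (beta + sigma + mu + gamma) * x[2]
        dx[3] = rho * fstar * x[0] + gamma * x[2] - (sigma + mu) * x[3]
        return dx

    def sources(x):
        xbar = x.sum(axis=0)
        s1 = x[2] * xbar ** (n - 1)
        s2 = x[0] * x[2] * xbar ** (n - 2)
        return s1, s2

    for k in range(K + 1):
        lam, fmin, fplus, prev, inc = environments(x, J)
        fstar = F - fmin - fplus
        env["Lambda_minus"][k] = lam
        env["F_minus"][k] = fmin
        env["F_plus"][k] = fplus
        env["F_star"][k] = fstar
        env["prevalence"][k] = prev
        env["incidence"][k] = inc
        if k == K:
            break
        # Heun step along characteristics with environment refreshed at the
        # predictor stage (second-order in the shared step)
        s1a, s2a = sources(x)
        Sa = np.vstack([s1a, s1a, s2a])
        dxa = rhs(x, lam, fmin, fplus, fstar)
        xp = x + da * dxa
        s1p, s2p = sources(xp)
        Jp = efac[:, None] * J + 0.5 * da * (
            efac[:, None] * Sa + np.vstack([s1p, s1p, s2p])
        )
        lam_p, fmin_p, fplus_p, _, _ = environments(xp, Jp)
        fstar_p = F - fmin_p - fplus_p
        dxb = rhs(xp, lam_p, fmin_p, fplus_p, fstar_p)
        x_new = x + 0.5 * da * (dxa + dxb)
        s1b, s2b = sources(x_new)
        J_new = efac[:, None] * J + 0.5 * da * (
            efac[:, None] * Sa + np.vstack([s1b, s1b, s2b])
        )
        # age shift: cohorts move up one grid slot; a newborn enters at age 0
        x[:, 1:] = x_new[:, :-1]
        x[:, 0] = (1.0, 0.0, 0.0, 0.0)
        J[:, 1:] = J_new[:, :-1]
        J[:, 0] = 0.0

    traj = EnvTrajectoryDemo(
        times=times,
        Lambda_minus=env["Lambda_minus"],
        F_minus=env["F_minus"],
        F_plus=env["F_plus"],
        F_star=env["F_star"],
        prevalence=env["prevalence"],
        incidence=env["incidence"],
        F=F,
    )
    return CohortField(ages=ages, x=x, J=J), traj


@dataclass
class EndemicState:
    """Constant environmental vector E = (F_plus, F_star, Lambda_minus)."""

    F_plus: float
    F_star: float
    Lambda_minus: float
    residual: float
    converged: bool
    iterations: int

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.F_plus, self.F_star, self.Lambda_minus])


def _G_map(params: DemoParams, ak: AgeKernels, E: np.ndarray) -> np.ndarray:
    """Evaluate G(E) by one high-accuracy age integration at constant environment."""
    beta, gamma, rho, sigma, mu, n = (
        params.beta, params.gamma, params.rho, params.sigma, params.mu, params.n,
    )
    F, th, ci = ak.F, ak.theta, ak.c_inf
    fplus, fstar, lam = E
    fmin = F - fplus - fstar

    def rhs(a, u):
        x0, x1, x2, x3, j0, j1, j2, o1, o2, o3n, o3d = u
        xbar = x0 + x1 + x2 + x3
        xb1 = xbar ** (n - 1)
        xb2 = xbar ** (n - 2)
        s1 = x2 * xb1
        s2 = x0 * x2 * xb2
        h = beta * (n * ci * (j0 - j1) + (n - 1) * j2)
        wgt = mu * np.exp(-mu * a)
        return [
            -rho * F * x0 + (sigma + mu) * (x1 + x2 + x3),
            rho * fmin * x0 - (beta * lam + sigma + mu) * x1,
            rho * fplus * x0 + beta * lam * x1 - (beta + sigma + mu + gamma) * x2,
            rho * fstar * x0 + gamma * x2 - (sigma + mu) * x3,
            -gamma * j0 + s1,
            -(gamma + th) * j1 + s1,
            -(gamma + th) * j2 + s2,
            wgt * h,
            wgt * x0 * xb1,
            wgt * x1 * x2 * xb2,
            wgt * x1 * xb1,
        ]

    a_cap = max(params.age_cutoff, 30.0 / mu)
    u0 = [1.0] + [0.0] * 10
    sol = solve_ivp(
        rhs, (0.0, a_cap), u0, method="LSODA", rtol=1e-12, atol=1e-14,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"endemic age integration failed: {sol.message}")
    o1, o2, o3n, o3d = sol.y[7:, -1]
    G1 = o1
    G2 = F - o2 - G1
    G3 = (n - 1) * o3n / o3d if o3d > _XBAR_FLOOR else 0.0
    return np.array([G1, G2, G3])


def _project_admissible(E: np.ndarray, F: float, n: int) -> np.ndarray:
    fp = min(max(E[0], 0.0), F)
    fs = min(max(E[1], 0.0), F - fp)
    lam = min(max(E[2], 0.0), float(n - 1))
    return np.array([fp, fs, lam])


def endemic_fixed_point(
    params: DemoParams,
    start: np.ndarray | None = None,
    omega: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> EndemicState:
    """Damped fixed-point iteration E <- (1-omega) E + omega G(E).

    Starts from a small supercritical heuristic unless a start is given;
    iterates are projected to the admissible set F_plus, F_star >= 0,
    F_plus + F_star <= F, 0 <= Lambda_minus <= n-1.
    """
    ak = age_kernels(params)
    F, n = ak.F, params.n
    if start is None:
        E = np.array([0.01 * F, 0.01 * F, 0.01 * (n - 1)])
    else:
        E = _project_admissible(np.asarray(start, dtype=float), F, n)
    res = np.inf
    for it in range(1, max_iter + 1):
        G = _G_map(params, ak, E)
        res = float(np.max(np.abs(E - G)))
        if res < tol:
            return EndemicState(E[0], E[1], E[2], res, True, it)
        E = _project_admissible((1.0 - omega) * E + omega * G, F, n)
    return EndemicState(E[0], E[1], E[2], res, False, max_iter)
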