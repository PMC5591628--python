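"""Case II: SIR on a dynamic partnership network without demography.

Partnerships form and dissolve while the epidemic runs: a free binding site
becomes occupied at rate rho*F (F the stationary fraction of free binding
sites) and an occupied one becomes free at rate sigma.  The susceptible
binding-site probabilities x = (x0, x1, x2, x3) (free / susceptible partner /
infectious partner / recovered partner) together with the fraction I of
infectious binding sites and the fraction F_plus of free infectious binding
sites form a closed six-dimensional ODE system.  The same dynamics can be
written as a delay system in which F_plus is an explicit integral over the
incidence history; both forms are implemented and cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .static_net import RootResult

__all__ = [
    "DynamicParams",
    "DynamicTrajectory",
    "free_fraction_dynamic",
    "phi1_dynamic",
    "solve_dynamic_closed",
    "fplus_history_check",
    "prevalence_history_check",
    "r0_dynamic",
    "malthusian_dynamic",
    "final_size_dynamic",
]

_XBAR_FLOOR = 1e-300


@dataclass(frozen=True)
class DynamicParams:
    """Parameters of the dynamic-network SIR model."""

    beta: float
    gamma: float
    rho: float
    sigma: float
    n: int
    eps: float = 1e-6
    t_end: float = 40.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")
        if self.rho < 0 or self.sigma < 0:
            raise ValueError("rho and sigma must be nonnegative")
        if self.rho > 0 and self.sigma == 0:
            # sites that pair never separate: F = 0, no new partnerships form;
            # allowed, handled by free_fraction_dynamic
            pass
        if self.n < 2:
            raise ValueError("partnership capacity n must be at least 2")
        if not 0.0 <= self.eps < 1.0:
            raise ValueError("eps must be in [0, 1)")

    @property
    def F(self) -> float:
        return free_fraction_dynamic(self.rho, self.sigma)


def free_fraction_dynamic(rho: float, sigma: float) -> float:
    """Stationary fraction F of free binding sites: root of rho F^2 + sigma F - sigma = 0."""
    if rho < 0 or sigma < 0:
        raise ValueError("rho and sigma must be nonnegative")
    if rho == 0 and sigma == 0:
        raise ValueError("degenerate partnership process: rho = sigma = 0")
    if rho == 0:
        return 1.0
    if sigma == 0:
        return 0.0
    # positive root of rho F^2 + sigma F - sigma = 0
    return (-sigma + np.sqrt(sigma * sigma + 4.0 * rho * sigma)) / (2.0 * rho)


def phi1_dynamic(xi, rho: float, sigma: float):
    """Probability a binding site occupied at time 0 is free at time xi."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("xi must be nonnegative")
    F = free_fraction_dynamic(rho, sigma)
    theta = rho * F + sigma
    out = F * (1.0 - np.exp(-theta * xi))
    return float(out) if out.ndim == 0 else out


@dataclass
class DynamicTrajectory:
    """Output of solve_dynamic_closed on a uniform time grid."""

    times: np.ndarray
    x: np.ndarray        # shape (4, K): x0, x1, x2, x3
    I: np.ndarray        # fraction of infectious binding sites
    F_plus: np.ndarray   # fraction of free infectious binding sites
    F: float             # stationary free fraction
    status: str = "ok"

    @property
    def xbar(self) -> np.ndarray:
        return self.x.sum(axis=0)

    @property
    def F_minus(self) -> np.ndarray:
        n = self._n
        return self.x[0] * self.xbar ** (n - 1)

    @property
    def F_star(self) -> np.ndarray:
        return self.F - self.F_minus - self.F_plus

    @property
    def s_frac(self) -> np.ndarray:
        return self.xbar ** self._n

    @property
    def incidence(self) -> np.ndarray:
        return self._beta * self._n * self.x[2] * self.xbar ** (self._n - 1)

    @property
    def lambda_minus(self) -> np.ndarray:
        xb = np.maximum(self.xbar, _XBAR_FLOOR)
        return (self._n - 1) * self.x[2] / xb

    # set by the solver
    _n: int = 3
    _beta: float = 0.0


def _dynamic_rhs(params: DynamicParams, F: float):
    beta, gamma, rho, sigma, n = (
        params.beta,
        params.gamma,
        params.rho,
        params.sigma,
        params.n,
    )

    def rhs(t, u):
        x0, x1, x2, x3, I, Fp = u
        xbar = x0 + x1 + x2 + x3
        ratio = 0.0 if x2 < _XBAR_FLOOR or xbar < _XBAR_FLOOR else x2 / xbar
        xbar_nm1 = xbar ** (n - 1)
        xbar_nm2 = xbar ** (n - 2)
        F_minus = x0 * xbar_nm1
        F_star = F - F_minus - Fp
        dx0 = -rho * F * x0 + sigma * (x1 + x2 + x3)
        dx1 = rho * x0 * x0 * xbar_nm1 - (sigma + beta * (n - 1) * ratio) * x1
        dx2 = (
            rho * Fp * x0
            + beta * (n - 1) * ratio * x1
            - (sigma + beta + gamma) * x2
        )
        dx3 = rho * F_star * x0 + gamma * x2 - sigma * x3
        dI = beta * n * x2 * xbar_nm1 - gamma * I
        dFp = (
            beta * (n - 1) * x0 * x2 * xbar_nm2
            - (rho * F + gamma) * Fp
            + sigma * (I - Fp)
        )
        return [dx0, dx1, dx2, dx3, dI, dFp]

    return rhs


def solve_dynamic_closed(params: DynamicParams) -> DynamicTrajectory:
    """Integrate the closed six-ODE system (x0..x3, I, F_plus).

    Initial state: the disease-free partnership equilibrium with a fraction
    eps of binding sites moved from susceptible-partner to infectious-partner
    status; newly infected binding sites are free with probability F, so
    F_plus(0) = F * eps and I(0) = eps.
    """
    F = params.F
    eps = params.eps
    u0 = [F, 1.0 - F - eps, eps, 0.0, eps, F * eps]
    K = int(round(params.t_end / params.dt))
    times = np.arange(K + 1) * params.dt
    sol = solve_ivp(
        _dynamic_rhs(params, F),
        (0.0, params.t_end),
        u0,
        method="LSODA",
        t_eval=times,
        rtol=1e-10,
        atol=1e-12,
    )
    status = "ok" if sol.success else f"solver failed: {sol.message}"
    traj = DynamicTrajectory(
        times=sol.t,
        x=sol.y[:4],
        I=sol.y[4],
        F_plus=sol.y[5],
        F=F,
        status=status,
    )
    traj._n = params.n
    traj._beta = params.beta
    return traj


def fplus_history_check(
    traj: DynamicTrajectory, params: DynamicParams, t: float
) -> float:
    """Evaluate F_plus(t) from the incidence history by trapezoid quadrature.

    F_plus(t) = eps F e^{-gamma t}  (initial infectious cohort, free fraction F)
              + int_0^t e^{-gamma (t-s)} beta x2 xbar^{n-1}(s)
                    { n phi1(t-s) + (n-1) (x0/xbar)(s) e^{-(rho F + sigma)(t-s)} } ds
    """
    F = traj.F
    n, beta, gamma = params.n, params.beta, params.gamma
    theta = params.rho * F + params.sigma
    j = int(round(t / params.dt))
    if abs(traj.times[j] - t) > 1e-9:
        raise ValueError(f"t={t} not on the trajectory grid")
    ts = traj.times[: j + 1]
    tau = t - ts
    xbar = traj.xbar[: j + 1]
    x2 = traj.x[2, : j + 1]
    x0 = traj.x[0, : j + 1]
    ratio0 = np.where(xbar > _XBAR_FLOOR, x0 / np.maximum(xbar, _XBAR_FLOOR), 0.0)
    phi1 = F * (1.0 - np.exp(-theta * tau))
    integrand = (
        np.exp(-gamma * tau)
        * beta
        * x2
        * xbar ** (n - 1)
        * (n * phi1 + (n - 1) * ratio0 * np.exp(-theta * tau))
    )
    boundary = params.eps * F * np.exp(-gamma * t)
    if j == 0:
        return boundary
    return boundary + float(np.trapezoid(integrand, ts))


def prevalence_history_check(
    traj: DynamicTrajectory, params: DynamicParams, t: float
) -> float:
    """Evaluate I(t) = eps e^{-gamma t} + int_0^t e^{-gamma(t-s)} beta n x2 xbar^{n-1}(s) ds."""
    n, beta, gamma = params.n, params.beta, params.gamma
    j = int(round(t / params.dt))
    if abs(traj.times[j] - t) > 1e-9:
        raise ValueError(f"t={t} not on the trajectory grid")
    ts = traj.times[: j + 1]
    tau = t - ts
    integrand = (
        np.exp(-gamma * tau)
        * beta
        * n
        * traj.x[2, : j + 1]
        * traj.xbar[: j + 1] ** (n - 1)
    )
    boundary = params.eps * np.exp(-gamma * t)
    if j == 0:
        return boundary
    return boundary + float(np.trapezoid(integrand, ts))


def _kernel_laplace_dynamic(params: DynamicParams, lam: float) -> float:
    """Laplace transform of the linearized-invasion kernel k(xi), closed form.

    k has a factor e^{-(sigma+beta+gamma) xi} (waiting to transmit along a
    -+ link) convolved with e^{-gamma tau} rho F (phi1(tau) + (n-1) F)
    (free-site re-occupation while infectious), plus the direct term
    (n-1)(1-F) at transmission.
    """
    beta, gamma, sigma, rho, n = (
        params.beta,
        params.gamma,
        params.sigma,
        params.rho,
        params.n,
    )
    F = params.F
    theta = rho * F + sigma
    pref = beta / (lam + sigma + beta + gamma)
    # int e^{-(lam+gamma) tau} phi1(tau) dtau = F (1/(lam+gamma) - 1/(lam+gamma+theta))
    phi1_hat = F * (1.0 / (lam + gamma) - 1.0 / (lam + gamma + theta))
    inner = rho * F * (phi1_hat + (n - 1) * F / (lam + gamma))
    return pref * ((n - 1) * (1.0 - F) + inner)


def r0_dynamic(params: DynamicParams) -> float:
    """R0 for case II, closed form of the integrated kernel (lambda = 0)."""
    return _kernel_laplace_dynamic(params, 0.0)


def malthusian_dynamic(params: DynamicParams) -> RootResult:
    """Unique real root of 1 = int e^{-lam xi} k(xi) d xi (Malthusian parameter)."""
    gamma = params.gamma
    abscissa = -gamma  # rightmost singularity of the Laplace transform
    f = lambda lam: _kernel_laplace_dynamic(params, lam) - 1.0
    r0 = r0_dynamic(params)
    if abs(r0 - 1.0) < 1e-14:
        return RootResult(0.0)
    if r0 > 1.0:
        lo, hi = 0.0, 1.0
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                return RootResult(np.nan, "no real root")
        return RootResult(brentq(f, lo, hi, xtol=1e-13))
    # subcritical: search in (abscissa, 0)
    hi = 0.0
    lo = abscissa + 0.75 * (0.0 - abscissa)
    while f(lo) < 0.0:
        lo = abscissa + 0.5 * (lo - abscissa)
        if lo - abscissa < 1e-13:
            return RootResult(np.nan, "no real root")
    return RootResult(brentq(f, lo, hi, xtol=1e-13))


def final_size_dynamic(params: DynamicParams) -> RootResult:
    """Final size 1 - xbar(inf)^n by integrating the closed system to quiescence.

    No scalar final-size equation is available in case II; the trajectory is
    integrated until max|RHS| < 1e-12 sustained over 10 output steps (or
    t_end, in which case a warning status is set).
    """
    from dataclasses import replace

    F = params.F
    rhs = _dynamic_rhs(params, F)
    t_end = params.t_end
    t_cap = max(64.0 * params.t_end, 4000.0)
    while True:
        traj = solve_dynamic_closed(replace(params, t_end=t_end))
        quiet = 0
        t_quiet = None
        for j in range(traj.times.size):
            u = [
                traj.x[0, j], traj.x[1, j], traj.x[2, j], traj.x[3, j],
                traj.I[j], traj.F_plus[j],
            ]
            if max(abs(v) for v in rhs(traj.times[j], u)) < 1e-12:
                quiet += 1
                if quiet >= 10:
                    t_quiet = traj.times[j]
                    break
            else:
                quiet = 0
        if t_quiet is not None:
            xbar_end = float(traj.xbar[int(round(t_quiet / params.dt))])
            return RootResult(1.0 - xbar_end ** params.n)
        if 2.0 * t_end > t_cap:
            return RootResult(
                1.0 - float(traj.xbar[-1]) ** params.n,
                "warning: not quiescent at t_end",
            )
        t_end *= 2.0
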