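"""Degree distributions and infectiousness (escape) kernels.

The escape kernel ``F(tau)`` is the probability that a susceptible partner
of an individual infected ``tau`` time units ago has not (yet) received
infection across that partnership.  It is the single disease ingredient
needed by the renewal-equation formulation of an SIR-type epidemic on a
configuration network: Markovian SIR, phase-type (SEIR and friends) and
user-supplied kernels are all handled through the same interface.

The degree distribution enters only through the size-biased generating
function ``g(x) = sum_n n p_n x^(n-1) / sum_m m p_m`` and its derivative
at one, ``g'(1) = E[n(n-1)] / E[n]`` (the mean excess degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DegreeDistribution",
    "MarkovianSIRSpec",
    "PhaseTypeSpec",
    "InfectiousnessKernel",
    "markovian_kernel",
    "phase_type_kernel",
    "escape_probability",
    "degree_generating",
    "gprime_at_one",
]

_PMF_TOL = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """Finite-support distribution of the partnership capacity ``n``.

    Infinite-support distributions must be truncated by the caller so that
    the discarded mass is below 1e-12; the pmf is then renormalised here.
    """

    pmf: dict[int, float]

    def __post_init__(self) -> None:
        if not self.pmf:
            raise ValueError("degree pmf is empty")
        cleaned = {}
        for n, p in self.pmf.items():
            n = int(n)
            p = float(p)
            if n < 0:
                raise ValueError(f"negative degree {n}")
            if p < -_PMF_TOL:
                raise ValueError(f"negative probability for degree {n}")
            if p > 0.0:
                cleaned[n] = p
        total = sum(cleaned.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"degree pmf sums to {total}, not 1")
        object.__setattr__(
            self, "pmf", {n: p / total for n, p in sorted(cleaned.items())}
        )
        if self.mean_degree() <= 0.0:
            raise ValueError("mean degree must be positive")

    @classmethod
    def uniform(cls, n: int) -> "DegreeDistribution":
        """Every individual has exactly ``n`` binding sites."""
        return cls({int(n): 1.0})

    def degrees(self) -> np.ndarray:
        return np.array(sorted(self.pmf), dtype=int)

    def probabilities(self) -> np.ndarray:
        return np.array([self.pmf[n] for n in sorted(self.pmf)])

    def mean_degree(self) -> float:
        return float(sum(n * p for n, p in self.pmf.items()))

    def to_config(self) -> dict:
        if len(self.pmf) == 1:
            (n,) = self.pmf
            return {"type": "uniform", "n": n}
        return {"type": "pmf", "pmf": {str(n): p for n, p in self.pmf.items()}}

    @classmethod
    def from_config(cls, cfg: dict) -> "DegreeDistribution":
        kind = cfg.get("type", "uniform")
        if kind == "uniform":
            return cls.uniform(int(cfg["n"]))
        if kind == "pmf":
            return cls({int(n): float(p) for n, p in cfg["pmf"].items()})
        raise ValueError(f"unknown degree type {kind!r}")


def degree_generating(dist: DegreeDistribution, x: float) -> float:
    """Size-biased generating function g(x) = sum n p_n x^(n-1) / sum m p_m."""
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x={x} outside [0, 1]")
    ns = dist.degrees()
    ps = dist.probabilities()
    mean = float(np.dot(ns, ps))
    with np.errstate(invalid="ignore"):
        terms = ns * ps * np.where(ns >= 1, float(x) ** np.maximum(ns - 1, 0), 0.0)
    # degree-0 individuals contribute no edges
    terms = np.where(ns == 0, 0.0, terms)
    return float(terms.sum() / mean)


def gprime_at_one(dist: DegreeDistribution) -> float:
    """Mean excess degree g'(1) = E[n(n-1)] / E[n]."""
    ns = dist.degrees()
    ps = dist.probabilities()
    mean = float(np.dot(ns, ps))
    return float(np.dot(ns * (ns - 1), ps) / mean)


@dataclass(frozen=True)
class MarkovianSIRSpec:
    """Markovian SIR: transmission at rate beta, recovery at rate gamma."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass(frozen=True)
class PhaseTypeSpec:
    """Phase-type infectiousness: m stages, per-stage transmission rates.

    ``Sigma`` is a positive-off-diagonal m x m stage-transition matrix,
    ``beta_vec`` the per-stage transmission rates, ``V`` the (sub)probability
    distribution over the initial stage.  The escape kernel is

        F(tau) = 1 - int_0^tau beta . exp(eta (Sigma - diag beta)) V d eta.
    """

    beta_vec: np.ndarray
    Sigma: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.beta_vec, dtype=float))
        S = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        v = np.atleast_1d(np.asarray(self.V, dtype=float))
        m = b.size
        if S.shape != (m, m) or v.size != m:
            raise ValueError("inconsistent phase-type dimensions")
        if np.any(b < 0) or np.any(v < 0):
            raise ValueError("beta_vec and V must be nonnegative")
        off = S - np.diag(np.diag(S))
        if np.any(off < 0):
            raise ValueError("Sigma must have nonnegative off-diagonal entries")
        A = S - np.diag(b)
        if np.max(np.linalg.eigvals(A).real) >= 0:
            raise ValueError("kernel limit undefined: Sigma - diag(beta) not stable")
        object.__setattr__(self, "beta_vec", b)
        object.__setattr__(self, "Sigma", S)
        object.__setattr__(self, "V", v)

    @property
    def m(self) -> int:
        return self.beta_vec.size


@dataclass
class InfectiousnessKernel:
    """Escape kernel F(tau): F(0) = 1, nonincreasing, limit F(infty) >= 0.

    ``escape_deriv_laplace(lam)`` returns int_0^infty e^{-lam tau}(-F'(tau)) dtau
    (the Laplace transform of the infection-time density along a partnership);
    ``laplace_abscissa`` is the infimum of lam for which it is finite.
    """

    escape: Callable[[np.ndarray], np.ndarray]
    escape_deriv: Callable[[np.ndarray], np.ndarray]
    escape_limit: float
    escape_deriv_laplace: Callable[[float], float]
    laplace_abscissa: float
    config: dict = field(default_factory=dict)

    def __call__(self, tau):
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < 0):
            raise ValueError("tau must be nonnegative")
        return self.escape(tau)


def escape_probability(kernel: InfectiousnessKernel, tau: float) -> float:
    """Probability a susceptible partner escapes infection up to age tau."""
    return float(kernel(float(tau)))


def markovian_kernel(spec: MarkovianSIRSpec) -> InfectiousnessKernel:
    """F(tau) = gamma/(beta+gamma) + beta/(beta+gamma) e^{-(beta+gamma) tau}."""
    beta, gamma = spec.beta, spec.gamma
    rate = beta + gamma
    limit = gamma / rate

    def escape(tau):
        return limit + (beta / rate) * np.exp(-rate * tau)

    def escape_deriv(tau):
        return -beta * np.exp(-rate * tau)

    def deriv_laplace(lam: float) -> float:
        return beta / (lam + rate)

    return InfectiousnessKernel(
        escape=escape,
        escape_deriv=escape_deriv,
        escape_limit=limit,
        escape_deriv_laplace=deriv_laplace,
        laplace_abscissa=-rate,
        config={"type": "markovian", "beta": beta, "gamma": gamma},
    )


def phase_type_kernel(spec: PhaseTypeSpec) -> InfectiousnessKernel:
    """Build the escape kernel of a phase-type infectiousness model.

    All evaluations use exact matrix exponentials; the limit F(infty) is the
    closed form 1 - beta . (diag beta - Sigma)^{-1} V, never a large-tau
    evaluation.
    """
    b, S, v = spec.beta_vec, spec.Sigma, spec.V
    A = S - np.diag(b)
    Ainv_v = np.linalg.solve(A, v)
    limit = float(1.0 + b @ Ainv_v)  # = 1 - b . (diag b - Sigma)^{-1} V
    if limit < -1e-12:
        raise ValueError("kernel limit undefined")
    abscissa = float(np.max(np.linalg.eigvals(A).real))

    def escape(tau):
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        # F(tau) = 1 - b . A^{-1} (e^{tau A} - I) V
        out = np.array([1.0 - b @ (expm(t * A) @ Ainv_v - Ainv_v) for t in tau])
        return out if out.size > 1 else float(out[0])

    def escape_deriv(tau):
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        out = np.array([-(b @ (expm(t * A) @ v)) for t in tau])
        return out if out.size > 1 else float(out[0])

    def deriv_laplace(lam: float) -> float:
        # int e^{-lam tau} b . e^{tau A} V dtau = b . (lam I - A)^{-1} V
        m = b.size
        return float(b @ np.linalg.solve(lam * np.eye(m) - A, v))

    return InfectiousnessKernel(
        escape=escape,
        escape_deriv=escape_deriv,
        escape_limit=limit,
        escape_deriv_laplace=deriv_laplace,
        laplace_abscissa=abscissa,
        config={
            "type": "phase_type",
            "m": spec.m,
            "beta_vec": b.tolist(),
            "Sigma": S.reshape(-1).tolist(),
            "V": v.tolist(),
        },
    )


def kernel_from_config(cfg: dict) -> InfectiousnessKernel:
    kind = cfg.get("type", "markovian")
    if kind == "markovian":
        return markovian_kernel(MarkovianSIRSpec(float(cfg["beta"]), float(cfg["gamma"])))
    if kind == "phase_type":
        m = int(cfg["m"])
        return phase_type_kernel(
            PhaseTypeSpec(
                beta_vec=np.asarray(cfg["beta_vec"], dtype=float),
                Sigma=np.asarray(cfg["Sigma"], dtype=float).reshape(m, m),
                V=np.asarray(cfg["V"], dtype=float),
            )
        )
    raise ValueError(f"unknown kernel type {kind!r}")
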