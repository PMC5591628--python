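"""Unit and property tests for degree distributions and escape kernels."""

import numpy as np
import pytest
from scipy.integrate import quad

from bindingsir.kernels import (
    DegreeDistribution,
    InfectiousnessKernel,
    MarkovianSIRSpec,
    PhaseTypeSpec,
    degree_generating,
    escape_probability,
    gprime_at_one,
    kernel_from_config,
    markovian_kernel,
    phase_type_kernel,
)


class TestDegreeDistribution:
    def test_uniform_moments(self):
        deg = DegreeDistribution.uniform(3)
        assert deg.mean_degree() == 3.0
        assert gprime_at_one(deg) == pytest.approx(2.0, abs=1e-14)

    def test_generating_function_endpoints(self):
        deg = DegreeDistribution({1: 0.2, 2: 0.3, 4: 0.5})
        assert degree_generating(deg, 1.0) == pytest.approx(1.0, abs=1e-14)
        # g(x) = sum n p_n x^(n-1) / mean: hand evaluation at x = 0.5
        mean = 0.2 * 1 + 0.3 * 2 + 0.5 * 4
        expect = (0.2 * 1 * 1.0 + 0.3 * 2 * 0.5 + 0.5 * 4 * 0.125) / mean
        assert degree_generating(deg, 0.5) == pytest.approx(expect, rel=1e-14)

    def test_excess_degree(self):
        deg = DegreeDistribution({1: 0.5, 3: 0.5})
        # E[n(n-1)]/E[n] = (0.5*0 + 0.5*6)/2 = 1.5
        assert gprime_at_one(deg) == pytest.approx(1.5, rel=1e-14)

    def test_rejects_bad_pmf(self):
        with pytest.raises(ValueError):
            DegreeDistribution({2: 0.6, 3: 0.6})
        with pytest.raises(ValueError):
            DegreeDistribution({-1: 1.0})
        with pytest.raises(ValueError):
            DegreeDistribution({})
        with pytest.raises(ValueError):
            DegreeDistribution({0: 1.0})  # mean degree zero

    def test_config_round_trip(self):
        deg = DegreeDistribution({2: 0.25, 3: 0.75})
        back = DegreeDistribution.from_config(deg.to_config())
        assert back.pmf == deg.pmf


class TestMarkovianKernel:
    def test_escape_closed_form(self):
        beta, gamma = 2.0, 1.0
        kern = markovian_kernel(MarkovianSIRSpec(beta, gamma))
        tau = np.linspace(0.0, 10.0, 101)
        expect = gamma / (beta + gamma) + beta / (beta + gamma) * np.exp(
            -(beta + gamma) * tau
        )
        np.testing.assert_allclose(kern(tau), expect, rtol=1e-14)
        assert kern.escape_limit == pytest.approx(gamma / (beta + gamma), rel=1e-14)
        assert escape_probability(kern, 0.0) == pytest.approx(1.0, abs=1e-14)

    def test_deriv_laplace_matches_quadrature(self):
        kern = markovian_kernel(MarkovianSIRSpec(1.7, 0.6))
        for lam in (0.0, 0.5, 2.0, -0.3):
            num, _ = quad(lambda t: -kern.escape_deriv(t) * np.exp(-lam * t), 0, np.inf)
            assert kern.escape_deriv_laplace(lam) == pytest.approx(num, rel=1e-10)

    def test_monotone_nonincreasing(self):
        kern = markovian_kernel(MarkovianSIRSpec(3.0, 0.2))
        tau = np.linspace(0.0, 20.0, 401)
        vals = kern(tau)
        assert np.all(np.diff(vals) <= 1e-15)
        assert np.all(kern.escape_deriv(tau) <= 0.0)

    def test_negative_tau_rejected(self):
        kern = markovian_kernel(MarkovianSIRSpec(1.0, 1.0))
        with pytest.raises(ValueError):
            kern(-0.1)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MarkovianSIRSpec(0.0, 1.0)
        with pytest.raises(ValueError):
            MarkovianSIRSpec(1.0, -0.5)


class TestPhaseTypeKernel:
    def test_single_stage_reduces_to_markovian(self):
        beta, gamma = 2.0, 1.0
        pt = phase_type_kernel(
            PhaseTypeSpec(beta_vec=[beta], Sigma=[[-gamma]], V=[1.0])
        )
        mk = markovian_kernel(MarkovianSIRSpec(beta, gamma))
        tau = np.linspace(0.0, 15.0, 151)
        np.testing.assert_allclose(pt(tau), mk(tau), rtol=1e-12, atol=1e-14)
        assert pt.escape_limit == pytest.approx(mk.escape_limit, rel=1e-12)
        for lam in (0.0, 0.7, -0.2):
            assert pt.escape_deriv_laplace(lam) == pytest.approx(
                mk.escape_deriv_laplace(lam), rel=1e-12
            )

    def test_seir_two_stage_properties(self):
        # latent stage with no transmission, then infectious stage
        nu, beta, gamma = 1.5, 2.0, 1.0
        spec = PhaseTypeSpec(
            beta_vec=[0.0, beta],
            Sigma=[[-nu, 0.0], [nu, -gamma]],
            V=[1.0, 0.0],
        )
        kern = phase_type_kernel(spec)
        tau = np.linspace(0.0, 30.0, 301)
        vals = kern(tau)
        assert vals[0] == pytest.approx(1.0, abs=1e-13)
        assert np.all(np.diff(vals) <= 1e-14)
        # escape limit by quadrature of the density
        num, _ = quad(lambda t: -kern.escape_deriv(t), 0, np.inf, limit=200)
        assert 1.0 - kern.escape_limit == pytest.approx(num, rel=1e-9)

    def test_unstable_spec_rejected(self):
        with pytest.raises(ValueError):
            PhaseTypeSpec(beta_vec=[0.0], Sigma=[[0.0]], V=[1.0])

    def test_config_round_trip(self):
        spec = PhaseTypeSpec(
            beta_vec=[0.0, 2.0], Sigma=[[-1.5, 0.0], [1.5, -1.0]], V=[1.0, 0.0]
        )
        kern = phase_type_kernel(spec)
        back = kernel_from_config(kern.config)
        tau = np.linspace(0.0, 5.0, 51)
        np.testing.assert_allclose(back(tau), kern(tau), rtol=1e-13)

    def test_markovian_config_round_trip(self):
        kern = markovian_kernel(MarkovianSIRSpec(1.3, 0.4))
        back = kernel_from_config(kern.config)
        tau = np.linspace(0.0, 5.0, 51)
        np.testing.assert_allclose(back(tau), kern(tau), rtol=1e-13)
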