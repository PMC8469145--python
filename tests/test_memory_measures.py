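"""Divergences, conditional information, information length, time constants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from bmem import (
    PARTITION_1D,
    ParameterError,
    build_categorical_model,
    categorical_cmi,
    categorical_kl,
    conditional_covariance,
    conditional_mutual_information,
    gaussian_kl,
    information_length,
    stationary_covariance,
    time_constants,
)
from conftest import random_spd


class TestGaussianKL:
    def test_identical_is_zero(self, rng):
        cov = random_spd(rng)
        mode = rng.standard_normal(3)
        assert gaussian_kl(mode, cov, mode, cov) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "a, A, b, B, expected",
        [
            (0.0, 1.0, 1.0, 1.0, 0.5),  # unit-variance mean shift: d^2/2
            (0.0, 2.0, 0.0, 1.0, 0.5 * (2 - 1 + np.log(0.5))),
            (0.0, 1.0, 0.0, 2.0, 0.5 * (0.5 - 1 + np.log(2.0))),
        ],
    )
    def test_univariate_closed_forms(self, a, A, b, B, expected):
        assert gaussian_kl([a], [[A]], [b], [[B]]) == pytest.approx(expected, rel=1e-12)

    def test_against_numerical_quadrature_1d(self):
        p = stats.norm(0.3, 1.2)
        q = stats.norm(-0.5, 0.8)
        integrand = lambda x: p.pdf(x) * (p.logpdf(x) - q.logpdf(x))
        oracle, _ = integrate.quad(integrand, -12, 12)
        ours = gaussian_kl([0.3], [[1.2**2]], [-0.5], [[0.8**2]])
        assert ours == pytest.approx(oracle, abs=1e-4)

    def test_against_numerical_quadrature_2d(self):
        A = np.array([[1.0, 0.4], [0.4, 0.8]])
        B = np.array([[1.5, -0.2], [-0.2, 1.0]])
        a = np.array([0.2, -0.1])
        b = np.array([0.0, 0.3])
        Ai, Bi = np.linalg.inv(A), np.linalg.inv(B)
        log_norm_a = -0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(A))
        log_norm_b = -0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(B))

        def integrand(y, x):
            da, db_ = np.array([x, y]) - a, np.array([x, y]) - b
            logp = log_norm_a - 0.5 * da @ Ai @ da
            logq = log_norm_b - 0.5 * db_ @ Bi @ db_
            return np.exp(logp) * (logp - logq)

        oracle, _ = integrate.dblquad(integrand, -8, 8, -8, 8, epsabs=1e-6)
        assert gaussian_kl(a, A, b, B) == pytest.approx(oracle, abs=1e-4)

    @given(
        shift=st.floats(-3, 3),
        scale_p=st.floats(0.3, 3),
        scale_q=st.floats(0.3, 3),
    )
    def test_nonnegativity(self, shift, scale_p, scale_q):
        assert gaussian_kl([0.0], [[scale_p]], [shift], [[scale_q]]) >= 0.0


class TestConditionalCovariance:
    def test_steady_state_has_no_cross_term(self, default_model):
        Y = conditional_covariance(stationary_covariance(default_model), PARTITION_1D)
        assert Y[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert Y[0, 0] == pytest.approx(0.5, abs=1e-12)  # 3/4 - (1/2)^2 / 1

    def test_block_diagonal_passthrough(self):
        Sigma = np.diag([2.0, 5.0, 3.0])
        Sigma[0, 2] = Sigma[2, 0] = 0.7
        Y = conditional_covariance(Sigma, PARTITION_1D)
        assert np.allclose(Y, [[2.0, 0.7], [0.7, 3.0]])


class TestConditionalMutualInformation:
    def test_zero_at_steady_state(self, default_model):
        S = stationary_covariance(default_model)
        assert conditional_mutual_information(S, PARTITION_1D) == 0.0

    def test_known_conditional_correlation(self):
        """Conditional correlation 0.5 gives -ln(0.75)/2 in nats."""
        Sigma = np.eye(3)
        Sigma[0, 2] = Sigma[2, 0] = 0.5  # b independent of both
        cmi = conditional_mutual_information(Sigma, PARTITION_1D)
        assert cmi == pytest.approx(-0.5 * np.log(0.75), rel=1e-12)

    @given(s_mu=st.floats(0.2, 5.0), s_eta=st.floats(0.2, 5.0))
    def test_invariant_to_unit_rescaling(self, s_mu, s_eta, default_model,
                                         perturbed_relaxation):
        """Mutual information does not depend on the units of mu or eta."""
        Sigma = perturbed_relaxation.covariances[200]
        D = np.diag([s_mu, 1.0, s_eta])
        base = conditional_mutual_information(Sigma, PARTITION_1D)
        scaled = conditional_mutual_information(D @ Sigma @ D, PARTITION_1D)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_against_monte_carlo_plugin(self, perturbed_relaxation):
        """The closed form agrees with a sampling estimate of
        E[ln p(mu,eta|b) - ln p(mu|b) - ln p(eta|b)] within 3 SE."""
        Sigma = perturbed_relaxation.covariances[150]  # mid-transient
        rng = np.random.default_rng(123)
        n = 1_000_000
        x = rng.multivariate_normal(np.zeros(3), Sigma, size=n)
        Y = conditional_covariance(Sigma, PARTITION_1D)
        # residuals of (mu, eta) after conditioning on b
        gain = Sigma[[0, 2], 1] / Sigma[1, 1]
        resid = x[:, [0, 2]] - np.outer(x[:, 1], gain)
        log_joint = stats.multivariate_normal(np.zeros(2), Y).logpdf(resid)
        log_marg = stats.norm(0, np.sqrt(Y[0, 0])).logpdf(resid[:, 0]) + stats.norm(
            0, np.sqrt(Y[1, 1])
        ).logpdf(resid[:, 1])
        contrib = log_joint - log_marg
        estimate, se = contrib.mean(), contrib.std(ddof=1) / np.sqrt(n)
        closed = conditional_mutual_information(Sigma, PARTITION_1D)
        assert abs(closed - estimate) < 3.0 * se


class TestInformationLength:
    def test_constant_trajectory(self):
        seq = [(np.zeros(1), np.eye(1))] * 5
        assert np.allclose(information_length(seq, gaussian_kl), 0.0)

    def test_single_step_increment(self):
        def fake_kl(*args):
            return 0.02

        lengths = information_length([1, 2], fake_kl)
        assert lengths[-1] == pytest.approx(0.2, rel=1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_translation_family_closed_form(self, sigma):
        """Moving a fixed-variance 1-D Gaussian a distance d has Fisher
        length d/sigma; the discrete sum converges under dt-refinement."""
        d = 2.0
        total_prev = None
        for n_steps in (64, 128, 256):
            modes = np.linspace(0.0, d, n_steps + 1)
            seq = [(np.array([mu]), np.array([[sigma**2]])) for mu in modes]
            total = information_length(seq, gaussian_kl)[-1]
            if total_prev is not None:
                assert abs(total - total_prev) / total < 0.01
            total_prev = total
        assert total == pytest.approx(d / sigma, rel=0.01)

    def test_invariant_under_affine_reparameterization(self):
        """Rescaling the state (units change) leaves the length unchanged."""
        modes = np.linspace(0.0, 1.0, 101)
        seq = [(np.array([m]), np.array([[0.25]])) for m in modes]
        c = 3.7
        seq_scaled = [(c * m, c**2 * S) for m, S in seq]
        base = information_length(seq, gaussian_kl)
        scaled = information_length(seq_scaled, gaussian_kl)
        assert np.allclose(base, scaled, rtol=1e-9)

    def test_profile_is_nondecreasing(self, perturbed_relaxation):
        seq = [
            (perturbed_relaxation.modes[k], perturbed_relaxation.covariances[k])
            for k in range(0, len(perturbed_relaxation), 8)
        ]
        profile = information_length(seq, gaussian_kl)
        assert np.all(np.diff(profile) >= 0)


class TestTimeConstants:
    def test_real_diagonal(self):
        constants, excluded = time_constants(np.diag([-2.0, -4.0]))
        assert np.allclose(constants, [0.5, 0.25])
        assert excluded == 0

    def test_complex_pair_uses_real_part(self):
        J = np.array([[-1.0, 3.0], [-3.0, -1.0]])  # eigenvalues -1 +/- 3i
        constants, _ = time_constants(J)
        assert np.allclose(constants, [1.0, 1.0])

    def test_zero_mode_excluded(self):
        J = np.diag([-2.0, 0.0, -0.5])
        constants, excluded = time_constants(J)
        assert excluded == 1
        assert np.allclose(constants, [2.0, 0.5])

    def test_covariance_jacobian_constants_finite(self, default_model):
        from bmem import covariance_jacobian

        constants, excluded = time_constants(covariance_jacobian(default_model))
        assert excluded == 0
        assert np.all(constants > 0) and np.all(np.isfinite(constants))


class TestCategoricalDivergences:
    def test_kl_identical_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert categorical_kl(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_kl_degenerate_vs_uniform(self):
        assert categorical_kl([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_kl_support_violation(self):
        with pytest.raises(ParameterError):
            categorical_kl([0.5, 0.5], [1.0, 0.0])

    @given(
        raw_p=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
        raw_q=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    def test_kl_nonnegative(self, raw_p, raw_q):
        p = np.array(raw_p) / np.sum(raw_p)
        q = np.array(raw_q) / np.sum(raw_q)
        assert categorical_kl(p, q) >= -1e-12


class TestCategoricalCMI:
    def test_factorized_tensor_is_zero(self, rng):
        s_b = np.array([0.3, 0.5, 0.2])
        cond_mu = rng.dirichlet(np.ones(3), size=3).T  # columns indexed by b
        cond_eta = rng.dirichlet(np.ones(3), size=3).T
        s = np.einsum("mb,eb,b->mbe", cond_mu, cond_eta, s_b)
        assert categorical_cmi(s) == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_of_canonical_model_is_zero(self, default_categorical):
        assert categorical_cmi(default_categorical.s_joint_inf) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_perfect_correlation_single_blanket_state(self):
        s = np.zeros((2, 1, 2))
        s[0, 0, 0] = s[1, 0, 1] = 0.5
        assert categorical_cmi(s) == pytest.approx(np.log(2), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            categorical_cmi(-np.ones((2, 2, 2)) / 8)
        bad = np.ones((2, 2, 2))
        with pytest.raises(ParameterError):
            categorical_cmi(bad)


def test_categorical_steady_state_construction(default_categorical):
    """Sanity: the canonical steady state really factorizes given b."""
    cm = build_categorical_model(1.0, 1.0, 2.0)
    for model in (default_categorical, cm):
        s = model.s_joint_inf
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        assert categorical_cmi(s) == pytest.approx(0.0, abs=1e-12)
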