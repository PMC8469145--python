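"""Exact density dynamics of the blanketed Ornstein–Uhlenbeck system.

Because the potential is quadratic and the flow operators constant, the
Fokker–Planck equation closes on a Gaussian: the density stays multivariate
normal with a mode ``xi`` and covariance ``Sigma`` obeying the linear system

    xi'    = -A (xi - theta),            A = (Gamma - Q) Pi
    Sigma' = 2 Gamma - A Sigma - Sigma A^T

(a Lyapunov/Sylvester flow whose fixed point is ``Sigma = Pi^{-1}``).  The
module also propagates the precision ``Phi = Sigma^{-1}`` directly, exposes
the vectorized covariance Jacobian, and builds the high-blanket-precision
initial density used by the perturbation experiments: starting from steady
state, the blanket coordinate of the initial precision is set very high
(``exp(4)`` by default), as if the blanket had just been observed at its
expected value.

Production integration is fixed-step classical Runge–Kutta (RK4); the affine
structure also admits a matrix-exponential closed form, provided here as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import IntegrationError, ParameterError, ShapeError
from .gaussian_model import GaussianModelParams

__all__ = [
    "GaussianDensityState",
    "DensityTrajectory",
    "PrecisionState",
    "perturbed_initial_density",
    "propagate_density",
    "closed_form_density",
    "covariance_jacobian",
    "precision_rate",
    "precision_rate_mu_eta",
    "PrecisionRateTerms",
    "propagate_precision",
]

DEFAULT_DT = 1.0 / 64.0
DEFAULT_HORIZON = 16.0
DEFAULT_LOG_PRECISION = 4.0


def _require_spd(mat: np.ndarray, what: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ParameterError(f"{what} must be symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as err:
        raise ParameterError(f"{what} must be positive-definite") from err


@dataclass(frozen=True)
class GaussianDensityState:
    """A multivariate normal density N(mode, covariance) at one time."""

    mode: np.ndarray
    covariance: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "mode", np.asarray(self.mode, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        n = self.mode.size
        if self.covariance.shape != (n, n):
            raise ShapeError("covariance shape must match mode dimension")
        if not (np.all(np.isfinite(self.mode)) and np.all(np.isfinite(self.covariance))):
            raise ParameterError("density state contains non-finite values")
        _require_spd(self.covariance, "covariance")

    @property
    def precision(self) -> np.ndarray:
        phi = np.linalg.inv(self.covariance)
        return 0.5 * (phi + phi.T)


@dataclass(frozen=True)
class PrecisionState:
    """Inverse-covariance parameterization of a Gaussian density state."""

    precision: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "precision", np.asarray(self.precision, dtype=float))
        _require_spd(self.precision, "precision")


@dataclass(frozen=True)
class DensityTrajectory:
    """Time-ordered Gaussian density states on a uniform grid.

    Stored as stacked arrays: ``modes`` (n_times, n), ``covariances``
    (n_times, n, n).
    """

    times: np.ndarray
    modes: np.ndarray
    covariances: np.ndarray
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "modes", np.asarray(self.modes, dtype=float))
        object.__setattr__(self, "covariances", np.asarray(self.covariances, dtype=float))

    def __len__(self) -> int:
        return self.times.size

    def state(self, k: int) -> GaussianDensityState:
        return GaussianDensityState(
            mode=self.modes[k], covariance=self.covariances[k], time=float(self.times[k])
        )

    @property
    def precisions(self) -> np.ndarray:
        phis = np.linalg.inv(self.covariances)
        return 0.5 * (phis + np.swapaxes(phis, -1, -2))

    @property
    def final(self) -> GaussianDensityState:
        return self.state(len(self) - 1)


def perturbed_initial_density(
    m: GaussianModelParams,
    log_precision: float = DEFAULT_LOG_PRECISION,
    additive: bool = False,
) -> GaussianDensityState:
    """Steady-state density with a sharply observed blanket.

    The initial precision equals the steady-state Hessian ``Pi`` except that
    the blanket diagonal entry is set to ``exp(log_precision)`` (or, with
    ``additive=True``, increased by that amount).  The mode is the
    steady-state mode.  Conditioned on the blanket, internal and external
    states are initially unchanged from steady state — the perturbation only
    expresses certainty about the blanket coordinate.
    """
    b = m.partition.blanket_idx[0]
    phi0 = m.hessian.copy()
    if additive:
        phi0[b, b] += np.exp(log_precision)
    else:
        phi0[b, b] = np.exp(log_precision)
    try:
        np.linalg.cholesky(phi0)
    except np.linalg.LinAlgError as err:
        raise IntegrationError(
            "perturbed initial precision is not positive-definite; "
            "increase log_precision"
        ) from err
    sigma0 = np.linalg.inv(phi0)
    return GaussianDensityState(
        mode=m.theta_mode.copy(), covariance=0.5 * (sigma0 + sigma0.T), time=0.0
    )


def _density_rhs(m: GaussianModelParams, xi: np.ndarray, Sigma: np.ndarray):
    A = m.flow_operator
    dxi = -A @ (xi - m.theta_mode)
    dSigma = 2.0 * m.diffusion - A @ Sigma - Sigma @ A.T
    return dxi, dSigma


def propagate_density(
    m: GaussianModelParams,
    state0: GaussianDensityState,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_HORIZON,
) -> DensityTrajectory:
    """Integrate the mode/covariance flow with fixed-step RK4.

    The covariance is re-symmetrized after every step; loss of
    positive-definiteness raises :class:`IntegrationError` (try a smaller
    ``dt``).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n_steps = int(round(T / dt))
    n = m.n_states
    modes = np.empty((n_steps + 1, n))
    covs = np.empty((n_steps + 1, n, n))
    xi, Sigma = state0.mode.copy(), state0.covariance.copy()
    modes[0], covs[0] = xi, Sigma
    for k in range(n_steps):
        k1 = _density_rhs(m, xi, Sigma)
        k2 = _density_rhs(m, xi + 0.5 * dt * k1[0], Sigma + 0.5 * dt * k1[1])
        k3 = _density_rhs(m, xi + 0.5 * dt * k2[0], Sigma + 0.5 * dt * k2[1])
        k4 = _density_rhs(m, xi + dt * k3[0], Sigma + dt * k3[1])
        xi = xi + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        Sigma = Sigma + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        Sigma = 0.5 * (Sigma + Sigma.T)
        try:
            np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError as err:
            raise IntegrationError(
                f"covariance lost positive-definiteness at step {k + 1} "
                f"(t={dt * (k + 1):.4f}); use a smaller dt"
            ) from err
        modes[k + 1], covs[k + 1] = xi, Sigma
    times = state0.time + dt * np.arange(n_steps + 1)
    return DensityTrajectory(times=times, modes=modes, covariances=covs, dt=float(dt))


def closed_form_density(
    m: GaussianModelParams, state0: GaussianDensityState, t: float
) -> GaussianDensityState:
    """Matrix-exponential solution of the affine mode/covariance flow.

    ``xi(t) = theta + expm(-A t) (xi0 - theta)`` and
    ``vec(Sigma(t) - Sigma_inf) = expm(J t) vec(Sigma0 - Sigma_inf)`` with
    ``J`` the covariance Jacobian and ``Sigma_inf = Pi^{-1}``.  Used as an
    independent oracle for :func:`propagate_density`.
    """
    A = m.flow_operator
    xi = m.theta_mode + expm(-A * t) @ (state0.mode - m.theta_mode)
    sigma_inf = np.linalg.inv(m.hessian)
    J = covariance_jacobian(m)
    dev = (state0.covariance - sigma_inf).reshape(-1, order="F")
    sigma = sigma_inf + (expm(J * t) @ dev).reshape(m.n_states, m.n_states, order="F")
    sigma = 0.5 * (sigma + sigma.T)
    return GaussianDensityState(mode=xi, covariance=sigma, time=state0.time + t)


def covariance_jacobian(m: GaussianModelParams) -> np.ndarray:
    """Jacobian of the vectorized covariance flow, ``-(A (+) A)``.

    Column-stacking (Fortran-order) vectorization is used, under which
    ``vec(A Sigma + Sigma A^T) = (I (x) A + A (x) I) vec(Sigma)``; the
    covariance flow Jacobian is the negative Kronecker sum
    ``-(kron(I, A) + kron(A, I))``.  Its eigenvalues are ``-(li + lj)`` over
    eigenvalue pairs of ``A``, so the relaxation time constants of the
    covariance are read directly off this matrix.
    """
    A = m.flow_operator
    eye = np.eye(m.n_states)
    return -(np.kron(eye, A) + np.kron(A, eye))


def precision_rate(m: GaussianModelParams, Phi: PrecisionState | np.ndarray) -> np.ndarray:
    """Rate of change of the precision matrix along the density flow.

    ``Phi' = Pi (Gamma - Q)^T Phi + Phi (Gamma - Q) Pi - 2 Phi Gamma Phi``,
    the pushforward of the covariance flow through ``Phi = Sigma^{-1}``
    (equivalently ``-Phi Sigma' Phi``).  Zero at ``Phi = Pi``.
    """
    phi = Phi.precision if isinstance(Phi, PrecisionState) else np.asarray(Phi, float)
    if not np.allclose(phi, phi.T, atol=1e-8):
        raise ParameterError("precision must be symmetric")
    GmQ = m.diffusion - m.solenoidal
    Pi = m.hessian
    rate = Pi @ GmQ.T @ phi + phi @ GmQ @ Pi - 2.0 * phi @ m.diffusion @ phi
    return 0.5 * (rate + rate.T)


@dataclass(frozen=True)
class PrecisionRateTerms:
    """Labelled contributions to the internal-external precision rate.

    ``dissipation_internal_external`` collects the terms proportional to the
    internal/external diffusion rate gamma, ``dissipation_blanket`` those
    through the blanket diffusion channel, and ``solenoidal`` the coupling
    through Q.  Their sum is the (mu, eta) entry of :func:`precision_rate`.
    """

    dissipation_internal_external: float
    dissipation_blanket: float
    solenoidal: float

    @property
    def total(self) -> float:
        return (
            self.dissipation_internal_external
            + self.dissipation_blanket
            + self.solenoidal
        )


def precision_rate_mu_eta(
    m: GaussianModelParams, Phi: PrecisionState | np.ndarray
) -> PrecisionRateTerms:
    """Scalar expansion of the (mu, eta) precision rate for the canonical model.

    Only valid for one-dimensional partition cells.  With the canonical
    parameterization (Gamma = diag(gamma,1,gamma)/4, the tridiagonal Pi and
    the blanket-coupled Q), the three labelled groups are, writing
    ``P`` for Phi and ``rk`` for 1/sqrt(kappa):

    * internal/external dissipation:
      ``gamma (1/kappa - (P_mm + P_ee)/2) P_me``
    * blanket dissipation:
      ``(rk P_be + rk P_mb - 2 P_mb P_be) / 4``
    * solenoidal coupling:
      ``theta (2 (P_mb - P_be)/kappa + rk (P_mm - P_ee))``

    At steady state (``Phi = Pi``) every group vanishes; the solenoidal
    contributions cancel in aggregate.
    """
    part = m.partition
    if not (len(part.internal_idx) == len(part.blanket_idx) == len(part.external_idx) == 1):
        raise ParameterError("scalar expansion requires 1-D partition cells")
    phi = Phi.precision if isinstance(Phi, PrecisionState) else np.asarray(Phi, float)
    i, b, e = part.internal_idx[0], part.blanket_idx[0], part.external_idx[0]
    Pi, Gamma, Q = m.hessian, m.diffusion, m.solenoidal

    P_mm, P_ee, P_me = phi[i, i], phi[e, e], phi[i, e]
    P_mb, P_be = phi[i, b], phi[b, e]

    # general 3-state scalar expansion of the matrix form, grouped by channel
    diss_ie = (
        Gamma[i, i] * (Pi[i, i] - 2 * P_mm) * P_me
        + Gamma[e, e] * (Pi[e, e] - 2 * P_ee) * P_me
    )
    diss_b = Gamma[b, b] * (
        Pi[i, b] * P_be + Pi[e, b] * P_mb - 2 * P_mb * P_be
    )
    sol = Q[i, b] * (Pi[i, i] * P_be - Pi[b, e] * P_mm - Pi[i, b] * P_me) + Q[e, b] * (
        Pi[e, e] * P_mb - Pi[i, b] * P_ee - Pi[e, b] * P_me
    )
    return PrecisionRateTerms(
        dissipation_internal_external=float(diss_ie),
        dissipation_blanket=float(diss_b),
        solenoidal=float(sol),
    )


def propagate_precision(
    m: GaussianModelParams,
    phi0: np.ndarray,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_HORIZON,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the precision flow directly with fixed-step RK4.

    Returns ``(times, phis)`` with ``phis`` of shape (n_times, n, n).
    Cross-checks the covariance route: inverting the propagated covariance
    must agree with this trajectory.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n_steps = int(round(T / dt))
    phi = np.asarray(phi0, dtype=float).copy()
    phis = np.empty((n_steps + 1,) + phi.shape)
    phis[0] = phi

    def rhs(p):
        return precision_rate(m, p)

    for k in range(n_steps):
        k1 = rhs(phi)
        k2 = rhs(phi + 0.5 * dt * k1)
        k3 = rhs(phi + 0.5 * dt * k2)
        k4 = rhs(phi + dt * k3)
        phi = phi + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        phi = 0.5 * (phi + phi.T)
        phis[k + 1] = phi
    return dt * np.arange(n_steps + 1), phis
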