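"""Categorical analogue of the blanketed system: a 3x3x3 master equation.

The joint distribution over internal (mu), blanket (b) and external (eta)
states — each with three levels — evolves under a linear master equation

    vec(s') = L vec(s),      L = Omega Lambda,

where ``Lambda = diag(vec s(inf))^{-1}`` rescales by the steady state, and
``Omega = Gamma + Q`` splits into a symmetric part ``Gamma`` (which on its
own preserves detailed balance with respect to s(inf)) and an antisymmetric
part ``Q`` (which breaks it — the categorical counterpart of solenoidal
flow).  The steady state factorizes as
``s(mu, eta, b) = s(mu|b) s(eta|b) s(b)``, i.e. it carries a Markov blanket.

Note on signs: the symmetric component is stored generator-shaped (negative
diagonal, positive off-diagonal, zero row/column sums), so that
``L = (Gamma + Q) Lambda`` is a valid transition-rate matrix — columns sum
to zero and, provided ``theta <= 4 gamma``, all off-diagonal rates are
nonnegative.  Scaling the antisymmetric part too far relative to the
symmetric part produces negative transition rates, which is why the builder
enforces that bound.

The canonical construction mirrors the continuous one:

* ``s_b(inf) = softmax(kappa ln(1, 3, 1))``,
* ``s_{mu|b}(inf) = s_{eta|b}(inf) =`` column-wise softmax of
  ``kappa ln [[1,3,1],[3,1,1],[1,1,3]]`` (columns indexed by b),
* ``Gamma = (gamma/128) (ones(27) - 27 I)``,
* ``Q = (theta/512) A (x) A (x) A`` with the 3-cycle
  ``A = [[0,-1,1],[1,0,-1],[-1,1,0]]``.

Axis order is (mu, b, eta) throughout, with C-order (row-major)
vectorization: the eta index varies fastest, matching
``kron(A_mu, kron(A_b, A_eta))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .exceptions import GeneratorValidityError, ParameterError, ShapeError

__all__ = [
    "CategoricalModel",
    "CategoricalTrajectory",
    "build_categorical_model",
    "build_generator",
    "categorical_initial_condition",
    "integrate_master",
    "categorical_time_constants",
    "diagonal_time_constants",
    "detailed_balance_residual",
]

N_LEVELS = 3
N_JOINT = N_LEVELS**3
DEFAULT_DT = 1.0 / 64.0
DEFAULT_HORIZON = 8.0

#: three-state cyclic antisymmetric pattern used in the Kronecker build of Q
CYCLE = np.array([[0.0, -1.0, 1.0], [1.0, 0.0, -1.0], [-1.0, 1.0, 0.0]])

#: un-normalized steady-state weights (softmax arguments are kappa * ln of these)
_B_WEIGHTS = np.array([1.0, 3.0, 1.0])
_COND_WEIGHTS = np.array([[1.0, 3.0, 1.0], [3.0, 1.0, 1.0], [1.0, 1.0, 3.0]])


def _softmax_cols(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=0, keepdims=True))
    return z / z.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class CategoricalModel:
    """Steady state and flow components of the categorical system."""

    s_b_inf: np.ndarray
    s_mu_given_b: np.ndarray
    s_eta_given_b: np.ndarray
    s_joint_inf: np.ndarray  # (mu, b, eta) tensor
    gamma_mat: np.ndarray  # 27x27 symmetric, generator-shaped
    q_mat: np.ndarray  # 27x27 antisymmetric
    lambda_scale: np.ndarray  # 27x27 diagonal, diag(vec s_inf)^-1
    generator: np.ndarray  # 27x27, L = (Gamma + Q) Lambda
    gamma: float
    theta_s: float
    kappa: float

    @property
    def vec_s_inf(self) -> np.ndarray:
        return self.s_joint_inf.reshape(-1)


def build_categorical_model(
    gamma: float = 1.0, theta_s: float = 1.0, kappa: float = 1.0
) -> CategoricalModel:
    """Construct the canonical 3x3x3 categorical model.

    Raises :class:`GeneratorValidityError` if ``theta_s > 4 * gamma``: the
    smallest off-diagonal entry of ``Gamma + Q`` is
    ``gamma/128 - theta_s/512``, which must stay nonnegative for a valid
    transition-rate matrix.
    """
    for name, v in (("gamma", gamma), ("theta_s", theta_s), ("kappa", kappa)):
        if not np.isfinite(v) or v <= 0:
            raise ParameterError(f"{name} must be a positive finite scalar")
    if theta_s > 4.0 * gamma + 1e-12:
        raise GeneratorValidityError(
            f"theta_s={theta_s} > 4*gamma={4 * gamma}: the antisymmetric flow "
            "would produce negative off-diagonal transition rates"
        )

    s_b = _softmax_cols((kappa * np.log(_B_WEIGHTS))[:, None]).ravel()
    cond = _softmax_cols(kappa * np.log(_COND_WEIGHTS))  # columns indexed by b
    # joint tensor over (mu, b, eta)
    s_joint = np.einsum("mb,eb,b->mbe", cond, cond, s_b)

    gamma_mat = (gamma / 128.0) * (np.ones((N_JOINT, N_JOINT)) - N_JOINT * np.eye(N_JOINT))
    q_mat = (theta_s / 512.0) * np.kron(CYCLE, np.kron(CYCLE, CYCLE))
    lambda_scale = np.diag(1.0 / s_joint.reshape(-1))

    model = CategoricalModel(
        s_b_inf=s_b,
        s_mu_given_b=cond,
        s_eta_given_b=cond,
        s_joint_inf=s_joint,
        gamma_mat=gamma_mat,
        q_mat=q_mat,
        lambda_scale=lambda_scale,
        generator=np.empty((N_JOINT, N_JOINT)),
        gamma=float(gamma),
        theta_s=float(theta_s),
        kappa=float(kappa),
    )
    object.__setattr__(model, "generator", build_generator(model))
    return model


def build_generator(model: CategoricalModel) -> np.ndarray:
    """Assemble the transition-rate matrix ``L = (Gamma + Q) Lambda``.

    By construction ``(Gamma + Q) 1 = 0`` row-wise and column-wise, so
    ``L vec(s_inf) = (Gamma + Q) 1 = 0`` (exact stationarity) and every
    column of L sums to zero (probability conservation).  Raises if any
    off-diagonal rate is negative.
    """
    omega = model.gamma_mat + model.q_mat
    off_diag = omega[~np.eye(N_JOINT, dtype=bool)]
    if off_diag.min() < -1e-14:
        raise GeneratorValidityError(
            f"negative off-diagonal rate {off_diag.min():.3e} in Gamma + Q"
        )
    return omega @ model.lambda_scale


def categorical_initial_condition(model: CategoricalModel) -> np.ndarray:
    """Steady-state conditionals with a sharply observed blanket.

    The blanket marginal is collapsed onto its most likely steady-state
    level (one-hot); internal and external states keep their steady-state
    conditionals given that level, so the initial joint still factorizes
    given the blanket and the blanket-conditioned mutual information starts
    at zero.  Ties in the argmax break to the lowest index.
    """
    b_star = int(np.argmax(model.s_b_inf))
    s0 = np.zeros((N_LEVELS, N_LEVELS, N_LEVELS))
    s0[:, b_star, :] = np.outer(
        model.s_mu_given_b[:, b_star], model.s_eta_given_b[:, b_star]
    )
    return s0


@dataclass(frozen=True)
class CategoricalTrajectory:
    """Time-ordered joint probability tensors (mu, b, eta) on a uniform grid."""

    times: np.ndarray
    tensors: np.ndarray  # (n_times, 3, 3, 3)

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "tensors", np.asarray(self.tensors, dtype=float))

    def __len__(self) -> int:
        return self.times.size

    def marginal(self, axis_name: str) -> np.ndarray:
        """Marginal time course over 'mu', 'b' or 'eta'; shape (n_times, 3)."""
        axes = {"mu": (2, 3), "b": (1, 3), "eta": (1, 2)}
        try:
            return self.tensors.sum(axis=axes[axis_name])
        except KeyError:
            raise ParameterError(f"unknown axis {axis_name!r}") from None

    @property
    def final(self) -> np.ndarray:
        return self.tensors[-1]


def integrate_master(
    L: np.ndarray,
    s0: np.ndarray,
    dt: float = DEFAULT_DT,
    T: float = DEFAULT_HORIZON,
) -> CategoricalTrajectory:
    """Propagate the master equation by repeated one-step matrix exponential.

    The 27x27 step matrix ``expm(L dt)`` is computed once and applied
    repeatedly, so probability is conserved to round-off and entries stay
    nonnegative (tiny negative round-off is clipped).
    """
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (N_LEVELS, N_LEVELS, N_LEVELS):
        raise ShapeError("s0 must be a 3x3x3 tensor")
    if np.any(s0 < -1e-12) or not np.isclose(s0.sum(), 1.0, atol=1e-8):
        raise ParameterError("s0 must be a probability tensor summing to 1")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n_steps = int(round(T / dt))
    step = expm(np.asarray(L, dtype=float) * dt)
    vec = s0.reshape(-1).copy()
    out = np.empty((n_steps + 1, N_JOINT))
    out[0] = vec
    for k in range(n_steps):
        vec = step @ vec
        out[k + 1] = vec
    out = np.clip(out, 0.0, None)
    tensors = out.reshape(n_steps + 1, N_LEVELS, N_LEVELS, N_LEVELS)
    return CategoricalTrajectory(times=dt * np.arange(n_steps + 1), tensors=tensors)


def categorical_time_constants(
    L: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, int]:
    """Relaxation time constants from the generator spectrum.

    Returns ``-1/Re(lambda)`` for each eigenvalue with ``Re < -tol``, sorted
    descending, plus the count of excluded zero modes (exactly one for an
    irreducible generator: the stationary distribution).
    """
    re = np.real(np.linalg.eigvals(np.asarray(L, dtype=float)))
    decaying = re < -tol
    constants = np.sort(-1.0 / re[decaying])[::-1]
    return constants, int(np.sum(~decaying))


def diagonal_time_constants(L: np.ndarray) -> np.ndarray:
    """Alternative reading: negative reciprocals of the diagonal rates.

    The diagonal entry of a rate matrix is minus the total exit rate of a
    state, so ``-1/L_ii`` is that state's mean holding time.  Exposed
    alongside the spectral version; the spectral version is what the
    relaxation analysis uses.
    """
    d = np.diag(np.asarray(L, dtype=float))
    return -1.0 / d


def detailed_balance_residual(L: np.ndarray, s_inf: np.ndarray) -> float:
    """Largest violation of ``L_ij s_j = L_ji s_i`` (zero iff reversible)."""
    L = np.asarray(L, dtype=float)
    s = np.asarray(s_inf, dtype=float).ravel()
    flux = L * s[None, :]
    return float(np.max(np.abs(flux - flux.T)))
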