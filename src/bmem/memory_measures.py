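"""Information-theoretic measures of transient memory.

After a perturbation (an imposed initial condition on the blanket), a
Markov-blanketed system transiently violates the conditional independence
that defines the blanket.  This module quantifies that violation and its
persistence:

* **blanket-conditioned mutual information** between internal and external
  states — exactly zero at steady state, positive during the relaxation;
* **information length** — the cumulative distance the evolving density
  travels on the statistical manifold, accumulated as ``sqrt(2 KL)`` per
  step (the local KL divergence is symmetric to second order, with the
  Fisher metric as its Hessian);
* **time constants** — reciprocals of |Re| of the relaxation eigenvalues of
  a linear flow's Jacobian, the e-folding times of each decaying mode.

Gaussian and categorical variants are provided; all divergences are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ShapeError
from .gaussian_model import BlanketPartition

__all__ = [
    "gaussian_kl",
    "conditional_covariance",
    "conditional_mutual_information",
    "information_length",
    "time_constants",
    "categorical_kl",
    "categorical_cmi",
    "MeasureSeries",
]

#: eigenvalues with |Re| below this are treated as exact zero modes
ZERO_MODE_TOL = 1e-10


def gaussian_kl(
    mode_a: np.ndarray, cov_a: np.ndarray, mode_b: np.ndarray, cov_b: np.ndarray
) -> float:
    """KL divergence D(N(a, A) || N(b, B)) between multivariate normals.

    ``(tr(B^-1 A) + (a-b)·B^-1 (a-b) - d + ln det B - ln det A) / 2``.
    """
    a = np.atleast_1d(np.asarray(mode_a, dtype=float))
    b = np.atleast_1d(np.asarray(mode_b, dtype=float))
    A = np.atleast_2d(np.asarray(cov_a, dtype=float))
    B = np.atleast_2d(np.asarray(cov_b, dtype=float))
    d = a.size
    if b.size != d or A.shape != (d, d) or B.shape != (d, d):
        raise ShapeError("mode/covariance dimensions do not match")
    chol_b = np.linalg.cholesky(B)  # raises LinAlgError if B singular
    Binv_A = np.linalg.solve(B, A)
    diff = a - b
    maha = diff @ np.linalg.solve(B, diff)
    sign_a, logdet_a = np.linalg.slogdet(A)
    if sign_a <= 0:
        raise np.linalg.LinAlgError("first covariance must be positive-definite")
    logdet_b = 2.0 * np.sum(np.log(np.diag(chol_b)))
    return 0.5 * float(np.trace(Binv_A) + maha - d + logdet_b - logdet_a)


def conditional_covariance(Sigma: np.ndarray, part: BlanketPartition) -> np.ndarray:
    """Covariance of (internal, external) given the blanket.

    The Schur complement of the blanket block:
    ``Y = S_cc - S_cb S_bb^-1 S_bc`` with ``c = internal + external`` indices
    (internal first).  Returned over the (internal, external) ordering.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    c = list(part.internal_idx) + list(part.external_idx)
    b = list(part.blanket_idx)
    S_cc = Sigma[np.ix_(c, c)]
    S_cb = Sigma[np.ix_(c, b)]
    S_bb = Sigma[np.ix_(b, b)]
    Y = S_cc - S_cb @ np.linalg.solve(S_bb, S_cb.T)
    return 0.5 * (Y + Y.T)


def conditional_mutual_information(Sigma: np.ndarray, part: BlanketPartition) -> float:
    """Mutual information between internal and external states given the blanket.

    ``I = ln(det Y_ee / det(Y_ee - Y_em Y_mm^-1 Y_me)) / 2`` where Y is the
    blanket-conditioned covariance.  Zero exactly when the blanket condition
    holds; for scalar blocks it reduces to ``-ln(1 - rho^2)/2`` with rho the
    conditional correlation.  Clipped at 0 against round-off.
    """
    Y = conditional_covariance(Sigma, part)
    n_mu = len(part.internal_idx)
    Y_mm = Y[:n_mu, :n_mu]
    Y_ee = Y[n_mu:, n_mu:]
    Y_em = Y[n_mu:, :n_mu]
    resid = Y_ee - Y_em @ np.linalg.solve(Y_mm, Y_em.T)
    sign_full, logdet_full = np.linalg.slogdet(Y_ee)
    sign_resid, logdet_resid = np.linalg.slogdet(resid)
    if sign_full <= 0 or sign_resid <= 0:
        raise np.linalg.LinAlgError("conditional covariance is not positive-definite")
    return max(0.0, 0.5 * float(logdet_full - logdet_resid))


def information_length(
    trajectory: Sequence, kl: Callable[..., float]
) -> np.ndarray:
    """Cumulative information length along a density trajectory.

    ``trajectory`` is a sequence of density parameterizations; ``kl(p1, p0)``
    must return the divergence of consecutive entries (each entry is splatted
    if it is a tuple, so Gaussian trajectories can be given as
    ``[(mode, cov), ...]`` with ``kl=gaussian_kl``, and categorical ones as
    ``[p_vec, ...]`` with ``kl=categorical_kl``).

    Returns the nondecreasing profile ``l(t_k) = sum_{j<k} sqrt(2 KL_j)``
    with ``l(t_0) = 0``.  Tiny negative divergences from round-off are
    clipped at zero.
    """
    items = list(trajectory)
    lengths = np.zeros(len(items))
    for j in range(len(items) - 1):
        nxt, cur = items[j + 1], items[j]
        if isinstance(nxt, tuple):
            div = kl(*nxt, *cur)
        else:
            div = kl(nxt, cur)
        lengths[j + 1] = lengths[j] + np.sqrt(2.0 * max(0.0, float(div)))
    return lengths


def time_constants(
    J: np.ndarray, tol: float = ZERO_MODE_TOL
) -> tuple[np.ndarray, int]:
    """Decay time constants of a linear flow from its Jacobian spectrum.

    For each eigenvalue with ``|Re| > tol`` return ``1/|Re|``, sorted
    descending (slowest mode first).  Eigenvalues within tolerance of the
    imaginary axis are zero modes (e.g. probability conservation of a
    master-equation generator); they are excluded and their count returned.
    """
    J = np.asarray(J, dtype=float)
    re = np.real(np.linalg.eigvals(J))
    nonzero = np.abs(re) > tol
    constants = np.sort(1.0 / np.abs(re[nonzero]))[::-1]
    return constants, int(np.sum(~nonzero))


def categorical_kl(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence sum(p ln(p/q)) between probability vectors (nats).

    Zero-probability entries of p contribute 0; a positive p entry where q
    vanishes is a support violation.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ShapeError("p and q must have the same shape")
    if np.any(p < -1e-12) or np.any(q < -1e-12):
        raise ParameterError("probabilities must be nonnegative")
    if not (np.isclose(p.sum(), 1.0, atol=1e-8) and np.isclose(q.sum(), 1.0, atol=1e-8)):
        raise ParameterError("p and q must each sum to 1")
    support = p > 0
    if np.any(q[support] <= 0):
        raise ParameterError("q must be positive wherever p is")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def categorical_cmi(s: np.ndarray, p_tol: float = 1e-12) -> float:
    """Blanket-averaged mutual information of a joint (mu, b, eta) tensor.

    ``sum_b P(b) I(mu; eta | b)`` with each conditional mutual information
    computed from the conditional joint ``s(mu, eta | b)``.  Blanket states
    with probability below ``p_tol`` contribute nothing.  Axis order is
    (mu, b, eta).
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 3:
        raise ShapeError("joint tensor must have 3 axes (mu, b, eta)")
    if np.any(s < -1e-12):
        raise ParameterError("joint tensor has negative entries")
    if not np.isclose(s.sum(), 1.0, atol=1e-8):
        raise ParameterError("joint tensor must sum to 1")
    s = np.clip(s, 0.0, None)
    total = 0.0
    for b in range(s.shape[1]):
        p_b = s[:, b, :].sum()
        if p_b <= p_tol:
            continue
        joint = s[:, b, :] / p_b  # s(mu, eta | b)
        p_mu = joint.sum(axis=1, keepdims=True)
        p_eta = joint.sum(axis=0, keepdims=True)
        mask = joint > 0
        mi = np.sum(joint[mask] * np.log(joint[mask] / (p_mu @ p_eta)[mask]))
        total += p_b * max(0.0, float(mi))
    return total


@dataclass(frozen=True)
class MeasureSeries:
    """Time-indexed memory measures for one relaxation experiment.

    ``phi_mu_eta`` is the internal-external precision entry (continuous
    systems only; None for categorical runs).  ``time_constants_`` is the
    static spectrum-derived set of decay times, not time-indexed.
    """

    times: np.ndarray
    cmi: np.ndarray
    il_joint: np.ndarray
    il_blanket: np.ndarray
    phi_mu_eta: np.ndarray | None = None
    time_constants_: np.ndarray | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.cmi) < -1e-12):
            raise ParameterError("conditional mutual information must be nonnegative")
        for name in ("il_joint", "il_blanket"):
            arr = np.asarray(getattr(self, name))
            if np.any(np.diff(arr) < -1e-9):
                raise ParameterError(f"{name} must be nondecreasing")

    @property
    def il_excess(self) -> np.ndarray:
        """Joint minus blanket information length: distance travelled not
        attributable to the blanket marginal alone."""
        return np.asarray(self.il_joint) - np.asarray(self.il_blanket)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.times,
            "cmi": self.cmi,
            "il_joint": self.il_joint,
            "il_blanket": self.il_blanket,
            "il_excess": self.il_excess,
        }
        if self.phi_mu_eta is not None:
            data["phi_mu_eta"] = self.phi_mu_eta
        return pd.DataFrame(data)
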