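"""Three-state Ornstein–Uhlenbeck system whose steady state has a Markov blanket.

The state vector is partitioned into internal (mu), blanket (b) and external
(eta) coordinates, in that order.  The steady-state density is Gaussian,
``p(x, inf) ∝ exp(-J(x))`` with quadratic potential
``J(x) = (x - theta)·Pi·(x - theta)/2``.  A Markov blanket at steady state is
enforced by a zero (mu, eta) entry of the Hessian ``Pi``: internal and
external states are then conditionally independent given the blanket.

The drift decomposes into a dissipative gradient flow (symmetric ``Gamma``,
which also sets the noise covariance ``2*Gamma``) and a solenoidal flow
(antisymmetric ``Q``) circulating along the contours of the potential:

    f(x) = -(Gamma - Q) · Pi · (x - theta)

Three positive scalars parameterize the family used throughout:

* ``gamma`` — rate of the dissipative flow on the internal and external
  channels (both scaled together; the blanket channel is fixed),
* ``theta`` — strength of the solenoidal coupling through the blanket,
* ``kappa`` — steady-state variance scale: the marginal variances of the
  internal and external states are ``3*kappa/4`` while the conditional
  variance of the blanket given either neighbour stays ``2/3``.  Larger
  ``kappa`` flattens the potential, so gradients are shallower and
  relaxation slower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .exceptions import BlanketStructureError, ParameterError, ShapeError

__all__ = [
    "BlanketPartition",
    "GaussianModelParams",
    "build_gaussian_model",
    "stationary_covariance",
    "drift",
    "assert_blanket_structure",
    "model_to_config",
    "model_from_config",
    "save_model",
    "load_model",
]

#: numerical tolerance for structural checks (symmetry, antisymmetry, PSD)
STRUCTURE_ATOL = 1e-10


@dataclass(frozen=True)
class BlanketPartition:
    """Index partition of the state vector into internal / blanket / external.

    The three index lists must be disjoint, nonempty, and jointly cover
    ``0..n-1`` for the state dimension ``n``.
    """

    internal_idx: tuple[int, ...]
    blanket_idx: tuple[int, ...]
    external_idx: tuple[int, ...]

    def __post_init__(self):
        internal = tuple(int(i) for i in self.internal_idx)
        blanket = tuple(int(i) for i in self.blanket_idx)
        external = tuple(int(i) for i in self.external_idx)
        object.__setattr__(self, "internal_idx", internal)
        object.__setattr__(self, "blanket_idx", blanket)
        object.__setattr__(self, "external_idx", external)
        if not (internal and blanket and external):
            raise ParameterError("each partition cell must be nonempty")
        all_idx = internal + blanket + external
        if len(set(all_idx)) != len(all_idx):
            raise ParameterError("partition cells must be disjoint")
        if set(all_idx) != set(range(len(all_idx))):
            raise ParameterError("partition must cover indices 0..n-1")

    @property
    def n_states(self) -> int:
        return len(self.internal_idx) + len(self.blanket_idx) + len(self.external_idx)


#: the canonical three-state partition, state order (mu, b, eta)
PARTITION_1D = BlanketPartition((0,), (1,), (2,))


@dataclass(frozen=True)
class GaussianModelParams:
    """Parameters of the Markov-blanketed Ornstein–Uhlenbeck system.

    Attributes
    ----------
    theta_mode : (n,) array
        Mode of the steady-state density (the potential's minimum).
    hessian : (n, n) array
        Hessian ``Pi`` of the potential; symmetric positive-definite, with
        a zero (internal, external) block (the blanket condition).
    diffusion : (n, n) array
        Dissipative operator ``Gamma``; symmetric positive-semidefinite.
        The noise covariance of the stochastic system is ``2*Gamma``.
    solenoidal : (n, n) array
        Solenoidal operator ``Q``; antisymmetric.
    gamma, theta_s, kappa : float
        The scalar parameters the canonical family is built from.
    partition : BlanketPartition
        Which coordinates are internal / blanket / external.
    """

    theta_mode: np.ndarray
    hessian: np.ndarray
    diffusion: np.ndarray
    solenoidal: np.ndarray
    gamma: float
    theta_s: float
    kappa: float
    partition: BlanketPartition = field(default=PARTITION_1D)

    def __post_init__(self):
        object.__setattr__(self, "theta_mode", np.asarray(self.theta_mode, dtype=float))
        object.__setattr__(self, "hessian", np.asarray(self.hessian, dtype=float))
        object.__setattr__(self, "diffusion", np.asarray(self.diffusion, dtype=float))
        object.__setattr__(self, "solenoidal", np.asarray(self.solenoidal, dtype=float))
        n = self.partition.n_states
        if self.theta_mode.shape != (n,):
            raise ShapeError(f"theta_mode must have shape ({n},)")
        for name in ("hessian", "diffusion", "solenoidal"):
            if getattr(self, name).shape != (n, n):
                raise ShapeError(f"{name} must have shape ({n}, {n})")

    @property
    def n_states(self) -> int:
        return self.partition.n_states

    @property
    def flow_operator(self) -> np.ndarray:
        """The drift matrix ``A = (Gamma - Q) @ Pi``; drift is ``-A (x - theta)``."""
        return (self.diffusion - self.solenoidal) @ self.hessian


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ParameterError(f"{name} must be a positive finite scalar, got {value!r}")
    return value


def build_gaussian_model(
    gamma: float = 1.0, theta_s: float = 1.0, kappa: float = 1.0
) -> GaussianModelParams:
    """Construct the canonical three-state model from its three scalars.

    State order is (mu, b, eta).  The components are

    * mode ``theta = (0, 0, 0)``,
    * solenoidal ``Q = theta_s * [[0,-1,0],[1,0,-1],[0,1,0]]``,
    * diffusion ``Gamma = diag(gamma, 1, gamma)/4``,
    * Hessian ``Pi = [[2/k, 1/sqrt(k), 0], [1/sqrt(k), 2, 1/sqrt(k)],
      [0, 1/sqrt(k), 2/k]]`` with ``k = kappa``; its inverse has
      internal/external marginal variance ``3k/4`` and blanket conditional
      variance ``2/3`` for every ``k``.
    """
    gamma = _check_positive("gamma", gamma)
    theta_s = _check_positive("theta_s", theta_s)
    kappa = _check_positive("kappa", kappa)
    rk = 1.0 / np.sqrt(kappa)
    hessian = np.array(
        [
            [2.0 / kappa, rk, 0.0],
            [rk, 2.0, rk],
            [0.0, rk, 2.0 / kappa],
        ]
    )
    diffusion = 0.25 * np.diag([gamma, 1.0, gamma])
    solenoidal = theta_s * np.array(
        [
            [0.0, -1.0, 0.0],
            [1.0, 0.0, -1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return GaussianModelParams(
        theta_mode=np.zeros(3),
        hessian=hessian,
        diffusion=diffusion,
        solenoidal=solenoidal,
        gamma=gamma,
        theta_s=theta_s,
        kappa=kappa,
    )


def stationary_covariance(m: GaussianModelParams) -> np.ndarray:
    """Covariance of the steady-state density, ``Sigma(inf) = Pi^{-1}``."""
    try:
        cov = np.linalg.inv(m.hessian)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"hessian is singular: {err}") from err
    return 0.5 * (cov + cov.T)


def drift(m: GaussianModelParams, x: np.ndarray) -> np.ndarray:
    """Deterministic flow ``f(x) = -(Gamma - Q) Pi (x - theta)``.

    Accepts a single state vector of shape ``(n,)`` or a batch ``(..., n)``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != m.n_states:
        raise ShapeError(
            f"state has trailing dimension {x.shape[-1]}, expected {m.n_states}"
        )
    return -(x - m.theta_mode) @ m.flow_operator.T


@dataclass(frozen=True)
class BlanketReport:
    """Outcome of the structural validation of a model."""

    blanket_condition: bool
    hessian_positive_definite: bool
    solenoidal_antisymmetric: bool
    diffusion_psd: bool

    @property
    def ok(self) -> bool:
        return (
            self.blanket_condition
            and self.hessian_positive_definite
            and self.solenoidal_antisymmetric
            and self.diffusion_psd
        )


def assert_blanket_structure(
    m: GaussianModelParams, atol: float = STRUCTURE_ATOL
) -> BlanketReport:
    """Validate the structural invariants of a Markov-blanketed model.

    Checks, and raises :class:`BlanketStructureError` on the first failure:

    1. ``Pi`` symmetric with a zero (internal, external) block,
    2. ``Pi`` positive-definite,
    3. ``Q`` antisymmetric,
    4. ``Gamma`` symmetric positive-semidefinite.
    """
    Pi, Gamma, Q = m.hessian, m.diffusion, m.solenoidal
    part = m.partition

    if not np.allclose(Pi, Pi.T, atol=atol):
        raise BlanketStructureError("hessian_symmetry", "Pi is not symmetric")
    mu_eta_block = Pi[np.ix_(part.internal_idx, part.external_idx)]
    if not np.allclose(mu_eta_block, 0.0, atol=atol):
        raise BlanketStructureError(
            "blanket_condition",
            f"Pi[mu, eta] = {mu_eta_block!r} must be zero for a Markov blanket",
        )
    eigs = np.linalg.eigvalsh(Pi)
    if eigs.min() <= atol:
        raise BlanketStructureError(
            "hessian_positive_definite", f"Pi has non-positive eigenvalue {eigs.min()}"
        )
    if not np.allclose(Q, -Q.T, atol=atol):
        raise BlanketStructureError("solenoidal_antisymmetry", "Q + Q^T != 0")
    if not np.allclose(Gamma, Gamma.T, atol=atol):
        raise BlanketStructureError("diffusion_symmetry", "Gamma is not symmetric")
    gamma_eigs = np.linalg.eigvalsh(0.5 * (Gamma + Gamma.T))
    if gamma_eigs.min() < -atol:
        raise BlanketStructureError(
            "diffusion_psd", f"Gamma has negative eigenvalue {gamma_eigs.min()}"
        )
    return BlanketReport(True, True, True, True)


# ---------------------------------------------------------------------------
# flat key-value (YAML) serialization
# ---------------------------------------------------------------------------

def model_to_config(m: GaussianModelParams) -> dict:
    """Flatten a model to a plain key-value mapping.

    The three scalars always round-trip; the matrices are included explicitly
    so that non-canonical systems can be represented too.
    """
    return {
        "gamma": float(m.gamma),
        "theta": float(m.theta_s),
        "kappa": float(m.kappa),
        "theta_mode": m.theta_mode.tolist(),
        "hessian": m.hessian.tolist(),
        "diffusion": m.diffusion.tolist(),
        "solenoidal": m.solenoidal.tolist(),
    }


def model_from_config(config: Mapping) -> GaussianModelParams:
    """Rebuild a model from :func:`model_to_config` output.

    A config carrying only ``gamma``/``theta``/``kappa`` yields the canonical
    system; explicit matrices override the canonical construction.
    """
    gamma = float(config.get("gamma", 1.0))
    theta_s = float(config.get("theta", 1.0))
    kappa = float(config.get("kappa", 1.0))
    base = build_gaussian_model(gamma, theta_s, kappa)
    if not any(k in config for k in ("theta_mode", "hessian", "diffusion", "solenoidal")):
        return base
    return GaussianModelParams(
        theta_mode=np.asarray(config.get("theta_mode", base.theta_mode), dtype=float),
        hessian=np.asarray(config.get("hessian", base.hessian), dtype=float),
        diffusion=np.asarray(config.get("diffusion", base.diffusion), dtype=float),
        solenoidal=np.asarray(config.get("solenoidal", base.solenoidal), dtype=float),
        gamma=gamma,
        theta_s=theta_s,
        kappa=kappa,
    )


def save_model(m: GaussianModelParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_config(m), fh)


def load_model(path) -> GaussianModelParams:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))
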