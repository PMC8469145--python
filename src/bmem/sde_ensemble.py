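"""Seeded Euler–Maruyama ensemble simulation of the blanketed SDE.

The stochastic system is ``dx = f(x) dt + dW`` with linear drift
``f(x) = -(Gamma - Q) Pi (x - theta)`` and white-noise increments of
covariance ``2 Gamma dt``.  An ensemble of independent paths started from a
common point estimates the relaxing probability density; its sample moments
converge on the density dynamics of :mod:`bmem.density_dynamics` as the
number of paths grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, ShapeError, StabilityError
from .gaussian_model import GaussianModelParams, drift

__all__ = ["EnsembleTrajectories", "simulate_ensemble", "ensemble_moments"]

DEFAULT_DT = 0.01


@dataclass(frozen=True)
class EnsembleTrajectories:
    """Seeded sample paths of the SDE.

    ``paths`` has shape (n_paths, n_times, n_states); ``times`` is the
    uniform grid (including t=0) the paths are recorded on.
    """

    times: np.ndarray
    paths: np.ndarray
    seed: int
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "paths", np.asarray(self.paths, dtype=float))
        if self.paths.ndim != 3 or self.paths.shape[1] != self.times.size:
            raise ShapeError("paths must have shape (n_paths, n_times, n_states)")
        steps = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(steps, self.dt, rtol=1e-8):
            raise ParameterError("times must be uniformly spaced by dt")
        if not np.all(np.isfinite(self.paths)):
            raise ParameterError("paths contain non-finite values")

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    def index_of_time(self, t: float) -> int:
        """Nearest grid index to ``t`` (must lie within the simulated range)."""
        if t < self.times[0] - self.dt / 2 or t > self.times[-1] + self.dt / 2:
            raise ParameterError(f"time {t} outside simulated range")
        return int(np.argmin(np.abs(self.times - t)))


def _noise_transform(m: GaussianModelParams, dt: float) -> np.ndarray:
    """Matrix B with B B^T = 2 Gamma dt (symmetric PSD square root)."""
    cov = 2.0 * m.diffusion * dt
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals) @ vecs.T


def simulate_ensemble(
    m: GaussianModelParams,
    x0: np.ndarray,
    n_paths: int = 512,
    dt: float = DEFAULT_DT,
    T: float = 16.0,
    seed: int = 0,
    noise_scale: float = 1.0,
    on_unstable: str = "error",
) -> EnsembleTrajectories:
    """Euler–Maruyama ensemble from a common initial point.

    Each path iterates ``x <- x + f(x) dt + noise_scale * eps`` with
    ``eps ~ N(0, 2 Gamma dt)``.  Per-path noise streams are spawned from the
    root seed, so path *i* is identical whatever ``n_paths`` is and the same
    seed reproduces the ensemble bit-for-bit.

    The explicit update map ``I - dt (Gamma - Q) Pi`` is checked for
    stability; ``on_unstable`` chooses between ``"error"``, ``"warn"`` and
    ``"ignore"``.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if T < dt:
        raise ParameterError("horizon T must be at least dt")
    if n_paths < 1:
        raise ParameterError("n_paths must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (m.n_states,):
        raise ShapeError(f"x0 must have shape ({m.n_states},)")

    n_steps = int(round(T / dt))
    A = m.flow_operator
    update = np.eye(m.n_states) - dt * A
    radius = np.max(np.abs(np.linalg.eigvals(update)))
    if radius > 1.0 + 1e-12:
        msg = (
            f"dt={dt} is unstable for this system: spectral radius of the "
            f"Euler update map is {radius:.4f} > 1"
        )
        if on_unstable == "error":
            raise StabilityError(msg)
        if on_unstable == "warn":
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    # one independent Philox stream per path, derived from the root seed
    children = np.random.SeedSequence(seed).spawn(n_paths)
    B = _noise_transform(m, dt)
    noise = np.empty((n_paths, n_steps, m.n_states))
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.Philox(child))
        noise[i] = rng.standard_normal((n_steps, m.n_states))
    noise = noise_scale * (noise @ B.T)

    paths = np.empty((n_paths, n_steps + 1, m.n_states))
    paths[:, 0] = x0
    x = np.broadcast_to(x0, (n_paths, m.n_states)).copy()
    for k in range(n_steps):
        x = x + dt * drift(m, x) + noise[:, k]
        paths[:, k + 1] = x

    times = dt * np.arange(n_steps + 1)
    return EnsembleTrajectories(times=times, paths=paths, seed=int(seed), dt=float(dt))


def ensemble_moments(
    traj: EnsembleTrajectories, t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample mean, covariance (divisor n-1) and correlation at time ``t``.

    ``t`` is snapped to the nearest grid point.  With a single path the
    covariance is undefined and an error is raised.
    """
    if traj.n_paths < 2:
        raise ParameterError("sample covariance requires at least 2 paths")
    snap = traj.paths[:, traj.index_of_time(t), :]
    mean = snap.mean(axis=0)
    cov = np.cov(snap, rowvar=False, ddof=1)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    return mean, cov, corr
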