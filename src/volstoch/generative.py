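"""Generative processes for outcomes under dynamic volatility and stochasticity.

The latent reward rate x_t follows a Gaussian random walk whose innovation
variance is the *volatility* v_t; each observed outcome o_t is the current
rate corrupted by Gaussian noise whose variance is the *stochasticity* s_t:

    x_t = x_{t-1} + e_t,        e_t ~ N(0, v_t)
    o_t = x_t + noise,          o_t ~ N(x_t, s_t)

Both noise variances are themselves dynamic.  Two parameterizations are
supported:

* ``beta_multiplicative`` -- the inverses z_t = 1/v_t and y_t = 1/s_t follow
  multiplicative dynamics z_t = eta^{-1} z_{t-1} eps_t with
  eps_t ~ Beta(0.5 eta/(1-eta), 0.5).  Because E[eps_t] = eta the process is
  a martingale: E[z_t | z_{t-1}] = z_{t-1}.  The constant eta in (0, 1) is
  the persistence; lambda = 1 - eta acts as an update rate.
* ``gaussian_log`` -- log v_t and log s_t follow independent Gaussian random
  walks with step standard deviations sigma_v and sigma_s.

The two variances leave distinct fingerprints on the outcome series: both
inflate its marginal variance, but volatility raises the lag-1
autocorrelation of outcomes while stochasticity lowers it.  That signature
is what makes the two jointly identifiable from outcomes alone, and
:func:`lag1_autocorrelation` is the diagnostic used to check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "GenerativeParams",
    "NoiseTrajectory",
    "GeneratedSeries",
    "diffuse_inverse_beta",
    "diffuse_log_gaussian",
    "generate_series",
    "lag1_autocorrelation",
]

# Floor applied to Beta draws: shape-b = 0.5 < 1 puts density near 0, and at
# float resolution a draw can round to exactly 0, which would pin the inverse
# noise at 0 forever.  The floor is far below any draw that matters.
_EPS_FLOOR = 1e-12


@dataclass
class GenerativeParams:
    """Configuration of the generative process.

    Parameters
    ----------
    eta_v, eta_s
        Persistence of inverse volatility / inverse stochasticity in (0, 1);
        the complement ``1 - eta`` is the update rate.  Used only by the
        ``beta_multiplicative`` dynamics.
    v0, s0
        Initial volatility and stochasticity (variance units, > 0).
    x0
        Initial reward rate.  Defaults to 0, matching the zero-mean prior
        used by the learner.
    n_trials
        Number of trials to generate.
    dynamics_kind
        ``beta_multiplicative`` (Beta-distributed multiplicative noise on
        the inverse variances) or ``gaussian_log`` (Gaussian random walks
        on the log variances).
    sigma_v, sigma_s
        Random-walk step standard deviations for ``gaussian_log``.
    """

    eta_v: float = 0.9
    eta_s: float = 0.9
    v0: float = 1.0
    s0: float = 2.0
    x0: float = 0.0
    n_trials: int = 200
    dynamics_kind: Literal["beta_multiplicative", "gaussian_log"] = "beta_multiplicative"
    sigma_v: float = 0.0
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        if self.dynamics_kind not in ("beta_multiplicative", "gaussian_log"):
            raise ValueError(f"unknown dynamics_kind: {self.dynamics_kind!r}")
        if self.dynamics_kind == "beta_multiplicative":
            if not (0.0 < self.eta_v < 1.0 and 0.0 < self.eta_s < 1.0):
                raise ValueError("eta_v and eta_s must lie strictly in (0, 1)")
        if self.v0 <= 0 or self.s0 <= 0:
            raise ValueError("v0 and s0 must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.sigma_v < 0 or self.sigma_s < 0:
            raise ValueError("sigma_v and sigma_s must be nonnegative")


@dataclass
class NoiseTrajectory:
    """Per-trial volatility/stochasticity with their inverses.

    ``v = 1/z`` and ``s = 1/y`` elementwise; all entries strictly positive.
    """

    v: np.ndarray
    s: np.ndarray
    z: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.v.shape != self.s.shape:
            raise ValueError("v and s must have equal length")
        if np.any(self.v <= 0) or np.any(self.s <= 0):
            raise ValueError("all noise values must be strictly positive")
        if self.z is None:
            self.z = 1.0 / self.v
        else:
            self.z = np.asarray(self.z, dtype=float)
        if self.y is None:
            self.y = 1.0 / self.s
        else:
            self.y = np.asarray(self.y, dtype=float)

    @classmethod
    def constant(cls, v: float, s: float, n_trials: int) -> "NoiseTrajectory":
        """Constant-parameter trajectory used by the factorial designs."""
        return cls(v=np.full(n_trials, float(v)), s=np.full(n_trials, float(s)))

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class GeneratedSeries:
    """One generated episode: latent rates, outcomes, noise path, innovations."""

    x: np.ndarray
    o: np.ndarray
    noise: NoiseTrajectory
    e: np.ndarray

    def __len__(self) -> int:
        return len(self.o)


def diffuse_inverse_beta(prev_inverse: float, eta: float, rng: np.random.Generator) -> float:
    """One step of the multiplicative Beta dynamics on an inverse variance.

    Returns ``eta^{-1} * prev_inverse * eps`` with
    ``eps ~ Beta(0.5 eta / (1 - eta), 0.5)``.  Since ``E[eps] = eta`` the
    conditional expectation of the return equals ``prev_inverse``.

    ``eta == 1`` (zero update rate) is the degenerate fixed case and returns
    the input unchanged; this keeps the zero-update-rate learner exactly
    deterministic rather than relying on a Beta with infinite shape.
    """
    prev = np.asarray(prev_inverse, dtype=float)
    if np.any(prev <= 0):
        raise ValueError("prev_inverse must be positive")
    if eta == 1.0:
        return prev_inverse
    if not (0.0 < eta < 1.0):
        raise ValueError("eta must lie in (0, 1]")
    a = 0.5 * eta / (1.0 - eta)
    eps = rng.beta(a, 0.5, size=prev.shape if prev.shape else None)
    eps = np.maximum(eps, _EPS_FLOOR)
    return prev_inverse / eta * eps


def diffuse_log_gaussian(prev_log: float, sigma: float, rng: np.random.Generator) -> float:
    """One Gaussian random-walk step on a log variance."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return prev_log
    step = rng.normal(0.0, sigma, size=np.shape(prev_log) if np.ndim(prev_log) else None)
    return prev_log + step


def _evolve_noise(params: GenerativeParams, rng: np.random.Generator) -> NoiseTrajectory:
    n = params.n_trials
    z = np.empty(n)
    y = np.empty(n)
    if params.dynamics_kind == "beta_multiplicative":
        z_prev, y_prev = 1.0 / params.v0, 1.0 / params.s0
        for t in range(n):
            z_prev = diffuse_inverse_beta(z_prev, params.eta_v, rng)
            y_prev = diffuse_inverse_beta(y_prev, params.eta_s, rng)
            z[t], y[t] = z_prev, y_prev
        return NoiseTrajectory(v=1.0 / z, s=1.0 / y, z=z, y=y)
    # gaussian_log: v = exp(log-walk), so z = 1/v
    logv = np.log(params.v0) + np.cumsum(rng.normal(0.0, 1.0, n)) * params.sigma_v
    logs = np.log(params.s0) + np.cumsum(rng.normal(0.0, 1.0, n)) * params.sigma_s
    v = np.exp(logv)
    s = np.exp(logs)
    return NoiseTrajectory(v=v, s=s)


def generate_series(
    params: GenerativeParams,
    rng: np.random.Generator,
    fixed_noise: Optional[NoiseTrajectory] = None,
) -> GeneratedSeries:
    """Generate a full episode of latent rates and outcomes.

    When ``fixed_noise`` is given (the constant-parameter factorial designs)
    the noise trajectory is taken verbatim instead of evolving; it must cover
    at least ``n_trials`` entries.  Zero entries are permitted in a fixed
    trajectory to express noiseless limits.
    """
    n = params.n_trials
    if fixed_noise is not None:
        if len(fixed_noise) < n:
            raise ValueError("fixed_noise shorter than n_trials")
        # Fixed trajectories may contain exact zeros (noiseless limits), so
        # bypass the positivity validation and take reciprocals guardedly.
        v = np.asarray(fixed_noise.v[:n], dtype=float).copy()
        s = np.asarray(fixed_noise.s[:n], dtype=float).copy()
        noise = NoiseTrajectory.__new__(NoiseTrajectory)
        noise.v, noise.s = v, s
        with np.errstate(divide="ignore"):
            noise.z, noise.y = 1.0 / v, 1.0 / s
    else:
        noise = _evolve_noise(params, rng)
    e = rng.normal(0.0, 1.0, n) * np.sqrt(noise.v)
    x = params.x0 + np.cumsum(e)
    o = x + rng.normal(0.0, 1.0, n) * np.sqrt(noise.s)
    return GeneratedSeries(x=x, o=o, noise=noise, e=e)


def lag1_autocorrelation(series: Sequence[float]) -> float:
    """Pearson correlation between a series and its one-step lag.

    Raises ``ValueError`` on series shorter than 3 or with zero variance
    (the correlation is undefined there, and silently returning 0 would
    corrupt the volatility/stochasticity dissociation diagnostic).
    """
    arr = np.asarray(series, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 observations")
    a, b = arr[1:], arr[:-1]
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        raise ValueError("zero-variance series: lag-1 autocorrelation undefined")
    return float(np.corrcoef(a, b)[0, 1])
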