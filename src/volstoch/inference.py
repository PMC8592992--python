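"""The learner: conditional Kalman filter wrapped in a Rao-Blackwellized
particle filter over inverse volatility and inverse stochasticity.

Conditional on a volatility sample v and stochasticity sample s, inference
about the latent reward rate is exact and Gaussian, with posterior mean m
and variance w updated on each outcome o by the Kalman recursion

    delta = o - m
    alpha = (w + v) / (w + v + s)
    m'    = m + alpha * delta
    w'    = (1 - alpha) (w + v)

The learning rate alpha rises with volatility (the latent rate has likely
moved, so the new outcome matters more) and falls with stochasticity (the
new outcome is less informative).  Since v and s are unknown, a particle
filter tracks them: each particle carries a sample of the inverse
volatility z = 1/v and inverse stochasticity y = 1/s together with its own
conditional Kalman statistics (m, w).  Per trial the filter

1. diffuses each particle's (z, y) under the multiplicative Beta dynamics,
2. reweights particles by the predictive likelihood
   N(o | m, w + v + s) and resamples systematically when the effective
   sample size falls below a fraction of the particle count,
3. applies the Kalman update per particle.

Reported signals (learning rate, posterior mean, volatility and
stochasticity estimates) are importance-weighted ensemble averages.

Lesioned variants pin z (``fix_volatility``) or y (``fix_stochasticity``)
at a fixed value for every particle, modelling a learner unable to update
that noise estimate; surprise then gets misattributed to the remaining
free noise term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .generative import diffuse_inverse_beta

__all__ = [
    "ModelParams",
    "ParticleEnsemble",
    "FilterTrace",
    "kalman_step",
    "predict_particles",
    "weight_particles",
    "effective_sample_size",
    "systematic_resample",
    "filter_trial",
    "run_filter",
]

Lesion = Literal["none", "fix_volatility", "fix_stochasticity"]

_WEIGHT_TOL = 1e-10


@dataclass
class ModelParams:
    """Full learner configuration.

    Parameters
    ----------
    lambda_v, lambda_s
        Update rates for volatility and stochasticity in [0, 1); the
        complements ``eta = 1 - lambda`` are the persistences of the
        multiplicative dynamics.  Zero freezes the estimate.
    v0, s0
        Initial volatility and stochasticity (variance units).
    n_particles
        Ensemble size (default 100).
    prior_mean, prior_var
        Gaussian prior on the latent reward rate.
    lesion
        ``none``, ``fix_volatility`` or ``fix_stochasticity``.
    lesion_value
        Value at which the lesioned variance is pinned; defaults to ``v0``
        or ``s0`` respectively.
    ess_ratio_threshold
        Resample when ESS / n_particles falls below this (default 0.5).
    """

    lambda_v: float = 0.1
    lambda_s: float = 0.1
    v0: float = 1.0
    s0: float = 2.0
    n_particles: int = 100
    prior_mean: float = 0.0
    prior_var: float = 100.0
    lesion: Lesion = "none"
    lesion_value: Optional[float] = None
    ess_ratio_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_v < 1.0 and 0.0 <= self.lambda_s < 1.0):
            raise ValueError("lambda_v and lambda_s must lie in [0, 1)")
        if self.v0 <= 0 or self.s0 <= 0 or self.prior_var <= 0:
            raise ValueError("v0, s0 and prior_var must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.lesion not in ("none", "fix_volatility", "fix_stochasticity"):
            raise ValueError(f"unknown lesion: {self.lesion!r}")
        if not (0.0 < self.ess_ratio_threshold <= 1.0):
            raise ValueError("ess_ratio_threshold must lie in (0, 1]")
        if self.lesion_value is not None and self.lesion_value <= 0:
            raise ValueError("lesion_value must be positive")

    @property
    def fixed_v(self) -> Optional[float]:
        if self.lesion == "fix_volatility":
            return self.lesion_value if self.lesion_value is not None else self.v0
        return None

    @property
    def fixed_s(self) -> Optional[float]:
        if self.lesion == "fix_stochasticity":
            return self.lesion_value if self.lesion_value is not None else self.s0
        return None

    def to_dict(self) -> dict:
        return {
            "lambda_v": self.lambda_v,
            "lambda_s": self.lambda_s,
            "v0": self.v0,
            "s0": self.s0,
            "n_particles": self.n_particles,
            "prior_mean": self.prior_mean,
            "prior_var": self.prior_var,
            "lesion": self.lesion,
            "lesion_value": self.lesion_value,
            "ess_ratio_threshold": self.ess_ratio_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class ParticleEnsemble:
    """Vectorized particle set.

    Arrays are aligned by particle index: ``z`` (inverse volatility),
    ``y`` (inverse stochasticity), ``m``/``w`` (conditional Kalman mean and
    variance) and normalized importance ``weights``.
    """

    z: np.ndarray
    y: np.ndarray
    m: np.ndarray
    w: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.z)
        for name in ("y", "m", "w", "weights"):
            if len(getattr(self, name)) != n:
                raise ValueError("all particle arrays must have equal length")
        if np.any(self.z <= 0) or np.any(self.y <= 0) or np.any(self.w < 0):
            raise ValueError("z, y must be positive and w nonnegative")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("weights must be normalized")

    @classmethod
    def initial(cls, params: ModelParams) -> "ParticleEnsemble":
        """All particles start at (1/v0, 1/s0) with the Gaussian rate prior.

        Starting from a point mass makes the zero-update-rate filter
        collapse exactly onto the fixed-hyperparameter Kalman filter.
        """
        n = params.n_particles
        v_init = params.fixed_v if params.fixed_v is not None else params.v0
        s_init = params.fixed_s if params.fixed_s is not None else params.s0
        return cls(
            z=np.full(n, 1.0 / v_init),
            y=np.full(n, 1.0 / s_init),
            m=np.full(n, float(params.prior_mean)),
            w=np.full(n, float(params.prior_var)),
            weights=np.full(n, 1.0 / n),
        )

    @property
    def n(self) -> int:
        return len(self.z)

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(
            z=self.z.copy(), y=self.y.copy(), m=self.m.copy(),
            w=self.w.copy(), weights=self.weights.copy(),
        )


@dataclass
class FilterTrace:
    """Per-trial record of the filter's reported signals."""

    outcomes: np.ndarray
    m: np.ndarray
    w: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    v_hat: np.ndarray
    s_hat: np.ndarray
    ess: np.ndarray
    resampled: np.ndarray

    def __len__(self) -> int:
        return len(self.m)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table (trial is 1-based)."""
        return pd.DataFrame({
            "trial": np.arange(1, len(self) + 1),
            "outcome": self.outcomes,
            "m": self.m,
            "w": self.w,
            "alpha": self.alpha,
            "delta": self.delta,
            "v_hat": self.v_hat,
            "s_hat": self.s_hat,
            "ess": self.ess,
            "resampled": self.resampled,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def kalman_step(
    m: float, w: float, v: float, s: float, o: float
) -> Tuple[float, float, float, float]:
    """One Kalman update with known noise variances.

    Returns ``(m_next, w_next, alpha, delta)``.  The posterior variance is
    computed as ``s (w+v) / (w+v+s)``, algebraically equal to
    ``(1-alpha)(w+v)`` but immune to cancellation when alpha is close to 1.
    """
    total = w + v + s
    if np.ndim(total) == 0:
        if total <= 0:
            raise ValueError("degenerate input: w + v + s must be positive")
    elif np.any(np.asarray(total) <= 0):
        raise ValueError("degenerate input: w + v + s must be positive")
    delta = o - m
    alpha = (w + v) / total
    m_next = m + alpha * delta
    w_next = s * (w + v) / total
    return m_next, w_next, alpha, delta


def predict_particles(
    ensemble: ParticleEnsemble, params: ModelParams, rng: np.random.Generator
) -> ParticleEnsemble:
    """Diffuse each particle's noise samples one step; weights unchanged.

    A lesioned variable is left pinned; a zero update rate likewise leaves
    the corresponding sample untouched (eta = 1 is deterministic).
    """
    out = ensemble.copy()
    if params.fixed_v is None and params.lambda_v > 0:
        out.z = diffuse_inverse_beta(out.z, 1.0 - params.lambda_v, rng)
    if params.fixed_s is None and params.lambda_s > 0:
        out.y = diffuse_inverse_beta(out.y, 1.0 - params.lambda_s, rng)
    return out


def weight_particles(ensemble: ParticleEnsemble, o: float) -> np.ndarray:
    """Update importance weights by the predictive outcome likelihood.

    Each particle's predictive density is N(o | m, w + v + s) with
    v = 1/z and s = 1/y; the new weight is the prior weight times that
    density, renormalized.  Computation is done in log space; if every
    product underflows to zero the weights fall back to uniform with a
    warning rather than propagating NaNs.
    """
    var = ensemble.w + 1.0 / ensemble.z + 1.0 / ensemble.y
    if np.any(var <= 0):
        raise ValueError("nonpositive predictive variance")
    with np.errstate(over="ignore"):
        logdens = -0.5 * (np.log(2.0 * np.pi * var) + (o - ensemble.m) ** 2 / var)
    with np.errstate(divide="ignore"):
        logw = np.where(ensemble.weights > 0, np.log(ensemble.weights), -np.inf) + logdens
    mx = np.max(logw)
    if not np.isfinite(mx):
        warnings.warn("all particle weights underflowed; falling back to uniform")
        return np.full(ensemble.n, 1.0 / ensemble.n)
    w = np.exp(logw - mx)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size ``1 / sum(w_i^2)`` of normalized weights."""
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    return float(1.0 / np.sum(weights ** 2))


def systematic_resample(
    ensemble: ParticleEnsemble, rng: np.random.Generator
) -> ParticleEnsemble:
    """Systematic resampling: one uniform offset, a comb of N strata.

    Offspring counts of particle i differ from ``N * weight_i`` by less
    than 1.  Output weights are uniform.
    """
    n = ensemble.n
    u = rng.uniform(0.0, 1.0 / n)
    positions = u + np.arange(n) / n
    cumulative = np.cumsum(ensemble.weights)
    cumulative[-1] = 1.0  # guard against roundoff excluding the last stratum
    idx = np.searchsorted(cumulative, positions, side="left")
    return ParticleEnsemble(
        z=ensemble.z[idx],
        y=ensemble.y[idx],
        m=ensemble.m[idx],
        w=ensemble.w[idx],
        weights=np.full(n, 1.0 / n),
    )


def filter_trial(
    ensemble: ParticleEnsemble,
    o: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> Tuple[ParticleEnsemble, dict]:
    """One trial of the Rao-Blackwellized particle filter.

    Order: predict -> weight -> (resample if ESS ratio below threshold) ->
    per-particle Kalman update.  Reported signals are weighted ensemble
    averages taken with the weights as they stand after the conditional
    resampling step (uniform whenever resampling fired).
    """
    ens = predict_particles(ensemble, params, rng)
    ens.weights = weight_particles(ens, o)
    ess = effective_sample_size(ens.weights)
    resampled = ess / ens.n < params.ess_ratio_threshold
    if resampled:
        ens = systematic_resample(ens, rng)
    v = 1.0 / ens.z
    s = 1.0 / ens.y
    m_next, w_next, alpha, delta = kalman_step(ens.m, ens.w, v, s, o)
    ens.m = np.asarray(m_next)
    ens.w = np.asarray(w_next)
    b = ens.weights
    record = {
        "m": float(b @ ens.m),
        "w": float(b @ ens.w),
        "alpha": float(b @ alpha),
        "delta": float(b @ delta),
        "v_hat": float(b @ v),
        "s_hat": float(b @ s),
        "ess": ess,
        "resampled": bool(resampled),
    }
    return ens, record


def run_filter(
    outcomes: Sequence[float],
    params: ModelParams,
    seed: int | np.random.Generator = 0,
) -> FilterTrace:
    """Run the filter over an outcome sequence.

    Deterministic given (outcomes, params, seed): a single seeded stream
    drives prediction draws and resampling offsets in trial order.
    A ``numpy.random.Generator`` may be passed directly in place of a seed.
    """
    o = np.asarray(outcomes, dtype=float)
    if o.size == 0:
        raise ValueError("outcomes must be nonempty")
    bad = np.flatnonzero(~np.isfinite(o))
    if bad.size:
        raise ValueError(f"non-finite outcome at trial {bad[0] + 1}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ens = ParticleEnsemble.initial(params)
    n = o.size
    trace = FilterTrace(
        outcomes=o,
        m=np.empty(n), w=np.empty(n), alpha=np.empty(n), delta=np.empty(n),
        v_hat=np.empty(n), s_hat=np.empty(n), ess=np.empty(n),
        resampled=np.zeros(n, dtype=bool),
    )
    for t in range(n):
        ens, rec = filter_trial(ens, o[t], params, rng)
        trace.m[t] = rec["m"]
        trace.w[t] = rec["w"]
        trace.alpha[t] = rec["alpha"]
        trace.delta[t] = rec["delta"]
        trace.v_hat[t] = rec["v_hat"]
        trace.s_hat[t] = rec["s_hat"]
        trace.ess[t] = rec["ess"]
        trace.resampled[t] = rec["resampled"]
    return trace
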