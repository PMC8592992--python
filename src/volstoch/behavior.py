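"""Choice/response mappings and behavioral summary statistics.

Values learned by the filter are mapped to responses with a softmax whose
inverse-temperature ``beta`` is the decision-noise parameter.  The summary
statistics here (win-stay/lose-shift, relative log learning rate, windowed
means/medians) are the quantities the simulated experiments report.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import expit

from .inference import FilterTrace

__all__ = [
    "softmax_probs",
    "response_prob",
    "win_stay_lose_shift",
    "WSLSResult",
    "relative_log_learning_rate",
    "summarize_window",
]


def softmax_probs(values: Sequence[float], beta: float) -> np.ndarray:
    """Softmax choice probabilities: p_i proportional to exp(beta * v_i).

    ``beta = 0`` gives uniform choice; large ``beta`` approaches argmax.
    Invariant to adding a constant to all values.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    z = beta * (v - v.max())
    e = np.exp(z)
    return e / e.sum()


def response_prob(value: float, beta: float) -> float:
    """Probability of responding to a single cue: logistic in the value.

    Implemented as the two-option softmax of (value, 0), i.e.
    ``1 / (1 + exp(-beta * value))``.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    return float(expit(beta * float(value)))


class WSLSResult(NamedTuple):
    win_stay: Optional[float]
    lose_shift: Optional[float]
    combined: Optional[float]


def win_stay_lose_shift(
    choices: Sequence[int],
    rewards: Sequence[float],
    win_threshold: float = 0.5,
) -> WSLSResult:
    """Win-stay and lose-shift rates of a choice sequence.

    A trial counts as a win when its reward exceeds ``win_threshold``
    (rewards may carry small additive noise around 0/1).  Rates condition
    on the *previous* trial's outcome; a component with no qualifying
    trials is ``None`` rather than 0.  ``combined`` is the
    frequency-weighted mean of the two rates.
    """
    c = np.asarray(choices)
    r = np.asarray(rewards, dtype=float)
    if c.size != r.size:
        raise ValueError("choices and rewards must align")
    if c.size < 2:
        raise ValueError("need at least 2 trials")
    stay = c[1:] == c[:-1]
    win = r[:-1] > win_threshold
    n_win = int(win.sum())
    n_loss = int((~win).sum())
    ws = float(stay[win].mean()) if n_win else None
    ls = float((~stay[~win]).mean()) if n_loss else None
    if ws is None or ls is None:
        combined = None
    else:
        combined = (ws * n_win + ls * n_loss) / (n_win + n_loss)
    return WSLSResult(ws, ls, combined)


def relative_log_learning_rate(
    trace: FilterTrace, block_labels: Sequence[str],
    volatile_label: str = "volatile", stable_label: str = "stable",
) -> float:
    """Mean log learning rate in volatile trials minus that in stable trials.

    Positive values mean the learner speeds up under volatility; the
    contrast shrinks (or reverses) when stochasticity updating is impaired.
    """
    labels = np.asarray(block_labels)
    if labels.size != len(trace):
        raise ValueError("block_labels must align with the trace")
    vol = labels == volatile_label
    sta = labels == stable_label
    if not vol.any() or not sta.any():
        raise ValueError("both volatile and stable labels must be present")
    log_alpha = np.log(trace.alpha)
    return float(log_alpha[vol].mean() - log_alpha[sta].mean())


def summarize_window(
    trace: FilterTrace, field: str, window: Sequence[int], use_median: bool = False
) -> float:
    """Mean (or median) of a trace field over a set of trial indices.

    ``window`` holds 0-based trial indices; out-of-range indices raise.
    """
    idx = np.asarray(window, dtype=int)
    if idx.size == 0:
        raise ValueError("window must be nonempty")
    values = np.asarray(getattr(trace, field), dtype=float)
    if idx.min() < 0 or idx.max() >= values.size:
        raise ValueError("window indices out of range")
    sel = values[idx]
    return float(np.median(sel) if use_median else np.mean(sel))
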