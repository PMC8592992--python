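"""Outcome schedules for the simulated experiment battery.

Each constructor returns a :class:`TaskEpisode` holding the per-trial
outcome(s), the true latent reward rate(s), phase labels and any
choice-task bookkeeping (which option was correct).  Single-cue tasks emit
one outcome per trial; choice tasks emit the potential outcome of every
option and leave it to the experiment runner to decide what the learner
observes.

Constructors are deterministic given their ``rng`` and record their full
parameterization in ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .generative import GenerativeParams, NoiseTrajectory, generate_series

__all__ = [
    "TaskEpisode",
    "make_constant_2x2",
    "make_switching_task",
    "make_conditioned_suppression",
    "make_partial_reinforcement",
    "make_serial_prediction",
    "make_reversal_task",
    "make_changepoint_task",
    "make_two_choice_task",
    "label_switch_window",
]


@dataclass
class TaskEpisode:
    """A generated task episode.

    ``outcomes`` has shape (n_trials,) for single-cue tasks and
    (n_trials, n_channels) for multi-channel / choice tasks, aligned with
    ``reward_rate_true``.  ``phase`` labels partition the trials.
    """

    outcomes: np.ndarray
    reward_rate_true: np.ndarray
    phase: np.ndarray
    correct_option: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.reward_rate_true = np.asarray(self.reward_rate_true, dtype=float)
        self.phase = np.asarray(self.phase)
        n = self.outcomes.shape[0]
        if self.reward_rate_true.shape[0] != n or self.phase.shape[0] != n:
            raise ValueError("outcomes, reward_rate_true and phase must align")
        if self.correct_option is not None:
            self.correct_option = np.asarray(self.correct_option)
            if self.correct_option.shape[0] != n:
                raise ValueError("correct_option must align with outcomes")

    @property
    def n_trials(self) -> int:
        return self.outcomes.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.outcomes.ndim == 1 else self.outcomes.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (trial, channel)."""
        o = np.atleast_2d(self.outcomes.T).T
        r = np.atleast_2d(self.reward_rate_true.T).T
        rows = []
        for ch in range(o.shape[1]):
            rows.append(pd.DataFrame({
                "trial": np.arange(1, self.n_trials + 1),
                "channel": ch,
                "outcome": o[:, ch],
                "rate_true": r[:, ch] if r.shape[1] > 1 else r[:, 0],
                "phase": self.phase,
                "correct_option": (
                    self.correct_option if self.correct_option is not None
                    else np.full(self.n_trials, -1)
                ),
            }))
        return pd.concat(rows, ignore_index=True)


def make_constant_2x2(
    v_true: float,
    s_true: float,
    n_trials: int = 200,
    rng: np.random.Generator | int = 0,
    x0: float = 0.0,
) -> TaskEpisode:
    """Diffusing-rate task with constant (but unknown to the learner)
    volatility and stochasticity — one cell of the factorial design.

    The canonical small/large values are v in {0.5, 1.5} and s in {1, 3}.
    """
    if v_true <= 0 or s_true <= 0:
        raise ValueError("v_true and s_true must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = GenerativeParams(v0=v_true, s0=s_true, x0=x0, n_trials=n_trials)
    series = generate_series(
        params, rng, fixed_noise=NoiseTrajectory.constant(v_true, s_true, n_trials)
    )
    return TaskEpisode(
        outcomes=series.o,
        reward_rate_true=series.x,
        phase=np.full(n_trials, "constant"),
        meta={"task": "constant_2x2", "v_true": v_true, "s_true": s_true,
              "n_trials": n_trials, "x0": x0},
    )


def make_switching_task(
    rng: np.random.Generator | int = 0,
    stable_rate: float = 0.8,
    volatile_rates: tuple = (0.25, 0.75),
    block_lengths: Sequence[int] = (90, 90),
    block_order: Sequence[str] = ("stable", "volatile"),
    switch_every: int = 15,
    outcome_var: float = 0.01,
) -> TaskEpisode:
    """Probabilistic switching task with stable and volatile blocks.

    The true rate is constant at ``stable_rate`` in stable blocks and
    alternates between the two ``volatile_rates`` every ``switch_every``
    trials in volatile blocks.  Outcomes are the rate plus Gaussian noise
    (not binary).  Default block structure: a 90-trial stable block
    followed by a 90-trial volatile block.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(block_lengths) != len(block_order):
        raise ValueError("block_lengths and block_order must align")
    rates, phases, switches = [], [], []
    for L, kind in zip(block_lengths, block_order):
        if kind == "stable":
            rates.extend([stable_rate] * L)
            switches.extend([False] * L)
        elif kind == "volatile":
            lo, hi = volatile_rates
            cur = hi
            for t in range(L):
                if t > 0 and t % switch_every == 0:
                    cur = lo if cur == hi else hi
                    switches.append(True)
                else:
                    switches.append(False)
                rates.append(cur)
        else:
            raise ValueError(f"unknown block kind: {kind!r}")
        phases.extend([kind] * L)
    rates = np.asarray(rates)
    n = len(rates)
    outcomes = rates + rng.normal(0.0, np.sqrt(outcome_var), n)
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=np.asarray(phases),
        meta={"task": "switching", "stable_rate": stable_rate,
              "volatile_rates": tuple(volatile_rates),
              "block_lengths": tuple(block_lengths),
              "block_order": tuple(block_order),
              "switch_every": switch_every, "outcome_var": outcome_var,
              "switch_trials": np.flatnonzero(switches).tolist()},
    )


def label_switch_window(switch_trials: Sequence[int], n_trials: int, window: int = 10) -> np.ndarray:
    """Classify trials by recency of a contingency switch.

    A trial is labeled ``"stable"`` when no switch occurred in its preceding
    ``window`` trials and ``"volatile"`` otherwise.  The window-based
    labeling is exposed as a parameterized classifier because block
    boundaries and switch recency give slightly different partitions.
    """
    recent = np.zeros(n_trials, dtype=bool)
    for st in switch_trials:
        recent[st: st + window + 1] = True
    return np.where(recent, "volatile", "stable")


def make_conditioned_suppression(
    condition: Literal["omission", "control"],
    rng: np.random.Generator | int = 0,
    n_pretrain: int = 100,
    n_omission: int = 5,
    n_retrain: int = 20,
    weak: float = 0.3,
    strong: float = 1.0,
    outcome_var: float = 1e-2,
) -> TaskEpisode:
    """Conditioned-suppression design: weak-shock pretraining, optional
    surprise omissions, then strong-shock retraining.

    Pretraining pairs the cue with a weak outcome (0.3); in the omission
    condition the last ``n_omission`` pretraining trials deliver nothing
    (outcome 0).  Retraining delivers the strong outcome (1).  Small
    Gaussian noise (variance 1e-2) is added throughout.
    """
    if condition not in ("omission", "control"):
        raise ValueError(f"unknown condition: {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rates = np.concatenate([
        np.full(n_pretrain, weak),
        np.full(n_retrain, strong),
    ])
    phases = np.concatenate([
        np.full(n_pretrain, "pretraining"),
        np.full(n_retrain, "retraining"),
    ])
    if condition == "omission":
        rates[n_pretrain - n_omission: n_pretrain] = 0.0
        phases[n_pretrain - n_omission: n_pretrain] = "omission"
    outcomes = rates + rng.normal(0.0, np.sqrt(outcome_var), rates.size)
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=phases,
        meta={"task": "conditioned_suppression", "condition": condition,
              "n_pretrain": n_pretrain, "n_omission": n_omission,
              "n_retrain": n_retrain, "weak": weak, "strong": strong,
              "outcome_var": outcome_var,
              "first_retraining_trial": n_pretrain},
    )


def make_partial_reinforcement(
    condition: Literal["partial", "full"],
    rng: np.random.Generator | int = 0,
    n_pretrain: int = 100,
    n_extinction: int = 20,
    p_reward: float = 0.5,
    outcome_var: float = 1e-4,
) -> TaskEpisode:
    """Partial-reinforcement extinction design.

    Pretraining rewards the cue on every trial (``full``) or on a random
    half of trials (``partial``); the test phase is extinction (reward 0).
    A tiny Gaussian noise (variance 1e-4) is added.
    """
    if condition not in ("partial", "full"):
        raise ValueError(f"unknown condition: {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if condition == "full":
        pre = np.ones(n_pretrain)
    else:
        pre = np.zeros(n_pretrain)
        k = int(round(p_reward * n_pretrain))
        pre[rng.choice(n_pretrain, size=k, replace=False)] = 1.0
    rates = np.concatenate([pre, np.zeros(n_extinction)])
    phases = np.concatenate([
        np.full(n_pretrain, "pretraining"),
        np.full(n_extinction, "extinction"),
    ])
    outcomes = rates + rng.normal(0.0, np.sqrt(outcome_var), rates.size)
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=phases,
        meta={"task": "partial_reinforcement", "condition": condition,
              "n_pretrain": n_pretrain, "n_extinction": n_extinction,
              "p_reward": p_reward, "outcome_var": outcome_var,
              "first_extinction_trial": n_pretrain},
    )


def make_serial_prediction(
    condition: Literal["consistent", "shift"],
    rng: np.random.Generator | int = 0,
    n_phase1: int = 200,
    n_phase2: int = 80,
    outcome_var: float = 1e-6,
) -> TaskEpisode:
    """Serial prediction task with two outcome channels per trial:
    tone-given-light (channel 0) and reward-given-light (channel 1).

    Phase 1 (both conditions): the light is always followed by the tone
    (contingency 1) and rewarded on half of trials (contingency 0.5).
    Phase 2 (shorter): the ``consistent`` condition continues the same
    schedule; under ``shift`` the tone follows the light on only half of
    trials (light-tone-reward on half, light-nothing on the other half),
    dropping the tone contingency from 1 to 0.5 while leaving the reward
    contingency at 0.5.  Outcomes report the scheduled contingencies plus
    a very small Gaussian noise (variance 1e-6) rather than trial-wise
    binary events, so a contingency shift is experienced as an abrupt
    level change.
    """
    if condition not in ("consistent", "shift"):
        raise ValueError(f"unknown condition: {condition!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tone2_rate = 1.0 if condition == "consistent" else 0.5
    rates = np.column_stack([
        np.concatenate([np.ones(n_phase1), np.full(n_phase2, tone2_rate)]),
        np.full(n_phase1 + n_phase2, 0.5),
    ])
    outcomes = rates + rng.normal(0.0, np.sqrt(outcome_var), rates.shape)
    phases = np.concatenate([
        np.full(n_phase1, "phase1"), np.full(n_phase2, "phase2"),
    ])
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=phases,
        meta={"task": "serial_prediction", "condition": condition,
              "n_phase1": n_phase1, "n_phase2": n_phase2,
              "outcome_var": outcome_var,
              "probe_trial": n_phase1 + n_phase2 - 1},
    )


_REVERSAL_SCHEDULES = {
    "deterministic_100_0": (1.0, 0.0),
    "stochastic_80_20": (0.8, 0.2),
    "stochastic_70_30": (0.7, 0.3),
    "stochastic_60_40": (0.6, 0.4),
}


def make_reversal_task(
    schedule: str = "deterministic_100_0",
    rng: np.random.Generator | int = 0,
    n_trials: int = 80,
    reversal_range: tuple = (30, 50),
    outcome_var: float = 1e-6,
) -> TaskEpisode:
    """Two-option probabilistic reversal learning (80 trials).

    Option 0 is rewarded with the schedule's high probability and option 1
    with the low one until a reversal on a trial drawn uniformly from
    ``reversal_range``; after the reversal the contingencies swap.
    Schedules: 100%/0% (deterministic), 80%/20%, 70%/30%, 60%/40%.
    Rewards are binary plus a tiny Gaussian noise (variance 1e-6).
    """
    if schedule not in _REVERSAL_SCHEDULES:
        raise ValueError(
            f"unknown schedule {schedule!r}; available: {sorted(_REVERSAL_SCHEDULES)}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p_hi, p_lo = _REVERSAL_SCHEDULES[schedule]
    rev = int(rng.integers(reversal_range[0], reversal_range[1] + 1))
    rates = np.empty((n_trials, 2))
    rates[:rev] = (p_hi, p_lo)
    rates[rev:] = (p_lo, p_hi)
    rewards = (rng.uniform(size=(n_trials, 2)) < rates).astype(float)
    outcomes = rewards + rng.normal(0.0, np.sqrt(outcome_var), (n_trials, 2))
    correct = np.where(np.arange(n_trials) < rev, 0, 1)
    phases = np.where(np.arange(n_trials) < rev, "acquisition", "reversal")
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=phases,
        correct_option=correct,
        meta={"task": "reversal", "schedule": schedule, "n_trials": n_trials,
              "reversal_trial": rev, "reversal_range": tuple(reversal_range),
              "outcome_var": outcome_var},
    )


def make_changepoint_task(
    noise_level: Literal["small", "large"] = "small",
    n_trials: int = 200,
    rng: np.random.Generator | int = 0,
    rate_range: tuple = (0.0, 10.0),
    hazard_rate: float = 0.05,
    min_run: int = 5,
) -> TaskEpisode:
    """Piecewise-constant prediction task with abrupt change points.

    The latent rate is redrawn uniformly in ``rate_range`` at each change
    point; run lengths are ``min_run`` plus an exponential draw with the
    given rate (mean 20), rounded up to an integer, so every run lasts at
    least ``min_run`` trials.  Outcome noise variance is 1 (``small``) or
    9 (``large``).
    """
    if noise_level not in ("small", "large"):
        raise ValueError(f"unknown noise_level: {noise_level!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    noise_var = 1.0 if noise_level == "small" else 9.0
    rates = np.empty(n_trials)
    changepoints = []
    t = 0
    seg = 0
    while t < n_trials:
        run = min_run + int(np.ceil(rng.exponential(1.0 / hazard_rate)))
        rate = rng.uniform(*rate_range)
        end = min(t + run, n_trials)
        rates[t:end] = rate
        if t > 0:
            changepoints.append(t)
        t = end
        seg += 1
    outcomes = rates + rng.normal(0.0, np.sqrt(noise_var), n_trials)
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=np.full(n_trials, noise_level),
        meta={"task": "changepoint", "noise_level": noise_level,
              "noise_var": noise_var, "n_trials": n_trials,
              "rate_range": tuple(rate_range), "hazard_rate": hazard_rate,
              "min_run": min_run, "changepoints": changepoints},
    )


def make_two_choice_task(
    rng: np.random.Generator | int = 0,
    p_rewards: tuple = (0.75, 0.25),
    block_length: int = 20,
    n_blocks: int = 8,
    outcome_var: float = 0.01,
) -> TaskEpisode:
    """Two-option probabilistic task with block-wise contingency switches.

    Option reward probabilities swap every ``block_length`` trials.
    Outcomes are Bernoulli rewards plus Gaussian noise (variance 0.01).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_trials = block_length * n_blocks
    p_hi, p_lo = p_rewards
    rates = np.empty((n_trials, 2))
    correct = np.empty(n_trials, dtype=int)
    switch_trials = []
    for b in range(n_blocks):
        sl = slice(b * block_length, (b + 1) * block_length)
        if b % 2 == 0:
            rates[sl] = (p_hi, p_lo)
            correct[sl] = 0
        else:
            rates[sl] = (p_lo, p_hi)
            correct[sl] = 1
        if b > 0:
            switch_trials.append(b * block_length)
    rewards = (rng.uniform(size=(n_trials, 2)) < rates).astype(float)
    outcomes = rewards + rng.normal(0.0, np.sqrt(outcome_var), (n_trials, 2))
    phases = label_switch_window(switch_trials, n_trials)
    return TaskEpisode(
        outcomes=outcomes,
        reward_rate_true=rates,
        phase=phases,
        correct_option=correct,
        meta={"task": "two_choice", "p_rewards": tuple(p_rewards),
              "block_length": block_length, "n_blocks": n_blocks,
              "outcome_var": outcome_var, "switch_trials": switch_trials},
    )
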