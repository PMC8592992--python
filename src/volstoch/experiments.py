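"""Orchestration of model x task x replication sweeps.

Each registered experiment reproduces one simulated design at a
configurable scale: the factorial noise designs, the Pavlovian
conditioning experiments, the anxiety simulations (lesioned model and
continuous trait cohort), the amygdala-lesion serial-prediction and
reversal tasks, and the change-point prediction task.  Results come back
as a tidy table with one row per (simulation, group, condition, statistic)
so that raw per-simulation values are always retained alongside any
aggregate.

Reproducibility: per-replication random generators are derived as
``SeedSequence([config.seed, replication_index])`` (with extra indices for
subjects or channels where applicable), then split into independent task
and filter streams, so reruns with the same config are bit-identical and
individual replications can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import (
    softmax_probs,
    summarize_window,
    win_stay_lose_shift,
)
from .generative import lag1_autocorrelation
from .inference import (
    FilterTrace,
    ModelParams,
    ParticleEnsemble,
    filter_trial,
    predict_particles,
    run_filter,
)
from .tasks import (
    TaskEpisode,
    label_switch_window,
    make_changepoint_task,
    make_conditioned_suppression,
    make_constant_2x2,
    make_partial_reinforcement,
    make_reversal_task,
    make_serial_prediction,
    make_switching_task,
    make_two_choice_task,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "CohortSpec",
    "run_experiment",
    "run_choice_experiment",
    "run_choice_episode",
    "run_coupled_choice_episode",
    "run_anxiety_cohort",
    "aggregate",
    "EXPERIMENT_REGISTRY",
]

# Replication counts: scaled-down defaults for routine runs, and the full
# counts used by the original simulations behind the ``full`` flag.
_DEFAULT_N_SIMS = {
    "fig1": 1000, "fig2": 200, "fig3": 200, "fig4": 1000,
    "fig5": 200, "fig6": 100, "fig7": 200, "fig8": 200,
    "supp_changepoint": 200,
}
_FULL_N_SIMS = {
    "fig1": 10_000, "fig2": 10_000, "fig3": 10_000, "fig4": 40_000,
    "fig5": 1000, "fig6": 1000, "fig7": 40_000, "fig8": 1000,
    "supp_changepoint": 10_000,
}

_2X2_CONDITIONS = [(0.5, 1.0), (0.5, 3.0), (1.5, 1.0), (1.5, 3.0)]


@dataclass
class ExperimentConfig:
    """Configuration of one registered experiment.

    ``overrides`` are experiment-specific knobs (e.g. model-parameter
    overrides per group, decision noise, task sizes); unknown keys raise
    inside the experiment runner.
    """

    name: str
    n_sims: Optional[int] = None
    n_particles: int = 100
    seed: int = 0
    full: bool = False
    overrides: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_REGISTRY:
            raise ValueError(
                f"unknown experiment {self.name!r}; available: "
                f"{sorted(EXPERIMENT_REGISTRY)}"
            )
        if self.n_sims is not None and self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")

    @property
    def resolved_n_sims(self) -> int:
        if self.n_sims is not None:
            return self.n_sims
        return _FULL_N_SIMS[self.name] if self.full else _DEFAULT_N_SIMS[self.name]

    def to_dict(self) -> dict:
        return {
            "name": self.name, "n_sims": self.resolved_n_sims,
            "n_particles": self.n_particles, "seed": self.seed,
            "full": self.full, "overrides": dict(self.overrides),
        }


@dataclass
class ExperimentResult:
    """Tidy per-simulation table plus the config that produced it."""

    table: pd.DataFrame
    config: dict

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CohortSpec:
    """Synthetic cohort for the continuous trait-anxiety simulation.

    Trait anxiety is the ratio of volatility to stochasticity update rates.
    Each set holds ``subjects_per_set`` subjects split evenly across the
    ``trait_means`` subsets; traits are drawn uniformly around each subset
    mean (half-width the distance to the nearer bound, so the subset mean
    is honored) and truncated to ``trait_bounds``.  The volatility update
    rate is uniform on ``lambda_v_range`` and the stochasticity update rate
    follows from the trait.
    """

    n_sets: int = 1000
    subjects_per_set: int = 30
    trait_means: Sequence[float] = (0.5, 1.0, 3.0)
    trait_bounds: Sequence[float] = (0.26, 4.0)
    lambda_v_range: Sequence[float] = (0.0, 0.2)
    v0: float = 0.001
    s0: float = 0.001

    def __post_init__(self) -> None:
        if self.subjects_per_set % len(self.trait_means) != 0:
            raise ValueError("subjects_per_set must divide evenly across subsets")


def _rng_pair(seed: int, *indices: int):
    """Derive independent (task, filter) generators for one replication."""
    children = np.random.SeedSequence([int(seed)] + [int(i) for i in indices]).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _rows(sim, group, condition, stats_dict, seed):
    return [
        {"sim": sim, "group": group, "condition": condition,
         "statistic": k, "value": v, "seed": seed}
        for k, v in stats_dict.items()
    ]


def _last_k_idx(n: int, k: int = 20) -> np.ndarray:
    return np.arange(max(0, n - k), n)


# --------------------------------------------------------------------------
# registered experiments
# --------------------------------------------------------------------------

def _run_fig1(config: ExperimentConfig) -> pd.DataFrame:
    """Generative signatures: outcome variance and lag-1 autocorrelation
    across the 2x2 volatility/stochasticity factorial."""
    n_trials = config.overrides.get("n_trials", 200)
    rows = []
    for v_true, s_true in _2X2_CONDITIONS:
        cond = f"v={v_true},s={s_true}"
        for i in range(config.resolved_n_sims):
            task_rng, _ = _rng_pair(config.seed, i, int(10 * v_true), int(10 * s_true))
            ep = make_constant_2x2(v_true, s_true, n_trials=n_trials, rng=task_rng)
            stats_dict = {
                "outcome_var": float(np.var(ep.outcomes, ddof=1)),
                "lag1_autocorr": lag1_autocorrelation(ep.outcomes),
            }
            rows.extend(_rows(i, "generative", cond, stats_dict, config.seed))
    return pd.DataFrame(rows)


def _model_2x2(config: ExperimentConfig, lesion: str = "none") -> ModelParams:
    return ModelParams(
        lambda_v=0.1, lambda_s=0.1, v0=1.0, s0=2.0,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=100.0,
        lesion=lesion,
    )


def _run_2x2_recovery(config: ExperimentConfig, groups: Dict[str, ModelParams]) -> pd.DataFrame:
    n_trials = config.overrides.get("n_trials", 200)
    window = config.overrides.get("window", 20)
    rows = []
    for v_true, s_true in _2X2_CONDITIONS:
        cond = f"v={v_true},s={s_true}"
        for i in range(config.resolved_n_sims):
            task_rng, _ = _rng_pair(config.seed, i, int(10 * v_true), int(10 * s_true))
            ep = make_constant_2x2(v_true, s_true, n_trials=n_trials, rng=task_rng)
            for g_idx, (gname, params) in enumerate(groups.items()):
                _, filt_rng = _rng_pair(
                    config.seed, i, int(10 * v_true), int(10 * s_true), g_idx
                )
                trace = run_filter(ep.outcomes, params, filt_rng)
                idx = _last_k_idx(len(trace), window)
                stats_dict = {
                    "alpha": summarize_window(trace, "alpha", idx),
                    "v_hat": summarize_window(trace, "v_hat", idx),
                    "s_hat": summarize_window(trace, "s_hat", idx),
                }
                rows.extend(_rows(i, gname, cond, stats_dict, config.seed))
    return pd.DataFrame(rows)


def _run_fig2(config: ExperimentConfig) -> pd.DataFrame:
    """Joint recovery of constant volatility and stochasticity: last-20-trial
    learning rate and noise estimates across the 2x2 design."""
    return _run_2x2_recovery(config, {"healthy": _model_2x2(config)})


def _run_fig3(config: ExperimentConfig) -> pd.DataFrame:
    """Lesioned variants on the 2x2 design: fixing one noise estimate
    reverses the learning-rate effect of the other factor."""
    wanted = config.overrides.get(
        "groups", ("healthy", "fix_stochasticity", "fix_volatility")
    )
    groups = {name: _model_2x2(config, lesion="none" if name == "healthy" else name)
              for name in wanted}
    return _run_2x2_recovery(config, groups)


def _conditioning_model(config: ExperimentConfig) -> ModelParams:
    return ModelParams(
        lambda_v=0.2, lambda_s=0.2, v0=0.1, s0=0.1,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=1.0,
    )


def _run_fig4(config: ExperimentConfig) -> pd.DataFrame:
    """Pavlovian conditioning: surprise omissions raise inferred volatility
    and speed relearning; partial reinforcement raises inferred
    stochasticity and slows extinction."""
    params = _conditioning_model(config)
    # The probe is the learner state carried into retraining/extinction:
    # the trace entry after the last pretraining outcome, i.e. the gain and
    # noise estimates the agent brings to the first retraining trial,
    # before that trial's own (surprising) outcome reweights the ensemble.
    probe_offset = config.overrides.get("probe_offset", -1)
    rows = []
    designs = [
        ("suppression", make_conditioned_suppression, ("omission", "control"),
         "first_retraining_trial"),
        ("partial_reinforcement", make_partial_reinforcement, ("partial", "full"),
         "first_extinction_trial"),
    ]
    for d_idx, (dname, ctor, conditions, probe_key) in enumerate(designs):
        for c_idx, condition in enumerate(conditions):
            for i in range(config.resolved_n_sims):
                task_rng, filt_rng = _rng_pair(config.seed, i, d_idx, c_idx)
                ep = ctor(condition, rng=task_rng)
                trace = run_filter(ep.outcomes, params, filt_rng)
                probe = ep.meta[probe_key] + probe_offset
                stats_dict = {
                    "alpha_probe": float(trace.alpha[probe]),
                    "v_hat_probe": float(trace.v_hat[probe]),
                    "s_hat_probe": float(trace.s_hat[probe]),
                }
                rows.extend(_rows(i, dname, condition, stats_dict, config.seed))
    return pd.DataFrame(rows)


def run_choice_episode(
    episode: TaskEpisode,
    params: ModelParams,
    beta: float,
    rng: np.random.Generator,
) -> dict:
    """Closed-loop choice run: one filter per option, softmax over the
    options' posterior means, full update of the chosen option and a
    prediction-only update (uncertainty grows, mean unchanged) of the
    unchosen one.

    Returns per-trial arrays: choices, observed rewards, model choice
    probabilities, accuracy vs. the correct option, and the chosen
    option's learning rate.
    """
    if episode.outcomes.ndim != 2 or episode.outcomes.shape[1] < 2:
        raise ValueError("choice episodes need >= 2 outcome channels")
    n_trials, n_options = episode.outcomes.shape
    ensembles = [ParticleEnsemble.initial(params) for _ in range(n_options)]
    choices = np.empty(n_trials, dtype=int)
    rewards = np.empty(n_trials)
    p_choice = np.empty(n_trials)
    alpha = np.empty(n_trials)
    for t in range(n_trials):
        values = [float(e.weights @ e.m) for e in ensembles]
        probs = softmax_probs(values, beta)
        choice = int(rng.choice(n_options, p=probs))
        choices[t] = choice
        p_choice[t] = probs[choice]
        rewards[t] = episode.outcomes[t, choice]
        for k in range(n_options):
            if k == choice:
                ensembles[k], rec = filter_trial(ensembles[k], rewards[t], params, rng)
                alpha[t] = rec["alpha"]
            else:
                ens = predict_particles(ensembles[k], params, rng)
                ens.w = ens.w + 1.0 / ens.z  # uncertainty grows by current v
                ensembles[k] = ens
    out = {"choices": choices, "rewards": rewards, "p_choice": p_choice, "alpha": alpha}
    if episode.correct_option is not None:
        out["accuracy"] = (choices == np.asarray(episode.correct_option)).astype(float)
    return out


def run_coupled_choice_episode(
    episode: TaskEpisode,
    params: ModelParams,
    beta: float,
    rng: np.random.Generator,
) -> dict:
    """Closed-loop choice run over a single shared contingency.

    For two-option tasks whose reward probabilities are complementary, one
    filter tracks the first option's reward rate x; the second option's
    value is 1 - x.  Observing the chosen option's outcome o updates the
    filter with o (option 0) or 1 - o (option 1), so every loss is direct
    evidence that the contingency moved -- the coupling that turns an
    elevated learning rate into lose-shift behavior.
    """
    if episode.outcomes.ndim != 2 or episode.outcomes.shape[1] != 2:
        raise ValueError("coupled choice episodes need exactly 2 outcome channels")
    n_trials = episode.outcomes.shape[0]
    ens = ParticleEnsemble.initial(params)
    choices = np.empty(n_trials, dtype=int)
    rewards = np.empty(n_trials)
    p_choice = np.empty(n_trials)
    alpha = np.empty(n_trials)
    for t in range(n_trials):
        m = float(ens.weights @ ens.m)
        probs = softmax_probs([m, 1.0 - m], beta)
        choice = int(rng.choice(2, p=probs))
        choices[t] = choice
        p_choice[t] = probs[choice]
        rewards[t] = episode.outcomes[t, choice]
        obs = rewards[t] if choice == 0 else 1.0 - rewards[t]
        ens, rec = filter_trial(ens, obs, params, rng)
        alpha[t] = rec["alpha"]
    out = {"choices": choices, "rewards": rewards, "p_choice": p_choice, "alpha": alpha}
    if episode.correct_option is not None:
        out["accuracy"] = (choices == np.asarray(episode.correct_option)).astype(float)
    return out


def _block_relative_log_alpha(
    trace: FilterTrace, episode: TaskEpisode, burn_in: int = 20
) -> float:
    """Volatile-minus-stable mean log learning rate over block labels.

    The first ``burn_in`` trials are excluded: early learning rates are
    dominated by the prior (posterior variance starts high), not by the
    block manipulation."""
    labels = episode.phase[burn_in:]
    log_alpha = np.log(trace.alpha[burn_in:])
    return float(
        log_alpha[labels == "volatile"].mean() - log_alpha[labels == "stable"].mean()
    )


def _anxiety_model(config: ExperimentConfig, lesion_s: float) -> ModelParams:
    return ModelParams(
        lambda_v=0.2, lambda_s=0.2, v0=0.1, s0=0.1,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=1.0,
        lesion="fix_stochasticity", lesion_value=lesion_s,
    )


def _run_fig5(config: ExperimentConfig) -> pd.DataFrame:
    """Anxiety as a stochasticity lesion: blunted learning-rate adaptation
    to volatility on the switching task, and elevated learning rate /
    lose-shift on the probabilistic two-choice task."""
    control = _conditioning_model(config)
    lesioned_switch = _anxiety_model(config, config.overrides.get("lesion_s_switch", 0.001))
    lesioned_choice = _anxiety_model(config, config.overrides.get("lesion_s_choice", 0.05))
    beta = config.overrides.get("beta", 3.0)
    rows = []
    # switching task (single-cue, rate-plus-noise outcomes)
    for g_idx, (gname, params) in enumerate(
        [("control", control), ("anxious", lesioned_switch)]
    ):
        for i in range(config.resolved_n_sims):
            task_rng, filt_rng = _rng_pair(config.seed, i, 0, g_idx)
            ep = make_switching_task(rng=task_rng)
            trace = run_filter(ep.outcomes, params, filt_rng)
            stats_dict = {
                "relative_log_alpha": _block_relative_log_alpha(trace, ep),
                "mean_alpha": float(np.mean(trace.alpha)),
            }
            rows.extend(_rows(i, gname, "switching", stats_dict, config.seed))
    # two-choice task (closed loop over a shared contingency)
    for g_idx, (gname, params) in enumerate(
        [("control", control), ("anxious", lesioned_choice)]
    ):
        for i in range(config.resolved_n_sims):
            task_rng, filt_rng = _rng_pair(config.seed, i, 1, g_idx)
            ep = make_two_choice_task(rng=task_rng)
            res = run_coupled_choice_episode(ep, params, beta, filt_rng)
            wsls = win_stay_lose_shift(res["choices"], res["rewards"])
            stable = ep.phase == "stable"
            stats_dict = {
                "win_stay": np.nan if wsls.win_stay is None else wsls.win_stay,
                "lose_shift": np.nan if wsls.lose_shift is None else wsls.lose_shift,
                "mean_alpha": float(np.mean(res["alpha"])),
                "accuracy_stable": float(res["accuracy"][stable].mean()),
                "accuracy_volatile": float(res["accuracy"][~stable].mean()),
            }
            rows.extend(_rows(i, gname, "two_choice", stats_dict, config.seed))
    return pd.DataFrame(rows)


def run_anxiety_cohort(spec: CohortSpec, seed: int = 0, n_particles: int = 100):
    """Continuous trait-anxiety cohort on the switching task.

    For each set, synthesize subjects differing only in their update rates,
    run each on a fresh switching-task episode, compute the relative log
    learning rate (volatile minus stable), and correlate it with trait
    anxiety (Spearman) within the set.

    Returns ``(per_set_correlations, subject_table)``.
    """
    lo, hi = spec.trait_bounds
    per_subset = spec.subjects_per_set // len(spec.trait_means)
    correlations = np.empty(spec.n_sets)
    records = []
    for s in range(spec.n_sets):
        traits = []
        sampler = np.random.default_rng(np.random.SeedSequence([int(seed), s, 999]))
        for mean in spec.trait_means:
            half = min(mean - lo, hi - mean)
            traits.extend(sampler.uniform(mean - half, mean + half, per_subset))
        traits = np.asarray(traits)
        rel_lr = np.empty(traits.size)
        for j, trait in enumerate(traits):
            task_rng, filt_rng = _rng_pair(seed, s, j)
            lambda_v = sampler.uniform(*spec.lambda_v_range)
            lambda_s = min(lambda_v / trait, 0.999)
            params = ModelParams(
                lambda_v=lambda_v, lambda_s=lambda_s,
                v0=spec.v0, s0=spec.s0, n_particles=n_particles,
                prior_mean=0.0, prior_var=1.0,
            )
            ep = make_switching_task(rng=task_rng)
            trace = run_filter(ep.outcomes, params, filt_rng)
            rel_lr[j] = _block_relative_log_alpha(trace, ep)
            records.append({
                "set": s, "subject": j, "trait": trait,
                "lambda_v": lambda_v, "lambda_s": lambda_s,
                "relative_log_alpha": rel_lr[j], "seed": seed,
            })
        if np.allclose(traits, traits[0]):
            raise ValueError("zero trait variance in set: correlation undefined")
        correlations[s] = stats.spearmanr(traits, rel_lr).statistic
    return correlations, pd.DataFrame(records)


def _run_fig6(config: ExperimentConfig) -> pd.DataFrame:
    """Trait anxiety as the ratio of update rates: Spearman correlation with
    the relative log learning rate across synthetic cohorts."""
    spec = CohortSpec(n_sets=config.resolved_n_sims)
    for key, val in config.overrides.items():
        if hasattr(spec, key):
            setattr(spec, key, val)
    correlations, _ = run_anxiety_cohort(spec, config.seed, config.n_particles)
    rows = []
    for s, corr in enumerate(correlations):
        rows.extend(_rows(s, "cohort", "switching", {"spearman": corr}, config.seed))
    return pd.DataFrame(rows)


def _run_fig7(config: ExperimentConfig) -> pd.DataFrame:
    """Serial prediction with a contingency shift: a volatility-lesioned
    learner misattributes the shift to stochasticity and slows down instead
    of speeding up."""
    control = ModelParams(
        lambda_v=0.2, lambda_s=0.2, v0=0.5, s0=0.5,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=1.0,
    )
    lesioned = control.with_overrides(
        lesion="fix_volatility",
        lesion_value=config.overrides.get("lesion_v", 0.25e-6),
    )
    n_phase1 = config.overrides.get("n_phase1", 200)
    n_phase2 = config.overrides.get("n_phase2", 80)
    rows = []
    for c_idx, condition in enumerate(("consistent", "shift")):
        for g_idx, (gname, params) in enumerate(
            [("control", control), ("lesioned", lesioned)]
        ):
            for i in range(config.resolved_n_sims):
                task_rng, filt_rng = _rng_pair(config.seed, i, c_idx, g_idx)
                ep = make_serial_prediction(
                    condition, rng=task_rng, n_phase1=n_phase1, n_phase2=n_phase2
                )
                probe = config.overrides.get("probe_trial", ep.meta["probe_trial"])
                # the first cue (tone-given-light) carries the contingency shift
                trace = run_filter(ep.outcomes[:, 0], params, filt_rng)
                stats_dict = {
                    "alpha_probe": float(trace.alpha[probe]),
                    "v_hat_probe": float(trace.v_hat[probe]),
                    "s_hat_probe": float(trace.s_hat[probe]),
                }
                rows.extend(_rows(i, gname, condition, stats_dict, config.seed))
    return pd.DataFrame(rows)


def _run_fig8(config: ExperimentConfig) -> pd.DataFrame:
    """Probabilistic reversal learning: a volatility-lesioned chooser is
    disrupted more by a deterministic than a stochastic reversal."""
    control = ModelParams(
        lambda_v=0.2, lambda_s=0.2, v0=0.5, s0=0.5,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=1.0,
    )
    lesioned = control.with_overrides(
        lesion="fix_volatility",
        lesion_value=config.overrides.get("lesion_v", 0.01),
    )
    betas = config.overrides.get("betas", {"control": 3.0, "lesioned": 1.0})
    schedules = config.overrides.get(
        "schedules", ("deterministic_100_0", "stochastic_60_40")
    )
    rows = []
    for sc_idx, schedule in enumerate(schedules):
        for g_idx, (gname, params) in enumerate(
            [("control", control), ("lesioned", lesioned)]
        ):
            for i in range(config.resolved_n_sims):
                task_rng, filt_rng = _rng_pair(config.seed, i, sc_idx, g_idx)
                ep = make_reversal_task(schedule, rng=task_rng)
                res = run_choice_episode(ep, params, betas[gname], filt_rng)
                post = ep.phase == "reversal"
                stats_dict = {
                    "accuracy_pre": float(res["accuracy"][~post].mean()),
                    "accuracy_post": float(res["accuracy"][post].mean()),
                    "accuracy": float(res["accuracy"].mean()),
                    "mean_alpha": float(np.mean(res["alpha"])),
                }
                rows.extend(_rows(i, gname, schedule, stats_dict, config.seed))
    return pd.DataFrame(rows)


def _run_supp_changepoint(config: ExperimentConfig) -> pd.DataFrame:
    """Change-point prediction task with two observation-noise levels:
    learning rate falls as the noise (stochasticity) rises."""
    params = ModelParams(
        lambda_v=0.4, lambda_s=0.2, v0=5.0, s0=5.0,
        n_particles=config.n_particles, prior_mean=0.0, prior_var=100.0,
    )
    n_trials = config.overrides.get("n_trials", 200)
    rows = []
    for c_idx, level in enumerate(("small", "large")):
        for i in range(config.resolved_n_sims):
            task_rng, filt_rng = _rng_pair(config.seed, i, c_idx)
            ep = make_changepoint_task(level, n_trials=n_trials, rng=task_rng)
            trace = run_filter(ep.outcomes, params, filt_rng)
            stats_dict = {
                "mean_alpha": float(np.mean(trace.alpha)),
                "mean_s_hat": float(np.mean(trace.s_hat)),
                "mean_v_hat": float(np.mean(trace.v_hat)),
            }
            rows.extend(_rows(i, "healthy", level, stats_dict, config.seed))
    return pd.DataFrame(rows)


EXPERIMENT_REGISTRY: Dict[str, Callable[[ExperimentConfig], pd.DataFrame]] = {
    "fig1": _run_fig1,
    "fig2": _run_fig2,
    "fig3": _run_fig3,
    "fig4": _run_fig4,
    "fig5": _run_fig5,
    "fig6": _run_fig6,
    "fig7": _run_fig7,
    "fig8": _run_fig8,
    "supp_changepoint": _run_supp_changepoint,
}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run a registered experiment; deterministic given ``config``."""
    runner = EXPERIMENT_REGISTRY[config.name]
    table = runner(config)
    return ExperimentResult(table=table, config=config.to_dict())


def run_choice_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run a registered choice-task experiment (softmax-coupled loop).

    Provided as a named entry point for the closed-loop designs; delegates
    to the registry and validates that the experiment is choice-based.
    """
    if config.name not in ("fig5", "fig8"):
        raise ValueError(f"{config.name!r} is not a choice experiment")
    return run_experiment(config)


def aggregate(
    result: ExperimentResult,
    statistic: str = "mean",
    error: str = "sem",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group x condition x statistic summaries with a dispersion estimate.

    ``statistic`` is ``mean`` or ``median``; ``error`` is ``sem`` (standard
    error of the mean) or ``sem_median`` (bootstrap standard error of the
    median, seeded and with ``n_boot`` resamples).
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if error not in ("sem", "sem_median"):
        raise ValueError("error must be 'sem' or 'sem_median'")
    table = result.table
    if table.empty:
        raise ValueError("empty result")
    rng = np.random.default_rng(seed)

    def _summary(values: pd.Series) -> pd.Series:
        x = values.to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        center = float(np.mean(x)) if statistic == "mean" else float(np.median(x))
        if x.size < 2:
            disp = np.nan
        elif error == "sem":
            disp = float(np.std(x, ddof=1) / np.sqrt(x.size))
        else:
            boots = np.median(
                x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1
            )
            disp = float(np.std(boots, ddof=1))
        return pd.Series({statistic: center, error: disp, "n": x.size})

    return (
        table.groupby(["group", "condition", "statistic"])["value"]
        .apply(_summary)
        .unstack()
        .reset_index()
    )
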