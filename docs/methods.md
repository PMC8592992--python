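# Methods

## The model

`volstoch` implements a learner for noisy, changing environments that
jointly tracks two kinds of noise while estimating a latent reward rate.

**Generative model.** The latent reward rate diffuses and outcomes are
noisy readings of it:

    x_t = x_{t-1} + e_t,   e_t ~ N(0, v_t)        (volatility v_t)
    o_t ~ N(x_t, s_t)                             (stochasticity s_t)

Both noise variances evolve. In the default parameterization their
inverses, z_t = 1/v_t and y_t = 1/s_t, follow multiplicative dynamics

    z_t = eta^{-1} z_{t-1} eps_t,   eps_t ~ Beta(0.5 eta/(1-eta), 0.5)

with persistence eta in (0, 1). Because E[eps_t] = eta the process is a
martingale: the noise estimate is expected to stay put, with spread
controlled by the update rate lambda = 1 - eta. An alternative
`gaussian_log` parameterization lets log v_t and log s_t follow Gaussian
random walks with step sizes sigma_v, sigma_s.

**Why two noise terms are identifiable.** Both inflate outcome variance,
but volatility raises the lag-1 autocorrelation of outcomes (the rate
itself wanders) whereas stochasticity lowers it (independent perturbations
around a stickier rate). `generative.lag1_autocorrelation` is the
diagnostic; the test suite verifies the orderings by simulation.

**Inference.** Conditional on (v, s) the rate posterior is Gaussian and
updated exactly by the Kalman recursion

    delta = o - m
    alpha = (w + v) / (w + v + s)
    m' = m + alpha * delta
    w' = (1 - alpha)(w + v)

so the learning rate alpha rises with volatility and falls with
stochasticity. Since (v, s) are unknown, a Rao-Blackwellized particle
filter tracks them: each of N particles carries (z, y) samples plus its own
conditional Kalman statistics (m, w). Per trial: (1) diffuse each
particle's (z, y) under the Beta dynamics; (2) reweight by the predictive
likelihood N(o | m, w + v + s), resampling systematically when
ESS/N = (1/sum w_i^2)/N falls below 0.5; (3) apply the Kalman update per
particle. Reported signals (m, w, alpha, v-hat, s-hat) are importance-
weighted ensemble averages using the weights as they stand after the
conditional resampling step.

**Lesions.** `fix_volatility` / `fix_stochasticity` pin one variance at a
fixed value for all particles. Because the two noise terms compete to
explain surprise ("explaining away"), a lesioned learner misattributes the
lesioned factor's noise to the other one, not merely losing but *reversing*
its learning-rate adjustments. Trait anxiety is modelled continuously as
the ratio lambda_v / lambda_s: large values emulate weak stochasticity
updating.

## Numerical choices

- Particles initialize as a point mass at (1/v0, 1/s0) with uniform
  weights, so a zero-update-rate filter is *exactly* the fixed-parameter
  Kalman filter (asserted to 1e-10 against an independent recursion).
- Weights are computed in log space with max-subtraction; if every density
  underflows the weights fall back to uniform with a warning.
- The posterior variance uses the cancellation-free form s(w+v)/(w+v+s);
  its identity with (1-alpha)(w+v) is asserted in tests.
- Beta draws are floored at 1e-12 to keep the inverse variances finite;
  eta = 1 (zero update rate) short-circuits to the deterministic identity.
- Each simulation run consumes a single seeded stream in a fixed order
  (volatility draw, stochasticity draw, resampling offset, per trial);
  experiment replications derive independent task/filter streams from
  SeedSequence([seed, replication index, ...]). Reruns are bit-identical.

## Tasks and what the generator emulates

The task battery generates the study designs as explicit schedules:

- `make_constant_2x2` — diffusing rate with constant (v, s); canonical
  cells v in {0.5, 1.5} x s in {1, 3}, 200 trials.
- `make_switching_task` — rate 0.8 in a 90-trial stable block, then a
  90-trial volatile block alternating 0.25/0.75 every 15 trials; outcomes
  are rate plus N(0, 0.01), not binary. Block sizes are configurable; the
  two-block layout mirrors the standard two-level volatility manipulation.
  A separate classifier (`label_switch_window`) labels trials by switch
  recency (window 10) for analyses keyed to recent change rather than
  block identity.
- `make_conditioned_suppression` — 100 trials of a weak outcome (0.3),
  optionally ending with 5 omission trials (0), then strong retraining (1);
  noise variance 1e-2.
- `make_partial_reinforcement` — 100 pretraining trials rewarded always
  (full) or on a random half (partial), then extinction; noise 1e-4.
- `make_serial_prediction` — two channels (tone-given-light,
  reward-given-light) carrying contingency *rates* plus N(0, 1e-6): the
  tone contingency is 1 throughout for the consistent condition and drops
  to 0.5 in the shorter second phase under the shift. Reporting the
  scheduled contingency rather than trial-wise binary events matches the
  stated tiny outcome variance and makes the shift an abrupt level change.
  Defaults: 200 + 80 trials; the probe is the last phase-2 trial.
- `make_reversal_task` — 80 trials, two options with complementary reward
  probabilities (100/0, 80/20, 70/30, 60/40), one reversal uniform on
  trials 30-50; binary rewards plus N(0, 1e-6).
- `make_changepoint_task` — piecewise-constant rate redrawn uniformly in
  [0, 10]; run lengths 5 + Exp(rate 0.05) rounded up; noise variance 1
  (small) or 9 (large).
- `make_two_choice_task` — two options with complementary probabilities
  (default 0.75/0.25) swapping every 20 trials; binary rewards plus
  N(0, 0.01).

What the generator does **not** emulate: the empirical studies' exact trial
sequences, session structure, valence asymmetries, reaction times or
pupil/neural measures. Passing tests show the model reproduces the
qualitative behavioral patterns under these idealized schedules, not that
it fits any subject's data.

## Experiments

`run_experiment` dispatches on a registry (`fig1` ... `fig8`,
`supp_changepoint`) and returns a tidy per-simulation table. Headline
parameterizations (update rates, initial noise, priors, decision noise,
lesion values) follow the printed simulation settings; replication counts
default to 100-1000 and scale to the original counts with `full=True`.
Choices worth noting:

- **Conditioning probes** are the trace entries carrying the learner state
  *into* retraining/extinction (the entry after the last pretraining
  outcome). Placing the probe on the first retraining trial itself lets
  that trial's own surprising outcome reweight the ensemble within the
  trial, so the statistic would measure the reaction to the probe outcome
  rather than what pretraining taught the learner. The offset is
  configurable (`overrides["probe_offset"]`).
- **Choice coupling.** The reversal task (fig8) runs one independent filter
  per option; the chosen option gets the full update, the unchosen one a
  prediction-only update (uncertainty grows by its current volatility
  estimate, mean unchanged). The anxiety two-choice task (fig5) instead
  uses a *coupled* learner over a single shared contingency x with option
  values (x, 1-x): with complementary reward probabilities every loss is
  direct evidence the contingency moved, which is what converts an elevated
  learning rate into lose-shift behavior. With independent filters the
  unchosen value freezes and the group contrast in lose-shift nearly
  vanishes.
- **Relative log learning rate** (volatile minus stable mean log alpha)
  uses block labels and excludes the first 20 trials, where the gain is
  dominated by the prior rather than the block manipulation.
- **Trait-anxiety cohort**: per set, 30 subjects in three subsets with
  trait means 0.5/1/3, traits uniform around each mean with half-width
  min(mean - 0.26, 4 - mean) (exact subset means, bounds respected),
  lambda_v uniform on (0, 0.2), lambda_s = lambda_v / trait, v0 = s0 =
  0.001. Spearman correlation between trait and relative log learning rate
  per set; the median across sets is the headline number.
- **Serial-prediction phase lengths** (not part of the printed settings)
  default to 200 + 80: the consistent condition needs extensive first-phase
  exposure for its baseline learning rate to settle, and the shift
  condition's learning rate recovers over the shorter second phase as the
  initially inflated stochasticity estimate decays while volatility stays
  elevated.
- `aggregate` reports mean/SEM or median with a seeded bootstrap SEM of
  the median (1000 resamples by default).

## Known limitations

- The particle filter's behavior under extreme surprise (observation many
  predictive standard deviations away after a long quiet period) is
  winner-take-all: the single largest-variance particle absorbs all weight,
  which makes single-trial signals after such events heavy-tailed across
  runs. Summary statistics use means/medians over many replications.
- Only two noise levels per factor are exercised by the factorial designs;
  recovery quality degrades when true values fall far outside the initial
  values' order of magnitude.
- No fitting to empirical choice data and no variational inference backend
  are provided; inference is simulation-only by design.
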