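# Methods

## Problem formulation

A CGM trace is a sequence of glucose readings (mmol/L, printed to 1 dp)
at a nominal 5-minute cadence. One-step forecasting is posed as
supervised regression by sliding a window over each contiguous run of
readings: the inputs are the `w` readings immediately preceding a
target, the target is the next reading, and `w` is swept over 3–10.
Windows never span an unfilled gap or a trace boundary. The data is
split into chronological train/validation/test blocks (default
70/15/15, remainder to train); chronological rather than shuffled
splitting avoids look-ahead leakage in a time series, at the cost that
distribution drift between blocks shows up in the scores.

No input normalisation is applied by default — raw mmol/L units keep
MSEs directly interpretable (an MSE of 0.1 (mmol/L)² is an RMSE of
~0.32 mmol/L) — but a train-fitted z-scoring helper exists
(`standardize_splits`).

## Network

Fully connected feed-forward net, layer sizes `[w, 5, 5, 5, 1]`, ReLU
hidden activations, linear output. Two deliberate configuration
switches:

* **Bias placement** (`post_activation` default): the bias vector is
  added *after* the activation, `a = relu(a_prev W) + b`, with the
  conventional `a = relu(a_prev W + b)` available as
  `pre_activation`. Both forward pass and gradients honour the
  setting; for the linear output layer the two coincide.
* **Output activation** (`identity` default): a ReLU output can
  dead-lock gradient training at 0, and glucose targets are strictly
  positive anyway; the all-ReLU variant is available via config.

Initial parameters are drawn i.i.d. uniform on `[−0.5, 0.5]`.

## Genetic algorithm

The genotype is the ordered list of weight and bias matrices; the
phenotype is the network they instantiate. Fitness is evaluated on the
*training* block as `1/(MSE + ε)`, `ε = 1e-8` (strictly decreasing in
error; the ε guards a zero-error individual).

Each generation, `population_size` (default 100) families are formed:
two distinct parents drawn by roulette-wheel selection (cumulative
fitness distribution, sampling with replacement, redraw on identical
indices; an all-zero fitness vector falls back to uniform). Each family
produces four children by averaging crossover
`child = α·p1 + (1−α)·p2` with α ∈ {0.2, 0.4, 0.6, 0.8}; the last two
children are additionally mutated by i.i.d. uniform noise on
`[−max_mutation, max_mutation]` (default 0.1). The six family members —
parents first, then children — compete on training MSE and the argmin
survives (ties to the earliest pool member, for reproducibility). This
family elitism guarantees a survivor no worse than the better parent
and keeps the population size constant, with no separate
crossover/mutation/elitism rates.

The paper-level protocol runs 200 generations of 100 individuals per
window size. How parent pairs are formed and how the population count
is maintained is genuinely open in that protocol; one family per
population slot with roulette-drawn parents is the simplest scheme
consistent with four-children family elitism, and is what this package
does.

### Validation's two roles

Validation data never influences selection. It serves:

1. **Early stopping** — evolution halts when the population-mean
   validation MSE strictly increases for `patience = 3` consecutive
   generations (the increase threshold defaults to 0 and is
   configurable, as is switching the monitored statistic to the
   per-generation best via `early_stop_statistic`). The
   population-mean choice makes the signal noisier but reflects the
   population as a whole; with a plateaued population it will halt
   within a handful of generations, which is the intended behaviour.
2. **Model selection** — on convergence or early stop, the
   minimum-validation-MSE individual *of the final generation* is
   returned. A best-so-far champion (by validation MSE) is archived in
   the history for reporting but never re-injected into the
   population, so convergence rests on family elitism alone.

### Window sweep and comparison

For each window size the datasets are rebuilt, the method run, and the
best validation MSE recorded; the window with the minimum validation
MSE is selected and that single model evaluated once on the test
block. The backprop baseline (full-batch gradient descent, default
lr 0.01, 500 epochs, same patience rule, parameters restored from the
best-validation epoch) runs on byte-identical splits — the experiment
runner hashes every split and records the digest. A diverged backprop
run (non-finite loss, surfaced as `DivergenceError` naming the epoch)
is recorded in the sweep as an infinite-MSE row that selection skips.
The sweep accepts `replicates` to rerun each window and keep the best
validation score.

The comparison summary reports each method's selected window and best
validation MSE, test MSE, absolute and relative MSE/RMSE drops and the
window-size reduction. Headline improvements are computed from the
best MSEs rounded to 3 dp — matching what a reader recomputes from a
printed table — with unrounded variants alongside (MSE 3 dp, RMSE
4 dp, percentages 1 dp).

## CGM I/O and preprocessing

The CSV dialect is `index,timestamp,value` with an optional header
(auto-detected), ISO-8601 timestamps (a `DD/MM/YYYY HH:MM:SS` dialect
is a config switch) and values written at exactly 1 dp. Distinct,
named errors cover empty input, parse failures, non-increasing
timestamps and out-of-bounds values. Plausibility bounds default to
[2.0, 22.2] mmol/L, a typical device reporting range; no statistical
outlier filtering beyond the bounds check is attempted.

Real exports show a ±1 s interval artifact on a large share of steps;
the jitter tolerance defaults to ±2 s and jittered steps are treated
as nominal for windowing. Gaps (spans beyond nominal + tolerance) of
up to `max_gap` = 60 min are filled by time-linear interpolation at
nominal grid points, rounded to 1 dp; longer gaps would require
fabricating structure, so they are left as segment boundaries that
windows cannot cross. Linear-with-a-cap is this package's choice — the
interpolation method and gap limit are not standardised anywhere.

## Synthetic data

`generate_cgm` produces: baseline (6 mmol/L) + circadian sinusoid
(amplitude 0.8 mmol/L, trough ~4 am) + additive meal bumps (3/day at
08:00/13:00/19:00, amplitude 3 mmol/L, linear 30-min rise, 90-min
exponential decay) + AR(1) noise (coefficient 0.85, innovation sd
0.15 mmol/L, started from its stationary distribution), clipped to the
plausibility bounds and rounded to 1 dp. These defaults emulate a
roughly two-week wear (default 13.8 days) and give one-step
differences of a few tenths of a mmol/L, the scale at which the
forecasting task is interesting. `inject_artifacts` deletes readings
in geometric-length runs (mean 3 — dropouts cluster) at a configured
expected fraction, and makes a configured fraction of steps (default
0.41) deviate from nominal by exactly ±1 s via per-timestamp offsets
bounded within ±1 s.

What the generator does **not** emulate: insulin–glucose kinetics,
exercise, meal-size variability, sensor drift/compression artifacts,
or inter-patient heterogeneity. Passing tests on synthetic data shows
the machinery is correct and that evolution can fit smooth
autocorrelated dynamics; it does not certify clinical forecasting
accuracy on real traces.

## Numerical and design choices

* **Determinism**: every stochastic stage takes a seed or generator;
  the experiment runner derives per-stage seeds from one global seed
  via `SeedSequence`, so a rerun is byte-identical and stages can be
  rerun in isolation.
* **Tie-breaks**: argmin everywhere takes the first minimum (parents
  before children in a family; lower window size in the sweep on exact
  ties).
* **Degenerate inputs**: segments no longer than the window contribute
  no pairs; an entirely-too-short series raises an empty-dataset
  error; all-zero fitness falls back to uniform selection.
* **Problem sizes in the checked runs**: the test suite and acceptance
  script exercise the full protocol at reduced scale — 1-day traces,
  populations of 30–50, 50–100 generations — which one CPU handles in
  seconds while preserving every structural property of the full-scale
  protocol (the defaults remain 100×200).
* **Parameter-recovery benchmark**: on
  `y_{t+1} = 0.5·y_t + 0.5·y_{t−1} + N(0, 0.15²)` the evolved network
  should reach the noise floor (test MSE ≤ 2σ²). These dynamics have a
  unit root, so the realisation decides how far the test block drifts
  from the training range; the benchmark series is therefore a frozen
  dataset (fixed seed), and the occasional premature early stop of a
  population-mean monitor is visible as an outlier run.

## Known limitations

* One-step (5-minute) horizon only; no multi-step or long-horizon
  targets, and no adjustable/learned window size.
* Weight evolution only: topology and hyper-parameters are fixed, and
  there is no recurrent architecture.
* Population-mean early stopping is noisy; on plateaus it halts within
  a few generations, which can occasionally be premature.
* Absolute MSEs on synthetic data are not comparable to scores on any
  clinical dataset; only the relative comparison between the two
  training methods on identical splits is meaningful here.
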