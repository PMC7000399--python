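# Methods

This note documents the models, parameters and numerical choices behind
`numcrow`: a simulation and analysis package for a delayed
match-to-numerosity task with sequential and simultaneous sample formats.

## Task and stimulus model

A trial runs pre-sample (500 ms empty background circle) → sample → delay
(1000 ms) → test. Simultaneous samples are dot arrays shown for 800 ms;
sequential samples are n items each followed by a pause (the final pause
abuts the delay; the figure evidence for the trailing element is ambiguous
and this symmetric choice is feasible for every numerosity). On non-match
trials a second, always-matching test follows 800 ms after the first.

**Standard sequential timing.** The 2n intervals must sum to 2625 ms with a
300 ms floor. The generator gives every interval the floor and splits the
excess (2625 − 600·n ms) with a flat Dirichlet weight vector, i.e. uniform
sampling on the constrained simplex; the last interval is assigned as the
exact remainder so the total is 2625 ms to machine precision. The published
description says only that timings are "randomly generated anew"; uniform on
the feasible set is the maximum-entropy reading.

**Temporal controls.** Equal-variance: all intervals equal 2625/(2n) ms.
Equal-item: every interval equals a configurable fixed duration (default
300 ms, the legal minimum, keeping the numerosity-4 total at 2400 ms close
to the 2625 ms standard), so the total grows affinely with n. Sessions use
one of the two controls (alternating between sessions in the original
design; `SimConfig.seq_control` selects it).

**Dot displays.** 30 mm background circle, dot radii 1–2 mm, rejection
sampling for non-overlap. The area/density control solves per-dot radius
analytically (equal total area A/n per dot) and rescales dot centers about
their centroid until the mean pairwise center distance matches a target
(default 7 mm), with tolerances of 2 % (area) and 5 % (density). Note the
radius bounds make A = 4π mm² the only total area feasible for all
numerosities with equal-size dots, giving radius 2 mm at n = 1 and 1 mm at
n = 4. Density is defined as the mean pairwise center distance; no published
tolerance exists, 5 % is the package's choice.

**Sessions** are exact crossings of numerosity (4) × format (2) × protocol
(2) × match (2), `trials_per_condition` trials per cell, order shuffled.
Sequential-standard numerosity-1 trials receive a uniform 0–500 ms
pre-sample jitter (flagged on the trial) so that sample-onset timing alone
cannot predict numerosity; these trials are excluded from delay-epoch
analyses.

## Behavioral model

The subject forms an internal estimate log₂(sample) + ε, ε ~ N(0, w²) with
Weber width w (default 0.35, which yields ~75–80 % correct, in the range a
trained subject shows on this task), reads out the numerosity whose log₂
magnitude is nearest the estimate, and responds "match" at the first test
exactly when the readout equals the test numerosity. A lapse rate (default
0.05) replaces the decision with a coin flip. Constant noise on the log axis
produces both classic signatures: bell-shaped performance curves peaking at
the sample (distance effect) and linear-scale widths growing with the sample
(size effect). The closed-form response probability (Gaussian CDF over the
readout bin) is exposed as `behavior.model_match_probability` and serves as
the oracle for curve-fit tests.

Curve widths are quantified by a least-squares Gaussian on the log₂ test
axis with the center fixed at the sample (four points cannot constrain a
free center) and binomial-standard-error weights. Because the readout bins
narrow toward numerosity 4, the log-axis σ *decreases* with the sample under
this model while the linear-scale width σ·n·ln 2 increases; both are
reported, and the size effect refers to the linear width.

## Neuron model

Five populations (defaults mirror the recorded sample the analyses were
designed around: 376 neurons; 64 sequential-sample, 45 simultaneous-sample,
37 delay-tuned; the remainder split into format-only and non-selective):

* Tuning is Gaussian on the log₂ numerosity axis,
  `exp(−(log₂n − log₂p)²/(2σ²))`, σ ~ U(0.35, 0.55): constant log-space
  width produces the neuronal size effect (wider linear-scale tuning at
  larger preferred numerosities).
* Baselines are lognormal (median ≈ 4 Hz, clipped to [0.5, 30] Hz); tuned
  gain ~ U(8, 12) Hz; sample responses lag stimulus onset by a 100 ms
  latency, matching the analysis-window shift.
* `SEQ_SAMPLE` neurons add gain·tuning only while sequential items are on
  screen; `SIM_SAMPLE` neurons only during the dot array.
* `DELAY_NUM` neurons add, during the delay,
  `amp·[format=seq]·decay(t) + gain·tuning·(1 − decay(t))` with a logistic
  decay centered 500 ms into the delay (steepness 50 ms): early-delay
  activity carries format, late-delay activity carries numerosity, and the
  two cross mid-delay. `FORMAT_ONLY` neurons carry only the decaying format
  term. The published result shows this phenomenon without equations; the
  complementary-logistic handover is the minimal parameterization.
* On error trials the tuning argument is the behaviorally estimated
  numerosity instead of the true sample (`SimConfig.error_corruption`,
  default on) — the minimal mechanism coupling neural and behavioral errors.
  Turning it off makes errors purely behavioral with clean spikes, the
  ablation used in tests.
* Spikes are an inhomogeneous Poisson process over the piecewise-constant
  rate profile (the smooth delay components are discretized at 20 ms);
  counts are drawn per segment, which is exact for piecewise-constant rates.
  Trial-to-trial overdispersion is available as an optional gamma rate
  multiplier and is off by default — real count dispersion in this area is
  not known from the published material.

**What the simulator does not emulate:** session structure across days
(all neurons share one session's trials), electrode/recording realism,
learning, non-Poisson spiking history effects, and any correlated
variability between neurons. Passing recovery tests therefore shows that
the analysis chain is correct and calibrated on data satisfying its own
assumptions, not that real recordings would satisfy them.

## Analysis conventions

* **Epoch windows** (ms): simultaneous sample, onset+100 to onset+900;
  sequential sample, per item onset+100 for the item duration capped at
  800 ms, all item windows of a trial pooled into a single rate (the
  per-trial observation for the ANOVA); delay, onset+600 for 500 ms — the
  100 ms overhang past the nominal delay end is kept as specified.
* **Selectivity**: two-way fixed-effects ANOVA with Type II sums of squares
  (cells are unbalanced because only correct trials enter; Type II prevents
  one factor from absorbing the other's variance). Criterion: numerosity
  p < 0.01 and cofactor/interaction p ≥ 0.01. Inclusion: session mean rate
  ≥ 0.5 Hz and ≥ 3 correct trials per numerosity × format × protocol cell.
* **ω²** uses Hays' formula `(SS_f − df_f·MS_err)/(SS_tot + MS_err)`, not
  clipped at zero. The sliding-window series (300 ms / 20 ms, first window
  opening 200 ms before delay onset, last ending 200 ms after delay offset)
  averages ω² across neurons at window midpoints. The permutation null
  shuffles each neuron's joint (numerosity, format) labels identically
  across that neuron's windows — preserving the temporal autocorrelation of
  the null — and thresholds are the 95th percentile of the across-neuron
  mean. Implementation note: label shuffling is realized as row permutation
  of the rate matrix against a fixed design, so the design projections are
  computed once per neuron.
* **Decoding**: rates from delay onset+700 for 400 ms; 32 correct trials
  per numerosity × format per neuron, conjoined across neurons by sampled
  index (neurons are treated as independently recorded). Leave-one-out
  cross-validation holds out one trial per condition; z-scoring (μ, σ) is
  always fitted on the training set. The classifier is a linear multi-class
  SVM (`SVC(kernel="linear")`, default regularization); predictions are the
  argmax class, Platt probability fitting is not enabled since only the
  argmax is used. The whole procedure repeats over iterations with fresh
  pseudo-trials (default 100); accuracies are means of per-iteration means.
  Error-trial testing trains on both formats (32+32 per numerosity), tests
  32 random draws of one error trial per numerosity (2–4) × format, and
  excludes numerosity-1 errors (too scarce). AUC is the rank-based
  probability of superiority with ties counted half.
* **State space**: trial-averaged spike density per condition (numerosity ×
  format, protocols pooled), Gaussian kernel with σ = 150 ms ("150 ms
  kernel" is read as σ, not FWHM), 300 ms bins stepped 25 ms spanning
  −600…+1200 ms around delay onset, then z-scored per neuron over the
  concatenated condition × time series (the unstated z-scoring axis; this
  choice makes every neuron's full trajectory contribute unit variance).
  PCA is fitted jointly on all conditions so trajectories share one space
  and is used for plotting only; all distances are Euclidean in the full
  neuron-dimensional space. Near the earliest bins of simultaneous trials
  the kernel tail is truncated at trial start, slightly biasing the first
  ~100 ms of the span; delay-period statistics are unaffected.

## Determinism and problem sizes

Every generator takes an explicit seed; `build_dataset` spawns independent
substreams (session, behavior, neuron parameters, per-neuron spiking) from
one master seed, and the pipeline derives one stream per stage, so any stage
can be re-run in isolation with identical results. Identical (config, seed)
pairs produce byte-identical bundles (HDF5 written without timestamps).

The test suite exercises the full chain on a reduced population (44 neurons,
16 trials per condition cell, ~512 trials) with default gains and behavior —
the package's standard desk-scale configuration — and uses 100–300
permutation shuffles and 10–20 decoder iterations; the library defaults
remain 1000 shuffles and 100 iterations.

## Known limitations

* All neurons share one simulated session; multi-session pseudo-population
  assembly is supported by the API (per-neuron trial sampling) but not by
  the simulator.
* The delay format→numerosity handover is a fixed parametric form; only its
  midpoint and steepness are configurable.
* The area/density dot-display control admits a single total area given the
  published radius bounds, so control displays use equal-size dots within a
  display.
* Behavioral readout assumes an unbiased estimate and symmetric criterion;
  no response bias or sequential effects are modeled.
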