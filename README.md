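# numcrow

Simulation and population analysis of a delayed match-to-numerosity task in
which set sizes of one to four items are presented either **sequentially**
(one dot at a time, separated by pauses) or **simultaneously** (a dot array),
held across a 1 s memory delay, and compared with a test array. The package
is aimed at systems neuroscientists who want an executable, testable version
of the full analysis chain for this paradigm — from stimulus constraints
through single-neuron selectivity, information time courses, population
decoding and state-space dynamics — with a spiking-neuron simulator that
provides ground truth for every stage.

## What it implements

* **Stimuli** (`numcrow.stimgen`) — sequential sample timings under the
  standard protocol (random item/pause durations constrained to a total of
  2625 ms with a 300 ms floor per interval, sampled uniformly on the
  constrained simplex) and two temporal controls (equal-variance,
  equal-item-duration); dot displays on a 30 mm background circle with 1–2 mm
  dot radii, plus an area/density-equalized control; balanced session
  generation over numerosity × format × protocol × match.
* **Synthetic subject and neurons** (`numcrow.synthdata`) — behavior from a
  noisy internal log₂ magnitude estimate with Weber width *w* (produces the
  numerical distance and size effects); five neuron populations
  (sequential-sample-tuned, simultaneous-sample-tuned, format-independent
  delay-tuned, format-only, non-selective) with log-Gaussian numerosity
  tuning and inhomogeneous-Poisson spiking. On error trials the tuned drive
  follows the behaviorally estimated numerosity, coupling neural and
  behavioral errors.
* **Behavior** (`numcrow.behavior`) — performance curves
  P(match response | test numerosity), exact binomial tests against chance
  0.5, and Gaussian curve-width fits on the log₂ axis quantifying the
  distance/size effects.
* **Selectivity** (`numcrow.selectivity`) — two-factor ANOVA classification
  (numerosity × protocol in the sample epochs, numerosity × format in the
  delay; selective iff p_num < 0.01 with no cofactor/interaction effect),
  min-max-normalized pooled tuning curves, the chance-overlap product rule
  `100·(n_a/N)·(n_b/N)` with an exact binomial tail test, Spearman
  correlation of preferred numerosities with a permutation p, and
  correct-vs-error firing-rate comparison (Wilcoxon signed rank).
* **PEV** (`numcrow.pev`) — sliding-window (300 ms / 20 ms) ω² explained
  variance per factor, ω² = (SS_f − df_f·MS_err)/(SS_tot + MS_err), with
  1000-shuffle permutation nulls and 95th-percentile thresholds.
* **Decoding** (`numcrow.decoding`) — pseudo-population linear SVM, 32
  trials per numerosity × format, leave-one-out cross-validation with
  train-set z-scoring, cross-format transfer, error-trial testing and
  rank-based AUC separation of accuracy distributions.
* **State space** (`numcrow.statespace`) — condition-averaged trajectories
  (150 ms Gaussian kernel, 300 ms bins / 25 ms steps, neuron-wise z-score),
  3-PC projection for plotting, and full-dimensional Euclidean distances
  between formats and between numerosities pooled by numerical distance.
* **I/O and pipeline** (`numcrow.io`, `numcrow.pipeline`, CLI `numcrow`) —
  hashed dataset bundles (CSV/JSON/HDF5), deterministic seed-per-stage
  pipeline, structured report.

## Worked example

```python
from numcrow.pipeline import PipelineConfig, run_pipeline
from numcrow.synthdata import SimConfig

config = PipelineConfig(
    sim=SimConfig(n_seq_sample=10, n_sim_sample=10, n_delay_num=12,
                  n_format_only=4, n_nonsel=8, trials_per_condition=16),
    seed=11, pev_shuffles=200, decode_iterations=20,
    error_decode_outer=20, error_decode_inner=16,
)
run_pipeline(config, "demo_out")
```

The run writes per-stage tables and `report.json`; with the configuration
above it prints (abridged):

```json
{
  "percent_correct_by_format": {"seq": 76.2, "sim": 77.7},
  "selectivity": {"counts": {"sample_seq": 10, "sample_sim": 10, "delay": 12},
                  "sample_overlap": 0},
  "pev": {"crossover_time_ms": 510.0},
  "decoding": {"cv_seq": 0.739, "cv_sim": 0.778,
               "transfer_seq_to_sim": 0.746, "transfer_sim_to_seq": 0.744,
               "error_trials_correct_accuracy": 0.789,
               "error_trials_error_accuracy": 0.191,
               "correct_vs_error_auc": 1.0},
  "statespace": {"pc_variance_explained": [0.690, 0.182, 0.096]}
}
```

Reading: the simulated subject performs ~76–78 % correct in both formats;
the ANOVA recovers every tuned neuron in its own epoch with no
sample-phase overlap between the format-specific populations; the delay
population hands information over from format to numerosity at ~510 ms into
the delay (the ω² crossover); a decoder trained on one format transfers to
the other far above the 25 % chance level, while error-trial activity
decodes poorly because the tuned drive followed the subject's (wrong)
numerosity estimate; and the first three PCs capture ~97 % of the
condition-averaged state variance.

The same stages are available from the shell:

```bash
numcrow simulate --seed 11 --out bundle/
numcrow behavior --data bundle/ --out results/
numcrow run --seed 11 --out full_run/
```

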