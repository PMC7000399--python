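"""Sliding-window omega-squared explained-variance time courses.

For each delay-selective neuron, firing rates are computed in 300 ms windows
stepped by 20 ms, the first window opening 200 ms before delay onset and the
last ending 200 ms after the nominal delay offset.  A two-factor ANOVA
(numerosity x presentation format, correct trials) yields an omega-squared
effect size per factor and window; the population series is the mean across
neurons, plotted at window midpoints.

Significance thresholds come from a permutation null: per replicate, each
neuron's (numerosity, format) trial labels are shuffled jointly — the same
permutation for all of that neuron's windows, preserving the temporal
autocorrelation of the null — the across-neuron mean series is recomputed,
and the 95th percentile over replicates is taken per factor and time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from numcrow.anova import TwoWayAnova, omega_squared_two_way  # noqa: F401  (re-export)
from numcrow.selectivity import Epoch, _epoch_trials
from numcrow.stimgen import DELAY_MS
from numcrow.synthdata import Dataset

WINDOW_MS = 300.0
STEP_MS = 20.0
START_MS = -200.0  # first window start relative to delay onset
TAIL_MS = 200.0  # analysis extends this far past delay offset

_FACTOR_KEYS = {"numerosity": "a", "format": "b", "interaction": "ab"}


@dataclass
class PEVSeries:
    factor: str
    time_centers_ms: np.ndarray  # window midpoints relative to delay onset
    mean_omega2: np.ndarray
    null_q95: np.ndarray | None = None
    n_neurons: int = 0


def window_starts(delay_ms: float = DELAY_MS, tail_ms: float = TAIL_MS) -> np.ndarray:
    """Window start times (ms relative to delay onset), 20 ms apart, from
    -200 ms to the last window fully inside delay + tail."""
    last = delay_ms + tail_ms - WINDOW_MS
    return np.arange(START_MS, last + 1e-9, STEP_MS)


def _neuron_window_rates(
    dataset: Dataset, neuron_id: int, trials: pd.DataFrame, starts: np.ndarray
) -> np.ndarray:
    """(n_trials, n_windows) firing-rate matrix aligned to delay onset."""
    spikes = dataset.spikes[neuron_id]
    rates = np.empty((len(trials), len(starts)))
    for i, (_, tr) in enumerate(trials.iterrows()):
        times = spikes[int(tr["trial_id"])]
        t0 = tr["delay_on"] + starts
        lo = np.searchsorted(times, t0)
        hi = np.searchsorted(times, t0 + WINDOW_MS)
        rates[i] = (hi - lo) * (1000.0 / WINDOW_MS)
    return rates


def _prepare(dataset: Dataset, neuron_ids: list[int]):
    trials = _epoch_trials(dataset, Epoch.DELAY)
    starts = window_starts()
    designs, rate_mats = [], []
    aov = TwoWayAnova(trials["sample_numerosity"], trials["format"])
    for nid in neuron_ids:
        designs.append(aov)  # all neurons share the session's trials
        rate_mats.append(_neuron_window_rates(dataset, nid, trials, starts))
    return starts, designs, rate_mats


def sliding_pev(dataset: Dataset, neuron_ids: list[int]) -> dict[str, PEVSeries]:
    """Observed mean omega-squared series for numerosity, format, interaction."""
    if not neuron_ids:
        raise ValueError("no neurons supplied")
    starts, designs, rate_mats = _prepare(dataset, neuron_ids)
    centers = starts + WINDOW_MS / 2.0
    per_neuron = {k: [] for k in _FACTOR_KEYS}
    for aov, rates in zip(designs, rate_mats):
        w = aov.omega2(rates)
        for name, key in _FACTOR_KEYS.items():
            per_neuron[name].append(w[key])
    return {
        name: PEVSeries(
            name, centers, np.mean(np.stack(vals), axis=0), None, len(neuron_ids)
        )
        for name, vals in per_neuron.items()
    }


def permutation_threshold(
    dataset: Dataset,
    neuron_ids: list[int],
    n_shuffle: int = 1000,
    rng: np.random.Generator | None = None,
    q: float = 95.0,
) -> dict[str, np.ndarray]:
    """Per-factor, per-time 95th percentile of the null mean omega-squared."""
    if n_shuffle < 100:
        raise ValueError("n_shuffle must be >= 100")
    rng = rng or np.random.default_rng()
    starts, designs, rate_mats = _prepare(dataset, neuron_ids)
    n_windows = len(starts)
    null = {k: np.empty((n_shuffle, n_windows)) for k in _FACTOR_KEYS}
    for s in range(n_shuffle):
        acc = {k: np.zeros(n_windows) for k in _FACTOR_KEYS}
        for aov, rates in zip(designs, rate_mats):
            # Shuffling the joint labels == permuting the trial rows.
            w = aov.omega2(rates[rng.permutation(rates.shape[0])])
            for name, key in _FACTOR_KEYS.items():
                acc[name] += w[key]
        for name in _FACTOR_KEYS:
            null[name][s] = acc[name] / len(neuron_ids)
    return {name: np.percentile(null[name], q, axis=0) for name in _FACTOR_KEYS}


def pev_analysis(
    dataset: Dataset,
    neuron_ids: list[int],
    n_shuffle: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, PEVSeries]:
    """Observed series with permutation thresholds attached."""
    series = sliding_pev(dataset, neuron_ids)
    thresholds = permutation_threshold(dataset, neuron_ids, n_shuffle, rng)
    for name, s in series.items():
        s.null_q95 = thresholds[name]
    return series


def series_to_frame(series: dict[str, PEVSeries]) -> pd.DataFrame:
    rows = []
    for name, s in series.items():
        for i, t in enumerate(s.time_centers_ms):
            rows.append(
                {
                    "factor": name,
                    "time_ms": t,
                    "mean_omega2": s.mean_omega2[i],
                    "null_q95": np.nan if s.null_q95 is None else s.null_q95[i],
                    "n_neurons": s.n_neurons,
                }
            )
    return pd.DataFrame(rows)


def crossover_time_ms(series: dict[str, PEVSeries]) -> float | None:
    """First window midpoint (>= delay onset) at which the numerosity series
    rises above the format series after having started below it; None if the
    handover never happens."""
    num = series["numerosity"]
    fmt = series["format"]
    diff = num.mean_omega2 - fmt.mean_omega2
    started_below = diff[0] < 0
    for t, d in zip(num.time_centers_ms, diff):
        if started_below and d > 0:
            return float(t)
    return None
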