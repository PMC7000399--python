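"""Neuron selectivity classification, tuning curves and overlap statistics.

A neuron is numerosity selective in an epoch when a two-factor ANOVA on its
correct-trial firing rates shows a numerosity main effect at p < 0.01 with no
cofactor or interaction effect at that level.  The cofactor is the protocol
(standard vs. control) for the two sample epochs, which are analyzed
separately per presentation format, and the presentation format for the delay
epoch.

Analysis windows (ms):

* simultaneous sample: stimulus onset + 100 to onset + 900 (latency shift,
  full 800 ms display);
* sequential sample: per item, onset + 100 for the item duration clipped to
  800 ms; the rate pools all item windows of the trial;
* delay: delay onset + 600 for 500 ms (the window deliberately overhangs the
  nominal delay end by 100 ms).

Sequential-standard numerosity-1 trials carry a jittered pre-sample phase and
are excluded from the delay analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from numcrow.anova import TwoWayAnova
from numcrow.stimgen import Format, NUMEROSITIES, Protocol, SeqCondition
from numcrow.synthdata import Dataset

#: Response-latency shift of the sample analysis windows, ms.
LATENCY_SHIFT_MS = 100.0
#: Cap on a single item/stimulus analysis window, ms.
MAX_WINDOW_MS = 800.0
#: Delay window: onset + 600 ms, lasting 500 ms.
DELAY_WINDOW = (600.0, 1100.0)
#: Selectivity criterion.
ALPHA = 0.01
#: Inclusion: minimum session-wide mean firing rate, Hz.
MIN_RATE_HZ = 0.5
#: Inclusion: minimum correct trials per numerosity x format x protocol cell.
MIN_CORRECT_PER_CONDITION = 3


class Epoch(str, enum.Enum):
    SAMPLE_SEQ = "sample_seq"
    SAMPLE_SIM = "sample_sim"
    DELAY = "delay"


@dataclass
class SelectivityResult:
    neuron_id: int
    epoch: Epoch
    included: bool
    p_numerosity: float
    p_cofactor: float
    p_interaction: float
    selective: bool
    preferred_numerosity: int | None
    mean_rates: np.ndarray  # per numerosity 1..4, Hz


@dataclass
class TuningCurve:
    preferred_numerosity: int
    normalized: np.ndarray  # per numerosity 1..4, in [0, 1]
    n_neurons: int


def _count(times: np.ndarray, t0: float, t1: float) -> int:
    return int(np.searchsorted(times, t1) - np.searchsorted(times, t0))


def epoch_windows(trial_row: pd.Series, epoch: Epoch, timing=None) -> list[tuple[float, float]]:
    """Analysis window(s) of an epoch for one trial, in ms from trial start."""
    if epoch is Epoch.SAMPLE_SIM:
        on = trial_row["sample_on"]
        return [(on + LATENCY_SHIFT_MS, on + LATENCY_SHIFT_MS + MAX_WINDOW_MS)]
    if epoch is Epoch.SAMPLE_SEQ:
        if timing is None:
            raise ValueError("sequential epoch needs the trial's timing")
        on = timing.item_onsets(trial_row["sample_on"])
        dur = np.minimum(timing.item_durations_ms, MAX_WINDOW_MS)
        return [(a + LATENCY_SHIFT_MS, a + LATENCY_SHIFT_MS + d) for a, d in zip(on, dur)]
    d_on = trial_row["delay_on"]
    return [(d_on + DELAY_WINDOW[0], d_on + DELAY_WINDOW[1])]


def epoch_rate(spike_times: np.ndarray, windows: list[tuple[float, float]]) -> float:
    """Pooled firing rate over the window(s): total spikes / total time, Hz."""
    total_ms = sum(t1 - t0 for t0, t1 in windows)
    if total_ms <= 0:
        raise ValueError("empty analysis window")
    n = sum(_count(spike_times, t0, t1) for t0, t1 in windows)
    return 1000.0 * n / total_ms


def _epoch_trials(dataset: Dataset, epoch: Epoch, correct_only: bool = True) -> pd.DataFrame:
    df = dataset.trials
    if correct_only:
        df = df[df["correct"] == True]  # noqa: E712
    if epoch is Epoch.SAMPLE_SEQ:
        return df[df["format"] == Format.SEQ.value]
    if epoch is Epoch.SAMPLE_SIM:
        return df[df["format"] == Format.SIM.value]
    # Delay: drop sequential-standard numerosity-1 trials (jittered pre-sample).
    drop = (
        (df["format"] == Format.SEQ.value)
        & (df["protocol"] == Protocol.STANDARD.value)
        & (df["sample_numerosity"] == 1)
    )
    return df[~drop]


def trial_rates(
    dataset: Dataset, neuron_id: int, epoch: Epoch, trials: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-trial epoch firing rates of one neuron, with factor labels."""
    if trials is None:
        trials = _epoch_trials(dataset, epoch)
    spikes = dataset.spikes[neuron_id]
    rows = []
    for _, tr in trials.iterrows():
        tid = int(tr["trial_id"])
        windows = epoch_windows(tr, epoch, dataset.timings.get(tid))
        rows.append(
            {
                "trial_id": tid,
                "rate": epoch_rate(spikes[tid], windows),
                "numerosity": int(tr["sample_numerosity"]),
                "protocol": tr["protocol"],
                "format": tr["format"],
            }
        )
    return pd.DataFrame(rows)


def meets_inclusion(dataset: Dataset, neuron_id: int) -> bool:
    """Session-wide mean rate >= 0.5 Hz and >= 3 correct trials per
    numerosity x format x protocol cell."""
    spikes = dataset.spikes[neuron_id]
    total_spikes = sum(len(v) for v in spikes.values())
    total_s = dataset.trials["trial_end"].sum() / 1000.0
    if total_spikes / total_s < MIN_RATE_HZ:
        return False
    correct = dataset.trials[dataset.trials["correct"] == True]  # noqa: E712
    counts = correct.groupby(["sample_numerosity", "format", "protocol"]).size()
    if len(counts) < 16 or counts.min() < MIN_CORRECT_PER_CONDITION:
        return False
    return True


def classify_selectivity(
    rates: pd.DataFrame, epoch: Epoch, alpha: float = ALPHA, neuron_id: int = -1
) -> SelectivityResult:
    """Two-way ANOVA classification of one neuron in one epoch.

    ``rates`` must come from :func:`trial_rates` (correct trials).  The
    cofactor is the protocol for sample epochs and the format for the delay.
    """
    cofactor = "format" if epoch is Epoch.DELAY else "protocol"
    aov = TwoWayAnova(rates["numerosity"], rates[cofactor]).anova(rates["rate"].to_numpy())
    p_num = float(aov.p["a"])
    p_cof = float(aov.p["b"])
    p_int = float(aov.p["ab"])
    selective = (p_num < alpha) and (p_cof >= alpha) and (p_int >= alpha)
    means = np.array(
        [
            rates.loc[rates["numerosity"] == n, "rate"].mean() if (rates["numerosity"] == n).any() else np.nan
            for n in NUMEROSITIES
        ]
    )
    preferred = int(NUMEROSITIES[int(np.nanargmax(means))]) if selective else None
    return SelectivityResult(neuron_id, epoch, True, p_num, p_cof, p_int, selective, preferred, means)


def classify_all(dataset: Dataset, epochs: tuple[Epoch, ...] = tuple(Epoch)) -> pd.DataFrame:
    """Selectivity classification of every neuron in the requested epochs."""
    rows = []
    epoch_trials = {e: _epoch_trials(dataset, e) for e in epochs}
    for nsp in dataset.neurons:
        included = meets_inclusion(dataset, nsp.neuron_id)
        for epoch in epochs:
            if not included:
                res = SelectivityResult(
                    nsp.neuron_id, epoch, False, np.nan, np.nan, np.nan, False, None, np.full(4, np.nan)
                )
            else:
                rates = trial_rates(dataset, nsp.neuron_id, epoch, epoch_trials[epoch])
                res = classify_selectivity(rates, epoch, neuron_id=nsp.neuron_id)
            rows.append(
                {
                    "neuron_id": res.neuron_id,
                    "epoch": epoch.value,
                    "included": res.included,
                    "p_numerosity": res.p_numerosity,
                    "p_cofactor": res.p_cofactor,
                    "p_interaction": res.p_interaction,
                    "selective": res.selective,
                    "preferred_numerosity": (
                        np.nan if res.preferred_numerosity is None else res.preferred_numerosity
                    ),
                    **{f"rate_n{n}": res.mean_rates[i] for i, n in enumerate(NUMEROSITIES)},
                }
            )
    return pd.DataFrame(rows)


def delay_selective_ids(table: pd.DataFrame, exclusive: bool = True) -> list[int]:
    """Neurons selective during the delay; by default exclusively so (not
    numerosity selective in either sample epoch)."""
    piv = table.pivot(index="neuron_id", columns="epoch", values="selective")
    mask = piv[Epoch.DELAY.value].astype(bool)
    if exclusive:
        mask &= ~piv[Epoch.SAMPLE_SEQ.value].astype(bool)
        mask &= ~piv[Epoch.SAMPLE_SIM.value].astype(bool)
    return [int(i) for i in piv.index[mask]]


def normalize_and_pool(results: list[SelectivityResult]) -> list[TuningCurve]:
    """Min-max normalize each selective neuron's tuning, then average within
    preferred-numerosity groups."""
    groups: dict[int, list[np.ndarray]] = {}
    for r in results:
        if not r.selective or r.preferred_numerosity is None:
            continue
        lo, hi = np.nanmin(r.mean_rates), np.nanmax(r.mean_rates)
        if hi - lo <= 1e-12:
            import warnings

            warnings.warn(f"neuron {r.neuron_id}: flat tuning, skipped")
            continue
        groups.setdefault(r.preferred_numerosity, []).append((r.mean_rates - lo) / (hi - lo))
    return [
        TuningCurve(pref, np.mean(np.stack(v), axis=0), len(v))
        for pref, v in sorted(groups.items())
    ]


def chance_overlap_percent(n_a: int, n_b: int, n_total: int) -> float:
    """Chance percentage of neurons selective in both of two independent
    classifications: 100 * (n_a/N) * (n_b/N)."""
    if n_total <= 0:
        raise ValueError("total neuron count must be positive")
    if not (0 <= n_a <= n_total and 0 <= n_b <= n_total):
        raise ValueError("counts must lie in [0, N]")
    return 100.0 * (n_a / n_total) * (n_b / n_total)


def overlap_binomial_test(observed: int, n_total: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= observed | N, p0)."""
    if not (0 <= observed <= n_total):
        raise ValueError("observed must lie in [0, N]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(stats.binom.sf(observed - 1, n_total, p0))


def preferred_correlation(
    pref_a, pref_b, n_perm: int = 10000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Spearman correlation of preferred numerosities with a permutation p.

    With only four distinct levels the rank statistic is tie-laden, so the
    p-value is estimated by shuffling one vector (asymptotic p-values are
    unreliable at these sample sizes).
    """
    a = np.asarray(pref_a, dtype=float)
    b = np.asarray(pref_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired preferred numerosities")
    rng = rng or np.random.default_rng()
    rho = stats.spearmanr(a, b).statistic
    if np.isnan(rho):
        return float("nan"), float("nan")
    count = 0
    for _ in range(n_perm):
        r = stats.spearmanr(a, rng.permutation(b)).statistic
        if np.isnan(r) or abs(r) >= abs(rho) - 1e-12:
            count += 1
    return float(rho), (count + 1) / (n_perm + 1)


def error_trial_comparison(
    dataset: Dataset,
    results: list[SelectivityResult],
    epoch: Epoch,
    min_errors: int = 3,
) -> tuple[float, float, int]:
    """Correct- vs. error-trial rates at the preferred numerosity.

    For every selective neuron with at least ``min_errors`` error trials at
    its preferred numerosity (same format as the epoch), the mean error-trial
    rate is expressed as a percentage of the mean correct-trial rate.
    Returns (mean normalized error level in %, Wilcoxon signed-rank p over
    the paired raw rates, number of neurons contributing).
    """
    fmt = Format.SEQ.value if epoch is Epoch.SAMPLE_SEQ else Format.SIM.value
    df = dataset.trials
    if epoch is Epoch.DELAY:
        sub = _epoch_trials(dataset, epoch, correct_only=False)
    else:
        sub = df[df["format"] == fmt]
    correct_pairs, error_pairs = [], []
    for r in results:
        if not r.selective or r.preferred_numerosity is None:
            continue
        pref = r.preferred_numerosity
        at_pref = sub[sub["sample_numerosity"] == pref]
        cor = at_pref[at_pref["correct"] == True]  # noqa: E712
        err = at_pref[at_pref["correct"] == False]  # noqa: E712
        if len(err) < min_errors or len(cor) == 0:
            continue
        rc = trial_rates(dataset, r.neuron_id, epoch, cor)["rate"].mean()
        re = trial_rates(dataset, r.neuron_id, epoch, err)["rate"].mean()
        if rc <= 0:
            continue
        correct_pairs.append(rc)
        error_pairs.append(re)
    n = len(correct_pairs)
    if n == 0:
        return float("nan"), float("nan"), 0
    c = np.asarray(correct_pairs)
    e = np.asarray(error_pairs)
    level = float(np.mean(100.0 * e / c))
    if np.allclose(c, e):
        p = 1.0
    else:
        p = float(stats.wilcoxon(c, e).pvalue)
    return level, p, n
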