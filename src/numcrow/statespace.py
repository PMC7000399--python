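"""Population state-space trajectories across the memory delay.

Per neuron and condition (numerosity x presentation format), correct-trial
spike trains aligned to delay onset are averaged, smoothed with a Gaussian
kernel (sigma = 150 ms), averaged in 300 ms bins stepped by 25 ms from
600 ms before delay onset to 200 ms after the nominal delay offset, and
neuron-wise z-scored over the concatenation of all conditions and bins.
The resulting condition x time state vectors live in neuron-dimensional
space; a 3-component PCA is fitted jointly over all conditions for
visualization only, while all distance summaries use the full space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from numcrow.selectivity import Epoch, _epoch_trials
from numcrow.stimgen import Format, NUMEROSITIES
from numcrow.synthdata import Dataset

KERNEL_SIGMA_MS = 150.0
BIN_MS = 300.0
STEP_MS = 25.0
SPAN_MS = (-600.0, 1200.0)  # bin centers relative to delay onset
_FINE_MS = 5.0  # resolution of the smoothed density estimate


@dataclass
class TrajectorySet:
    conditions: list[tuple[int, str]]  # (numerosity, format)
    time_centers_ms: np.ndarray
    states: np.ndarray  # (n_conditions, n_bins, n_neurons), z-scored
    neuron_ids: list[int]


def bin_centers() -> np.ndarray:
    return np.arange(SPAN_MS[0], SPAN_MS[1] + 1e-9, STEP_MS)


def _smoothed_density(
    rel_times: np.ndarray, n_trials: int, grid: np.ndarray
) -> np.ndarray:
    """Trial-averaged smoothed firing rate (Hz) on a fine time grid."""
    edges = np.concatenate([grid - _FINE_MS / 2.0, [grid[-1] + _FINE_MS / 2.0]])
    counts, _ = np.histogram(rel_times, bins=edges)
    rate = counts / (n_trials * _FINE_MS / 1000.0)
    half = int(round(4 * KERNEL_SIGMA_MS / _FINE_MS))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * _FINE_MS) / KERNEL_SIGMA_MS) ** 2)
    k /= k.sum()
    return np.convolve(rate, k, mode="same")


def condition_averaged_states(
    dataset: Dataset, neuron_ids: list[int]
) -> TrajectorySet:
    """Build z-scored condition-averaged population states.

    Conditions pool the standard/control protocols.  Neurons with zero
    variance across all conditions and bins are excluded with a warning.
    """
    trials = _epoch_trials(dataset, Epoch.DELAY)
    centers = bin_centers()
    pad = BIN_MS / 2.0 + 4 * KERNEL_SIGMA_MS
    grid = np.arange(SPAN_MS[0] - pad, SPAN_MS[1] + pad + _FINE_MS, _FINE_MS)
    conditions = [(n, f.value) for n in NUMEROSITIES for f in (Format.SEQ, Format.SIM)]

    raw = np.empty((len(conditions), len(centers), len(neuron_ids)))
    for k, nid in enumerate(neuron_ids):
        spikes = dataset.spikes[nid]
        for ci, (num, fmt) in enumerate(conditions):
            sub = trials[(trials["sample_numerosity"] == num) & (trials["format"] == fmt)]
            if len(sub) == 0:
                raise ValueError(f"no correct trials for condition n={num} {fmt}")
            rel = np.concatenate(
                [
                    spikes[int(tr["trial_id"])] - tr["delay_on"]
                    for _, tr in sub.iterrows()
                ]
            )
            dens = _smoothed_density(rel, len(sub), grid)
            half_bin = BIN_MS / 2.0
            for bi, c in enumerate(centers):
                sel = (grid >= c - half_bin) & (grid < c + half_bin)
                raw[ci, bi, k] = dens[sel].mean()

    flat = raw.reshape(-1, len(neuron_ids))
    mu = flat.mean(axis=0)
    sd = flat.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        import warnings

        dropped = [nid for nid, ok in zip(neuron_ids, keep) if not ok]
        warnings.warn(f"neurons with zero variance excluded: {dropped}")
    z = (flat[:, keep] - mu[keep]) / sd[keep]
    return TrajectorySet(
        conditions=conditions,
        time_centers_ms=centers,
        states=z.reshape(len(conditions), len(centers), -1),
        neuron_ids=[nid for nid, ok in zip(neuron_ids, keep) if ok],
    )


def pca_project(ts: TrajectorySet, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Joint PCA over all condition-time states; returns (projections,
    explained variance ratio).  For plotting only — distances use the full
    neuron-dimensional states."""
    n_neurons = ts.states.shape[2]
    if n_components > n_neurons:
        raise ValueError("n_components exceeds the number of neurons")
    flat = ts.states.reshape(-1, n_neurons)
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(flat)
    return (
        proj.reshape(ts.states.shape[0], ts.states.shape[1], n_components),
        pca.explained_variance_ratio_,
    )


def _cond_index(ts: TrajectorySet, num: int, fmt: str) -> int:
    return ts.conditions.index((num, fmt))


def format_distance(ts: TrajectorySet) -> pd.DataFrame:
    """Per-numerosity Euclidean distance (full space) between the sequential
    and simultaneous trajectories at each time bin."""
    rows = {}
    for num in NUMEROSITIES:
        a = ts.states[_cond_index(ts, num, Format.SEQ.value)]
        b = ts.states[_cond_index(ts, num, Format.SIM.value)]
        rows[num] = np.sqrt(((a - b) ** 2).sum(axis=1))
    df = pd.DataFrame(rows, index=ts.time_centers_ms)
    df.index.name = "time_ms"
    return df


def numerosity_distance(ts: TrajectorySet) -> pd.DataFrame:
    """Within-format pairwise numerosity distances pooled by numerical
    distance: delta-1 averages 1v2, 2v3, 3v4 over both formats; delta-2
    averages 1v3 and 2v4; delta-3 averages 1v4."""
    pools: dict[int, list[np.ndarray]] = {1: [], 2: [], 3: []}
    for fmt in (Format.SEQ.value, Format.SIM.value):
        for i, na in enumerate(NUMEROSITIES):
            for nb in NUMEROSITIES[i + 1 :]:
                a = ts.states[_cond_index(ts, na, fmt)]
                b = ts.states[_cond_index(ts, nb, fmt)]
                pools[nb - na].append(np.sqrt(((a - b) ** 2).sum(axis=1)))
    df = pd.DataFrame(
        {d: np.mean(np.stack(v), axis=0) for d, v in pools.items()},
        index=ts.time_centers_ms,
    )
    df.index.name = "time_ms"
    return df
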