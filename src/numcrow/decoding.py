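"""Pseudo-population SVM decoding of numerosity from delay-period rates.

Neurons are treated as independently recorded units: for each condition a
pseudo-trial conjoins one freshly sampled trial per neuron (sampled-index
alignment).  Firing rates are taken 700 ms after delay onset for 400 ms.
A linear multi-class support-vector classifier is trained on z-scored rates
(mean and SD always fitted on the training set and applied to held-out
data), cross-validated leave-one-out with 32 trials per condition, and
tested across presentation formats and on error trials.  The whole procedure
is repeated over iterations with fresh pseudo-trials; chance is 25%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from numcrow.selectivity import Epoch, _epoch_trials
from numcrow.stimgen import Format, NUMEROSITIES
from numcrow.synthdata import Dataset

#: Rate window relative to delay onset, ms.
DECODE_WINDOW = (700.0, 1100.0)
#: Correct trials sampled per numerosity x format per neuron.
TRIALS_PER_CONDITION = 32
#: Numerosities eligible for error-trial testing (numerosity-1 errors are
#: too scarce and are excluded).
ERROR_TEST_NUMEROSITIES = (2, 3, 4)
CHANCE = 0.25


@dataclass
class PseudoTrialMatrix:
    x: np.ndarray  # (rows, neurons) rates, Hz
    numerosity: np.ndarray  # (rows,)
    format: np.ndarray  # (rows,) of Format values
    correct: np.ndarray  # (rows,) bool
    neuron_ids: list[int] = field(default_factory=list)


@dataclass
class DecodeResult:
    confusion: np.ndarray  # (4, 4), rows true, columns predicted, row-stochastic
    accuracy: float
    iteration_accuracies: np.ndarray
    train_format: str
    test_format: str


def delay_rate_table(dataset: Dataset, neuron_ids: list[int]) -> pd.DataFrame:
    """Per-trial decode-window rates, one column per neuron."""
    df = dataset.trials
    width_s = (DECODE_WINDOW[1] - DECODE_WINDOW[0]) / 1000.0
    out = {"trial_id": df["trial_id"].to_numpy()}
    t0 = (df["delay_on"] + DECODE_WINDOW[0]).to_numpy()
    t1 = (df["delay_on"] + DECODE_WINDOW[1]).to_numpy()
    for nid in neuron_ids:
        spikes = dataset.spikes[nid]
        rates = np.empty(len(df))
        for i, tid in enumerate(out["trial_id"]):
            times = spikes[int(tid)]
            rates[i] = (np.searchsorted(times, t1[i]) - np.searchsorted(times, t0[i])) / width_s
        out[f"n{nid}"] = rates
    return pd.DataFrame(out).set_index("trial_id")


def included_neurons(
    dataset: Dataset,
    candidate_ids: list[int],
    min_correct: int = TRIALS_PER_CONDITION,
    min_errors: int = 1,
) -> list[int]:
    """Neurons recorded for >= 32 correct and >= 1 error trial per
    numerosity x format.  All simulated neurons share the session's trials,
    so the criterion either admits all candidates or none; it is kept
    per-neuron for datasets assembled from multiple sessions."""
    df = dataset.trials
    ok = True
    for num in NUMEROSITIES:
        for fmt in (Format.SEQ.value, Format.SIM.value):
            cell = df[(df["sample_numerosity"] == num) & (df["format"] == fmt)]
            n_cor = int((cell["correct"] == True).sum())  # noqa: E712
            n_err = int((cell["correct"] == False).sum())  # noqa: E712
            if n_cor < min_correct or n_err < min_errors:
                ok = False
    return list(candidate_ids) if ok else []


def assemble_pseudotrials(
    rate_table: pd.DataFrame,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    n_per_condition: int = TRIALS_PER_CONDITION,
    correct: bool = True,
) -> PseudoTrialMatrix:
    """Sample ``n_per_condition`` trials per numerosity x format per neuron
    (without replacement, independently across neurons) and conjoin them
    row-wise into pseudo-trials."""
    neuron_cols = list(rate_table.columns)
    df = trials[trials["correct"] == correct]
    # per-neuron streams keyed by neuron id, so reordering neurons permutes
    # the matrix columns without changing any neuron's draws
    base = int(rng.integers(0, 2**31))
    xs, nums, fmts = [], [], []
    for num in NUMEROSITIES:
        for fi, fmt in enumerate((Format.SEQ.value, Format.SIM.value)):
            cell_ids = df.loc[
                (df["sample_numerosity"] == num) & (df["format"] == fmt), "trial_id"
            ].to_numpy()
            if len(cell_ids) < n_per_condition:
                raise ValueError(
                    f"cell n={num} fmt={fmt}: {len(cell_ids)} trials < {n_per_condition}"
                )
            block = np.empty((n_per_condition, len(neuron_cols)))
            for j, col in enumerate(neuron_cols):
                child = np.random.default_rng([base, int(col[1:]), num, fi])
                chosen = child.choice(cell_ids, size=n_per_condition, replace=False)
                block[:, j] = rate_table.loc[chosen, col].to_numpy()
            xs.append(block)
            nums.append(np.full(n_per_condition, num))
            fmts.append(np.full(n_per_condition, fmt, dtype=object))
    return PseudoTrialMatrix(
        x=np.vstack(xs),
        numerosity=np.concatenate(nums),
        format=np.concatenate(fmts).astype(str),
        correct=np.full(8 * n_per_condition, correct),
        neuron_ids=[int(c[1:]) for c in neuron_cols],
    )


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance neuron in training fold; column scaled to 0")
    return mu, sd


def _zscore_apply(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    return np.where(sd > 0, z, 0.0)


def _svc() -> SVC:
    # linear kernel (polynomial of degree one), default regularization
    return SVC(kernel="linear", C=1.0)


def _confusion(true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    m = np.zeros((4, 4))
    for t, p in zip(true, pred):
        m[int(t) - 1, int(p) - 1] += 1
    rows = m.sum(axis=1, keepdims=True)
    return np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)


def _loo_folds(n_per_class: int, labels: np.ndarray) -> list[np.ndarray]:
    """Fold i holds out the i-th sampled row of every class."""
    folds = []
    classes = np.unique(labels)
    index_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for i in range(n_per_class):
        folds.append(np.array([index_by_class[c][i] for c in classes]))
    return folds


def loo_cross_validate(
    matrix: PseudoTrialMatrix, fmt: str | None = None
) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation on one pseudo-trial matrix.

    Returns (accuracy, 4x4 row-stochastic confusion).  Each fold refits the
    z-scoring on the 31-trial training set.
    """
    if fmt is not None:
        keep = matrix.format == fmt
        x, y = matrix.x[keep], matrix.numerosity[keep]
    else:
        x, y = matrix.x, matrix.numerosity
    n_per_class = int(np.bincount(y).max())
    folds = _loo_folds(n_per_class, y)
    trues, preds = [], []
    for held in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[held] = False
        mu, sd = _zscore_fit(x[mask])
        clf = _svc().fit(_zscore_apply(x[mask], mu, sd), y[mask])
        preds.extend(clf.predict(_zscore_apply(x[held], mu, sd)))
        trues.extend(y[held])
    trues = np.asarray(trues)
    preds = np.asarray(preds)
    return float(np.mean(trues == preds)), _confusion(trues, preds)


def decode_within_format(
    dataset: Dataset,
    neuron_ids: list[int],
    fmt: Format | str,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    rate_table: pd.DataFrame | None = None,
) -> DecodeResult:
    """Within-format leave-one-out decoding over fresh pseudo-trial draws."""
    fmt = Format(fmt).value
    rng = rng or np.random.default_rng()
    if rate_table is None:
        rate_table = delay_rate_table(dataset, neuron_ids)
    accs, conf = [], np.zeros((4, 4))
    for _ in range(n_iterations):
        m = assemble_pseudotrials(rate_table, dataset.trials, rng)
        a, c = loo_cross_validate(m, fmt)
        accs.append(a)
        conf += c
    conf /= n_iterations
    accs = np.asarray(accs)
    return DecodeResult(conf, float(accs.mean()), accs, fmt, fmt)


def cross_format_test(
    matrix: PseudoTrialMatrix, train_fmt: str, test_fmt: str
) -> tuple[float, np.ndarray]:
    """Train on all trials of one format, test on the other format's rows,
    standardized with the training mean and SD."""
    tr = matrix.format == train_fmt
    te = matrix.format == test_fmt
    if not tr.any() or not te.any():
        raise ValueError("both formats must be present in the pseudo-trial matrix")
    mu, sd = _zscore_fit(matrix.x[tr])
    clf = _svc().fit(_zscore_apply(matrix.x[tr], mu, sd), matrix.numerosity[tr])
    pred = clf.predict(_zscore_apply(matrix.x[te], mu, sd))
    true = matrix.numerosity[te]
    return float(np.mean(pred == true)), _confusion(true, pred)


def decode_cross_format(
    dataset: Dataset,
    neuron_ids: list[int],
    train_fmt: Format | str,
    n_iterations: int = 100,
    rng: np.random.Generator | None = None,
    rate_table: pd.DataFrame | None = None,
) -> DecodeResult:
    """Cross-format transfer decoding over fresh pseudo-trial draws."""
    train_fmt = Format(train_fmt).value
    test_fmt = Format.SIM.value if train_fmt == Format.SEQ.value else Format.SEQ.value
    rng = rng or np.random.default_rng()
    if rate_table is None:
        rate_table = delay_rate_table(dataset, neuron_ids)
    accs, conf = [], np.zeros((4, 4))
    for _ in range(n_iterations):
        m = assemble_pseudotrials(rate_table, dataset.trials, rng)
        a, c = cross_format_test(m, train_fmt, test_fmt)
        accs.append(a)
        conf += c
    conf /= n_iterations
    accs = np.asarray(accs)
    return DecodeResult(conf, float(accs.mean()), accs, train_fmt, test_fmt)


def error_trial_decode(
    dataset: Dataset,
    neuron_ids: list[int],
    n_outer: int = 100,
    n_inner: int = 32,
    rng: np.random.Generator | None = None,
    rate_table: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Correct- vs. error-trial decoding with a both-format classifier.

    Per outer iteration: train on 32 sequential + 32 simultaneous correct
    trials per numerosity (with leave-one-out cross-validation providing the
    correct-trial accuracy), then test the full model on ``n_inner`` random
    draws of one error trial per numerosity (2-4) and format.  Returns the
    paired (correct, error) accuracy distributions over outer iterations.
    """
    rng = rng or np.random.default_rng()
    if rate_table is None:
        rate_table = delay_rate_table(dataset, neuron_ids)
    trials = dataset.trials
    err = trials[trials["correct"] == False]  # noqa: E712
    err_cells: dict[tuple[int, str], np.ndarray] = {}
    for num in ERROR_TEST_NUMEROSITIES:
        for fmt in (Format.SEQ.value, Format.SIM.value):
            ids = err.loc[
                (err["sample_numerosity"] == num) & (err["format"] == fmt), "trial_id"
            ].to_numpy()
            if len(ids) == 0:
                warnings.warn(f"no error trials for n={num} {fmt}; cell skipped")
                continue
            err_cells[(num, fmt)] = ids
    if not err_cells:
        raise ValueError("no error trials available for testing")

    correct_accs = np.empty(n_outer)
    error_accs = np.empty(n_outer)
    for it in range(n_outer):
        m = assemble_pseudotrials(rate_table, trials, rng)
        correct_accs[it], _ = loo_cross_validate(m)
        mu, sd = _zscore_fit(m.x)
        clf = _svc().fit(_zscore_apply(m.x, mu, sd), m.numerosity)
        inner = np.empty(n_inner)
        for j in range(n_inner):
            rows, labels = [], []
            for (num, _fmt), ids in err_cells.items():
                tid = int(rng.choice(ids))
                rows.append(rate_table.loc[tid].to_numpy())
                labels.append(num)
            pred = clf.predict(_zscore_apply(np.vstack(rows), mu, sd))
            inner[j] = np.mean(pred == np.asarray(labels))
        error_accs[it] = inner.mean()
    return correct_accs, error_accs


def auc_separation(dist_a, dist_b) -> float:
    """Rank-based AUC: probability a random value from ``dist_a`` exceeds one
    from ``dist_b``, counting ties as one half."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distributions must be non-empty")
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float((greater + 0.5 * ties) / (a.size * b.size))


def confusion_by_distance(confusion: np.ndarray) -> np.ndarray:
    """Mean confusion probability per numerical distance 0..3."""
    out = np.empty(4)
    for d in range(4):
        vals = [
            confusion[i, j]
            for i in range(4)
            for j in range(4)
            if abs(i - j) == d
        ]
        out[d] = float(np.mean(vals))
    return out
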