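"""Psychometric performance functions for the match-to-numerosity task.

The central object is the performance curve: for a given sample numerosity,
the probability that the subject judged the first test numerosity as equal to
the sample, as a function of the test numerosity.  Match points come from
match trials and non-match points from non-match trials, so each point is an
independent conditional probability (the curve is not a distribution).

Two classic signatures are summarized: the numerical distance effect
(bell-shaped curves peaking at the sample) and the numerical size effect
(curves widen with the sample numerosity), quantified by a Gaussian fit on
the log2 test-numerosity axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from numcrow.stimgen import NUMEROSITIES, Choice


@dataclass
class PerformanceCurve:
    """P(match response at test 1 | test numerosity) for one sample condition."""

    sample_numerosity: int
    format: str
    protocol: str  # "standard", "control" or "pooled"
    p_match: np.ndarray  # per test numerosity 1..4, nan where no trials
    n_trials: np.ndarray  # per test numerosity


def _match_responses(trials: pd.DataFrame) -> pd.Series:
    return trials["choice"] == Choice.RESPOND_AT_TEST1.value


def performance_curves(
    trials: pd.DataFrame, pool_protocols: bool = False
) -> list[PerformanceCurve]:
    """Compute performance curves per (sample, format[, protocol]).

    Cells without trials are reported as nan probabilities with zero counts,
    never as zero probability.
    """
    if "choice" not in trials or (trials["choice"] == "").any():
        raise ValueError("trials must have recorded choices")
    df = trials.copy()
    df["responded_match"] = _match_responses(df)
    group_cols = ["sample_numerosity", "format"]
    if not pool_protocols:
        group_cols.append("protocol")
    curves = []
    for key, grp in df.groupby(group_cols):
        sample, fmt = key[0], key[1]
        proto = key[2] if not pool_protocols else "pooled"
        p = np.full(4, np.nan)
        n = np.zeros(4, dtype=int)
        for i, test in enumerate(NUMEROSITIES):
            cell = grp[grp["test1_numerosity"] == test]
            n[i] = len(cell)
            if n[i]:
                p[i] = cell["responded_match"].mean()
        curves.append(PerformanceCurve(int(sample), str(fmt), str(proto), p, n))
    return curves


def curves_to_frame(curves: list[PerformanceCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i, test in enumerate(NUMEROSITIES):
            rows.append(
                {
                    "sample_numerosity": c.sample_numerosity,
                    "format": c.format,
                    "protocol": c.protocol,
                    "test_numerosity": test,
                    "p_match_response": c.p_match[i],
                    "n_trials": c.n_trials[i],
                }
            )
    return pd.DataFrame(rows)


def percent_correct(trials: pd.DataFrame, grouping: list[str] | None = None) -> pd.DataFrame:
    """Proportion correct per group with a two-sided exact binomial test.

    Chance is 0.5: match and non-match trials are equiprobable and the
    decision is a binary release/hold choice.
    """
    if grouping is None:
        grouping = ["sample_numerosity", "format", "protocol"]
    df = trials.copy()
    rows = []
    grouped = df.groupby(grouping) if grouping else [((), df)]
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        if n == 0:
            continue
        k = int(grp["correct"].sum())
        test = stats.binomtest(k, n, 0.5, alternative="two-sided")
        row = dict(zip(grouping, key))
        row.update(
            {
                "n_trials": n,
                "n_correct": k,
                "percent_correct": 100.0 * k / n,
                "p_binomial": test.pvalue,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _log_gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((np.log2(x) - mu) ** 2) / (2.0 * sigma**2))


@dataclass
class CurveFit:
    sample_numerosity: int
    format: str
    protocol: str
    peak: float
    mu_log2: float
    sigma_log2: float
    converged: bool


def distance_size_summary(curves: list[PerformanceCurve]) -> pd.DataFrame:
    """Least-squares Gaussian fit (log2 test axis) of each performance curve.

    The Gaussian is centered on the sample numerosity (four data points do
    not constrain a free center reliably) and two parameters are fitted:
    peak amplitude and width ``sigma_log2`` in octaves.  ``sigma_linear``
    converts the width to the linear numerosity axis at the sample
    (``sigma_log2 * sample * ln 2``); the numerical size effect appears as
    linear widths growing with the sample numerosity.  Degenerate (flat or
    sparsely defined) curves are flagged as non-converged.
    """
    rows = []
    for c in curves:
        mask = ~np.isnan(c.p_match)
        x = np.asarray(NUMEROSITIES, dtype=float)[mask]
        y = c.p_match[mask]
        fit = CurveFit(c.sample_numerosity, c.format, c.protocol, np.nan, np.nan, np.nan, False)
        if mask.sum() >= 3 and np.ptp(y) > 1e-9:
            mu = float(np.log2(c.sample_numerosity))
            # binomial standard errors as weights (floored away from zero)
            n = np.maximum(c.n_trials[mask], 1)
            se = np.sqrt(np.maximum(y * (1 - y), 0.25 / n) / n)
            try:
                popt, _ = optimize.curve_fit(
                    lambda x_, amp, sigma: _log_gaussian(x_, amp, mu, sigma),
                    x,
                    y,
                    p0=[max(y.max(), 1e-3), 0.5],
                    sigma=se,
                    absolute_sigma=True,
                    bounds=([0.0, 1e-3], [1.5, 5.0]),
                    maxfev=5000,
                )
                fit.peak, fit.sigma_log2 = map(float, popt)
                fit.mu_log2 = mu
                fit.converged = True
            except RuntimeError:
                pass
        row = vars(fit).copy()
        row["sigma_linear"] = fit.sigma_log2 * c.sample_numerosity * np.log(2.0)
        rows.append(row)
    return pd.DataFrame(rows)


def model_match_probability(
    sample: int, test: int, weber_w: float, lapse_rate: float = 0.0
) -> float:
    """Closed-form P(match response at test 1) under the estimate model.

    The internal estimate is N(log2 sample, w^2); the subject responds
    "match" exactly when the estimate falls in the readout bin of the test
    numerosity (bins bounded by midpoints between adjacent log2 levels).
    This is the analytic counterpart of
    :func:`numcrow.synthdata.simulate_choice` and serves as the oracle for
    simulated performance curves.
    """
    levels = np.log2(np.asarray(NUMEROSITIES, dtype=float))
    i = NUMEROSITIES.index(test)
    lo = -np.inf if i == 0 else 0.5 * (levels[i - 1] + levels[i])
    hi = np.inf if i == len(levels) - 1 else 0.5 * (levels[i] + levels[i + 1])
    mu = np.log2(sample)
    p_bin = stats.norm.cdf(hi, mu, weber_w) - stats.norm.cdf(lo, mu, weber_w)
    return float((1.0 - lapse_rate) * p_bin + lapse_rate * 0.5)
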