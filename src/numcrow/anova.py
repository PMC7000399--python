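"""Two-way fixed-effects ANOVA with Type II sums of squares and omega-squared.

This is the statistical workhorse shared by the selectivity classification
and the sliding-window explained-variance analysis.  It is written against
column-stacked response matrices so that one set of design projections can be
reused across many response series (time windows, neurons, permutations):
permuting the factor labels jointly is equivalent to permuting the rows of
the response matrix while keeping the design fixed.

Type II sums of squares are used so that unbalanced cell counts (only correct
trials enter the analyses) do not let one factor absorb the other's variance:
SS_A = SSE(B) - SSE(A+B), SS_B = SSE(A) - SSE(A+B),
SS_AxB = SSE(A+B) - SSE(A+B+AxB).

The effect size is Hays' omega squared,
``omega2_f = (SS_f - df_f * MS_error) / (SS_total + MS_error)``,
which may be slightly negative under the null and is deliberately not
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats, linalg

_EFFECTS = ("a", "b", "ab")


def _codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, inv = np.unique(labels, return_inverse=True)
    return inv.astype(np.intp)


def _dummies(codes: np.ndarray) -> np.ndarray:
    k = int(codes.max()) + 1 if codes.size else 0
    d = np.zeros((codes.size, k))
    if k:
        d[np.arange(codes.size), codes] = 1.0
    return d[:, 1:]  # treatment coding


def _basis(*blocks: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis and rank of the column space of stacked blocks."""
    X = np.hstack([b for b in blocks if b.shape[1] > 0] or [blocks[0]])
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], 0)), 0
    q, r, _ = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return q[:, :rank], rank


@dataclass
class AnovaResult:
    """Per-effect statistics; each field maps effect -> array over response columns."""

    ss: dict[str, np.ndarray]
    df: dict[str, int]
    f: dict[str, np.ndarray]
    p: dict[str, np.ndarray]
    ms_error: np.ndarray
    df_error: int
    ss_total: np.ndarray

    def omega2(self) -> dict[str, np.ndarray]:
        denom = self.ss_total + self.ms_error
        out = {}
        for eff in _EFFECTS:
            with np.errstate(invalid="ignore", divide="ignore"):
                w = (self.ss[eff] - self.df[eff] * self.ms_error) / denom
            out[eff] = np.where(denom > 1e-12, w, 0.0)
        return out


class TwoWayAnova:
    """Fixed design for a two-factor layout, reusable across response columns.

    Parameters
    ----------
    a_labels, b_labels:
        Factor levels per observation (any hashable values). Factor ``a`` is
        the effect of scientific interest (numerosity); factor ``b`` is the
        cofactor (protocol or presentation format).
    """

    def __init__(self, a_labels, b_labels) -> None:
        a = _codes(a_labels)
        b = _codes(b_labels)
        if a.size != b.size:
            raise ValueError("factor label lengths differ")
        self.n = int(a.size)
        one = np.ones((self.n, 1))
        A = _dummies(a)
        B = _dummies(b)
        AB = (A[:, :, None] * B[:, None, :]).reshape(self.n, -1)
        self._q_full, r_full = _basis(one, A, B, AB)
        self._q_add, r_add = _basis(one, A, B)
        self._q_a, r_a = _basis(one, A)
        self._q_b, r_b = _basis(one, B)
        self.df = {
            "a": r_add - r_b,
            "b": r_add - r_a,
            "ab": r_full - r_add,
        }
        self.df_error = self.n - r_full
        if self.df_error < 1:
            raise ValueError("no error degrees of freedom (too few observations)")

    @staticmethod
    def _sse(q: np.ndarray, y: np.ndarray, yty: np.ndarray) -> np.ndarray:
        proj = q.T @ y
        return np.maximum(yty - np.einsum("ij,ij->j", proj, proj), 0.0)

    def anova(self, y: np.ndarray) -> AnovaResult:
        """Run the ANOVA on one response vector or a (n, m) response matrix."""
        y = np.asarray(y, dtype=float)
        squeeze = y.ndim == 1
        if squeeze:
            y = y[:, None]
        if y.shape[0] != self.n:
            raise ValueError("response length does not match design")
        yty = np.einsum("ij,ij->j", y, y)
        sse_full = self._sse(self._q_full, y, yty)
        sse_add = self._sse(self._q_add, y, yty)
        sse_a = self._sse(self._q_a, y, yty)
        sse_b = self._sse(self._q_b, y, yty)
        ss = {
            "a": np.maximum(sse_b - sse_add, 0.0),
            "b": np.maximum(sse_a - sse_add, 0.0),
            "ab": np.maximum(sse_add - sse_full, 0.0),
        }
        ms_error = sse_full / self.df_error
        ss_total = yty - (y.sum(0) ** 2) / self.n
        f: dict[str, np.ndarray] = {}
        p: dict[str, np.ndarray] = {}
        tiny = 1e-12
        for eff in _EFFECTS:
            d = self.df[eff]
            if d == 0:
                f[eff] = np.zeros_like(ms_error)
                p[eff] = np.ones_like(ms_error)
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                fv = (ss[eff] / d) / ms_error
            fv = np.where(ms_error > tiny, fv, np.where(ss[eff] > tiny, np.inf, 0.0))
            f[eff] = fv
            p[eff] = stats.f.sf(fv, d, self.df_error)
        res = AnovaResult(ss, dict(self.df), f, p, ms_error, self.df_error, ss_total)
        if squeeze:
            res = AnovaResult(
                {k: v[0] for k, v in res.ss.items()},
                res.df,
                {k: v[0] for k, v in res.f.items()},
                {k: v[0] for k, v in res.p.items()},
                res.ms_error[0],
                res.df_error,
                res.ss_total[0],
            )
        return res

    def omega2(self, y: np.ndarray) -> dict[str, np.ndarray]:
        """Omega-squared per effect for one vector or a response matrix."""
        return self.anova(y).omega2()


def omega_squared_two_way(rates, a_labels, b_labels) -> tuple[float, float, float]:
    """Convenience wrapper: omega2 for (factor A, factor B, interaction)."""
    w = TwoWayAnova(a_labels, b_labels).omega2(np.asarray(rates, dtype=float))
    return float(w["a"]), float(w["b"]), float(w["ab"])
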