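"""Question-to-lecture-moment matching and topic-variability comparisons.

A question's topic vector is correlated (Pearson) with the lecture
trajectory's topic vector at every second; the peak of that series locates
the lecture moment the question is most "about".  Comparing the per-topic
variance of a lecture's trajectory with that of a question set measures how
similar the two are in which themes they modulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import KnowmapWarning
from .topics import Trajectory

__all__ = [
    "CorrelationSeries",
    "question_timepoint_correlations",
    "peak_match",
    "topic_variability",
    "variability_correlation",
]


def _pearson_to_rows(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson r of vector ``x`` against each row of ``rows``.

    Zero-variance pairs yield r = 0 (degenerate: a constant vector carries no
    directional information).
    """
    x = np.asarray(x, dtype=np.float64)
    rows = np.asarray(rows, dtype=np.float64)
    xc = x - x.mean()
    rc = rows - rows.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xc**2).sum())
    rnorm = np.sqrt((rc**2).sum(axis=1))
    denom = xnorm * rnorm
    out = np.zeros(rows.shape[0])
    ok = denom > 0
    out[ok] = (rc[ok] @ xc) / denom[ok]
    return np.clip(out, -1.0, 1.0)


@dataclass(frozen=True)
class CorrelationSeries:
    qid: str
    lecture_id: str
    times: np.ndarray
    r: np.ndarray  # per-second Pearson correlation, in [-1, 1]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.r):
            raise ValueError("times and r length mismatch")


def question_timepoint_correlations(
    question_vector: np.ndarray, traj: Trajectory, qid: str = ""
) -> CorrelationSeries:
    """Correlate a question's topic vector with every trajectory second."""
    q = np.asarray(question_vector, dtype=np.float64)
    if q.shape[0] != traj.k:
        raise ValueError(f"dimension mismatch: question {q.shape[0]}, trajectory {traj.k}")
    if np.allclose(q, q[0]):
        warnings.warn(
            f"question {qid!r} has a constant (zero-variance) topic vector; r = 0",
            KnowmapWarning,
            stacklevel=2,
        )
    r = _pearson_to_rows(q, traj.vectors)
    return CorrelationSeries(qid=qid, lecture_id=traj.lecture_id, times=traj.times.copy(), r=r)


def peak_match(series: CorrelationSeries) -> tuple[float, float]:
    """(t_peak, r_peak): earliest timepoint attaining the maximum correlation."""
    i = int(np.argmax(series.r))  # argmax returns the first maximum on ties
    return float(series.times[i]), float(series.r[i])


def topic_variability(vectors: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Per-topic population variance (ddof=0) across observations."""
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D array of topic vectors")
    return arr.var(axis=0, ddof=0)


def variability_correlation(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pearson r between two per-topic variance vectors with a bootstrap CI.

    The 95% CI is the 2.5/97.5 percentile interval of ``n_boot`` correlations
    computed on resamples (with replacement) of the k paired values.
    Degenerate resamples (zero variance on either side) contribute r = 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("variance vectors must have equal length")
    k = len(a)

    def _r(x: np.ndarray, y: np.ndarray) -> float:
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        if denom == 0:
            # degenerate resample: exactly collinear (incl. both constant) -> 1
            return 1.0 if np.allclose(xc, yc) else 0.0
        return float(np.clip(xc @ yc / denom, -1.0, 1.0))

    r = _r(a, b)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, k, size=(n_boot, k))
    boots = np.array([_r(a[idx[i]], b[idx[i]]) for i in range(n_boot)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r, float(lo), float(hi)
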