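"""Correlation-weighted knowledge estimation from graded quiz responses.

The central estimator: a participant's knowledge about the concept at
embedding coordinate ``x`` is the weighted proportion of quiz questions they
answered correctly,

    k_hat(x) = sum_{i in correct} ncorr(x, q_i) / sum_{j=1..N} ncorr(x, q_j),

where each question's weight ``ncorr`` is the Pearson correlation between
``x`` and the question's topic vector, min-max normalized over the relevant
(timepoint, question) correlation set so every question contributes a
non-negative amount.  Evaluating k_hat at every second of a lecture
trajectory yields a *knowledge trace*; evaluating it at a held-out question's
coordinate (with the rebalancing correction) yields the per-question
estimates consumed by the mixed-model validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import KnowmapWarning
from .ingest import GENERAL_AREA
from .topics import Trajectory

__all__ = [
    "ResponseItem",
    "ResponseSet",
    "build_response_sets",
    "NormalizationBounds",
    "KnowledgeTrace",
    "compute_bounds",
    "ncorr",
    "knowledge_trace",
    "knowledge_at",
    "heldout_estimate",
    "heldout_table",
    "HeldoutEstimator",
    "compare_quiz_knowledge",
]

HeldoutMode = Literal["all", "within_lecture", "across_lecture"]


@dataclass(frozen=True)
class ResponseItem:
    qid: str
    embedding: np.ndarray  # topic vector of the question
    correct: bool
    area: str  # lecture id or "general"


@dataclass(frozen=True)
class ResponseSet:
    """One participant's graded answers on one quiz."""

    participant: str
    quiz: int
    items: tuple[ResponseItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(
                f"participant {self.participant!r} quiz {self.quiz}: empty response set"
            )

    def __len__(self) -> int:
        return len(self.items)

    @property
    def n_correct(self) -> int:
        return sum(item.correct for item in self.items)

    @property
    def proportion_correct(self) -> float:
        return self.n_correct / len(self.items)

    def about(self, area: str) -> tuple[ResponseItem, ...]:
        return tuple(item for item in self.items if item.area == area)

    def embeddings(self) -> np.ndarray:
        return np.vstack([item.embedding for item in self.items])


@dataclass(frozen=True)
class NormalizationBounds:
    mincorr: float
    maxcorr: float

    def __post_init__(self) -> None:
        if self.mincorr > self.maxcorr:
            raise ValueError("mincorr exceeds maxcorr")

    @property
    def degenerate(self) -> bool:
        return self.maxcorr == self.mincorr


@dataclass(frozen=True)
class KnowledgeTrace:
    participant: str
    quiz: int
    lecture_id: str
    times: np.ndarray
    khat: np.ndarray  # per-second estimated knowledge in [0, 1]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.khat):
            raise ValueError("times and khat length mismatch")
        if np.any((self.khat < -1e-12) | (self.khat > 1 + 1e-12)):
            raise ValueError("khat must lie in [0, 1]")

    def mean(self) -> float:
        return float(self.khat.mean())


def build_response_sets(
    table, embeddings: dict[str, np.ndarray], pool
) -> list[ResponseSet]:
    """Assemble per-(participant, quiz) response sets from a response table.

    ``embeddings`` maps qid -> topic vector; ``pool`` supplies each
    question's content area.
    """
    area_of = {q.qid: q.area for q in pool}
    cells: dict[tuple[str, int], list[ResponseItem]] = {}
    for participant, quiz, qid, correct in table.rows:
        cells.setdefault((participant, quiz), []).append(
            ResponseItem(
                qid=qid,
                embedding=np.asarray(embeddings[qid], dtype=np.float64),
                correct=bool(correct),
                area=area_of[qid],
            )
        )
    return [
        ResponseSet(participant=p, quiz=qz, items=tuple(items))
        for (p, qz), items in sorted(cells.items())
    ]


# --------------------------------------------------------------------------- #
# correlations and normalization
# --------------------------------------------------------------------------- #


def _corr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of ``x`` and rows of ``y``.

    Zero-variance rows correlate 0 with everything.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc**2).sum(axis=1))
    yn = np.sqrt((yc**2).sum(axis=1))
    num = xc @ yc.T
    denom = np.outer(xn, yn)
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def compute_bounds(
    lecture_vectors: np.ndarray, question_vectors: np.ndarray
) -> NormalizationBounds:
    """Min/max correlation over all (timepoint, question) pairs."""
    c = _corr_matrix(lecture_vectors, question_vectors)
    return NormalizationBounds(mincorr=float(c.min()), maxcorr=float(c.max()))


def ncorr(x: np.ndarray, y: np.ndarray, b: NormalizationBounds) -> float:
    """Min-max normalized correlation, clipped to [0, 1].

    When the bounds are degenerate (all relevant correlations equal), every
    pair is assigned weight 1, reducing the estimator to an unweighted
    proportion correct.
    """
    if b.degenerate:
        warnings.warn(
            "degenerate normalization bounds (mincorr == maxcorr); "
            "all pairs weighted 1",
            KnowmapWarning,
            stacklevel=2,
        )
        return 1.0
    c = _corr_matrix(x, y)[0, 0]
    return float(np.clip((c - b.mincorr) / (b.maxcorr - b.mincorr), 0.0, 1.0))


def _ncorr_weights(corr: np.ndarray, b: NormalizationBounds) -> np.ndarray:
    if b.degenerate:
        return np.ones_like(corr)
    return np.clip((corr - b.mincorr) / (b.maxcorr - b.mincorr), 0.0, 1.0)


# --------------------------------------------------------------------------- #
# knowledge estimators
# --------------------------------------------------------------------------- #


def knowledge_trace(rs: ResponseSet, traj: Trajectory, lecture_id: str | None = None) -> KnowledgeTrace:
    """Estimated knowledge at every second of a lecture.

    Normalization bounds are taken over all trajectory timepoints and all
    questions in ``rs`` (the questions about this lecture on this quiz).
    Timepoints where every weight is zero fall back to the participant's
    overall proportion correct.
    """
    q = rs.embeddings()
    corr = _corr_matrix(traj.vectors, q)  # (T, N)
    b = NormalizationBounds(float(corr.min()), float(corr.max()))
    if b.degenerate:
        warnings.warn(
            "degenerate normalization bounds over the lecture/question set; "
            "trace equals the unweighted proportion correct",
            KnowmapWarning,
            stacklevel=2,
        )
    w = _ncorr_weights(corr, b)
    correct = np.array([item.correct for item in rs.items], dtype=bool)
    num = w[:, correct].sum(axis=1)
    den = w.sum(axis=1)
    khat = np.full(len(den), rs.proportion_correct)
    nonzero = den > 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} timepoint(s) received zero total weight; "
            "falling back to the overall proportion correct there",
            KnowmapWarning,
            stacklevel=2,
        )
    khat[nonzero] = num[nonzero] / den[nonzero]
    return KnowledgeTrace(
        participant=rs.participant,
        quiz=rs.quiz,
        lecture_id=lecture_id or traj.lecture_id,
        times=traj.times.copy(),
        khat=np.clip(khat, 0.0, 1.0),
    )


def knowledge_at(
    x: np.ndarray, items: Sequence[ResponseItem], b: NormalizationBounds
) -> float:
    """Estimated knowledge at a single coordinate ``x`` from graded items.

    This is the trace estimator applied to a "lecture" consisting of the
    single timepoint ``x``.
    """
    if not items:
        raise ValueError("empty item set")
    q = np.vstack([item.embedding for item in items])
    corr = _corr_matrix(np.asarray(x)[None, :], q)[0]
    w = _ncorr_weights(corr, b)
    den = w.sum()
    correct = np.array([item.correct for item in items], dtype=bool)
    if den == 0:
        warnings.warn(
            "zero total weight at the query coordinate; falling back to the "
            "proportion correct",
            KnowmapWarning,
            stacklevel=2,
        )
        return float(correct.mean())
    return float(np.clip(w[correct].sum() / den, 0.0, 1.0))


def _candidate_items(
    rs: ResponseSet, target: ResponseItem, mode: HeldoutMode
) -> list[ResponseItem]:
    others = [item for item in rs.items if item.qid != target.qid]
    if mode == "all":
        return others
    if target.area == GENERAL_AREA:
        raise ValueError(
            f"general-knowledge target {target.qid!r} is only valid in mode='all'"
        )
    if mode == "within_lecture":
        return [item for item in others if item.area == target.area]
    if mode == "across_lecture":
        lecture_areas = sorted(
            {item.area for item in rs.items if item.area != GENERAL_AREA}
        )
        other_lectures = [a for a in lecture_areas if a != target.area]
        return [item for item in others if item.area in other_lectures]
    raise ValueError(f"unknown mode {mode!r}")


def heldout_estimate(
    target_qid: str,
    rs: ResponseSet,
    mode: HeldoutMode = "all",
    rebalance: bool | None = None,
) -> float | None:
    """Held-out knowledge estimate at a target question's coordinate.

    ``mode`` selects the candidate estimation set: all other items on the
    quiz, other items about the same lecture, or all items about the other
    lecture.  For the ``all`` / ``within_lecture`` modes the target's own
    correctness mechanically shifts the candidates' proportion correct, so a
    *rebalancing* correction is applied (and is the default): each remaining
    opposite-correctness item is held out alongside the target in turn, the
    estimate is computed from the rest, and the per-subset estimates are
    averaged.  Every subset then contains ``n - 1`` correct answers out of
    ``q - 2`` items (``n`` = correct answers among the target plus
    candidates, ``q`` = their total count), so the null expectation
    ``(n-1)/(q-2)`` is the same for correct and incorrect targets.

    Returns ``None`` (the excluded-marker) when the candidate set is empty or
    rebalancing finds no opposite-label item (e.g. a participant with a
    perfect or zero score on the quiz).
    """
    target = next((item for item in rs.items if item.qid == target_qid), None)
    if target is None:
        raise KeyError(f"target qid {target_qid!r} not in response set")
    if rebalance is None:
        rebalance = mode in ("all", "within_lecture")
    candidates = _candidate_items(rs, target, mode)
    if not candidates:
        return None

    def _estimate(items: Sequence[ResponseItem]) -> float:
        q = np.vstack([item.embedding for item in items])
        corr = _corr_matrix(np.asarray(target.embedding)[None, :], q)[0]
        b = NormalizationBounds(float(corr.min()), float(corr.max()))
        w = _ncorr_weights(corr, b)
        correct = np.array([item.correct for item in items], dtype=bool)
        den = w.sum()
        if den == 0:
            return float(correct.mean())
        return float(np.clip(w[correct].sum() / den, 0.0, 1.0))

    if not rebalance:
        return _estimate(candidates)
    opposite = [item for item in candidates if item.correct != target.correct]
    if not opposite:
        return None
    estimates = []
    for held in opposite:
        subset = [item for item in candidates if item.qid != held.qid]
        if not subset:
            return None
        estimates.append(_estimate(subset))
    return float(np.mean(estimates))


def heldout_table(
    response_sets: Iterable[ResponseSet], mode: HeldoutMode = "all"
) -> pd.DataFrame:
    """Per-question held-out estimates as a mixed-model input table.

    Columns: participant, quiz, qid, lecture (area), knowledge, accuracy.
    Excluded targets (no valid candidate/rebalancing set) are dropped.
    General-knowledge targets are only estimated in mode ``all``.
    """
    rows = []
    for rs in response_sets:
        for item in rs.items:
            if mode != "all" and item.area == GENERAL_AREA:
                continue
            est = heldout_estimate(item.qid, rs, mode=mode)
            if est is None:
                continue
            rows.append(
                {
                    "participant": rs.participant,
                    "quiz": rs.quiz,
                    "qid": item.qid,
                    "lecture": item.area,
                    "knowledge": est,
                    "accuracy": int(item.correct),
                }
            )
    return pd.DataFrame(rows, columns=["participant", "quiz", "qid", "lecture", "knowledge", "accuracy"])


class HeldoutEstimator:
    """Precomputed held-out estimation for fast re-estimation.

    The ncorr weights entering a held-out estimate depend only on the
    question embeddings, never on correctness labels, so they can be computed
    once per (participant, quiz) cell.  Re-estimating the knowledge column
    for a *new* response vector (as the full-pipeline parametric bootstrap
    requires) then costs a handful of dot products per cell instead of a full
    pass through the correlation machinery.

    Rows are ordered exactly as :func:`heldout_table` orders them, except
    that rows excluded for the observed labels are kept (with NaN knowledge)
    so the row set is label-independent.
    """

    def __init__(self, response_sets: Iterable[ResponseSet], mode: HeldoutMode = "all"):
        self.mode = mode
        self.rows: list[dict] = []
        self._cells: list[tuple[int, np.ndarray, list]] = []
        rebalance = mode in ("all", "within_lecture")
        self.rebalance = rebalance
        row_idx = 0
        for rs in response_sets:
            items = rs.items
            included = [
                i for i, item in enumerate(items)
                if mode == "all" or item.area != GENERAL_AREA
            ]
            if not included:
                continue
            emb = rs.embeddings()
            corr = _corr_matrix(emb, emb)
            cell_rows = []
            plans = []
            for i in included:
                target = items[i]
                cand = [
                    j for j, it in enumerate(items)
                    if j != i and it in _candidate_items(rs, target, mode)
                ]
                if not cand:
                    continue
                if rebalance:
                    # one weight vector per potential opposite-label holdout
                    per_holdout = []
                    for o in cand:
                        subset = [j for j in cand if j != o]
                        if not subset:
                            per_holdout.append((o, None, None))
                            continue
                        c = corr[i, subset]
                        lo, hi = c.min(), c.max()
                        w = np.ones_like(c) if hi == lo else np.clip((c - lo) / (hi - lo), 0, 1)
                        per_holdout.append((o, np.array(subset), w / w.sum()))
                    plans.append((i, None, per_holdout))
                else:
                    c = corr[i, cand]
                    lo, hi = c.min(), c.max()
                    w = np.ones_like(c) if hi == lo else np.clip((c - lo) / (hi - lo), 0, 1)
                    plans.append((i, (np.array(cand), w / w.sum()), None))
                cell_rows.append(
                    {
                        "participant": rs.participant,
                        "quiz": rs.quiz,
                        "qid": target.qid,
                        "lecture": target.area,
                        "item_index": i,
                    }
                )
            y_cell = np.array([it.correct for it in items], dtype=np.float64)
            self._cells.append((row_idx, y_cell, plans))
            for r in cell_rows:
                r["row"] = row_idx
                self.rows.append(r)
                row_idx += 1
        self.n_rows = row_idx
        self.y_observed = np.concatenate(
            [
                y[[p[0] for p in plans]]
                for _, y, plans in self._cells
            ]
        ) if self._cells else np.empty(0)
        self._item_counts = [len(y) for _, y, _ in self._cells]

    def recompute(self, accuracy: np.ndarray) -> np.ndarray:
        """Knowledge column for a new per-row accuracy vector.

        ``accuracy`` is aligned with this estimator's rows.  Items of the
        quiz that are not rows of the table (general-knowledge questions in
        the lecture-restricted modes) keep their observed labels; they never
        enter any candidate set in those modes, so this is inconsequential.
        Rows whose rebalancing finds no opposite-label item get NaN.
        """
        accuracy = np.asarray(accuracy, dtype=np.float64)
        if len(accuracy) != self.n_rows:
            raise ValueError("accuracy vector does not match the row count")
        out = np.full(self.n_rows, np.nan)
        row = 0
        for start, y_cell, plans in self._cells:
            y = y_cell.copy()
            k = len(plans)
            for offset, (i, _, _) in enumerate(plans):
                y[i] = accuracy[start + offset]
            for offset, (i, direct, per_holdout) in enumerate(plans):
                if not self.rebalance:
                    cand, w = direct
                    out[start + offset] = float(w @ y[cand])
                else:
                    ests = [
                        float(w @ y[subset])
                        for (o, subset, w) in per_holdout
                        if w is not None and y[o] != y[i]
                    ]
                    if ests:
                        out[start + offset] = float(np.mean(ests))
            row += k
        return np.clip(out, 0.0, 1.0)

    def table(self, accuracy: np.ndarray | None = None) -> pd.DataFrame:
        """The mixed-model input table (NaN-knowledge rows retained)."""
        if accuracy is None:
            accuracy = self.y_observed
        knowledge = self.recompute(accuracy)
        df = pd.DataFrame(
            [
                {
                    "participant": r["participant"],
                    "quiz": r["quiz"],
                    "qid": r["qid"],
                    "lecture": r["lecture"],
                }
                for r in self.rows
            ]
        )
        df["knowledge"] = knowledge
        df["accuracy"] = np.asarray(accuracy, dtype=np.float64).astype(int)
        return df


def compare_quiz_knowledge(
    traces: Iterable[KnowledgeTrace],
) -> dict[tuple[int, int], tuple[float, int, float]]:
    """Paired t-tests of time-averaged knowledge between quiz pairs.

    Each participant's trace is averaged over timepoints; for every ordered
    quiz pair (a < b) present, a two-sided paired t-test across participants
    compares quiz ``b`` against quiz ``a`` (positive t means higher knowledge
    on the later quiz).  Returns ``{(a, b): (t, df, p)}``.
    """
    by_quiz: dict[int, dict[str, float]] = {}
    for tr in traces:
        by_quiz.setdefault(tr.quiz, {})[tr.participant] = tr.mean()
    out: dict[tuple[int, int], tuple[float, int, float]] = {}
    for a, b in combinations(sorted(by_quiz), 2):
        shared = sorted(set(by_quiz[a]) & set(by_quiz[b]))
        if len(shared) < 2:
            continue
        xa = np.array([by_quiz[a][p] for p in shared])
        xb = np.array([by_quiz[b][p] for p in shared])
        if np.allclose(xa, xb):
            out[(a, b)] = (0.0, len(shared) - 1, 1.0)  # zero-variance differences
            continue
        res = stats.ttest_rel(xb, xa)
        out[(a, b)] = (float(res.statistic), len(shared) - 1, float(res.pvalue))
    return out
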