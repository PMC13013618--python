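"""How quiz performance falls off with embedding distance ("smoothness").

For each reference question a participant answered, concentric spheres of
correlation-distance radius 0.00, 0.01, ..., 2.00 are grown around its
embedding coordinate and the proportion of enclosed questions answered
correctly is tracked, separately for correctly and incorrectly answered
references.  At radius 2 every sphere encloses the full quiz, so both curves
converge to the participant's overall proportion correct.

The *divergence distance* of a curve is the smallest radius at which it
becomes statistically indistinguishable from the overall proportion correct,
estimated with a nested bootstrap: an outer resample of participants, and an
inner bootstrap giving the 95% confidence band of the across-participant
mean overall proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .knowledge import ResponseSet, _corr_matrix

__all__ = [
    "RADII",
    "SmoothnessCurves",
    "proportion_within_radius",
    "average_curves",
    "divergence_distance",
]

#: The sphere radii: correlation distance 0.00 to 2.00 in steps of 0.01.
RADII: np.ndarray = np.round(np.arange(0, 201) * 0.01, 2)


@dataclass(frozen=True)
class SmoothnessCurves:
    """Per-radius conditional proportion-correct curves for one participant-quiz.

    Curve values are NaN at radii where the participant has no reference
    question with the corresponding correctness label.
    """

    participant: str
    quiz: int
    radii: np.ndarray
    given_correct: np.ndarray  # proportion correct within r of correct references
    given_incorrect: np.ndarray
    overall: float

    def __post_init__(self) -> None:
        if len(self.radii) != 201:
            raise ValueError("expected the 201-point radius grid")


def proportion_within_radius(rs: ResponseSet) -> SmoothnessCurves:
    """Sphere curves for one participant's quiz responses.

    Each quiz item serves as a reference in turn; the reference itself counts
    as enclosed in its own sphere (so at radius 0 the correct-reference curve
    is 1 and the incorrect-reference curve is 0 whenever embeddings are
    distinct).
    """
    emb = rs.embeddings()
    correct = np.array([item.correct for item in rs.items], dtype=bool)
    dist = 1.0 - _corr_matrix(emb, emb)  # (N, N) correlation distances
    # enclosed[i, j, r] would be dist[i, j] <= RADII[r]; vectorize over radii
    enclosed = dist[:, :, None] <= RADII[None, None, :] + 1e-12  # (N, N, 201)
    n_in = enclosed.sum(axis=1)  # (N, 201)
    n_correct_in = (enclosed & correct[None, :, None]).sum(axis=1)
    per_ref = n_correct_in / n_in  # n_in >= 1 (the reference itself)

    def _avg(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            return np.full(len(RADII), np.nan)
        out = per_ref[mask].mean(axis=0)
        # correlation distance never exceeds 2, so the final sphere encloses
        # the full quiz for every reference: the average equals the overall
        # proportion exactly (avoid the rounding of the float mean)
        out[-1] = rs.proportion_correct
        return out

    return SmoothnessCurves(
        participant=rs.participant,
        quiz=rs.quiz,
        radii=RADII.copy(),
        given_correct=_avg(correct),
        given_incorrect=_avg(~correct),
        overall=rs.proportion_correct,
    )


def average_curves(curves: Sequence[SmoothnessCurves]) -> tuple[np.ndarray, np.ndarray]:
    """Across-participant means of the two conditional curves.

    Participants lacking a given reference label (NaN curves) are dropped
    from the mean at every radius for that label.
    """
    gc = np.vstack([c.given_correct for c in curves])
    gi = np.vstack([c.given_incorrect for c in curves])
    with np.errstate(invalid="ignore"):
        return np.nanmean(gc, axis=0), np.nanmean(gi, axis=0)


def _first_inside(curve: np.ndarray, lo: float, hi: float) -> tuple[float, bool]:
    """Minimum radius at which the curve lies inside [lo, hi].

    Returns (radius, flagged) where ``flagged`` marks curves that never enter
    the band (radius 2 is then reported).
    """
    inside = (curve >= lo) & (curve <= hi) & ~np.isnan(curve)
    idx = np.where(inside)[0]
    if len(idx) == 0:
        return float(RADII[-1]), True
    return float(RADII[idx[0]]), False


def divergence_distance(
    response_sets: Iterable[ResponseSet],
    n_outer: int = 10_000,
    n_inner: int = 1_000,
    seed: int = 0,
) -> dict[int, dict[str, dict[str, float]]]:
    """Nested-bootstrap divergence distances per quiz and reference label.

    Outer loop: resample participants with replacement and average their
    sphere curves.  Inner loop (per quiz): percentile 95% CI of the
    across-participant mean overall proportion correct.  The per-iteration
    divergence distance is the smallest radius at which the averaged curve
    enters that CI.  Returns, per quiz and per label (``"correct"`` /
    ``"incorrect"``), the mean distance and its 2.5/97.5 percentile CI over
    outer iterations, plus the fraction of iterations whose curve never
    entered the band.
    """
    sets = list(response_sets)
    participants = sorted({rs.participant for rs in sets})
    if len(participants) < 2:
        raise ValueError("need at least 2 participants")
    quizzes = sorted({rs.quiz for rs in sets})
    # precompute per-participant curves once; the bootstrap only reindexes
    curves: dict[int, dict[str, SmoothnessCurves]] = {qz: {} for qz in quizzes}
    for rs in sets:
        curves[rs.quiz][rs.participant] = proportion_within_radius(rs)

    rng = np.random.default_rng(seed)
    n_p = len(participants)
    dists: dict[int, dict[str, list[float]]] = {
        qz: {"correct": [], "incorrect": []} for qz in quizzes
    }
    flags: dict[int, dict[str, int]] = {qz: {"correct": 0, "incorrect": 0} for qz in quizzes}
    for _ in range(n_outer):
        outer_idx = rng.integers(0, n_p, size=n_p)
        chosen = [participants[i] for i in outer_idx]
        for qz in quizzes:
            qcurves = [curves[qz][p] for p in chosen if p in curves[qz]]
            if not qcurves:
                continue
            overall = np.array([c.overall for c in qcurves])
            inner = overall[rng.integers(0, len(overall), size=(n_inner, len(overall)))]
            lo, hi = np.percentile(inner.mean(axis=1), [2.5, 97.5])
            mean_gc, mean_gi = average_curves(qcurves)
            for label, curve in (("correct", mean_gc), ("incorrect", mean_gi)):
                d, flagged = _first_inside(curve, lo, hi)
                dists[qz][label].append(d)
                flags[qz][label] += flagged

    out: dict[int, dict[str, dict[str, float]]] = {}
    for qz in quizzes:
        out[qz] = {}
        for label in ("correct", "incorrect"):
            arr = np.array(dists[qz][label])
            lo, hi = np.percentile(arr, [2.5, 97.5])
            out[qz][label] = {
                "mean": float(arr.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "never_intersected_fraction": flags[qz][label] / len(arr),
            }
    return out
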