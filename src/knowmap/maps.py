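"""2D knowledge and learning maps over a projected topic space.

Topic vectors (every lecture second plus every question, from a
high-resolution model, typically k = 100) are log-transformed and projected
to a plane.  The default projector for analysis pipelines is UMAP with
correlation distance in the high-dimensional space and Euclidean distance in
the plane; a deterministic *linear* projector (top-2 principal directions of
the log-vectors, exactly invertible on its subspace) is provided for tests
and reproducible runs.  Inverting a plane coordinate exponentiates the
inverse-projected log-vector and renormalizes, so any map location yields a
valid topic mixture that can be rendered as a weighted word list.

Knowledge at a plane coordinate x is the RBF-weighted proportion of
correctly answered questions,

    k_hat(x) = sum_{i in correct} RBF(x, q_i) / sum_j RBF(x, q_j),
    RBF(x, mu) = exp(-||x - mu||^2 / lambda),

evaluated on a 100 x 100 grid tiling the bounding rectangle of the projected
lectures and questions.  A learning map is the pointwise difference of two
knowledge maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import KnowmapWarning
from .knowledge import ResponseSet
from .topics import TopicModel, Trajectory

__all__ = [
    "Projection",
    "RBFConfig",
    "KnowledgeMap",
    "fit_projection",
    "invert_coordinate",
    "build_grid",
    "knowledge_map",
    "learning_map",
    "word_cloud",
]

_LOG_EPS = 1e-12


@dataclass
class Projection:
    """An (approximately) invertible 2D projection of log-topic vectors."""

    method: str  # "linear" or "umap"
    mean_log: np.ndarray  # (k,)
    components: np.ndarray | None  # (2, k) for linear
    fit_metadata: dict = field(default_factory=dict)
    _umap: object | None = field(default=None, repr=False)

    def forward(self, vectors: np.ndarray) -> np.ndarray:
        """Topic vectors (rows) -> (n, 2) plane coordinates."""
        logv = np.log(np.asarray(vectors, dtype=np.float64) + _LOG_EPS)
        if self.method == "linear":
            return (logv - self.mean_log) @ self.components.T
        return np.asarray(self._umap.transform(logv), dtype=np.float64)

    def inverse_log(self, xy: np.ndarray) -> np.ndarray:
        """Plane coordinates (rows) -> log-topic vectors (approximate)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        if self.method == "linear":
            return xy @ self.components + self.mean_log
        return np.asarray(self._umap.inverse_transform(xy), dtype=np.float64)


@dataclass(frozen=True)
class RBFConfig:
    """Radial-basis-function bandwidth, in squared plane units.

    The default of 50 gives smooth maps at the plane scales produced by the
    projectors here; smaller values sharpen the maps around the questions.
    """

    lam: float = 50.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass(frozen=True)
class KnowledgeMap:
    grid: np.ndarray  # (n_grid, 2) plane coordinates
    values: np.ndarray  # (n_grid,), in [0, 1]
    quiz: int
    shape: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        if self.grid.shape[0] != self.values.shape[0]:
            raise ValueError("grid / values length mismatch")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("knowledge map values must lie in [0, 1]")


def fit_projection(
    vectors: np.ndarray,
    method: str = "linear",
    seed: int = 0,
    **umap_kwargs,
) -> Projection:
    """Fit the 2D projection on log-transformed topic vectors.

    ``method="linear"`` takes the top-2 principal directions of the centered
    log-vectors (deterministic, exactly invertible on the fitted subspace).
    ``method="umap"`` uses UMAP with 1 - correlation as the high-dimensional
    metric and Euclidean plane distances, seeded for per-run reproducibility.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 3:
        raise ValueError("need at least 3 vectors to fit a 2D projection")
    logv = np.log(vectors + _LOG_EPS)
    mean_log = logv.mean(axis=0)
    centered = logv - mean_log
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate spread: all vectors are identical")
    if method == "linear":
        # top-2 right singular vectors of the centered log matrix
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] <= s[0] * 1e-12:
            warnings.warn(
                "log-vectors span fewer than 2 directions; second axis is arbitrary",
                KnowmapWarning,
                stacklevel=2,
            )
        components = vt[:2]
        return Projection(
            method="linear",
            mean_log=mean_log,
            components=components,
            fit_metadata={"seed": seed, "singular_values": s[:2].tolist()},
        )
    if method == "umap":
        import umap

        reducer = umap.UMAP(
            n_components=2,
            metric="correlation",
            output_metric="euclidean",
            random_state=seed,
            **umap_kwargs,
        )
        reducer.fit(logv)
        return Projection(
            method="umap",
            mean_log=mean_log,
            components=None,
            fit_metadata={
                "seed": seed,
                "high_d_metric": "1 - correlation",
                "low_d_metric": "euclidean",
                **umap_kwargs,
            },
            _umap=reducer,
        )
    raise ValueError(f"unknown projection method {method!r}")


def invert_coordinate(p: Projection, xy: np.ndarray) -> np.ndarray:
    """Plane coordinate(s) -> simplex topic vector(s).

    The inverse-projected log-vector is exponentiated and normalized to sum
    to one, so the output is always a valid topic mixture.
    """
    logv = p.inverse_log(xy)
    v = np.exp(logv - logv.max(axis=1, keepdims=True))  # stable exponentiation
    v = v / v.sum(axis=1, keepdims=True)
    return v[0] if np.asarray(xy).ndim == 1 else v


def build_grid(
    points: np.ndarray, shape: tuple[int, int] = (100, 100), pad: float = 0.02
) -> np.ndarray:
    """Regular grid tiling the bounding rectangle of projected points.

    The rectangle is padded by ``pad`` (fraction of each side) so lecture
    trajectories do not touch the border.  Returns (nx * ny, 2) coordinates.
    """
    points = np.asarray(points, dtype=np.float64)
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    xs = np.linspace(lo[0], hi[0], shape[0])
    ys = np.linspace(lo[1], hi[1], shape[1])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _rbf_weights(grid: np.ndarray, centers: np.ndarray, lam: float) -> np.ndarray:
    d2 = ((grid[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / lam)


def knowledge_map(
    grid: np.ndarray,
    question_coords: dict[str, np.ndarray],
    response_sets: Sequence[ResponseSet] | ResponseSet,
    cfg: RBFConfig | None = None,
    quiz: int | None = None,
) -> KnowledgeMap:
    """RBF-weighted proportion-correct over the plane grid.

    ``question_coords`` maps qid -> 2D coordinate.  When several response
    sets are given (one per participant), their per-participant maps are
    averaged.  The denominator is strictly positive (Gaussians never vanish),
    so the map is defined everywhere.
    """
    if cfg is None:
        cfg = RBFConfig()
    if isinstance(response_sets, ResponseSet):
        response_sets = [response_sets]
    if not response_sets:
        raise ValueError("no response sets given")
    grid = np.asarray(grid, dtype=np.float64)
    total = np.zeros(grid.shape[0])
    for rs in response_sets:
        centers = np.vstack([question_coords[item.qid] for item in rs.items])
        correct = np.array([item.correct for item in rs.items], dtype=bool)
        w = _rbf_weights(grid, centers, cfg.lam)
        total += w[:, correct].sum(axis=1) / w.sum(axis=1)
    values = np.clip(total / len(response_sets), 0.0, 1.0)
    qz = quiz if quiz is not None else response_sets[0].quiz
    return KnowledgeMap(grid=grid, values=values, quiz=qz)


def learning_map(a: KnowledgeMap, b: KnowledgeMap) -> np.ndarray:
    """Pointwise change in knowledge from map ``a`` to map ``b`` (b - a)."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("knowledge maps must share the same grid")
    return b.values - a.values


def word_cloud(
    model: TopicModel,
    v: np.ndarray,
    lectures: Sequence[Trajectory],
    top_n: int = 25,
) -> list[tuple[str, float, float]]:
    """Top-weighted words for a topic mixture, with lecture association.

    Word weights are ``v @ topic_word``.  The association score in [-1, 1]
    contrasts each word's expected weight under the first lecture's
    time-averaged topic mixture against the second's (positive: more
    characteristic of the first lecture).  With one lecture the association
    is 0.  Ties in weight break by vocabulary order.
    """
    v = np.asarray(v, dtype=np.float64)
    weights = v @ model.topic_word  # (|V|,)
    if len(lectures) >= 2:
        mix_a = lectures[0].vectors.mean(axis=0) @ model.topic_word
        mix_b = lectures[1].vectors.mean(axis=0) @ model.topic_word
        denom = mix_a + mix_b
        assoc = np.where(denom > 0, (mix_a - mix_b) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        assoc = np.zeros_like(weights)
    # stable sort on (-weight, vocabulary index): vocabulary order breaks ties
    order = np.lexsort((np.arange(len(weights)), -weights))[:top_n]
    return [
        (model.vocabulary[i], float(weights[i]), float(assoc[i])) for i in order
    ]
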