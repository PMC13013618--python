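"""Topic-model embeddings of windows, questions and lecture trajectories.

The pooled sliding-window corpus (across all lectures) trains a single Latent
Dirichlet Allocation model, so windows from every lecture and all quiz
questions share one k-dimensional topic space.  The number of topics is
selected as the smallest k whose fitted model leaves at least one "unused"
topic -- a topic whose word weights stay at the (uniform) prior because the
corpus did not need it -- signalling that k exceeds the number of latent
themes the corpus supports.

Per-lecture trajectories are built by embedding every window and linearly
interpolating each topic dimension to one vector per integer second of video
(1 Hz), re-normalized onto the simplex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from . import KnowmapWarning
from .corpus import WindowCorpus

__all__ = [
    "TopicModel",
    "Trajectory",
    "fit_topic_model",
    "select_num_topics",
    "embed_document",
    "build_trajectory",
]

_SIMPLEX_ATOL = 1e-9


def _count_matrix(
    documents: Sequence[Sequence[str]], vocabulary: Sequence[str]
) -> sparse.csr_matrix:
    index = {word: i for i, word in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for d, tokens in enumerate(documents):
        counts: dict[int, int] = {}
        for tok in tokens:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(d)
            cols.append(j)
            data.append(c)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(documents), len(vocabulary)), dtype=np.float64
    )


@dataclass
class TopicModel:
    """A fitted LDA model over a fixed vocabulary.

    ``topic_word`` holds the normalized word distribution of each topic
    (rows sum to 1); ``components`` keeps the raw variational pseudo-counts
    needed to transform new documents.
    """

    k: int
    vocabulary: tuple[str, ...]
    topic_word: np.ndarray  # (k, |V|), rows on the simplex
    components: np.ndarray  # raw sklearn components_, same shape
    fit_metadata: dict = field(default_factory=dict)
    _estimator: LatentDirichletAllocation | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        rowsums = self.topic_word.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=_SIMPLEX_ATOL):
            raise ValueError("topic_word rows must sum to 1")

    # -- estimator plumbing ------------------------------------------------ #

    @property
    def estimator(self) -> LatentDirichletAllocation:
        if self._estimator is None:
            est = LatentDirichletAllocation(
                n_components=self.k,
                doc_topic_prior=self.fit_metadata.get("doc_topic_prior", 1.0 / self.k),
                topic_word_prior=self.fit_metadata.get("topic_word_prior", 1.0 / self.k),
                random_state=self.fit_metadata.get("seed", 0),
            )
            est.components_ = self.components.copy()
            est.exp_dirichlet_component_ = np.exp(
                _dirichlet_expectation(self.components)
            )
            est.n_features_in_ = len(self.vocabulary)
            est.n_batch_iter_ = 1
            est.n_iter_ = 1
            # fitted attributes sklearn's transform expects
            est.doc_topic_prior_ = est.doc_topic_prior
            est.topic_word_prior_ = est.topic_word_prior
            from sklearn.utils import check_random_state

            est.random_state_ = check_random_state(est.random_state)
            self._estimator = est
        return self._estimator

    def transform_documents(self, documents: Sequence[Sequence[str]]) -> np.ndarray:
        """Embed token lists as simplex topic vectors (rows)."""
        counts = _count_matrix(documents, self.vocabulary)
        theta = self.estimator.transform(counts)
        empty = np.asarray(counts.sum(axis=1)).ravel() == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} document(s) had no in-vocabulary tokens; "
                "embedded as the uniform topic vector",
                KnowmapWarning,
                stacklevel=2,
            )
            theta[empty] = 1.0 / self.k
        theta = theta / theta.sum(axis=1, keepdims=True)
        return theta

    def unused_topics(self, tol: float = 0.01) -> list[int]:
        """Indices of topics whose word weights are uniform within ``tol``.

        Uniformity is relative: ``max |w - 1/|V|| * |V| < tol``.
        """
        v = len(self.vocabulary)
        dev = np.abs(self.topic_word - 1.0 / v).max(axis=1) * v
        return [int(i) for i in np.where(dev < tol)[0]]

    # -- serialization ----------------------------------------------------- #

    def save(self, path: str | Path) -> None:
        """Serialize to a JSON file (vocabulary, metadata, raw components)."""
        payload = {
            "k": self.k,
            "vocabulary": list(self.vocabulary),
            "components": self.components.tolist(),
            "fit_metadata": self.fit_metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        payload = json.loads(Path(path).read_text())
        components = np.asarray(payload["components"], dtype=np.float64)
        topic_word = components / components.sum(axis=1, keepdims=True)
        return cls(
            k=int(payload["k"]),
            vocabulary=tuple(payload["vocabulary"]),
            topic_word=topic_word,
            components=components,
            fit_metadata=payload.get("fit_metadata", {}),
        )


def _dirichlet_expectation(alpha: np.ndarray) -> np.ndarray:
    from scipy.special import psi

    return psi(alpha) - psi(alpha.sum(axis=1, keepdims=True))


@dataclass(frozen=True)
class Trajectory:
    """Per-second topic vectors for one lecture (1 Hz resampling)."""

    lecture_id: str
    times: np.ndarray  # 0, 1, ..., floor(duration)
    vectors: np.ndarray  # (len(times), k), rows on the simplex

    def __post_init__(self) -> None:
        if len(self.times) != self.vectors.shape[0]:
            raise ValueError("times and vectors length mismatch")
        if not np.allclose(self.vectors.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("trajectory vectors must lie on the simplex")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def at(self, t: int) -> np.ndarray:
        i = int(np.searchsorted(self.times, t))
        return self.vectors[min(i, len(self.times) - 1)]

    def to_frame(self):
        import pandas as pd

        cols = {f"topic_{i}": self.vectors[:, i] for i in range(self.k)}
        return pd.DataFrame({"time": self.times, **cols})


def fit_topic_model(
    corpora: Iterable[WindowCorpus],
    k: int,
    seed: int = 0,
    max_iter: int = 50,
    doc_topic_prior: float | None = None,
    topic_word_prior: float | None = None,
) -> TopicModel:
    """Fit LDA on the pooled window documents of all lectures.

    The vocabulary is the union of tokens across all windows.  Symmetric
    Dirichlet priors default to ``1/k``; ``max_iter`` batch variational
    passes are enough for the held-out perplexity of desk-scale corpora to
    plateau.  The fit is deterministic given ``seed``.
    """
    corpora = list(corpora)
    documents: list[tuple[str, ...]] = []
    for c in corpora:
        documents.extend(c.documents)
    vocabulary = tuple(sorted({tok for doc in documents for tok in doc}))
    if not vocabulary:
        raise ValueError("pooled corpus has an empty vocabulary after preprocessing")
    if doc_topic_prior is None:
        doc_topic_prior = 1.0 / k
    if topic_word_prior is None:
        topic_word_prior = 1.0 / k
    counts = _count_matrix(documents, vocabulary)
    est = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=doc_topic_prior,
        topic_word_prior=topic_word_prior,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
    )
    est.fit(counts)
    components = est.components_
    topic_word = components / components.sum(axis=1, keepdims=True)
    model = TopicModel(
        k=k,
        vocabulary=vocabulary,
        topic_word=topic_word,
        components=components,
        fit_metadata={
            "seed": seed,
            "doc_topic_prior": doc_topic_prior,
            "topic_word_prior": topic_word_prior,
            "max_iter": max_iter,
            "n_documents": len(documents),
        },
        _estimator=est,
    )
    return model


def select_num_topics(
    corpora: Iterable[WindowCorpus],
    k_min: int = 2,
    k_max: int = 30,
    seed: int = 0,
    tol: float = 0.01,
    **fit_kwargs,
) -> int:
    """Smallest k in ``[k_min, k_max]`` whose fit leaves an unused topic.

    Falls back to ``k_max`` (with a warning) when no scanned model contains a
    near-uniform topic.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_min > k_max:
        raise ValueError(f"k_min ({k_min}) exceeds k_max ({k_max})")
    corpora = list(corpora)
    for k in range(k_min, k_max + 1):
        model = fit_topic_model(corpora, k=k, seed=seed, **fit_kwargs)
        if model.unused_topics(tol=tol):
            return k
    warnings.warn(
        f"no model in k={k_min}..{k_max} produced an unused topic; "
        f"returning k_max={k_max}",
        KnowmapWarning,
        stacklevel=2,
    )
    return k_max


def embed_document(model: TopicModel, tokens: Sequence[str]) -> np.ndarray:
    """Embed one token list as a simplex topic vector.

    Out-of-vocabulary tokens are ignored; a document with no in-vocabulary
    tokens embeds to the uniform vector ``1/k`` (the LDA prior mean).
    """
    return model.transform_documents([tuple(tokens)])[0]


def build_trajectory(
    model: TopicModel, corpus: WindowCorpus, duration: float
) -> Trajectory:
    """Resample window embeddings to one topic vector per second.

    Each topic dimension is linearly interpolated independently over the
    window timestamps; query times outside the window range clamp to the
    nearest window's value.  Interpolated vectors are re-normalized to guard
    against floating-point drift off the simplex.
    """
    if len(corpus) == 0:
        raise ValueError("empty window corpus")
    theta = model.transform_documents(corpus.documents)
    stamps = np.asarray(corpus.timestamps, dtype=np.float64)
    times = np.arange(int(np.floor(duration)) + 1)
    if len(corpus) == 1:
        warnings.warn(
            f"corpus for {corpus.lecture_id!r} has a single window; "
            "trajectory is constant",
            KnowmapWarning,
            stacklevel=2,
        )
        vectors = np.repeat(theta, len(times), axis=0)
    else:
        order = np.argsort(stamps, kind="stable")
        stamps = stamps[order]
        theta = theta[order]
        vectors = np.column_stack(
            [np.interp(times, stamps, theta[:, j]) for j in range(model.k)]
        )
    vectors = np.clip(vectors, 0.0, None)
    vectors = vectors / vectors.sum(axis=1, keepdims=True)
    return Trajectory(lecture_id=corpus.lecture_id, times=times, vectors=vectors)
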