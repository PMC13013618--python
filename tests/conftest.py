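"""Shared fixtures: generated study worlds and fitted models.

Heavy artifacts (LDA fits, simulated studies) are session-scoped so the
acceptance checks and unit tests share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from knowmap import KnowmapWarning
from knowmap.corpus import WindowConfig, build_windows
from knowmap.knowledge import build_response_sets
from knowmap.synthetic import ScenarioConfig, make_world, simulate_responses
from knowmap.topics import build_trajectory, fit_topic_model


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", KnowmapWarning)
        yield


@pytest.fixture(scope="session")
def smooth_cfg() -> ScenarioConfig:
    """The default smooth-knowledge scenario (50 learners, 5/5/3 quizzes)."""
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def smooth_study(smooth_cfg):
    """World + responses + fitted 15-topic model + 1 Hz trajectories."""
    world = make_world(smooth_cfg)
    responses, truth = simulate_responses(world, smooth_cfg)
    corpora = [build_windows(t, WindowConfig(w=30)) for t in world.transcripts]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_topic_model(corpora, k=15, seed=0)
        trajectories = {
            t.lecture_id: build_trajectory(model, c, t.duration)
            for t, c in zip(world.transcripts, corpora)
        }
    return {
        "cfg": smooth_cfg,
        "world": world,
        "responses": responses,
        "truth": truth,
        "corpora": corpora,
        "model": model,
        "trajectories": trajectories,
    }


@pytest.fixture(scope="session")
def smooth_response_sets(smooth_study):
    """Per-(participant, quiz) response sets with true-mixture embeddings."""
    world = smooth_study["world"]
    return build_response_sets(
        smooth_study["responses"], world.question_mixtures, world.pool
    )


@pytest.fixture(scope="session")
def fitted_response_sets(smooth_study):
    """Response sets embedded with the fitted 15-topic model."""
    from knowmap.corpus import preprocess

    world = smooth_study["world"]
    model = smooth_study["model"]
    wc = WindowConfig(w=30)
    docs = [tuple(preprocess(q.text, wc)) for q in world.pool]
    emb = model.transform_documents(docs)
    embeddings = {q.qid: emb[i] for i, q in enumerate(world.pool)}
    return build_response_sets(smooth_study["responses"], embeddings, world.pool), embeddings


def random_simplex(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    return rng.dirichlet(np.ones(k), size=n)
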