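"""LDA fitting, topic-count selection, embedding and 1 Hz trajectories."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from knowmap import KnowmapWarning
from knowmap.corpus import Window, WindowCorpus
from knowmap.topics import (
    TopicModel,
    build_trajectory,
    embed_document,
    fit_topic_model,
    select_num_topics,
)


def synthetic_corpus(k_true, vocab_size, n_docs, words_per_doc, seed):
    """Bag-of-words documents from known Dirichlet topics."""
    rng = np.random.default_rng(seed)
    vocab = [f"w{i:03d}" for i in range(vocab_size)]
    topics = rng.dirichlet(np.full(vocab_size, 0.08), size=k_true)
    windows = []
    for d in range(n_docs):
        mix = rng.dirichlet(np.full(k_true, 0.3))
        word_dist = mix @ topics
        idx = rng.choice(vocab_size, size=words_per_doc, p=word_dist)
        windows.append(
            Window(timestamp=float(d), tokens=tuple(vocab[i] for i in idx),
                   raw_line_span=(d, d))
        )
    return WindowCorpus("syn", tuple(windows)), topics, vocab


@pytest.fixture(scope="module")
def three_topic_corpus():
    return synthetic_corpus(k_true=3, vocab_size=60, n_docs=150, words_per_doc=40, seed=0)


def test_recovers_generating_topics_up_to_permutation(three_topic_corpus):
    corpus, true_topics, vocab = three_topic_corpus
    model = fit_topic_model([corpus], k=3, seed=1)
    # align fitted vocabulary order with the generator's
    order = [model.vocabulary.index(w) for w in vocab if w in model.vocabulary]
    fitted = model.topic_word[:, order]
    keep = [i for i, w in enumerate(vocab) if w in model.vocabulary]
    truth = true_topics[:, keep]
    truth = truth / truth.sum(axis=1, keepdims=True)
    # Hungarian matching on total-variation distance
    tv = 0.5 * np.abs(fitted[:, None, :] - truth[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(tv)
    assert tv[rows, cols].mean() < 0.2


def test_k1_degenerates_to_corpus_word_distribution(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    model = fit_topic_model([corpus], k=1, seed=0)
    counts = np.zeros(len(model.vocabulary))
    index = {w: i for i, w in enumerate(model.vocabulary)}
    for doc in corpus.documents:
        for tok in doc:
            counts[index[tok]] += 1
    empirical = counts / counts.sum()
    # single topic equals the empirical distribution up to prior smoothing
    assert np.abs(model.topic_word[0] - empirical).max() < 5e-3


def test_simplex_validity_and_determinism(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    m1 = fit_topic_model([corpus], k=5, seed=42)
    m2 = fit_topic_model([corpus], k=5, seed=42)
    assert np.array_equal(m1.topic_word, m2.topic_word)  # bit-reproducible
    theta = m1.transform_documents(corpus.documents)
    assert np.allclose(theta.sum(axis=1), 1.0, atol=1e-9)
    assert (theta >= 0).all()


def test_select_num_topics_finds_first_unused(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    k = select_num_topics([corpus], k_min=2, k_max=8, seed=0)
    # oracle: scan each fitted model directly for a near-uniform topic
    first_with_unused = None
    for kk in range(2, 9):
        model = fit_topic_model([corpus], k=kk, seed=0)
        v = len(model.vocabulary)
        if (np.abs(model.topic_word - 1 / v).max(axis=1) * v < 0.01).any():
            first_with_unused = kk
            break
    assert k == first_with_unused
    # the corpus holds 3 latent themes: an unused topic must require k > 3
    assert 3 < k <= 8
    with pytest.raises(ValueError):
        select_num_topics([corpus], k_min=5, k_max=4)


def test_select_num_topics_fallback_warns(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    with pytest.warns(KnowmapWarning, match="unused"):
        k = select_num_topics([corpus], k_min=2, k_max=2, seed=0)
    assert k == 2


def test_embed_document_posterior_mode(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    model = fit_topic_model([corpus], k=3, seed=1)
    for j in range(3):
        top_words = [model.vocabulary[i] for i in np.argsort(model.topic_word[j])[-10:]]
        rng = np.random.default_rng(j)
        doc = list(rng.choice(top_words, size=200))
        vec = embed_document(model, doc)
        assert np.argmax(vec) == j
    # empty / all-OOV documents embed to the uniform vector with a warning
    with pytest.warns(KnowmapWarning, match="no in-vocabulary"):
        vec = embed_document(model, ["zzz-not-in-vocab"])
    assert np.allclose(vec, 1 / 3)


def test_embedding_training_windows_is_self_consistent(three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    model = fit_topic_model([corpus], k=3, seed=1)
    theta = model.transform_documents(corpus.documents)
    single = embed_document(model, corpus.documents[7])
    assert np.allclose(single, theta[7], atol=1e-12)


def test_serialization_roundtrip(tmp_path, three_topic_corpus):
    corpus, _, _ = three_topic_corpus
    model = fit_topic_model([corpus], k=3, seed=1)
    model.save(tmp_path / "model.json")
    loaded = TopicModel.load(tmp_path / "model.json")
    assert loaded.vocabulary == model.vocabulary
    doc = corpus.documents[0]
    assert np.allclose(embed_document(loaded, doc), embed_document(model, doc), atol=1e-9)


# -- trajectories ----------------------------------------------------------- #


def _toy_model(k):
    topic_word = np.full((k, k), 1e-6)
    np.fill_diagonal(topic_word, 1.0)
    topic_word = topic_word / topic_word.sum(axis=1, keepdims=True)
    return TopicModel(
        k=k,
        vocabulary=tuple(f"w{i}" for i in range(k)),
        topic_word=topic_word,
        components=topic_word * 100,
    )


def test_trajectory_linear_midpoint_and_clamping():
    model = _toy_model(3)
    windows = (
        Window(timestamp=0.0, tokens=("w0",) * 50, raw_line_span=(0, 0)),
        Window(timestamp=10.0, tokens=("w1",) * 50, raw_line_span=(1, 1)),
    )
    corpus = WindowCorpus("lec", windows)
    traj = build_trajectory(model, corpus, duration=12.0)
    assert len(traj) == 13  # floor(duration) + 1 at 1 Hz
    assert np.allclose(traj.vectors.sum(axis=1), 1.0, atol=1e-9)
    v0, v5, v12 = traj.vectors[0], traj.vectors[5], traj.vectors[12]
    assert v0[0] > 0.95  # t=0 equals the first window's vector
    assert v5[0] == pytest.approx(v5[1], abs=0.02)  # midpoint blend
    assert np.allclose(v12, traj.vectors[10])  # clamped past the last window


def test_trajectory_matches_piecewise_linear_oracle():
    rng = np.random.default_rng(3)
    model = _toy_model(4)
    stamps = [0.0, 3.0, 7.5, 11.0, 15.0]
    windows = tuple(
        Window(timestamp=s, tokens=tuple(rng.choice(model.vocabulary, size=60)),
               raw_line_span=(i, i))
        for i, s in enumerate(stamps)
    )
    corpus = WindowCorpus("lec", windows)
    traj = build_trajectory(model, corpus, duration=15.0)
    theta = model.transform_documents(corpus.documents)
    # oracle: per-dimension piecewise-linear evaluation at each window stamp
    for i, s in enumerate(stamps):
        t = int(round(s))
        oracle = np.array(
            [np.interp(t, stamps, theta[:, j]) for j in range(model.k)]
        )
        oracle = oracle / oracle.sum()
        assert np.abs(traj.vectors[t] - oracle).sum() < 0.05


def test_single_window_constant_trajectory_warns():
    model = _toy_model(3)
    corpus = WindowCorpus(
        "lec", (Window(timestamp=5.0, tokens=("w2",) * 30, raw_line_span=(0, 0)),)
    )
    with pytest.warns(KnowmapWarning, match="single window"):
        traj = build_trajectory(model, corpus, duration=4.0)
    assert len(traj) == 5
    assert np.allclose(traj.vectors, traj.vectors[0])
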