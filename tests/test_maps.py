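"""2D projections, RBF knowledge / learning maps, word-cloud inversion."""

import numpy as np
import pytest

from knowmap.knowledge import ResponseItem, ResponseSet
from knowmap.maps import (
    KnowledgeMap,
    RBFConfig,
    build_grid,
    fit_projection,
    invert_coordinate,
    knowledge_map,
    learning_map,
    word_cloud,
)
from knowmap.topics import TopicModel, Trajectory

from conftest import random_simplex


def make_set(embedding_by_qid, correct_by_qid, participant="p0", quiz=1):
    items = tuple(
        ResponseItem(q, np.asarray(e, float), bool(correct_by_qid[q]), "lecture1")
        for q, e in embedding_by_qid.items()
    )
    return ResponseSet(participant, quiz, items)


def test_linear_projection_exactly_invertible_on_three_points():
    rng = np.random.default_rng(0)
    vecs = random_simplex(rng, 3, 5)
    proj = fit_projection(vecs, method="linear")
    xy = proj.forward(vecs)
    recovered = invert_coordinate(proj, xy)
    # 3 points span <= 2 directions around the mean: exact reconstruction
    assert np.abs(recovered - vecs).sum(axis=1).max() < 1e-9


def test_identical_vectors_rejected():
    vecs = np.tile([0.25, 0.25, 0.25, 0.25], (5, 1))
    with pytest.raises(ValueError, match="degenerate"):
        fit_projection(vecs, method="linear")
    with pytest.raises(ValueError, match="at least 3"):
        fit_projection(vecs[:2], method="linear")


def test_inverted_coordinates_are_simplex_valid():
    rng = np.random.default_rng(1)
    proj = fit_projection(random_simplex(rng, 40, 8), method="linear")
    xy = rng.normal(0, 5, size=(500, 2))
    v = invert_coordinate(proj, xy)
    assert (v >= 0).all()
    assert np.allclose(v.sum(axis=1), 1.0, atol=1e-9)


def test_midpoint_inverts_to_renormalized_geometric_mean():
    rng = np.random.default_rng(2)
    vecs = random_simplex(rng, 3, 4)
    proj = fit_projection(vecs, method="linear")
    xy = proj.forward(vecs)
    mid = invert_coordinate(proj, (xy[0] + xy[1]) / 2)
    gm = np.sqrt(vecs[0] * vecs[1])
    gm = gm / gm.sum()
    assert np.abs(mid - gm).max() < 1e-6


def test_projected_lectures_separate(smooth_study):
    """Within-lecture neighbors are closer than between-lecture ones."""
    world = smooth_study["world"]
    t1 = world.true_trajectory("lecture1")
    t2 = world.true_trajectory("lecture2")
    proj = fit_projection(np.vstack([t1, t2]), method="linear")
    p1, p2 = proj.forward(t1), proj.forward(t2)
    within = np.linalg.norm(np.diff(p1, axis=0), axis=1).mean()
    between = np.abs(p1.mean(axis=0) - p2.mean(axis=0)).sum()
    assert within < between


def test_grid_shape_and_padding():
    pts = np.array([[0.0, 0.0], [10.0, 4.0]])
    grid = build_grid(pts, shape=(100, 100), pad=0.02)
    assert grid.shape == (10_000, 2)
    assert grid[:, 0].min() == pytest.approx(-0.2)
    assert grid[:, 0].max() == pytest.approx(10.2)


def test_knowledge_map_matches_rbf_formula_oracle():
    coords = {"q0": np.array([0.0, 0.0]), "q1": np.array([3.0, 1.0]),
              "q2": np.array([-2.0, 4.0])}
    correct = {"q0": True, "q1": False, "q2": True}
    rs = make_set(coords, correct)
    lam = 50.0
    probes = np.array([[0, 0], [1, 1], [-3, 2], [5, -1], [0.5, 3.0]], dtype=float)
    km = knowledge_map(probes, coords, rs, RBFConfig(lam=lam))
    for i, x in enumerate(probes):
        w = {q: np.exp(-((x - mu) ** 2).sum() / lam) for q, mu in coords.items()}
        oracle = sum(w[q] for q in w if correct[q]) / sum(w.values())
        assert km.values[i] == pytest.approx(oracle, abs=1e-12)


def test_knowledge_map_limits():
    coords = {"q0": np.array([0.0, 0.0]), "q1": np.array([100.0, 0.0])}
    rs_all = make_set(coords, {"q0": True, "q1": True})
    rs_none = make_set(coords, {"q0": False, "q1": False})
    grid = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
    assert np.allclose(knowledge_map(grid, coords, rs_all).values, 1.0)
    assert np.allclose(knowledge_map(grid, coords, rs_none).values, 0.0)
    # a correct item far from all others dominates at its own coordinate
    rs = make_set(coords, {"q0": True, "q1": False})
    km = knowledge_map(np.array([[0.0, 0.0]]), coords, rs)
    assert km.values[0] > 0.999


def test_learning_map_difference_and_bounds():
    grid = np.array([[0.0, 0.0], [1.0, 1.0]])
    a = KnowledgeMap(grid, np.array([0.0, 0.25]), quiz=1)
    b = KnowledgeMap(grid, np.array([1.0, 0.25]), quiz=2)
    diff = learning_map(a, b)
    assert np.allclose(diff, [1.0, 0.0])
    assert np.allclose(learning_map(a, a), 0.0)
    assert ((diff >= -1) & (diff <= 1)).all()


def test_smaller_lambda_sharpens_maps():
    rng = np.random.default_rng(4)
    coords = {f"q{i}": rng.normal(0, 3, 2) for i in range(8)}
    correct = {f"q{i}": i % 2 == 0 for i in range(8)}
    rs = make_set(coords, correct)
    centers = np.vstack(list(coords.values()))
    errs = []
    for lam in (200.0, 50.0, 5.0):
        km = knowledge_map(centers, coords, rs, RBFConfig(lam=lam))
        err = np.abs(
            km.values - np.array([float(correct[q]) for q in coords])
        ).mean()
        errs.append(err)
    assert errs[0] >= errs[1] >= errs[2]


# -- word clouds ------------------------------------------------------------ #


def toy_model():
    topic_word = np.array([[0.6, 0.3, 0.08, 0.02], [0.05, 0.15, 0.5, 0.3]])
    return TopicModel(
        k=2, vocabulary=("alpha", "beta", "gamma", "delta"),
        topic_word=topic_word, components=topic_word * 50,
    )


def trajectory_of(vectors):
    vectors = np.asarray(vectors, float)
    return Trajectory("lec", np.arange(len(vectors)), vectors)


def test_word_cloud_pure_topic_and_uniform():
    model = toy_model()
    lec1 = trajectory_of([[0.9, 0.1], [0.8, 0.2]])
    lec2 = trajectory_of([[0.1, 0.9], [0.2, 0.8]])
    cloud = word_cloud(model, np.array([1.0, 0.0]), [lec1, lec2], top_n=4)
    words = [w for w, _, _ in cloud]
    assert words == ["alpha", "beta", "gamma", "delta"]  # topic 0's order
    weights = dict((w, wt) for w, wt, _ in cloud)
    assert weights["alpha"] == pytest.approx(0.6)

    uniform = word_cloud(model, np.array([0.5, 0.5]), [lec1, lec2], top_n=4)
    expected = model.topic_word.mean(axis=0)
    for w, wt, _ in uniform:
        assert wt == pytest.approx(expected[model.vocabulary.index(w)], abs=1e-12)


def test_word_cloud_association_hand_computed():
    model = toy_model()
    lec1 = trajectory_of([[1.0, 0.0]])
    lec2 = trajectory_of([[0.0, 1.0]])
    cloud = word_cloud(model, np.array([0.5, 0.5]), [lec1, lec2], top_n=4)
    w1 = model.topic_word[0]
    w2 = model.topic_word[1]
    for word, _, assoc in cloud:
        i = model.vocabulary.index(word)
        assert assoc == pytest.approx((w1[i] - w2[i]) / (w1[i] + w2[i]), abs=1e-12)
        assert -1.0 <= assoc <= 1.0


def test_umap_projection_runs_and_inverts(smooth_study):
    """Nonlinear projector: fit, forward, and simplex-valid inversion."""
    world = smooth_study["world"]
    vecs = np.vstack(
        [world.true_trajectory("lecture1")[::10], world.true_trajectory("lecture2")[::10]]
    )
    proj = fit_projection(vecs, method="umap", seed=0, n_neighbors=10)
    xy = proj.forward(vecs[:5])
    assert xy.shape == (5, 2)
    v = invert_coordinate(proj, xy.mean(axis=0))
    assert v.shape == (vecs.shape[1],)
    assert v.min() >= 0 and v.sum() == pytest.approx(1.0, abs=1e-9)
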