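"""Knowledge traces, held-out estimation and the rebalancing correction."""

import numpy as np
import pytest

from knowmap.knowledge import (
    HeldoutEstimator,
    KnowledgeTrace,
    NormalizationBounds,
    ResponseItem,
    ResponseSet,
    compare_quiz_knowledge,
    compute_bounds,
    heldout_estimate,
    heldout_table,
    knowledge_at,
    knowledge_trace,
    ncorr,
)
from knowmap.topics import Trajectory

from conftest import random_simplex


def make_set(embeddings, correct, areas=None, participant="p0", quiz=1):
    items = tuple(
        ResponseItem(
            qid=f"q{i}",
            embedding=np.asarray(e, dtype=np.float64),
            correct=bool(c),
            area=(areas[i] if areas else "lecture1"),
        )
        for i, (e, c) in enumerate(zip(embeddings, correct))
    )
    return ResponseSet(participant=participant, quiz=quiz, items=items)


def brute_force_khat(x, items, mincorr, maxcorr):
    """Direct evaluation of the weighted-proportion estimator."""
    num = den = 0.0
    for item in items:
        a, b = np.asarray(x, float), np.asarray(item.embedding, float)
        ac, bc = a - a.mean(), b - b.mean()
        denom = np.sqrt((ac**2).sum() * (bc**2).sum())
        c = 0.0 if denom == 0 else float(np.clip(ac @ bc / denom, -1, 1))
        if maxcorr == mincorr:
            w = 1.0
        else:
            w = min(max((c - mincorr) / (maxcorr - mincorr), 0.0), 1.0)
        den += w
        if item.correct:
            num += w
    if den == 0:
        return np.mean([it.correct for it in items])
    return num / den


def test_ncorr_bounds_and_arithmetic():
    b = NormalizationBounds(-0.4, 0.8)
    x = np.array([0.6, 0.3, 0.1])
    y = np.array([0.1, 0.5, 0.4])
    c = np.corrcoef(x, y)[0, 1]  # independent correlation oracle
    expected = min(max((c - b.mincorr) / (b.maxcorr - b.mincorr), 0.0), 1.0)
    assert ncorr(x, y, b) == pytest.approx(expected, abs=1e-12)
    assert ncorr(x, x, b) == 1.0  # corr = 1 exceeds maxcorr: clipped
    # exact bound attainment maps to the interval endpoints
    assert (0.2 - (-0.4)) / 1.2 == pytest.approx(0.5)
    with pytest.raises(ValueError):
        NormalizationBounds(0.5, 0.2)


def test_degenerate_bounds_weight_everything_one():
    b = NormalizationBounds(0.3, 0.3)
    x = np.array([0.6, 0.3, 0.1])
    y = np.array([0.1, 0.8, 0.1])
    with pytest.warns(Warning):
        assert ncorr(x, y, b) == 1.0


def test_all_correct_and_all_incorrect_traces():
    rng = np.random.default_rng(0)
    traj = Trajectory("lec", np.arange(6), random_simplex(rng, 6, 4))
    rs_all = make_set(random_simplex(rng, 5, 4), [True] * 5)
    rs_none = make_set(random_simplex(rng, 5, 4), [False] * 5)
    assert np.allclose(knowledge_trace(rs_all, traj).khat, 1.0)
    assert np.allclose(knowledge_trace(rs_none, traj).khat, 0.0)


def test_trace_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    traj = Trajectory("lec", np.arange(5), random_simplex(rng, 5, 3))
    rs = make_set(random_simplex(rng, 3, 3), [True, False, True])
    b = compute_bounds(traj.vectors, rs.embeddings())
    trace = knowledge_trace(rs, traj)
    for t in range(5):
        oracle = brute_force_khat(traj.vectors[t], rs.items, b.mincorr, b.maxcorr)
        assert trace.khat[t] == pytest.approx(oracle, abs=1e-12)


def test_knowledge_at_uniform_weights_reduce_to_proportion():
    rng = np.random.default_rng(2)
    emb = random_simplex(rng, 6, 4)
    rs = make_set(emb, [True, True, False, True, False, False])
    b = NormalizationBounds(0.2, 0.2)  # degenerate: all weights 1
    val = knowledge_at(rng.dirichlet(np.ones(4)), rs.items, b)
    assert val == pytest.approx(0.5)


def test_monotonicity_adding_correct_item():
    """Adding a correct item never decreases knowledge at any coordinate."""
    rng = np.random.default_rng(3)
    emb = random_simplex(rng, 5, 4)
    rs = make_set(emb, [True, False, False, True, False])
    extra = ResponseItem("new", rng.dirichlet(np.ones(4)), True, "lecture1")
    x = rng.dirichlet(np.ones(4))
    all_emb = np.vstack([emb, extra.embedding])
    b = compute_bounds(x[None, :], all_emb)
    before = knowledge_at(x, rs.items, b)
    after = knowledge_at(x, rs.items + (extra,), b)
    assert after >= before - 1e-12


# -- held-out estimation ---------------------------------------------------- #


def equal_weight_set(n_correct, n_total, quiz=1):
    """All candidates share one embedding: every pairwise weight is equal."""
    base = np.array([0.5, 0.3, 0.15, 0.05])
    target_emb = np.array([0.1, 0.2, 0.3, 0.4])
    emb = [target_emb] + [base] * (n_total - 1)
    correct = [True] * n_correct + [False] * (n_total - n_correct)
    areas = ["lecture1"] * 5 + ["lecture2"] * 5 + ["general"] * 3
    return make_set(emb, correct, areas=areas[:n_total], quiz=quiz)


@pytest.mark.parametrize("target_correct", [True, False])
def test_rebalancing_null_expectation_exact(target_correct):
    """Forced-uniform weights give exactly (n-1)/(q-2) for either label."""
    q, n = 13, 10
    rest_true = n - 1 if target_correct else n
    rest_false = (q - 1) - rest_true
    correct = [target_correct] + [True] * rest_true + [False] * rest_false
    assert len(correct) == q and sum(correct) == n
    base = np.array([0.5, 0.3, 0.15, 0.05])
    emb = [np.array([0.1, 0.2, 0.3, 0.4])] + [base] * (q - 1)
    rs = make_set(emb, correct)
    est = heldout_estimate("q0", rs, mode="all")
    assert est == pytest.approx((n - 1) / (q - 2), abs=1e-12)


def test_rebalancing_excludes_single_label_participants():
    rng = np.random.default_rng(4)
    rs = make_set(random_simplex(rng, 6, 4), [True] * 6)
    assert heldout_estimate("q0", rs, mode="all") is None


def test_across_lecture_uses_only_other_lecture_items():
    rng = np.random.default_rng(5)
    emb = random_simplex(rng, 13, 6)
    areas = ["lecture1"] * 5 + ["lecture2"] * 5 + ["general"] * 3
    correct = [True, False] * 6 + [True]
    rs = make_set(emb, correct, areas=areas)
    est = heldout_estimate("q0", rs, mode="across_lecture")
    # oracle: single un-rebalanced call on exactly the 5 lecture-2 items
    items = [it for it in rs.items if it.area == "lecture2"]
    target = rs.items[0]
    c = []
    for it in items:
        a, b = target.embedding, it.embedding
        ac, bc = a - a.mean(), b - b.mean()
        c.append(float(ac @ bc / np.sqrt((ac**2).sum() * (bc**2).sum())))
    c = np.array(c)
    w = (c - c.min()) / (c.max() - c.min())
    oracle = w[[it.correct for it in items]].sum() / w.sum()
    assert est == pytest.approx(oracle, abs=1e-12)
    with pytest.raises(ValueError, match="general"):
        heldout_estimate("q12", rs, mode="within_lecture")


def test_rebalanced_estimates_label_symmetric_under_permutation():
    """Permuting correctness labels equalizes mean estimates across labels."""
    rng = np.random.default_rng(6)
    emb = random_simplex(rng, 13, 6)
    areas = ["lecture1"] * 5 + ["lecture2"] * 5 + ["general"] * 3
    diffs = []
    for _ in range(200):
        correct = np.zeros(13, dtype=bool)
        correct[rng.choice(13, size=7, replace=False)] = True
        rs = make_set(emb, correct, areas=areas)
        ests = {True: [], False: []}
        for item in rs.items:
            e = heldout_estimate(item.qid, rs, mode="all")
            if e is not None:
                ests[item.correct].append(e)
        diffs.append(np.mean(ests[True]) - np.mean(ests[False]))
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 2 * se + 1e-9


def test_heldout_estimator_matches_reference_path(smooth_response_sets):
    """Precomputed fast estimator reproduces the reference implementation."""
    sets = [rs for rs in smooth_response_sets if rs.quiz == 2][:10]
    for mode in ("all", "within_lecture", "across_lecture"):
        ref = heldout_table(sets, mode=mode)
        est = HeldoutEstimator(sets, mode=mode)
        fast = est.table().dropna(subset=["knowledge"])
        merged = ref.merge(
            fast, on=["participant", "quiz", "qid"], suffixes=("_ref", "_fast")
        )
        assert len(merged) == len(ref)
        assert np.allclose(merged["knowledge_ref"], merged["knowledge_fast"], atol=1e-12)
        assert (merged["accuracy_ref"] == merged["accuracy_fast"]).all()


def test_compare_quiz_knowledge_paired_t_oracle():
    # 5-participant toy: paired t equals the textbook formula
    traces = []
    rng = np.random.default_rng(7)
    vals = {1: rng.uniform(0.2, 0.5, 5), 2: rng.uniform(0.4, 0.8, 5)}
    for quiz, v in vals.items():
        for i, khat in enumerate(v):
            traces.append(
                KnowledgeTrace(f"p{i}", quiz, "lecture1", np.arange(3),
                               np.full(3, khat))
            )
    out = compare_quiz_knowledge(traces)
    d = vals[2] - vals[1]
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    t, df, p = out[(1, 2)]
    assert t == pytest.approx(t_expected, abs=1e-10)
    assert df == 4

    identical = [
        KnowledgeTrace(f"p{i}", qz, "lecture1", np.arange(2), np.array([0.5, 0.5]))
        for i in range(4) for qz in (1, 2)
    ]
    t, df, p = compare_quiz_knowledge(identical)[(1, 2)]
    assert (t, p) == (0.0, 1.0)
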