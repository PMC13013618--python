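# knowmap

**Conceptual knowledge maps from short multiple-choice quizzes.**

A score of "9/13 correct" says how much a learner knows, but not *what* they
know. `knowmap` turns the same quiz responses into a map: it embeds lecture
transcripts and quiz questions in a shared topic space, estimates a
learner's knowledge at any coordinate of that space — any moment of a
lecture, any held-out question, any point on a 2D map — and statistically
validates those estimates. It is written for computational cognitive
scientists and education researchers working with lecture-based studies:
timestamped captions, a question pool, and a table of graded responses are
the only inputs.

## The model

Lecture transcripts are cut into ramping sliding windows (up to *w* = 30
caption lines, every line in exactly *w* windows) and, after standard text
preprocessing, train a Latent Dirichlet Allocation topic model. Every
window and every question becomes a point on the *k*-simplex; interpolating
windows at 1 Hz gives each lecture a trajectory through topic space.

Knowledge at a coordinate *x* is the correlation-weighted proportion of
questions the learner answered correctly,

```
k̂(x) = Σ_{i∈correct} ncorr(x, qᵢ) / Σ_{j=1..N} ncorr(x, qⱼ),
ncorr(x, y) = (corr(x, y) − mincorr) / (maxcorr − mincorr),
```

with the min–max bounds taken over the relevant timepoint × question set so
every question contributes a non-negative weight. On top of this estimator
the package provides:

- **knowledge traces** k̂(t) along each lecture, with paired-t quiz
  comparisons;
- **held-out validation**: leave-one-question-out estimates (with a
  rebalancing correction equalizing the null expectation at (n−1)/(q−2)
  for correct and incorrect targets), fed into logistic mixed models
  `accuracy ~ knowledge + (knowledge | participant) + (knowledge | question)`
  fit by a built-in Laplace (glmer-equivalent) engine, with bootstrap
  odds-ratio CIs and parametric-bootstrap likelihood-ratio tests;
- **smoothness estimation**: how performance decays with correlation
  distance from a reference question, and the divergence distance at which
  it becomes indistinguishable from the overall score (nested bootstrap);
- **knowledge & learning maps**: an invertible 2D projection of
  log-topic vectors (k = 100 model), RBF-weighted knowledge on a 100 × 100
  grid, pointwise quiz-to-quiz learning maps, and word clouds for any map
  location;
- a **synthetic study generator** — two overlapping-topic lectures,
  39 questions (15/15/9), 50 learners with smooth latent knowledge fields
  and scheduled learning — so the whole pipeline is testable without any
  external data.

## Worked example

```python
import dataclasses
from knowmap.synthetic import ScenarioConfig, make_world, simulate_responses
from knowmap.corpus import WindowConfig, build_windows, preprocess
from knowmap.topics import fit_topic_model, build_trajectory
from knowmap.knowledge import build_response_sets, knowledge_trace, compare_quiz_knowledge

cfg = ScenarioConfig(seed=1)                 # 2 lectures, 39 questions, 50 learners
world = make_world(cfg)
responses, _ = simulate_responses(world, cfg)

wc = WindowConfig(w=30)
corpora = [build_windows(t, wc) for t in world.transcripts]
model = fit_topic_model(corpora, k=15, seed=1)
traj = build_trajectory(model, corpora[0], world.cfg.lecture_duration)

emb = model.transform_documents([tuple(preprocess(q.text, wc)) for q in world.pool])
sets = build_response_sets(
    responses, {q.qid: emb[i] for i, q in enumerate(world.pool)}, world.pool
)
traces = [
    knowledge_trace(dataclasses.replace(rs, items=rs.about("lecture1")), traj)
    for rs in sets
]
t, df, p = compare_quiz_knowledge(traces)[(1, 2)]
print(f"lecture-1 knowledge, quiz 2 vs 1: t({df}) = {t:.2f}, p = {p:.2g}")
```

```
lecture-1 knowledge, quiz 2 vs 1: t(49) = 8.81, p = 1.1e-11
```

The positive paired t-statistic says the simulated learners' estimated
knowledge about lecture 1's content rose sharply between quiz 1 and quiz 2 —
exactly when the generator scheduled them to watch that lecture.

The same pipeline runs from the shell:

```bash
knowmap all --workdir run --seed 1            # simulate → embed → … → maps
knowmap glmm --workdir run --paper-scale      # 10,000-iteration bootstraps
```

## Layout

| module | role |
| --- | --- |
| `knowmap.ingest` | transcript (TSV / WebVTT), question-pool and response readers |
| `knowmap.corpus` | sliding-window corpus, preprocessing, lemmatizer |
| `knowmap.topics` | LDA fitting, k selection, embeddings, 1 Hz trajectories |
| `knowmap.correspond` | question ↔ lecture-moment matching, topic variability |
| `knowmap.knowledge` | knowledge traces, held-out estimates, rebalancing |
| `knowmap.mixedmodel` | Laplace logistic GLMM, bootstrap CIs and LRTs |
| `knowmap.smoothness` | sphere curves, nested-bootstrap divergence distances |
| `knowmap.maps` | 2D projections, RBF knowledge/learning maps, word clouds |
| `knowmap.synthetic` | the simulated two-lecture study |
| `knowmap.cli` | `knowmap` command: stage-wise pipeline with YAML config |

See `docs/methods.md` for the model's assumptions, parameter defaults, and
known limitations.
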