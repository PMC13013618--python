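"""Synthetic study generator: topics, lectures, questions, simulated learners.

The generator emulates the design of a two-lecture, three-quiz study:

- a vocabulary of synthetic word forms and ``k_true`` latent topics (Dirichlet
  word distributions);
- two lectures, each a smooth piecewise-linear path over the topic simplex
  biased toward a lecture-specific (but overlapping) topic subset, emitting
  one caption line of sampled words every few seconds;
- a question pool with 15 + 15 + 9 questions: lecture questions sample words
  from the topic mixture at a *planted* lecture timepoint, general-knowledge
  questions from reserved off-path topics;
- 50 simulated learners, each with a latent knowledge field over topic space
  built from radial-basis bumps with a controllable lengthscale (the
  smoothness assumption as a generative model).  Viewing a lecture raises the
  field in a neighborhood of that lecture's trajectory; the probability of a
  correct answer is ``guess_rate + (1 - guess_rate) * K(v)``.

Every quantity needed to check downstream estimates (planted timepoints,
true mixtures, true fields) is returned in the latent truth record.  With
``knowledge_lengthscale -> 0`` the field is flat and responses are
independent of embedding geometry -- the null scenario for calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .ingest import (
    GENERAL_AREA,
    Question,
    QuestionPool,
    ResponseTable,
    Transcript,
    write_questions,
    write_responses,
    write_transcript,
)

__all__ = ["ScenarioConfig", "World", "Truth", "make_world", "simulate_responses"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator parameters.

    Study-design fields (participants, question counts, quiz composition,
    guessing floor) default to the emulated two-lecture design; lecture
    length defaults to a desk-scale six-minute lecture with a caption line
    every ~2.4 s, preserving the real cadence at a size that keeps full
    pipelines fast.
    """

    seed: int = 0
    k_true: int = 12
    vocab_size: int = 150
    n_lectures: int = 2
    lines_per_lecture: int = 150
    lecture_duration: float = 360.0
    words_per_line: int = 8
    question_words: int = 30
    questions_per_area: tuple[int, int, int] = (15, 15, 9)
    n_participants: int = 50
    quiz_composition: tuple[int, int, int] = (5, 5, 3)  # per-quiz (L1, L2, general)
    n_quizzes: int = 3
    guess_rate: float = 0.25
    base_knowledge: float = 0.2
    bump_amplitude: float = 0.25
    n_bumps: int = 6
    learning_gain: float = 0.5
    knowledge_lengthscale: float = 0.5  # correlation-distance units
    # lecture index (0-based) -> viewed after this quiz number (1-based)
    learn_schedule: tuple[tuple[int, int], ...] = ((0, 1), (1, 2))
    n_anchors: int = 6
    topic_word_concentration: float = 0.1

    def null(self) -> "ScenarioConfig":
        """The geometry-independent (flat-field, no-learning) variant."""
        return replace(self, knowledge_lengthscale=1e-9, learning_gain=0.0)

    def lecture_ids(self) -> tuple[str, ...]:
        return tuple(f"lecture{i + 1}" for i in range(self.n_lectures))


@dataclass
class World:
    """The generated study materials plus their latent truth."""

    cfg: ScenarioConfig
    vocabulary: tuple[str, ...]
    topics: np.ndarray  # (k_true, vocab_size) word distributions
    transcripts: list[Transcript]
    pool: QuestionPool
    line_mixtures: dict[str, np.ndarray]  # lecture -> (n_lines, k_true)
    path_fns: dict[str, Callable[[float], np.ndarray]] = field(repr=False, default_factory=dict)
    question_mixtures: dict[str, np.ndarray] = field(default_factory=dict)
    planted_times: dict[str, float] = field(default_factory=dict)

    def true_trajectory(self, lecture_id: str, hz: float = 1.0) -> np.ndarray:
        """True topic mixtures at 1 Hz over the lecture duration."""
        times = np.arange(0, int(self.cfg.lecture_duration) + 1, int(1 / hz))
        return np.vstack([self.path_fns[lecture_id](t) for t in times])

    def write(self, directory: str | Path) -> None:
        """Emit the ingest dialects plus a ``truth.json`` side-file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t in self.transcripts:
            write_transcript(t, directory / f"{t.lecture_id}.tsv")
        write_questions(self.pool, directory / "questions.csv")
        truth = {
            "planted_times": self.planted_times,
            "question_mixtures": {q: m.tolist() for q, m in self.question_mixtures.items()},
            "seed": self.cfg.seed,
        }
        (directory / "truth.json").write_text(json.dumps(truth))


@dataclass
class Truth:
    """Latent truth of a simulated response table."""

    fields: dict[str, dict[int, Callable[[np.ndarray], float]]] = field(repr=False, default_factory=dict)
    p_correct: dict[tuple[str, int, str], float] = field(default_factory=dict)
    knowledge: dict[tuple[str, int, str], float] = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# world construction
# --------------------------------------------------------------------------- #

_CONSONANTS = "bdfgklmnprtvz"
_VOWELS = "aeiou"


def _make_vocabulary(rng: np.random.Generator, size: int) -> tuple[str, ...]:
    """Pronounceable CV-syllable nonsense words ending in a vowel.

    The shape survives the text-preprocessing pipeline untouched: no
    plural/verbal suffixes to strip and no collisions with stop-words.
    """
    words: set[str] = set()
    while len(words) < size:
        n_syll = int(rng.integers(3, 5))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        words.add(word)
    return tuple(sorted(words))


def _lecture_topic_subsets(cfg: ScenarioConfig) -> tuple[list[list[int]], list[int]]:
    """Overlapping per-lecture topic subsets plus reserved general topics."""
    k = cfg.k_true
    n_general = max(1, k // 6)
    usable = k - n_general
    general = list(range(usable, k))
    per = max(2, int(np.ceil(usable * 0.6)))
    subsets = []
    for i in range(cfg.n_lectures):
        start = int(round(i * (usable - per) / max(1, cfg.n_lectures - 1)))
        subsets.append(list(range(start, start + per)))
    return subsets, general


def _dirichlet_on_subset(
    rng: np.random.Generator, k: int, subset: Sequence[int], on: float = 1.0, off: float = 0.02
) -> np.ndarray:
    alpha = np.full(k, off)
    alpha[list(subset)] = on
    return rng.dirichlet(alpha)


def _piecewise_path(
    anchors: np.ndarray, duration: float
) -> Callable[[float], np.ndarray]:
    knots = np.linspace(0.0, duration, len(anchors))

    def path(t: float) -> np.ndarray:
        t = float(np.clip(t, 0.0, duration))
        out = np.array(
            [np.interp(t, knots, anchors[:, j]) for j in range(anchors.shape[1])]
        )
        return out / out.sum()

    return path


def make_world(cfg: ScenarioConfig | None = None) -> World:
    """Generate topics, lecture transcripts and the question pool."""
    if cfg is None:
        cfg = ScenarioConfig()
    rng = np.random.default_rng([cfg.seed, 101])
    vocabulary = _make_vocabulary(rng, cfg.vocab_size)
    topics = rng.dirichlet(
        np.full(cfg.vocab_size, cfg.topic_word_concentration), size=cfg.k_true
    )
    subsets, general_topics = _lecture_topic_subsets(cfg)

    transcripts: list[Transcript] = []
    line_mixtures: dict[str, np.ndarray] = {}
    path_fns: dict[str, Callable[[float], np.ndarray]] = {}
    lecture_ids = cfg.lecture_ids()
    for lec, subset in zip(lecture_ids, subsets):
        anchors = np.vstack(
            [_dirichlet_on_subset(rng, cfg.k_true, subset) for _ in range(cfg.n_anchors)]
        )
        path = _piecewise_path(anchors, cfg.lecture_duration)
        gap = cfg.lecture_duration / cfg.lines_per_lecture
        starts = np.arange(cfg.lines_per_lecture) * gap
        mixtures = np.vstack([path(t) for t in starts])
        lines = []
        for start, mix in zip(starts, mixtures):
            word_dist = mix @ topics
            idx = rng.choice(cfg.vocab_size, size=cfg.words_per_line, p=word_dist)
            lines.append((float(start), " ".join(vocabulary[i] for i in idx)))
        transcripts.append(
            Transcript(lecture_id=lec, lines=tuple(lines), duration=cfg.lecture_duration)
        )
        line_mixtures[lec] = mixtures
        path_fns[lec] = path

    questions: list[Question] = []
    question_mixtures: dict[str, np.ndarray] = {}
    planted_times: dict[str, float] = {}

    def _add_question(qid: str, area: str, mixture: np.ndarray) -> None:
        word_dist = mixture @ topics
        idx = rng.choice(cfg.vocab_size, size=cfg.question_words, p=word_dist)
        text = " ".join(vocabulary[i] for i in idx)
        options = tuple(f"option {c}" for c in "abcd")
        questions.append(Question(qid=qid, area=area, text=text, options=options, correct_index=0))
        question_mixtures[qid] = mixture

    n_l1, n_l2, n_gen = cfg.questions_per_area
    for lec, n_q, subset in zip(lecture_ids, (n_l1, n_l2), subsets):
        # planted timepoints spread over the lecture, jittered
        anchors_t = np.linspace(0.05, 0.95, n_q) * cfg.lecture_duration
        jitter = rng.uniform(-0.02, 0.02, size=n_q) * cfg.lecture_duration
        for j, t_star in enumerate(np.clip(anchors_t + jitter, 0, cfg.lecture_duration)):
            qid = f"{lec}_q{j:02d}"
            _add_question(qid, lec, path_fns[lec](t_star))
            planted_times[qid] = float(t_star)
    for j in range(n_gen):
        qid = f"general_q{j:02d}"
        _add_question(qid, GENERAL_AREA, _dirichlet_on_subset(rng, cfg.k_true, general_topics))

    return World(
        cfg=cfg,
        vocabulary=vocabulary,
        topics=topics,
        transcripts=transcripts,
        pool=QuestionPool(tuple(questions)),
        line_mixtures=line_mixtures,
        path_fns=path_fns,
        question_mixtures=question_mixtures,
        planted_times=planted_times,
    )


# --------------------------------------------------------------------------- #
# learner simulation
# --------------------------------------------------------------------------- #


def _corr_distance(v: np.ndarray, others: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between ``v`` and each row of ``others``."""
    vc = v - v.mean()
    oc = others - others.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum()) * np.sqrt((oc**2).sum(axis=1))
    r = np.where(denom > 0, oc @ vc / np.where(denom > 0, denom, 1.0), 0.0)
    return 1.0 - np.clip(r, -1.0, 1.0)


def _make_field(
    rng: np.random.Generator, cfg: ScenarioConfig, world: World
) -> Callable[[np.ndarray], float]:
    """One participant's baseline knowledge field K(v) in [0, 1]."""
    centers = rng.dirichlet(np.ones(cfg.k_true), size=cfg.n_bumps)
    amps = rng.uniform(-cfg.bump_amplitude, cfg.bump_amplitude, size=cfg.n_bumps)
    ls2 = cfg.knowledge_lengthscale**2

    def K(v: np.ndarray) -> float:
        if ls2 < 1e-12:
            return float(np.clip(cfg.base_knowledge, 0.0, 1.0))
        d = _corr_distance(v, centers)
        val = cfg.base_knowledge + float(amps @ np.exp(-(d**2) / ls2))
        return float(np.clip(val, 0.0, 1.0))

    return K


def _learning_boost(
    cfg: ScenarioConfig, world: World, lecture_idx: int, v: np.ndarray
) -> float:
    """Knowledge gained about coordinate ``v`` from viewing a lecture."""
    if cfg.learning_gain == 0.0:
        return 0.0
    ls2 = max(cfg.knowledge_lengthscale**2, 1e-12)
    lec = cfg.lecture_ids()[lecture_idx]
    traj = world.line_mixtures[lec]
    d_min = _corr_distance(v, traj).min()
    return float(cfg.learning_gain * np.exp(-(d_min**2) / ls2))


def simulate_responses(
    world: World, cfg: ScenarioConfig | None = None
) -> tuple[ResponseTable, Truth]:
    """Simulate learners answering the three quizzes.

    Question-to-quiz allocation is randomized per participant under the
    composition constraint (each quiz draws the configured number of
    questions per area) and each question is seen exactly once per
    participant.  Returns the graded response table and the latent truth
    record (per-row true knowledge and success probability).
    """
    if cfg is None:
        cfg = world.cfg
    n_q_total = sum(cfg.questions_per_area)
    for area_total, per_quiz in zip(cfg.questions_per_area, cfg.quiz_composition):
        if per_quiz * cfg.n_quizzes != area_total:
            raise ValueError(
                f"composition {cfg.quiz_composition} x {cfg.n_quizzes} quizzes "
                f"incompatible with pool sizes {cfg.questions_per_area}"
            )
    rng = np.random.default_rng([cfg.seed, 202])
    areas = list(cfg.lecture_ids()) + [GENERAL_AREA]
    qids_by_area = {a: [q.qid for q in world.pool.by_area(a)] for a in areas}
    viewed_after = dict(cfg.learn_schedule)  # lecture_idx -> quiz after which viewed

    rows = []
    truth = Truth()
    for p_idx in range(cfg.n_participants):
        participant = f"p{p_idx:03d}"
        K = _make_field(rng, cfg, world)
        truth.fields[participant] = {}
        # allocate each area's questions across quizzes
        allocation: dict[int, list[str]] = {qz: [] for qz in range(1, cfg.n_quizzes + 1)}
        for area, per_quiz in zip(areas, cfg.quiz_composition):
            qids = list(qids_by_area[area])
            rng.shuffle(qids)
            for qz in range(1, cfg.n_quizzes + 1):
                allocation[qz].extend(qids[(qz - 1) * per_quiz : qz * per_quiz])
        for qz in range(1, cfg.n_quizzes + 1):
            viewed = [lec for lec, after in viewed_after.items() if qz > after]
            for qid in allocation[qz]:
                v = world.question_mixtures[qid]
                k_val = K(v) + sum(_learning_boost(cfg, world, lec, v) for lec in viewed)
                k_val = float(np.clip(k_val, 0.0, 1.0))
                p_correct = cfg.guess_rate + (1.0 - cfg.guess_rate) * k_val
                correct = bool(rng.random() < p_correct)
                rows.append((participant, qz, qid, correct))
                truth.knowledge[(participant, qz, qid)] = k_val
                truth.p_correct[(participant, qz, qid)] = p_correct
    return ResponseTable(tuple(rows)), truth
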