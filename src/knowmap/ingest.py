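"""Readers, writers and validation for the on-disk study formats.

Three kinds of input are handled:

- timestamped lecture **transcripts**, as either a minimal two-column TSV
  (``start_seconds<TAB>text``, UTF-8, no header) or plain WebVTT;
- a **question pool** CSV with columns ``qid,area,text,options,correct_index``
  (options pipe-separated);
- a **quiz-response** CSV with columns ``participant,quiz,qid,correct``.

Text is returned verbatim; no preprocessing happens at this layer.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Transcript",
    "Question",
    "QuestionPool",
    "ResponseTable",
    "ParseError",
    "ValidationError",
    "read_transcript",
    "write_transcript",
    "read_questions",
    "write_questions",
    "read_responses",
    "write_responses",
]


class ParseError(ValueError):
    """A file could not be parsed under its declared dialect."""


class ValidationError(ValueError):
    """A parsed table violates a structural invariant."""


# --------------------------------------------------------------------------- #
# Transcripts
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Transcript:
    """One lecture's captions: ordered ``(start_time, text)`` lines.

    ``duration`` is the nominal end of the video in seconds.  When the source
    format carries no explicit end time, it defaults to the last line's start
    plus the mean inter-line gap, which gives the 1 Hz resampler a sensible
    endpoint.
    """

    lecture_id: str
    lines: tuple[tuple[float, str], ...]
    duration: float

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValidationError(f"transcript {self.lecture_id!r} has no lines")
        starts = [s for s, _ in self.lines]
        for i in range(1, len(starts)):
            if starts[i] <= starts[i - 1]:
                raise ValidationError(
                    f"transcript {self.lecture_id!r}: start times must be "
                    f"strictly increasing (line {i}: {starts[i]} after {starts[i - 1]})"
                )
        if starts[0] < 0:
            raise ValidationError(f"transcript {self.lecture_id!r}: negative start time")
        for i, (_, text) in enumerate(self.lines):
            if not text.strip():
                raise ValidationError(f"transcript {self.lecture_id!r}: empty text at line {i}")
        if self.duration < starts[-1]:
            raise ValidationError(
                f"transcript {self.lecture_id!r}: duration {self.duration} "
                f"precedes last start time {starts[-1]}"
            )

    @property
    def starts(self) -> tuple[float, ...]:
        return tuple(s for s, _ in self.lines)

    @property
    def texts(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.lines)

    @property
    def n_lines(self) -> int:
        return len(self.lines)


def _default_duration(starts: Sequence[float]) -> float:
    if len(starts) < 2:
        return float(starts[-1])
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    return float(starts[-1] + sum(gaps) / len(gaps))


def _parse_tsv_transcript(path: Path) -> list[tuple[float, str]]:
    lines: list[tuple[float, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t", 1)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'start<TAB>text', got {raw!r}")
            try:
                start = float(parts[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad start time {parts[0]!r}") from exc
            lines.append((start, parts[1]))
    return lines


_VTT_TIME = re.compile(
    r"(?:(\d+):)?(\d{1,2}):(\d{2})[.,](\d{3})\s*-->\s*(?:(\d+):)?(\d{1,2}):(\d{2})[.,](\d{3})"
)


def _vtt_seconds(h: str | None, m: str, s: str, ms: str) -> float:
    return (int(h) if h else 0) * 3600 + int(m) * 60 + int(s) + int(ms) / 1000.0


def _parse_webvtt(path: Path) -> tuple[list[tuple[float, str]], float | None]:
    """Return cue (start, text) pairs plus the last cue end time (if any)."""
    with open(path, encoding="utf-8-sig") as fh:
        raw_lines = fh.read().splitlines()
    if not raw_lines or not raw_lines[0].startswith("WEBVTT"):
        raise ParseError(f"{path}:1: missing WEBVTT header")
    cues: list[tuple[float, str]] = []
    last_end: float | None = None
    i = 1
    n = len(raw_lines)
    while i < n:
        line = raw_lines[i].strip()
        m = _VTT_TIME.search(line)
        if m is None:
            i += 1
            continue
        start = _vtt_seconds(m.group(1), m.group(2), m.group(3), m.group(4))
        end = _vtt_seconds(m.group(5), m.group(6), m.group(7), m.group(8))
        i += 1
        text_parts: list[str] = []
        while i < n and raw_lines[i].strip():
            text_parts.append(raw_lines[i].strip())
            i += 1
        if not text_parts:
            raise ParseError(f"{path}:{i}: cue at {start}s has no text")
        cues.append((start, " ".join(text_parts)))
        last_end = end
    if not cues:
        raise ParseError(f"{path}: no cues found")
    return cues, last_end


def read_transcript(
    path: str | Path,
    dialect: str = "tsv",
    lecture_id: str | None = None,
    duration: float | None = None,
) -> Transcript:
    """Read one lecture transcript.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"tsv"`` (``start_seconds<TAB>text``) or ``"webvtt"``.
    lecture_id:
        Defaults to the file stem.
    duration:
        Overrides the inferred duration.  For TSV the default is the last
        start time plus the mean inter-line gap; for WebVTT the last cue's
        end time is used when present.
    """
    path = Path(path)
    if lecture_id is None:
        lecture_id = path.stem
    if dialect == "tsv":
        lines = _parse_tsv_transcript(path)
        inferred = _default_duration([s for s, _ in lines]) if lines else 0.0
    elif dialect == "webvtt":
        lines, last_end = _parse_webvtt(path)
        inferred = last_end if last_end is not None else _default_duration([s for s, _ in lines])
    else:
        raise ValueError(f"unknown transcript dialect {dialect!r}")
    if not lines:
        raise ParseError(f"{path}: empty transcript")
    return Transcript(
        lecture_id=lecture_id,
        lines=tuple(lines),
        duration=float(duration if duration is not None else inferred),
    )


def write_transcript(t: Transcript, path: str | Path) -> None:
    """Write the TSV dialect (``start<TAB>text``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for start, text in t.lines:
            fh.write(f"{start:g}\t{text}\n")


# --------------------------------------------------------------------------- #
# Question pools
# --------------------------------------------------------------------------- #

GENERAL_AREA = "general"


@dataclass(frozen=True)
class Question:
    qid: str
    area: str  # a lecture id, or "general"
    text: str
    options: tuple[str, ...]
    correct_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.correct_index < len(self.options)):
            raise ValidationError(
                f"question {self.qid!r}: correct_index {self.correct_index} "
                f"out of range for {len(self.options)} options"
            )


@dataclass(frozen=True)
class QuestionPool:
    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        qids = [q.qid for q in self.questions]
        if len(set(qids)) != len(qids):
            dupes = sorted({q for q in qids if qids.count(q) > 1})
            raise ValidationError(f"duplicate question ids: {dupes}")

    def __len__(self) -> int:
        return len(self.questions)

    def __iter__(self):
        return iter(self.questions)

    def __getitem__(self, qid: str) -> Question:
        for q in self.questions:
            if q.qid == qid:
                return q
        raise KeyError(qid)

    @property
    def qids(self) -> tuple[str, ...]:
        return tuple(q.qid for q in self.questions)

    def area_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for q in self.questions:
            counts[q.area] = counts.get(q.area, 0) + 1
        return counts

    def by_area(self, area: str) -> tuple[Question, ...]:
        return tuple(q for q in self.questions if q.area == area)


def read_questions(path: str | Path) -> QuestionPool:
    """Read a question-pool CSV (``qid,area,text,options,correct_index``)."""
    df = pd.read_csv(path, dtype=str)
    required = {"qid", "area", "text", "options", "correct_index"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    questions = []
    for row in df.itertuples(index=False):
        questions.append(
            Question(
                qid=str(row.qid),
                area=str(row.area),
                text=str(row.text),
                options=tuple(str(row.options).split("|")),
                correct_index=int(row.correct_index),
            )
        )
    return QuestionPool(tuple(questions))


def write_questions(pool: QuestionPool, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["qid", "area", "text", "options", "correct_index"])
        for q in pool:
            writer.writerow([q.qid, q.area, q.text, "|".join(q.options), q.correct_index])


# --------------------------------------------------------------------------- #
# Quiz responses
# --------------------------------------------------------------------------- #

_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


@dataclass(frozen=True)
class ResponseTable:
    """Graded responses: one row per (participant, quiz, question).

    Each (participant, qid) pair may appear at most once across all quizzes
    (every question is seen exactly once per participant in the study design).
    """

    rows: tuple[tuple[str, int, str, bool], ...]
    composition: tuple[int, ...] | None = None  # expected per-area counts, optional

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for participant, quiz, qid, _ in self.rows:
            if quiz not in (1, 2, 3):
                raise ValidationError(f"quiz index {quiz} not in {{1,2,3}}")
            key = (participant, qid)
            if key in seen:
                raise ValidationError(
                    f"(participant={participant!r}, qid={qid!r}) appears more than once"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["participant", "quiz", "qid", "correct"])

    @property
    def participants(self) -> tuple[str, ...]:
        out: list[str] = []
        for p, _, _, _ in self.rows:
            if p not in out:
                out.append(p)
        return tuple(out)

    def for_participant_quiz(self, participant: str, quiz: int) -> tuple[tuple[str, bool], ...]:
        return tuple(
            (qid, correct)
            for p, qz, qid, correct in self.rows
            if p == participant and qz == quiz
        )

    def validate_against(
        self, pool: QuestionPool, composition: dict[str, int] | None = None
    ) -> None:
        """Check qids exist in the pool; optionally check per-quiz area counts.

        ``composition`` maps area -> required count per (participant, quiz),
        e.g. ``{"lecture1": 5, "lecture2": 5, "general": 3}``.
        """
        known = set(pool.qids)
        for participant, quiz, qid, _ in self.rows:
            if qid not in known:
                raise ValidationError(
                    f"response ({participant!r}, quiz {quiz}) references unknown qid {qid!r}"
                )
        if composition is not None:
            area_of = {q.qid: q.area for q in pool}
            cells: dict[tuple[str, int], dict[str, int]] = {}
            for participant, quiz, qid, _ in self.rows:
                cell = cells.setdefault((participant, quiz), {})
                area = area_of[qid]
                cell[area] = cell.get(area, 0) + 1
            for (participant, quiz), counts in cells.items():
                if counts != composition:
                    raise ValidationError(
                        f"(participant={participant!r}, quiz={quiz}): area counts "
                        f"{counts} do not match required composition {composition}"
                    )


def _parse_bool(value: object, context: str) -> bool:
    s = str(value).strip()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ParseError(f"{context}: boolean field must be one of 0/1/true/false, got {value!r}")


def read_responses(path: str | Path) -> ResponseTable:
    """Read a quiz-response CSV (``participant,quiz,qid,correct``)."""
    df = pd.read_csv(path, dtype=str)
    required = {"participant", "quiz", "qid", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        rows.append(
            (
                str(row.participant),
                int(row.quiz),
                str(row.qid),
                _parse_bool(row.correct, f"{path} row {i}"),
            )
        )
    return ResponseTable(tuple(rows))


def write_responses(table: ResponseTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant", "quiz", "qid", "correct"])
        for participant, quiz, qid, correct in table.rows:
            writer.writerow([participant, quiz, qid, int(correct)])
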