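"""Sliding-window document corpus and text preprocessing.

Each lecture transcript is decomposed into overlapping windows of up to ``w``
consecutive caption lines.  The windows *ramp* at both ends: the first window
covers only line 0, the second lines 0-1, and so on up to full length, with a
mirrored ramp-down at the tail.  This construction guarantees every transcript
line contributes to exactly ``w`` windows, so no part of the lecture is over-
or under-represented in the training corpus, and yields ``n_lines + w - 1``
windows in total.  Window text is preprocessed (lower-cased, punctuation
stripped, lemmatized, stop-words removed) into token lists ready for
bag-of-words topic modeling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from . import KnowmapWarning
from ._lemma import lemmatize
from .ingest import Transcript

__all__ = [
    "DEFAULT_EXTRA_STOPWORDS",
    "WindowConfig",
    "Window",
    "WindowCorpus",
    "preprocess",
    "build_windows",
]

#: Corpus-specific stop-words removed in addition to the base English list.
DEFAULT_EXTRA_STOPWORDS: tuple[str, ...] = (
    "actual", "actually", "also", "bit", "could", "e", "even", "first",
    "follow", "following", "four", "let", "like", "mc", "really", "saw",
    "see", "seen", "thing", "two",
)

_TOKEN_RE = re.compile(r"[a-z]+(?:'[a-z]+)?")


@dataclass(frozen=True)
class WindowConfig:
    """Corpus construction parameters.

    Parameters
    ----------
    w:
        Maximum window length in transcript lines.  The default of 30 lines
        matches caption exports where lines run a few seconds each, giving
        windows on the order of a minute of speech.
    extra_stopwords:
        Corpus-specific stop-words removed on top of the base English list.
    lemmatizer:
        Token -> lemma function; swap in any standard English lemmatizer.
        The choice is recorded in run metadata by the CLI.
    """

    w: int = 30
    extra_stopwords: tuple[str, ...] = DEFAULT_EXTRA_STOPWORDS
    lemmatizer: Callable[[str], str] = lemmatize

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError(f"window length w must be >= 1, got {self.w}")

    @property
    def stopwords(self) -> frozenset[str]:
        return frozenset(ENGLISH_STOP_WORDS) | frozenset(self.extra_stopwords)


@dataclass(frozen=True)
class Window:
    timestamp: float
    tokens: tuple[str, ...]
    raw_line_span: tuple[int, int]  # (first_line_idx, last_line_idx), inclusive


@dataclass(frozen=True)
class WindowCorpus:
    lecture_id: str
    windows: tuple[Window, ...]

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def timestamps(self) -> tuple[float, ...]:
        return tuple(w.timestamp for w in self.windows)

    @property
    def documents(self) -> tuple[tuple[str, ...], ...]:
        return tuple(w.tokens for w in self.windows)

    def to_jsonl(self, path) -> None:
        """Dump windows as JSON-lines of (timestamp, tokens) for inspection."""
        import json

        with open(path, "w", encoding="utf-8") as fh:
            for w in self.windows:
                fh.write(json.dumps({"timestamp": w.timestamp, "tokens": list(w.tokens)}) + "\n")


def preprocess(text: str, config: WindowConfig | None = None) -> list[str]:
    """Lower-case, strip punctuation, lemmatize and remove stop-words.

    A token is dropped if either its surface form or its lemma is a
    stop-word, so inflected stop-words ("actually" vs "actual") are caught
    either way.  Empty input yields an empty list.
    """
    if config is None:
        config = WindowConfig()
    stop = config.stopwords
    out: list[str] = []
    for raw in _TOKEN_RE.findall(text.lower()):
        raw = raw.split("'")[0]  # drop clitics: "it's" -> "it"
        if not raw or raw in stop:
            continue
        lemma = config.lemmatizer(raw)
        if lemma and lemma not in stop:
            out.append(lemma)
    return out


def window_spans(n_lines: int, w: int) -> list[tuple[int, int]]:
    """Inclusive line spans of the ramping sliding windows.

    Window ``t`` (``t = 0 .. n_lines + w - 2``) covers lines
    ``[max(0, t - w + 1), min(t, n_lines - 1)]``.  The head ramps up from a
    single line, the tail mirrors it, and every line index appears in exactly
    ``w`` spans.  When ``w > n_lines``, spans at full coverage repeat; windows
    are positional, so the count and coverage guarantees hold for all inputs.
    """
    if n_lines < 1:
        raise ValueError("transcript has no lines")
    if w < 1:
        raise ValueError("w must be >= 1")
    return [(max(0, t - w + 1), min(t, n_lines - 1)) for t in range(n_lines + w - 1)]


def build_windows(t: Transcript, config: WindowConfig | None = None) -> WindowCorpus:
    """Build the preprocessed sliding-window corpus for one transcript.

    Each window's timestamp is the midpoint of the start times of its first
    and last covered lines; its tokens are the preprocessed concatenation of
    the covered lines' text.
    """
    if config is None:
        config = WindowConfig()
    if t.n_lines == 0:
        raise ValueError(f"transcript {t.lecture_id!r} is empty")
    if config.w > t.n_lines:
        warnings.warn(
            f"window length w={config.w} exceeds transcript length "
            f"{t.n_lines}; full-coverage windows will repeat",
            KnowmapWarning,
            stacklevel=2,
        )
    starts = t.starts
    texts = t.texts
    windows: list[Window] = []
    for first, last in window_spans(t.n_lines, config.w):
        timestamp = 0.5 * (starts[first] + starts[last])
        tokens = preprocess(" ".join(texts[first : last + 1]), config)
        windows.append(Window(timestamp=timestamp, tokens=tuple(tokens), raw_line_span=(first, last)))
    return WindowCorpus(lecture_id=t.lecture_id, windows=tuple(windows))


def mean_window_span_seconds(t: Transcript, corpus: WindowCorpus) -> float:
    """Mean seconds spanned by each window's first-to-last line starts."""
    starts = t.starts
    spans = [starts[last] - starts[first] for (first, last) in
             (w.raw_line_span for w in corpus.windows)]
    return float(sum(spans) / len(spans))
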