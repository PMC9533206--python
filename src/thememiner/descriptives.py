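"""Corpus-level quantitative summaries.

Covers board composition and posting activity, per-board theme prevalence
by calendar year, and the top-word frequency table.  Rounding follows the
reporting conventions used downstream: percent shares to 2 decimals, means
to 1 decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus
from .scoring import ScoreMatrix, tokenize

__all__ = [
    "SummaryStats",
    "WordFrequencyTable",
    "summarize_corpus",
    "prevalence_by_year",
    "word_frequencies",
    "load_default_stopwords",
]


@dataclass(frozen=True)
class SummaryStats:
    total_posts: int
    per_board: dict[str, tuple[int, float]]  # board -> (count, percent share)
    unique_posters: int
    mean_posts_per_poster: float
    sd_posts_per_poster: float
    min_posts_per_poster: int
    max_posts_per_poster: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"board": b, "posts": c, "share_pct": s}
            for b, (c, s) in sorted(self.per_board.items(), key=lambda kv: -kv[1][0])
        ]
        return pd.DataFrame(rows)


def summarize_corpus(corpus: Corpus) -> SummaryStats:
    """Board counts/shares and posts-per-poster statistics.

    Shares are rounded to 2 decimals, the mean to 1 decimal and the SD to
    1 decimal; counts are exact.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    boards = pd.Series([p.board for p in corpus])
    users = pd.Series([p.username for p in corpus])
    total = len(corpus)
    board_counts = boards.value_counts()
    per_board = {
        b: (int(c), round(100.0 * c / total, 2)) for b, c in board_counts.items()
    }
    activity = users.value_counts()
    # SD over posters (population SD would divide by n; reported values use
    # the sample convention, ddof=1, degenerate single-poster case -> 0.0)
    sd = float(activity.std(ddof=1)) if len(activity) > 1 else 0.0
    return SummaryStats(
        total_posts=total,
        per_board=per_board,
        unique_posters=int(activity.size),
        mean_posts_per_poster=round(total / activity.size, 1),
        sd_posts_per_poster=round(sd, 1),
        min_posts_per_poster=int(activity.min()),
        max_posts_per_poster=int(activity.max()),
    )


def prevalence_by_year(
    corpus: Corpus,
    matrix: ScoreMatrix,
    theme: str | None = None,
    min_score: int | None = None,
) -> pd.DataFrame:
    """Related-post prevalence per (board, year) cell.

    A post counts as related when its classification set is non-empty, or —
    with ``theme`` given — when that single theme reaches the threshold.
    Cells with no posts are absent.  Columns: board, year, related, total,
    prevalence.
    """
    ids = set(corpus.post_ids())
    missing = [pid for pid in matrix.post_ids if pid not in ids]
    if missing:
        raise ValueError(f"matrix rows not in corpus: {missing[:5]}")
    tau = matrix.min_score if min_score is None else min_score
    if theme is None:
        related = matrix.related_mask(tau)
    else:
        related = matrix.frame[theme] >= tau
    meta = pd.DataFrame(
        {
            "board": [p.board for p in corpus],
            "year": [p.date.year for p in corpus],
        },
        index=pd.Index(corpus.post_ids(), name="post_id"),
    )
    meta["related"] = related.reindex(meta.index).fillna(False).astype(bool)
    grouped = meta.groupby(["board", "year"], sort=True).agg(
        related=("related", "sum"), total=("related", "size")
    )
    grouped["prevalence"] = grouped["related"] / grouped["total"]
    return grouped.reset_index()


@dataclass(frozen=True)
class WordFrequencyTable:
    entries: tuple[tuple[str, int], ...]
    n_top: int

    def words(self) -> list[str]:
        return [w for w, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["word", "count"])


def load_default_stopwords() -> frozenset[str]:
    """The shipped English stopword list (overridable by callers)."""
    text = resources.files("thememiner.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def word_frequencies(
    corpus: Corpus | Iterable[str],
    stopwords: Iterable[str] | None = None,
    n_top: int = 40,
) -> WordFrequencyTable:
    """Most frequent words over all posts, stopwords and digits removed.

    Ties are broken alphabetically.  ``corpus`` may be a :class:`Corpus` or
    any iterable of texts; ``stopwords=None`` selects the shipped default
    list (pass an empty set to disable filtering).
    """
    sw = load_default_stopwords() if stopwords is None else frozenset(stopwords)
    texts: Iterable[str] = corpus.texts() if isinstance(corpus, Corpus) else corpus
    counts: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            if tok in sw or tok.isdigit():
                continue
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return WordFrequencyTable(tuple(ranked[:n_top]), n_top=n_top)
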