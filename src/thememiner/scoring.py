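"""Tokenization, keyword matching, theme scores and post classification.

The scoring rule: a post's *theme score* is the number of keyword instances
of that theme appearing in the post.  A root keyword matches any token
having it as a prefix; a phrase matches a consecutive token run with each
phrase token a prefix of the corresponding text token.  Within one theme a
given token (or phrase span) counts at most once even if several of the
theme's patterns hit it; across themes double counting is deliberate.
A post is *related* to a theme when its score reaches the minimum
threshold (default 3), and *psychosocial-related* when related to at least
one theme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import Corpus, Post
    from .lexicon import KeywordPattern, Lexicon

__all__ = [
    "DEFAULT_MIN_SCORE",
    "tokenize",
    "match_count",
    "LexiconMatcher",
    "ThemeScoreRow",
    "ScoreMatrix",
    "score_post",
    "score_corpus",
    "classify_post",
    "top_theme",
    "total_theme_score",
    "select_qualitative_sample",
    "agreement",
]

#: Minimum theme score for a post to count as related to a theme.
DEFAULT_MIN_SCORE = 3

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase and split into maximal alphanumeric runs.

    Hyphens, apostrophes, underscores and all other punctuation are token
    boundaries; the function is deterministic and never yields empty tokens.
    """
    return tuple(_TOKEN_RE.findall(text.lower()))


def match_count(tokens: Sequence[str], patterns: Iterable["KeywordPattern"]) -> int:
    """Count keyword instances of one theme's patterns in a token sequence.

    Root patterns match token prefixes; phrases match consecutive prefix
    runs.  A token matched by several roots, or a span matched by several
    phrases, contributes one count.
    """
    roots = [p.tokens[0] for p in patterns if p.kind == "root"]
    phrases = [p.tokens for p in patterns if p.kind == "phrase"]
    hit_tokens: set[int] = set()
    hit_spans: set[tuple[int, int]] = set()
    for i, tok in enumerate(tokens):
        if any(tok.startswith(r) for r in roots):
            hit_tokens.add(i)
    for ph in phrases:
        L = len(ph)
        for i in range(len(tokens) - L + 1):
            if all(tokens[i + j].startswith(ph[j]) for j in range(L)):
                hit_spans.add((i, L))
    return len(hit_tokens) + len(hit_spans)


class LexiconMatcher:
    """Prefix-indexed matcher over a whole lexicon.

    Equivalent to per-theme :func:`match_count` but does a single pass per
    post: each token's prefixes are looked up in a root table instead of
    scanning every root of every theme.
    """

    def __init__(self, lexicon: "Lexicon"):
        self.lexicon = lexicon
        self.theme_names = tuple(lexicon.theme_names)
        # root surface -> sorted theme indices
        self._root_themes: dict[str, tuple[int, ...]] = {}
        # first-token prefix of a phrase -> list of (phrase tokens, theme idx)
        self._phrase_heads: dict[str, list[tuple[tuple[str, ...], int]]] = {}
        self._max_root_len = 0
        self._max_head_len = 0
        for ti, (_, pats) in enumerate(lexicon):
            for p in pats:
                if p.kind == "root":
                    r = p.tokens[0]
                    cur = self._root_themes.get(r, ())
                    if ti not in cur:
                        self._root_themes[r] = cur + (ti,)
                    self._max_root_len = max(self._max_root_len, len(r))
                else:
                    head = p.tokens[0]
                    self._phrase_heads.setdefault(head, []).append((p.tokens, ti))
                    self._max_head_len = max(self._max_head_len, len(head))

    def score_tokens(self, tokens: Sequence[str]) -> list[int]:
        """Theme scores for one token sequence, in lexicon theme order."""
        n_themes = len(self.theme_names)
        hit_tokens: list[set[int]] = [set() for _ in range(n_themes)]
        hit_spans: list[set[tuple[int, int]]] = [set() for _ in range(n_themes)]
        n = len(tokens)
        for i, tok in enumerate(tokens):
            for plen in range(1, min(len(tok), self._max_root_len) + 1):
                themes = self._root_themes.get(tok[:plen])
                if themes:
                    for ti in themes:
                        hit_tokens[ti].add(i)
            for plen in range(1, min(len(tok), self._max_head_len) + 1):
                cands = self._phrase_heads.get(tok[:plen])
                if not cands:
                    continue
                for ph, ti in cands:
                    L = len(ph)
                    if i + L <= n and all(tokens[i + j].startswith(ph[j]) for j in range(1, L)):
                        hit_spans[ti].add((i, L))
        return [len(hit_tokens[ti]) + len(hit_spans[ti]) for ti in range(n_themes)]


@dataclass(frozen=True)
class ThemeScoreRow:
    """Theme scores of one post; keys follow lexicon theme order."""

    post_id: str
    scores: Mapping[str, int]

    def __post_init__(self):
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("theme scores must be nonnegative")


class ScoreMatrix:
    """Posts x themes integer keyword counts plus the classification threshold."""

    def __init__(self, frame: pd.DataFrame, min_score: int = DEFAULT_MIN_SCORE, lexicon_id: str = "custom"):
        if min_score < 1:
            raise ValueError("min_score must be >= 1")
        if frame.index.has_duplicates:
            raise ValueError("duplicate post_id in score matrix")
        self.frame = frame.astype(int)
        self.min_score = int(min_score)
        self.lexicon_id = lexicon_id

    @property
    def theme_names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def post_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, post_id: str) -> ThemeScoreRow:
        s = self.frame.loc[post_id]
        return ThemeScoreRow(post_id, {t: int(s[t]) for t in self.frame.columns})

    def rows(self) -> Iterable[ThemeScoreRow]:
        for pid, s in zip(self.frame.index, self.frame.to_numpy()):
            yield ThemeScoreRow(pid, dict(zip(self.frame.columns, map(int, s))))

    def totals(self) -> pd.Series:
        """Total theme score per post."""
        return self.frame.sum(axis=1)

    def related_mask(self, min_score: int | None = None) -> pd.Series:
        """Boolean per post: related to at least one theme at the threshold."""
        tau = self.min_score if min_score is None else min_score
        return (self.frame >= tau).any(axis=1)

    def related_count(self, min_score: int | None = None) -> int:
        return int(self.related_mask(min_score).sum())

    def to_csv(self, path) -> Path:
        """Export with per-theme columns plus ``total`` and ``related`` (0/1)."""
        out = self.frame.copy()
        out["total"] = self.totals()
        out["related"] = self.related_mask().astype(int)
        out.index.name = "post_id"
        path = Path(path)
        out.to_csv(path, encoding="utf-8", lineterminator="\n")
        return path

    @classmethod
    def from_csv(cls, path, min_score: int = DEFAULT_MIN_SCORE, lexicon_id: str = "custom") -> "ScoreMatrix":
        df = pd.read_csv(path, index_col="post_id", encoding="utf-8")
        df.index = df.index.astype(str)
        df = df.drop(columns=[c for c in ("total", "related") if c in df.columns])
        return cls(df, min_score=min_score, lexicon_id=lexicon_id)


def score_post(post: "Post", lexicon: "Lexicon", matcher: LexiconMatcher | None = None) -> ThemeScoreRow:
    """Theme scores of one post against every theme of the lexicon."""
    m = matcher if matcher is not None else LexiconMatcher(lexicon)
    scores = m.score_tokens(tokenize(post.text))
    return ThemeScoreRow(post.post_id, dict(zip(m.theme_names, scores)))


def score_corpus(corpus: "Corpus", lexicon: "Lexicon", min_score: int = DEFAULT_MIN_SCORE) -> ScoreMatrix:
    """Score every post of a corpus; one row per post, deterministic."""
    matcher = LexiconMatcher(lexicon)
    data = [matcher.score_tokens(tokenize(p.text)) for p in corpus]
    frame = pd.DataFrame(data, index=pd.Index(corpus.post_ids(), name="post_id"), columns=list(matcher.theme_names))
    return ScoreMatrix(frame, min_score=min_score, lexicon_id=getattr(lexicon, "name", "custom"))


def classify_post(row: ThemeScoreRow, min_score: int = DEFAULT_MIN_SCORE) -> set[str]:
    """Themes whose score reaches the threshold; empty set = not related."""
    if min_score < 1:
        raise ValueError("min_score must be >= 1")
    return {t for t, s in row.scores.items() if s >= min_score}


def top_theme(row: ThemeScoreRow) -> str | None:
    """Highest-scoring theme; ties broken by lexicon order; None if all zero."""
    best_theme, best_score = None, 0
    for t, s in row.scores.items():  # insertion order = lexicon order
        if s > best_score:
            best_theme, best_score = t, s
    return best_theme


def total_theme_score(row: ThemeScoreRow) -> int:
    return sum(row.scores.values())


def select_qualitative_sample(
    matrix: ScoreMatrix,
    corpus: "Corpus",
    k: int = 20,
    max_per_user: int = 5,
) -> list[str]:
    """Pick the top-k posts by total theme score, capped per user.

    Posts are ranked by total theme score descending (ties: post_id
    ascending); walking the ranked list, a post is skipped once its author
    already holds ``max_per_user`` selections, and the walk continues with
    later posts until ``k`` are selected or the list is exhausted.
    """
    if k < 1 or max_per_user < 1:
        raise ValueError("k and max_per_user must be >= 1")
    user_of = {p.post_id: p.username for p in corpus}
    missing = [pid for pid in matrix.post_ids if pid not in user_of]
    if missing:
        raise ValueError(f"matrix rows not in corpus: {missing[:5]}")
    totals = matrix.totals()
    ranked = sorted(matrix.post_ids, key=lambda pid: (-int(totals[pid]), pid))
    selected: list[str] = []
    per_user: dict[str, int] = {}
    for pid in ranked:
        u = user_of[pid]
        if per_user.get(u, 0) >= max_per_user:
            continue
        selected.append(pid)
        per_user[u] = per_user.get(u, 0) + 1
        if len(selected) == k:
            break
    return selected


def agreement(top_a: Mapping[str, str | None], top_b: Mapping[str, str | None]) -> float:
    """Fraction of posts with identical top-theme designation."""
    if set(top_a) != set(top_b):
        raise ValueError("key sets differ")
    if not top_a:
        raise ValueError("empty designation mappings")
    same = sum(1 for k in top_a if top_a[k] == top_b[k])
    return same / len(top_a)
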