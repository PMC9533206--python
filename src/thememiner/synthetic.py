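"""Synthetic corpora with known structure.

Generates discussion-board corpora whose properties are known by
construction: planted psychosocial themes at configured prevalence,
heavy-tailed per-user activity, a board/year composition, and optional
separable latent topics for topic-model tests.  Background vocabulary is
screened against the lexicon so that, unless noise injection is enabled,
keyword hits can only come from planted themes — which makes scorer
recovery exact and testable.
"""

from __future__ import annotations

import datetime
import html
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus_io import Corpus, Post, parse_forum_html
from .lexicon import Lexicon, builtin_lexicon
from .scoring import ScoreMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ThemeRecovery",
    "RecoveryReport",
    "generate_corpus",
    "generate_fixture_html",
    "read_fixture_dir",
    "recovery_report",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SyntheticConfig:
    n_posts: int = 1000
    board_weights: Mapping[str, float] = field(
        default_factory=lambda: {"uterine": 0.49, "ovarian": 0.45, "other_gyn": 0.06}
    )
    year_range: tuple[int, int] = (2000, 2020)
    theme_prevalence: Mapping[str, float] = field(default_factory=dict)
    keywords_per_planted_theme: int = 4
    background_vocab_size: int = 500
    tokens_per_post_lognormal: tuple[float, float] = (3.3, 0.7)  # (mu, sigma) of log length
    user_activity_exponent: float = 2.0  # discrete power law; smaller = heavier tail
    noise_keyword_rate: float = 0.0  # per-post chance of one stray sub-threshold keyword
    n_latent_topics: int = 0
    topic_vocab_size: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_posts < 0:
            raise ValueError("n_posts must be >= 0")
        w = sum(self.board_weights.values())
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"board weights must sum to 1 (got {w})")
        for theme, p in self.theme_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {theme!r} outside [0, 1]")
        if not (0.0 <= self.noise_keyword_rate <= 1.0):
            raise ValueError("noise_keyword_rate outside [0, 1]")
        if self.keywords_per_planted_theme < 1:
            raise ValueError("keywords_per_planted_theme must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range reversed")
        if self.user_activity_exponent <= 1.0:
            raise ValueError("user_activity_exponent must be > 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels for a generated corpus."""

    planted: dict[str, frozenset[str]]  # post_id -> themes
    topic_of: dict[str, int | None]  # post_id -> latent topic (or None)
    theme_names: tuple[str, ...]  # themes eligible for planting, in lexicon order

    def realized_prevalence(self) -> dict[str, float]:
        n = len(self.planted)
        out = {}
        for theme in self.theme_names:
            out[theme] = (
                sum(1 for ts in self.planted.values() if theme in ts) / n if n else 0.0
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.planted:
            rows.append(
                {
                    "post_id": pid,
                    "planted_themes": "|".join(sorted(self.planted[pid])),
                    "topic": "" if self.topic_of.get(pid) is None else str(self.topic_of[pid]),
                }
            )
        return pd.DataFrame(rows, columns=["post_id", "planted_themes", "topic"])

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
        return path

    @classmethod
    def from_csv(cls, path, theme_names: Iterable[str]) -> "GroundTruth":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        planted = {}
        topic_of: dict[str, int | None] = {}
        for row in df.itertuples(index=False):
            planted[row.post_id] = frozenset(t for t in row.planted_themes.split("|") if t)
            topic_of[row.post_id] = int(row.topic) if row.topic else None
        return cls(planted, topic_of, tuple(theme_names))


def _pattern_tokens(lexicon: Lexicon) -> set[str]:
    toks = set()
    for _, pats in lexicon:
        for p in pats:
            toks.update(p.tokens)
    return toks


def _is_clean(word: str, forbidden: set[str], max_len: int) -> bool:
    """True when no lexicon pattern token is a prefix of ``word``."""
    for plen in range(1, min(len(word), max_len) + 1):
        if word[:plen] in forbidden:
            return False
    return True


def _screened_words(rng: np.random.Generator, n: int, forbidden: set[str], taken: set[str]) -> list[str]:
    max_len = max((len(t) for t in forbidden), default=0)
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(4, 10))
        word = "".join(_LETTERS[i] for i in rng.integers(0, 26, size=length))
        if word in taken or not _is_clean(word, forbidden, max_len):
            continue
        taken.add(word)
        out.append(word)
    return out


def _root_theme_index(lexicon: Lexicon) -> dict[str, set[str]]:
    idx: dict[str, set[str]] = {}
    for theme, pats in lexicon:
        for p in pats:
            if p.kind == "root":
                idx.setdefault(p.tokens[0], set()).add(theme)
    return idx


def _themes_hit_by_token(token: str, root_index: dict[str, set[str]]) -> set[str]:
    hit: set[str] = set()
    for root, themes in root_index.items():
        if token.startswith(root):
            hit |= themes
    return hit


def _surface_form(
    rng: np.random.Generator,
    theme: str,
    lexicon: Lexicon,
    root_index: dict[str, set[str]],
) -> list[str]:
    """Tokens realizing one keyword of ``theme``.

    Roots get a random lowercase suffix (length 0-4) to exercise prefix
    matching; the suffixed form is rejected if it would hit a theme that the
    bare root itself does not hit (keyword sharing across themes is
    inherent and allowed through).
    """
    pats = lexicon.patterns(theme)
    p = pats[int(rng.integers(0, len(pats)))]
    if p.kind == "phrase":
        return list(p.tokens)
    root = p.tokens[0]
    inherent = _themes_hit_by_token(root, root_index) | {theme}
    for _ in range(20):
        slen = int(rng.integers(0, 5))
        cand = root + "".join(_LETTERS[i] for i in rng.integers(0, 26, size=slen))
        if _themes_hit_by_token(cand, root_index) <= inherent:
            return [cand]
    return [root]


def generate_corpus(
    config: SyntheticConfig, lexicon: Lexicon | None = None
) -> tuple[Corpus, GroundTruth]:
    """Generate a seeded corpus plus its ground truth.

    Identical config (including seed) gives identical output.
    """
    config.validate()
    lex = builtin_lexicon() if lexicon is None else lexicon
    for theme in config.theme_prevalence:
        if theme not in lex:
            raise ValueError(f"unknown theme in prevalence config: {theme!r}")
    rng = np.random.default_rng(config.seed)
    forbidden = _pattern_tokens(lex)
    taken: set[str] = set()
    background = _screened_words(rng, config.background_vocab_size, forbidden, taken)
    topic_vocabs: list[list[str]] = []
    for _ in range(config.n_latent_topics):
        topic_vocabs.append(_screened_words(rng, config.topic_vocab_size, forbidden, taken))
    root_index = _root_theme_index(lex)

    # heavy-tailed per-user activity: draw zipf counts until posts are covered
    user_slots: list[int] = []
    uid = 0
    while len(user_slots) < config.n_posts:
        count = int(rng.zipf(config.user_activity_exponent))
        user_slots.extend([uid] * count)
        uid += 1
    user_slots = user_slots[: config.n_posts]
    perm = rng.permutation(config.n_posts)
    usernames = [f"user{user_slots[perm[i]]:05d}" for i in range(config.n_posts)]

    boards = list(config.board_weights)
    weights = np.array([config.board_weights[b] for b in boards], dtype=float)
    mu, sigma = config.tokens_per_post_lognormal
    y0, y1 = config.year_range

    posts: list[Post] = []
    planted: dict[str, frozenset[str]] = {}
    topic_of: dict[str, int | None] = {}
    all_themes = tuple(t for t in lex.theme_names if t in config.theme_prevalence)
    for i in range(config.n_posts):
        pid = f"p{i:06d}"
        board = boards[int(rng.choice(len(boards), p=weights))]
        date = datetime.date(
            int(rng.integers(y0, y1 + 1)), int(rng.integers(1, 13)), int(rng.integers(1, 29))
        )
        n_tokens = max(1, int(round(float(rng.lognormal(mu, sigma)))))
        if topic_vocabs:
            topic = int(rng.integers(0, len(topic_vocabs)))
            vocab = topic_vocabs[topic]
        else:
            topic = None
            vocab = background
        # Zipf-ish within-vocabulary weights keep word ranks deterministic
        ranks = np.arange(1, len(vocab) + 1, dtype=float)
        probs = (1.0 / ranks) / (1.0 / ranks).sum()
        tokens = [vocab[j] for j in rng.choice(len(vocab), size=n_tokens, p=probs)]
        themes_here = []
        for theme in all_themes:
            if rng.random() < config.theme_prevalence[theme]:
                themes_here.append(theme)
                for _ in range(config.keywords_per_planted_theme):
                    surface = _surface_form(rng, theme, lex, root_index)
                    pos = int(rng.integers(0, len(tokens) + 1))
                    tokens[pos:pos] = surface
        if config.noise_keyword_rate > 0 and rng.random() < config.noise_keyword_rate:
            noise_theme = lex.theme_names[int(rng.integers(0, len(lex)))]
            surface = _surface_form(rng, noise_theme, lex, root_index)
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens[pos:pos] = surface
        posts.append(Post(pid, board, usernames[i], date, " ".join(tokens)))
        planted[pid] = frozenset(themes_here)
        topic_of[pid] = topic
    truth = GroundTruth(planted, topic_of, all_themes)
    return Corpus(posts), truth


_PAGE_TEMPLATE = """<!DOCTYPE html>
<html><head><title>{board} board — page {page}</title></head>
<body>
<div class="thread">
{posts}
</div>
</body></html>
"""

_POST_TEMPLATE = """<div class="post" id="{pid}">
<span class="username">{user}</span>
<span class="date">{date}</span>
<div class="post-text">{text}</div>
</div>"""


def generate_fixture_html(corpus: Corpus, out_dir, posts_per_page: int = 25) -> list[Path]:
    """Write fixture-dialect pages; posts are grouped by board (order of
    first appearance), each board chunked into ``posts_per_page`` pages.

    A ``manifest.json`` records page order and board labels so
    :func:`read_fixture_dir` can reconstruct the corpus (exactly equal to
    the input whenever the input is already grouped by board, as each page
    carries a single board label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_board: dict[str, list[Post]] = {}
    for p in corpus:
        by_board.setdefault(p.board, []).append(p)
    manifest = []
    paths = []
    for board, posts in by_board.items():
        n_pages = math.ceil(len(posts) / posts_per_page)
        for page in range(n_pages):
            chunk = posts[page * posts_per_page : (page + 1) * posts_per_page]
            body = "\n".join(
                _POST_TEMPLATE.format(
                    pid=html.escape(p.post_id, quote=True),
                    user=html.escape(p.username),
                    date=p.date.isoformat(),
                    text=html.escape(p.text),
                )
                for p in chunk
            )
            name = f"{board}_page{page:04d}.html"
            (out_dir / name).write_text(
                _PAGE_TEMPLATE.format(board=board, page=page, posts=body), encoding="utf-8"
            )
            manifest.append({"file": name, "board": board})
            paths.append(out_dir / name)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return paths


def read_fixture_dir(out_dir) -> Corpus:
    """Parse every page listed in the manifest, in manifest order."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text(encoding="utf-8"))
    posts: list[Post] = []
    for entry in manifest:
        text = (out_dir / entry["file"]).read_text(encoding="utf-8")
        posts.extend(parse_forum_html(text, entry["board"]))
    return Corpus(posts)


@dataclass(frozen=True)
class ThemeRecovery:
    sensitivity: float  # nan when nothing was planted
    false_positive_rate: float
    planted_prevalence: float
    measured_prevalence: float


@dataclass(frozen=True)
class RecoveryReport:
    per_theme: dict[str, ThemeRecovery]
    overall_prevalence_error: float  # max |measured - planted| over planted themes


def recovery_report(truth: GroundTruth, matrix: ScoreMatrix) -> RecoveryReport:
    """Classification quality of the score matrix against planted labels."""
    if set(matrix.post_ids) != set(truth.planted):
        raise ValueError("post id sets differ between truth and matrix")
    n = len(matrix)
    per_theme: dict[str, ThemeRecovery] = {}
    errs = []
    for theme in matrix.theme_names:
        planted_ids = {pid for pid, ts in truth.planted.items() if theme in ts}
        flags = matrix.frame[theme] >= matrix.min_score
        tp = sum(1 for pid in planted_ids if flags[pid])
        fp = int(flags.sum()) - tp
        n_pos = len(planted_ids)
        n_neg = n - n_pos
        sens = tp / n_pos if n_pos else float("nan")
        fpr = fp / n_neg if n_neg else 0.0
        planted_prev = n_pos / n if n else 0.0
        measured_prev = float(flags.mean()) if n else 0.0
        per_theme[theme] = ThemeRecovery(sens, fpr, planted_prev, measured_prev)
        if theme in truth.theme_names:
            errs.append(abs(measured_prev - planted_prev))
    return RecoveryReport(per_theme, max(errs) if errs else 0.0)
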