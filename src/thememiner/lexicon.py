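"""The a-priori psychosocial theme lexicon.

A lexicon maps theme names (in a fixed, meaningful order) to keyword
patterns.  Patterns come in two kinds: a *root*, matched as a prefix of a
single token (``unemploy`` hits ``unemployment``), and a *phrase*, an
ordered token list matched against consecutive tokens.  The built-in
default ships the 29-theme keyword list verbatim; entries with internal
punctuation are normalized by the same tokenizer used at match time, so
``full-time`` becomes the phrase ``(full, time)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .scoring import tokenize

__all__ = [
    "KeywordPattern",
    "Lexicon",
    "LexiconError",
    "LexiconReport",
    "pattern_from_string",
    "builtin_lexicon",
    "load_lexicon",
    "loads_lexicon",
    "save_lexicon",
    "dumps_lexicon",
    "validate_lexicon",
]


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class KeywordPattern:
    """A single keyword: a prefix root or an ordered phrase."""

    kind: str  # "root" | "phrase"
    tokens: tuple[str, ...]

    def __post_init__(self):
        if self.kind not in ("root", "phrase"):
            raise LexiconError(f"unknown pattern kind {self.kind!r}")
        if not self.tokens or any(not t for t in self.tokens):
            raise LexiconError("pattern tokens must be non-empty")
        if self.kind == "root" and len(self.tokens) != 1:
            raise LexiconError("root pattern must have exactly one token")
        if self.kind == "phrase" and len(self.tokens) < 2:
            raise LexiconError("phrase pattern needs at least two tokens")
        if any(" " in t or t != t.lower() for t in self.tokens):
            raise LexiconError(f"pattern tokens must be lowercase, whitespace-free: {self.tokens!r}")

    @property
    def surface(self) -> str:
        return " ".join(self.tokens)


def pattern_from_string(raw: str) -> KeywordPattern:
    """Normalize a printed keyword into a pattern via the shared tokenizer."""
    toks = tokenize(raw)
    if not toks:
        raise LexiconError(f"keyword {raw!r} has no tokens")
    if len(toks) == 1:
        return KeywordPattern("root", toks)
    return KeywordPattern("phrase", toks)


@dataclass(frozen=True)
class Lexicon:
    """Ordered mapping theme name -> keyword patterns."""

    themes: tuple[tuple[str, tuple[KeywordPattern, ...]], ...]
    name: str = "custom"

    def __post_init__(self):
        names = [t for t, _ in self.themes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise LexiconError(f"duplicate theme name(s): {dupes}")
        for t, pats in self.themes:
            if not pats:
                raise LexiconError(f"theme {t!r} has no keywords")

    @property
    def theme_names(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.themes)

    def patterns(self, theme: str) -> tuple[KeywordPattern, ...]:
        for t, pats in self.themes:
            if t == theme:
                return pats
        raise KeyError(theme)

    def __len__(self) -> int:
        return len(self.themes)

    def __iter__(self) -> Iterator[tuple[str, tuple[KeywordPattern, ...]]]:
        return iter(self.themes)

    def __contains__(self, theme: str) -> bool:
        return theme in self.theme_names


def _build(pairs: Iterable[tuple[str, Iterable[str]]], name: str) -> Lexicon:
    themes = []
    for theme, keywords in pairs:
        pats = tuple(pattern_from_string(k) for k in keywords)
        themes.append((theme, pats))
    return Lexicon(tuple(themes), name=name)


def loads_lexicon(text: str, name: str = "custom") -> Lexicon:
    """Parse the plain-text lexicon config format.

    ``[Theme name]`` headers open a theme block; each following non-empty,
    non-comment line is one keyword.
    """
    pairs: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            theme = line[1:-1].strip()
            if not theme:
                raise LexiconError(f"line {lineno}: empty theme name")
            current = []
            pairs.append((theme, current))
        else:
            if current is None:
                raise LexiconError(f"line {lineno}: keyword before any [theme] header")
            if not tokenize(line):
                raise LexiconError(f"theme {pairs[-1][0]!r}: empty keyword at line {lineno}")
            current.append(line.lower())
    if not pairs:
        raise LexiconError("no themes found")
    for theme, kws in pairs:
        if not kws:
            raise LexiconError(f"theme {theme!r} has no keywords")
    return _build(pairs, name)


def load_lexicon(path) -> Lexicon:
    path = Path(path)
    return loads_lexicon(path.read_text(encoding="utf-8"), name=path.stem)


def dumps_lexicon(lex: Lexicon) -> str:
    lines = []
    for theme, pats in lex:
        lines.append(f"[{theme}]")
        lines.extend(p.surface for p in pats)
    return "\n".join(lines) + "\n"


def save_lexicon(lex: Lexicon, path) -> Path:
    path = Path(path)
    path.write_text(dumps_lexicon(lex), encoding="utf-8")
    return path


_BUILTIN_RESOURCE = "box1_lexicon.txt"
_builtin_cache: Lexicon | None = None


def builtin_lexicon() -> Lexicon:
    """The shipped 29-theme default lexicon."""
    global _builtin_cache
    if _builtin_cache is None:
        text = resources.files("thememiner.data").joinpath(_BUILTIN_RESOURCE).read_text("utf-8")
        _builtin_cache = loads_lexicon(text, name="box1")
    return _builtin_cache


def builtin_lexicon_sha256() -> str:
    data = resources.files("thememiner.data").joinpath(_BUILTIN_RESOURCE).read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass
class LexiconReport:
    """Report-only validation output; nothing here is fatal."""

    within_theme_duplicates: dict[str, list[str]] = field(default_factory=dict)
    cross_theme_shared: dict[str, list[str]] = field(default_factory=dict)  # surface -> themes
    short_roots: dict[str, list[str]] = field(default_factory=dict)  # theme -> roots

    @property
    def clean(self) -> bool:
        return not (self.within_theme_duplicates or self.cross_theme_shared or self.short_roots)


def validate_lexicon(lex: Lexicon, min_root_length: int = 5) -> LexiconReport:
    """Flag within-theme duplicates, cross-theme shared patterns and short roots.

    Short ambiguous roots (e.g. ``rest``) are kept for fidelity but are worth
    a human look; ``min_root_length`` controls the warning cut-off.
    """
    report = LexiconReport()
    seen_by_surface: dict[str, list[str]] = {}
    for theme, pats in lex:
        counts: dict[str, int] = {}
        for p in pats:
            counts[p.surface] = counts.get(p.surface, 0) + 1
            seen_by_surface.setdefault(p.surface, [])
            if theme not in seen_by_surface[p.surface]:
                seen_by_surface[p.surface].append(theme)
        dupes = sorted(s for s, c in counts.items() if c > 1)
        if dupes:
            report.within_theme_duplicates[theme] = dupes
        shorts = sorted({p.tokens[0] for p in pats if p.kind == "root" and len(p.tokens[0]) < min_root_length})
        if shorts:
            report.short_roots[theme] = shorts
    for surface, themes in seen_by_surface.items():
        if len(themes) > 1:
            report.cross_theme_shared[surface] = themes
    return report
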