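"""Read and write discussion-board post corpora.

Two physical representations are supported: a fixture HTML dialect (one
``<div class="post">`` element per post, see README) parsed with the
standard-library HTML parser, and an RFC-4180 CSV table with the canonical
columns ``post_id,board,username,date,text``.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, replace
from html.parser import HTMLParser
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "Post",
    "Corpus",
    "CANONICAL_BOARDS",
    "POST_TABLE_COLUMNS",
    "ForumParseError",
    "CorpusError",
    "parse_forum_html",
    "read_post_table",
    "write_post_table",
]

#: Board labels used by the shipped fixtures; other labels are legal but warned.
CANONICAL_BOARDS = ("ovarian", "uterine", "other_gyn")

POST_TABLE_COLUMNS = ("post_id", "board", "username", "date", "text")


class CorpusError(ValueError):
    """Raised for malformed tabular corpora (missing column, bad date, dup id)."""


class ForumParseError(ValueError):
    """Raised when a fixture HTML page violates the dialect.

    Attributes
    ----------
    field : str
        Name of the missing/invalid field (``username``, ``date``, ``text``
        or ``id``).
    element_index : int
        Zero-based index of the offending post element in document order.
    """

    def __init__(self, field: str, element_index: int, message: str | None = None):
        self.field = field
        self.element_index = element_index
        super().__init__(
            message
            or f"post element {element_index}: missing or invalid field {field!r}"
        )


@dataclass(frozen=True, order=True)
class Post:
    """One discussion-board message."""

    post_id: str
    board: str
    username: str
    date: datetime.date
    text: str

    def with_board(self, board: str) -> "Post":
        return replace(self, board=board)


class Corpus:
    """An ordered collection of :class:`Post` with unique ids."""

    def __init__(self, posts: Iterable[Post], *, date_range: tuple[datetime.date, datetime.date] | None = None):
        self.posts: list[Post] = list(posts)
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise CorpusError(f"duplicate post_id {p.post_id!r}")
            seen.add(p.post_id)
            if date_range is not None and not (date_range[0] <= p.date <= date_range[1]):
                raise CorpusError(
                    f"post {p.post_id!r}: date {p.date} outside valid range {date_range}"
                )
        unknown = self.boards - set(CANONICAL_BOARDS)
        if unknown:
            warnings.warn(f"non-canonical board labels present: {sorted(unknown)}", stacklevel=2)

    @property
    def boards(self) -> set[str]:
        return {p.board for p in self.posts}

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __getitem__(self, i):
        return self.posts[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Corpus) and self.posts == other.posts

    def __repr__(self) -> str:
        return f"Corpus({len(self.posts)} posts, boards={sorted(self.boards)})"

    def texts(self) -> list[str]:
        return [p.text for p in self.posts]

    def post_ids(self) -> list[str]:
        return [p.post_id for p in self.posts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "post_id": [p.post_id for p in self.posts],
                "board": [p.board for p in self.posts],
                "username": [p.username for p in self.posts],
                "date": [p.date.isoformat() for p in self.posts],
                "text": [p.text for p in self.posts],
            }
        )


class _FixtureHTMLParser(HTMLParser):
    """State machine for the fixture dialect.

    Posts are ``<div class="post" id="...">`` containing
    ``<span class="username">``, ``<span class="date">`` (ISO 8601) and
    ``<div class="post-text">``.
    """

    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.records: list[dict] = []
        self._in_post_depth = 0  # div nesting depth inside current post
        self._current: dict | None = None
        self._capture: str | None = None  # username | date | text
        self._capture_depth = 0
        self._buf: list[str] = []

    @staticmethod
    def _attr(attrs, name):
        for k, v in attrs:
            if k == name:
                return v
        return None

    def handle_starttag(self, tag, attrs):
        cls = self._attr(attrs, "class") or ""
        classes = cls.split()
        if tag == "div" and self._current is None and "post" in classes:
            self._current = {"id": self._attr(attrs, "id")}
            self._in_post_depth = 1
            return
        if self._current is None:
            return
        if self._capture is not None:
            if tag == "div":
                self._capture_depth += 1
            return
        if tag == "span" and "username" in classes:
            self._capture, self._buf = "username", []
        elif tag == "span" and "date" in classes:
            self._capture, self._buf = "date", []
        elif tag == "div" and "post-text" in classes:
            self._capture, self._buf = "text", []
            self._capture_depth = 0
            self._in_post_depth += 1
        elif tag == "div":
            self._in_post_depth += 1

    def handle_endtag(self, tag):
        if self._current is None:
            return
        if self._capture in ("username", "date"):
            if tag == "span":
                self._current[self._capture] = "".join(self._buf)
                self._capture = None
            return
        if self._capture == "text":
            if tag == "div":
                if self._capture_depth == 0:
                    self._current["text"] = "".join(self._buf)
                    self._capture = None
                    self._in_post_depth -= 1
                else:
                    self._capture_depth -= 1
            return
        if tag == "div":
            self._in_post_depth -= 1
            if self._in_post_depth == 0:
                self.records.append(self._current)
                self._current = None

    def handle_data(self, data):
        if self._capture is not None:
            self._buf.append(data)

    def close(self):
        super().close()
        if self._current is not None:  # unclosed post div
            self.records.append(self._current)
            self._current = None


def parse_forum_html(html_doc: str, board_label: str) -> list[Post]:
    """Parse one fixture-dialect page into posts, in document order.

    Raises :class:`ForumParseError` naming the first missing field and the
    index of the offending post element.
    """
    parser = _FixtureHTMLParser()
    parser.feed(html_doc)
    parser.close()
    posts = []
    for i, rec in enumerate(parser.records):
        if rec.get("id") in (None, ""):
            raise ForumParseError("id", i)
        for field in ("username", "date", "text"):
            if field not in rec:
                raise ForumParseError(field, i)
        try:
            date = datetime.date.fromisoformat(rec["date"].strip())
        except ValueError as exc:
            raise ForumParseError("date", i, f"post element {i}: unparseable date {rec['date']!r}") from exc
        posts.append(
            Post(
                post_id=rec["id"],
                board=board_label,
                username=rec["username"],
                date=date,
                text=rec["text"],
            )
        )
    return posts


def read_post_table(path) -> Corpus:
    """Read the canonical CSV post table into a :class:`Corpus`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in POST_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"missing column(s): {', '.join(missing)}")
    posts = []
    for row in df.itertuples(index=False):
        try:
            date = datetime.date.fromisoformat(row.date)
        except ValueError as exc:
            raise CorpusError(f"post {row.post_id!r}: unparseable date {row.date!r}") from exc
        posts.append(Post(row.post_id, row.board, row.username, date, row.text))
    return Corpus(posts)


def write_post_table(corpus: Corpus, path) -> Path:
    """Write a corpus as the canonical CSV table (UTF-8, RFC-4180 quoting)."""
    path = Path(path)
    corpus.to_frame().to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path
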