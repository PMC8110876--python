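"""Canonical post/corpus data model and JSONL/CSV readers and writers.

A :class:`Post` is one tweet or retweet record with the engagement metadata
the downstream influence analysis needs (likes, comments, shares, author
follower count, retweet linkage).  A :class:`Corpus` is an ordered collection
of posts together with the half-open collection window ``[start, end)``.

Timestamps are serialized as ISO-8601 UTC with a trailing ``Z``.  Ingestion
tolerates offset-bearing stamps (converted to UTC) and treats naive stamps as
UTC.  Retweets whose original is absent from the corpus are retained and
reported by :meth:`Corpus.unresolved_retweets`, never dropped: the upstream
feed captures retweets independently of their originals.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import DuplicateIdError, SchemaError

__all__ = [
    "Post",
    "Corpus",
    "read_posts",
    "write_posts",
    "DEFAULT_WINDOW",
    "CSV_FIELDS",
]

#: Default collection window: six whole calendar months, half-open.
DEFAULT_WINDOW = (
    datetime(2019, 6, 1, tzinfo=timezone.utc),
    datetime(2019, 12, 1, tzinfo=timezone.utc),
)

CSV_FIELDS = [
    "post_id",
    "author_id",
    "text",
    "timestamp",
    "is_retweet",
    "retweet_of",
    "likes",
    "comments",
    "shares",
    "author_followers",
]

_COUNT_FIELDS = ("likes", "comments", "shares", "author_followers")


@dataclass(frozen=True, slots=True)
class Post:
    """One tweet/retweet record with engagement metadata.

    Invariants (enforced at construction): ``is_retweet`` is true exactly when
    ``retweet_of`` is set; ``retweet_of`` never equals ``post_id``; all counts
    are nonnegative integers; the timestamp is timezone-aware UTC.
    """

    post_id: str
    author_id: str
    text: str
    timestamp: datetime
    is_retweet: bool = False
    retweet_of: Optional[str] = None
    likes: int = 0
    comments: int = 0
    shares: int = 0
    author_followers: int = 0

    def __post_init__(self):
        if not self.post_id:
            raise SchemaError("post_id must be a nonempty string")
        if not self.author_id:
            raise SchemaError("author_id must be a nonempty string")
        if self.is_retweet != (self.retweet_of is not None):
            raise SchemaError(
                f"post {self.post_id!r}: is_retweet must be set iff retweet_of is set"
            )
        if self.retweet_of == self.post_id:
            raise SchemaError(f"post {self.post_id!r}: retweet_of equals post_id")
        for name in _COUNT_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise SchemaError(
                    f"post {self.post_id!r}: {name} must be a nonnegative integer, got {value!r}"
                )
        ts = self.timestamp
        if not isinstance(ts, datetime):
            raise SchemaError(f"post {self.post_id!r}: timestamp must be a datetime")
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        object.__setattr__(self, "timestamp", ts.astimezone(timezone.utc))

    @property
    def interactions(self) -> int:
        """Likes + comments + shares (one engagement event each)."""
        return self.likes + self.comments + self.shares


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of posts with a half-open collection window."""

    posts: tuple[Post, ...]
    window_start: datetime = DEFAULT_WINDOW[0]
    window_end: datetime = DEFAULT_WINDOW[1]

    def __post_init__(self):
        object.__setattr__(self, "posts", tuple(self.posts))
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise DuplicateIdError(f"duplicate post_id {p.post_id!r}")
            seen.add(p.post_id)
        by_id = {p.post_id: p for p in self.posts}
        for p in self.posts:
            if p.retweet_of is not None and p.retweet_of in by_id:
                if by_id[p.retweet_of].is_retweet:
                    raise SchemaError(
                        f"post {p.post_id!r}: retweet_of points at another retweet"
                    )

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __getitem__(self, i):
        return self.posts[i]

    def by_id(self) -> dict[str, Post]:
        return {p.post_id: p for p in self.posts}

    def unresolved_retweets(self) -> tuple[Post, ...]:
        """Retweets whose original is not in this corpus (retained, flagged)."""
        ids = {p.post_id for p in self.posts}
        return tuple(
            p for p in self.posts if p.retweet_of is not None and p.retweet_of not in ids
        )

    def subset(self, posts: Iterable[Post]) -> "Corpus":
        """A corpus over the same window containing only ``posts``."""
        return Corpus(tuple(posts), self.window_start, self.window_end)

    def in_window(self) -> "Corpus":
        """Posts whose timestamps fall in ``[window_start, window_end)``."""
        return self.subset(
            p for p in self.posts if self.window_start <= p.timestamp < self.window_end
        )


# ---------------------------------------------------------------------------
# serialization


def _format_timestamp(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _parse_timestamp(raw: str) -> datetime:
    if not isinstance(raw, str) or not raw:
        raise ValueError(f"bad timestamp {raw!r}")
    text = raw[:-1] + "+00:00" if raw.endswith("Z") else raw
    ts = datetime.fromisoformat(text)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _post_to_record(post: Post) -> dict:
    return {
        "post_id": post.post_id,
        "author_id": post.author_id,
        "text": post.text,
        "timestamp": _format_timestamp(post.timestamp),
        "is_retweet": post.is_retweet,
        "retweet_of": post.retweet_of,
        "likes": post.likes,
        "comments": post.comments,
        "shares": post.shares,
        "author_followers": post.author_followers,
    }


def _record_to_post(record: dict, line: int) -> Post:
    for name in ("post_id", "author_id", "text", "timestamp"):
        if name not in record or record[name] is None:
            raise SchemaError(f"missing required field {name!r}", line=line)
    try:
        ts = _parse_timestamp(record["timestamp"])
    except ValueError as exc:
        raise SchemaError(f"unparseable timestamp: {exc}", line=line) from exc
    counts = {}
    for name in _COUNT_FIELDS:
        value = record.get(name, 0)
        try:
            counts[name] = int(value)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"bad count for {name!r}: {value!r}", line=line) from exc
    retweet_of = record.get("retweet_of") or None
    is_retweet = record.get("is_retweet", retweet_of is not None)
    if isinstance(is_retweet, str):
        is_retweet = is_retweet.strip().lower() in ("true", "1", "yes")
    try:
        return Post(
            post_id=str(record["post_id"]),
            author_id=str(record["author_id"]),
            text=str(record["text"]),
            timestamp=ts,
            is_retweet=bool(is_retweet),
            retweet_of=retweet_of,
            **counts,
        )
    except SchemaError as exc:
        raise SchemaError(str(exc), line=line) from exc


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_posts(
    path,
    format: Optional[str] = None,
    window: Optional[tuple[datetime, datetime]] = None,
    filter_window: bool = False,
) -> Corpus:
    """Read a corpus from a JSON Lines or CSV file.

    Malformed records are rejected with their line numbers; duplicate post ids
    raise :class:`DuplicateIdError`.  When ``filter_window`` is true, posts
    outside ``[window_start, window_end)`` are dropped on ingest.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    posts: list[Post] = []
    problems: list[str] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    problems.append(f"line {lineno}: invalid JSON ({exc.msg})")
                    continue
                try:
                    posts.append(_record_to_post(record, lineno))
                except SchemaError as exc:
                    problems.append(str(exc))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError("empty CSV file: header row required")
            missing = set(("post_id", "author_id", "text", "timestamp")) - set(
                reader.fieldnames
            )
            if missing:
                raise SchemaError(f"CSV header missing fields: {sorted(missing)}")
            for record in reader:
                lineno = reader.line_num
                try:
                    posts.append(_record_to_post(record, lineno))
                except SchemaError as exc:
                    problems.append(str(exc))
    if problems:
        raise SchemaError(
            f"{len(problems)} malformed record(s) in {path.name}: "
            + "; ".join(problems[:20])
        )
    start, end = window if window is not None else DEFAULT_WINDOW
    corpus = Corpus(tuple(posts), start, end)
    if filter_window:
        corpus = corpus.in_window()
    return corpus


def write_posts(corpus: Corpus, path, format: Optional[str] = None) -> None:
    """Write a corpus to JSONL or CSV so that ``read_posts`` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for post in corpus:
                fh.write(json.dumps(_post_to_record(post), ensure_ascii=False))
                fh.write("\n")
    else:
        # newline='' so csv's own RFC-4180 quoting handles embedded newlines
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
            writer.writeheader()
            for post in corpus:
                record = _post_to_record(post)
                record["is_retweet"] = "true" if record["is_retweet"] else "false"
                record["retweet_of"] = record["retweet_of"] or ""
                writer.writerow(record)


def dumps_jsonl(corpus: Corpus) -> str:
    """Corpus as a JSONL string (used for byte-identity checks)."""
    buf = io.StringIO()
    for post in corpus:
        buf.write(json.dumps(_post_to_record(post), ensure_ascii=False))
        buf.write("\n")
    return buf.getvalue()
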