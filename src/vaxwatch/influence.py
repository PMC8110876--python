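"""Engagement accounting and top-author (influencer) identification.

An *interaction* is a like, a comment, or a share of a post.  For every
calendar month of the collection window, authors are ranked by the total
interactions received on their opposition posts in that month; the top ``k``
(default 50) are that month's *top authors*.  The registry aggregates the
per-month rankings into the union of all top authors and each author's
persistence (number of months ranked).  *Potential impressions* of a post are
the original author's followers plus the followers of every account that
shared it.

Interactions on a retweet accrue to the retweet's own author; the share event
itself is already counted in the original post's ``shares``.  Accounts that a
manual screen rejected (mockery or news accounts) are supplied as a deny-list
and removed before ranking.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus import Corpus, Post
from .errors import LinkageError
from .themes import TaggedPost

__all__ = [
    "AuthorMonthStats",
    "TopAuthorRegistry",
    "interaction_count",
    "monthly_top_authors",
    "potential_impressions",
    "partition_by_top_authors",
    "DEFAULT_TOP_K",
]

DEFAULT_TOP_K = 50

Month = tuple[int, int]  # (year, month), UTC calendar month of the timestamp


def interaction_count(post: Post) -> int:
    """Likes + comments + shares received by one post."""
    return post.likes + post.comments + post.shares


def month_of(post: Post) -> Month:
    ts = post.timestamp
    return (ts.year, ts.month)


@dataclass(frozen=True)
class AuthorMonthStats:
    """One author's activity and engagement in one calendar month."""

    author_id: str
    month: Month
    n_posts: int
    interactions_received: int
    rank: Optional[int] = None  # 1-based; only assigned to the top k


@dataclass(frozen=True)
class TopAuthorRegistry:
    """Per-month top-k rankings plus union membership and persistence."""

    k: int
    monthly: dict[Month, tuple[AuthorMonthStats, ...]]
    union: frozenset[str] = field(init=False)
    months_as_top: dict[str, int] = field(init=False)

    def __post_init__(self):
        months_as_top: dict[str, int] = {}
        for ranked in self.monthly.values():
            for stats in ranked:
                months_as_top[stats.author_id] = months_as_top.get(stats.author_id, 0) + 1
        object.__setattr__(self, "union", frozenset(months_as_top))
        object.__setattr__(self, "months_as_top", months_as_top)

    def persistent_authors(self, min_months: int) -> frozenset[str]:
        """Authors ranked in at least ``min_months`` months."""
        return frozenset(
            a for a, m in self.months_as_top.items() if m >= min_months
        )

    def to_rows(self) -> list[dict]:
        rows = []
        for month in sorted(self.monthly):
            for stats in self.monthly[month]:
                rows.append(
                    {
                        "month": f"{month[0]:04d}-{month[1]:02d}",
                        "rank": stats.rank,
                        "author_id": stats.author_id,
                        "interactions": stats.interactions_received,
                        "n_posts": stats.n_posts,
                    }
                )
        return rows

    def to_csv(self, path) -> None:
        rows = self.to_rows()
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["month", "rank", "author_id", "interactions", "n_posts"]
            )
            writer.writeheader()
            writer.writerows(rows)

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "rankings": self.to_rows(),
            "union_size": len(self.union),
            "months_as_top": dict(sorted(self.months_as_top.items())),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def monthly_top_authors(
    corpus: Corpus | Iterable[Post],
    k: int = DEFAULT_TOP_K,
    deny_list: Iterable[str] = (),
) -> TopAuthorRegistry:
    """Rank authors by interactions received within each calendar month.

    Ties break by (n_posts descending, author_id ascending) so the ranking is
    a deterministic permutation regardless of input order.  Months with no
    posts simply have no ranking.  ``deny_list`` authors are removed before
    ranking (the manual screen for mockery/news accounts).
    """
    deny = frozenset(deny_list)
    per_month: dict[Month, dict[str, list[int]]] = {}
    for post in corpus:
        if post.author_id in deny:
            continue
        month = month_of(post)
        stats = per_month.setdefault(month, {}).setdefault(post.author_id, [0, 0])
        stats[0] += 1
        stats[1] += interaction_count(post)
    monthly: dict[Month, tuple[AuthorMonthStats, ...]] = {}
    for month, authors in sorted(per_month.items()):
        order = sorted(
            authors.items(), key=lambda kv: (-kv[1][1], -kv[1][0], kv[0])
        )
        ranked = tuple(
            AuthorMonthStats(
                author_id=author,
                month=month,
                n_posts=n_posts,
                interactions_received=interactions,
                rank=i + 1,
            )
            for i, (author, (n_posts, interactions)) in enumerate(order[:k])
        )
        monthly[month] = ranked
    return TopAuthorRegistry(k=k, monthly=monthly)


def potential_impressions(post: Post, sharers: Iterable[Post] = ()) -> int:
    """Original author's followers plus followers of every sharer."""
    total = post.author_followers
    for sharer in sharers:
        if sharer.retweet_of != post.post_id:
            raise LinkageError(
                f"post {sharer.post_id!r} is not a share of {post.post_id!r}"
            )
        total += sharer.author_followers
    return total


def total_potential_impressions(corpus: Corpus, authors: Iterable[str]) -> int:
    """Summed potential impressions over all original posts of ``authors``."""
    authors = frozenset(authors)
    sharers_of: dict[str, list[Post]] = {}
    for p in corpus:
        if p.retweet_of is not None:
            sharers_of.setdefault(p.retweet_of, []).append(p)
    return sum(
        potential_impressions(p, sharers_of.get(p.post_id, ()))
        for p in corpus
        if not p.is_retweet and p.author_id in authors
    )


def partition_by_top_authors(
    tagged: Sequence[TaggedPost], registry: TopAuthorRegistry
) -> tuple[list[TaggedPost], list[TaggedPost]]:
    """Split tagged posts into (top-author posts, everything else).

    The two lists partition the input: a post lands in the first exactly when
    its author is in the registry union.
    """
    union = registry.union
    top = [tp for tp in tagged if tp.post.author_id in union]
    other = [tp for tp in tagged if tp.post.author_id not in union]
    return top, other
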