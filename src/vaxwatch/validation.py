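"""Human-in-the-loop quality gates for the automated coding.

The workflow audits every automated keyword query against manually coded
posts: random samples drawn for manual coding (retweets optionally excluded,
since they duplicate their originals), a precision gate that approves a query
only when at least 90% of an audited sample is correctly labeled, simple
percent agreement between two coders, and per-theme top-engagement review
sets used when deriving misinformation categories.

Sampling uses numpy's PCG64 generator; the algorithm identifier and seed are
recorded on every sample so an audit is reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .corpus import Corpus, Post
from .errors import (
    AlignmentError,
    LookupError_,
    SampleSizeError,
    UndefinedDenominatorError,
)
from .themes import TaggedPost

__all__ = [
    "ValidationSample",
    "PrecisionReport",
    "draw_sample",
    "precision_gate",
    "intercoder_agreement",
    "top_engaged",
]

PRNG_ALGORITHM = "numpy-PCG64"

#: Approval threshold for automated queries: at least 90% correct.
DEFAULT_PRECISION_THRESHOLD = 0.90


@dataclass(frozen=True)
class ValidationSample:
    """A reproducible random sample of posts drawn for manual coding."""

    sample_posts: tuple[Post, ...]
    seed: int
    excluded_retweets: bool
    algorithm: str = PRNG_ALGORITHM

    def __post_init__(self):
        ids = [p.post_id for p in self.sample_posts]
        if len(ids) != len(set(ids)):
            raise SampleSizeError("sample contains duplicate posts")
        if self.excluded_retweets and any(p.is_retweet for p in self.sample_posts):
            raise SampleSizeError("retweet present in a retweet-excluded sample")

    def __len__(self):
        return len(self.sample_posts)

    def to_csv(self, path) -> None:
        """Export for manual coding: post_id, text, plus an empty label column."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["post_id", "text", "label"])
            for p in self.sample_posts:
                writer.writerow([p.post_id, p.text, ""])


@dataclass(frozen=True)
class PrecisionReport:
    """Outcome of auditing automated labels against manual coding."""

    n_checked: int
    n_correct: int
    threshold: float = DEFAULT_PRECISION_THRESHOLD
    strict: bool = False  # if true, require precision strictly above threshold

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_checked

    @property
    def passed(self) -> bool:
        if self.strict:
            return self.precision > self.threshold
        return self.precision >= self.threshold

    def to_dict(self) -> dict:
        return {
            "n_checked": self.n_checked,
            "n_correct": self.n_correct,
            "precision": self.precision,
            "threshold": self.threshold,
            "passed": self.passed,
        }


def draw_sample(
    corpus: Corpus | Sequence[Post],
    n: int,
    seed: int,
    exclude_retweets: bool = True,
) -> ValidationSample:
    """Uniform sample of ``n`` posts without replacement, reproducible by seed.

    Retweets are excluded from the eligible pool by default: manual coders
    concentrate on unique messages.
    """
    pool = [p for p in corpus if not (exclude_retweets and p.is_retweet)]
    if n > len(pool):
        raise SampleSizeError(
            f"requested sample of {n} exceeds eligible pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return ValidationSample(
        sample_posts=tuple(pool[i] for i in idx),
        seed=seed,
        excluded_retweets=exclude_retweets,
    )


def _as_label(value) -> Hashable:
    """Labels may be strings or collections; collections compare as sets."""
    if isinstance(value, (set, frozenset, list, tuple)):
        return frozenset(value)
    return value


def precision_gate(
    auto_labels: Mapping[str, object],
    manual_labels: Mapping[str, object],
    threshold: float = DEFAULT_PRECISION_THRESHOLD,
    strict: bool = False,
) -> PrecisionReport:
    """Precision of automated labels over the manually checked subset.

    ``manual_labels`` keys must be a subset of ``auto_labels`` keys; labels
    compare as exact (multi-label) sets.
    """
    if not manual_labels:
        raise UndefinedDenominatorError("no manually coded posts to check against")
    missing = set(manual_labels) - set(auto_labels)
    if missing:
        raise AlignmentError(
            f"manually coded post(s) absent from automated labels: {sorted(missing)[:5]}"
        )
    n_correct = sum(
        1
        for pid, manual in manual_labels.items()
        if _as_label(auto_labels[pid]) == _as_label(manual)
    )
    return PrecisionReport(
        n_checked=len(manual_labels),
        n_correct=n_correct,
        threshold=threshold,
        strict=strict,
    )


def intercoder_agreement(
    labels_a: Mapping[str, object], labels_b: Mapping[str, object]
) -> float:
    """Proportion of posts on which two coders assign identical label sets."""
    if not labels_a or not labels_b:
        raise UndefinedDenominatorError("agreement undefined over empty label maps")
    if set(labels_a) != set(labels_b):
        raise AlignmentError("coders labeled different post sets")
    agree = sum(
        1 for pid in labels_a if _as_label(labels_a[pid]) == _as_label(labels_b[pid])
    )
    return agree / len(labels_a)


def top_engaged(
    tagged: Iterable[TaggedPost], theme: str, n: int,
    known_themes: Optional[Iterable[str]] = None,
) -> list[Post]:
    """The ``n`` most-interacted posts of one theme, for manual review.

    Ordered by interactions descending with ties broken by post_id ascending;
    a theme with fewer than ``n`` posts returns all of them.
    """
    tagged = list(tagged)
    if known_themes is None:
        known_themes = set().union(*(tp.themes for tp in tagged)) if tagged else set()
    if theme not in set(known_themes):
        raise LookupError_(f"unknown theme {theme!r}")
    pool = [tp.post for tp in tagged if theme in tp.themes]
    pool.sort(key=lambda p: (-p.interactions, p.post_id))
    return pool[:n]
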