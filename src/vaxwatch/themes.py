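"""Opposition filtering and rule-based multi-label theme/misinformation tagging.

The coding pipeline mirrors a supervised-coding workflow: an opposition
keyword query isolates the opposition sub-corpus; each theme carries its own
keyword query and every post receives *every* theme whose query matches
(multi-label, so theme percentages can sum past 100%); misinformation
categories are nested under themes and a category tag is assigned only to
posts that already carry the parent theme.  Saturation (a candidate theme
covering under 1% of the conversation) is the stop rule for theme creation.

Retweets are tagged from their own text, which in practice duplicates the
original's, rather than by copying tags from the original record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .corpus import Corpus, Post
from .errors import ConfigError, UndefinedDenominatorError
from .query import CompiledQuery, QuerySpec, collect, compile_query, match, spec_from_mapping

__all__ = [
    "ThemeRule",
    "MisinfoRule",
    "TaggedPost",
    "filter_opposition",
    "tag_themes",
    "tag_misinformation",
    "saturation_check",
    "coverage",
    "theme_counts",
    "load_rulebook",
    "Rulebook",
]

#: Threshold under which a theme is considered saturated: strictly below 1%.
SATURATION_THRESHOLD = 0.01


@dataclass(frozen=True)
class ThemeRule:
    """One named theme with the keyword query that assigns it."""

    theme_name: str
    query: QuerySpec
    _compiled: CompiledQuery = field(init=False, compare=False, repr=False)

    def __post_init__(self):
        if not self.theme_name:
            raise ConfigError("theme_name must be nonempty")
        object.__setattr__(self, "_compiled", compile_query(self.query))

    @property
    def compiled(self) -> CompiledQuery:
        return self._compiled


@dataclass(frozen=True)
class MisinfoRule:
    """One misinformation category nested under a parent theme."""

    category_name: str
    parent_theme: str
    query: QuerySpec
    _compiled: CompiledQuery = field(init=False, compare=False, repr=False)

    def __post_init__(self):
        if not self.category_name:
            raise ConfigError("category_name must be nonempty")
        object.__setattr__(self, "_compiled", compile_query(self.query))

    @property
    def compiled(self) -> CompiledQuery:
        return self._compiled


@dataclass(frozen=True)
class TaggedPost:
    """A post with its opposition flag, theme set and misinfo category set.

    ``misinfo`` holds ``(parent_theme, category_name)`` pairs and only ever
    references themes the post carries; ``themes`` is nonempty only for
    opposition posts.
    """

    post: Post
    opposition: bool
    themes: frozenset[str] = frozenset()
    misinfo: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        if self.themes and not self.opposition:
            raise ConfigError(
                f"post {self.post.post_id!r}: themes assigned to a non-opposition post"
            )
        parents = {parent for parent, _ in self.misinfo}
        if not parents <= self.themes:
            raise ConfigError(
                f"post {self.post.post_id!r}: misinfo category under a theme the post "
                f"does not carry: {sorted(parents - self.themes)}"
            )


def _check_unique_themes(rules: Sequence[ThemeRule]) -> None:
    names = [r.theme_name for r in rules]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate theme_name(s): {dupes}")


def filter_opposition(corpus: Corpus, opposition_query: CompiledQuery) -> Corpus:
    """Sub-corpus of posts matching the opposition keyword query.

    All downstream analyses (themes, influencers, comparisons) run on this
    sub-corpus only.
    """
    return collect(corpus, opposition_query)


def tag_themes(corpus: Corpus, rules: Sequence[ThemeRule]) -> list[TaggedPost]:
    """Tag every post with every theme whose query matches (multi-label).

    Input is the opposition sub-corpus, so every output post has
    ``opposition=True``; posts matching no theme carry the empty set.
    Deterministic and order-independent: tags depend only on each post's text.
    """
    _check_unique_themes(rules)
    tagged = []
    for post in corpus:
        themes = frozenset(
            rule.theme_name for rule in rules if match(post, rule.compiled)
        )
        tagged.append(TaggedPost(post=post, opposition=True, themes=themes))
    return tagged


def tag_misinformation(
    tagged: Iterable[TaggedPost], rules: Sequence[MisinfoRule],
    theme_rules: Optional[Sequence[ThemeRule]] = None,
) -> list[TaggedPost]:
    """Assign misinformation categories, gated on the parent theme.

    A category is assigned only to posts that carry its parent theme *and*
    match its keyword query.  If ``theme_rules`` is given, every rule's parent
    theme must exist in it.
    """
    if theme_rules is not None:
        known = {r.theme_name for r in theme_rules}
        unknown = {r.parent_theme for r in rules} - known
        if unknown:
            raise ConfigError(f"misinfo rule(s) reference unknown theme(s): {sorted(unknown)}")
    out = []
    for tp in tagged:
        cats = frozenset(
            (rule.parent_theme, rule.category_name)
            for rule in rules
            if rule.parent_theme in tp.themes and match(tp.post, rule.compiled)
        )
        out.append(replace(tp, misinfo=cats))
    return out


def theme_counts(tagged: Iterable[TaggedPost]) -> dict[str, int]:
    """Posts per theme (a multi-label post counts once per theme it carries)."""
    counts: dict[str, int] = {}
    for tp in tagged:
        for theme in tp.themes:
            counts[theme] = counts.get(theme, 0) + 1
    return counts


def saturation_check(
    counts: Mapping[str, int], total_opposition: int,
    threshold: float = SATURATION_THRESHOLD,
) -> dict[str, bool]:
    """Flag themes covering strictly less than ``threshold`` of the conversation.

    A flagged (saturated) theme signals the stop rule for creating new themes;
    exactly 1% is *not* saturated.
    """
    if total_opposition <= 0:
        raise UndefinedDenominatorError("saturation undefined for empty conversation")
    return {
        theme: count / total_opposition < threshold for theme, count in counts.items()
    }


def coverage(tagged: Sequence[TaggedPost]) -> float:
    """Fraction of opposition posts carrying at least one theme."""
    if not tagged:
        raise UndefinedDenominatorError("coverage undefined for empty input")
    themed = sum(1 for tp in tagged if tp.themes)
    return themed / len(tagged)


# ---------------------------------------------------------------------------
# rulebook config


@dataclass(frozen=True)
class Rulebook:
    """Opposition query plus theme and misinformation rules, as one config."""

    opposition: QuerySpec
    theme_rules: tuple[ThemeRule, ...]
    misinfo_rules: tuple[MisinfoRule, ...]

    def __post_init__(self):
        _check_unique_themes(self.theme_rules)
        known = {r.theme_name for r in self.theme_rules}
        unknown = {r.parent_theme for r in self.misinfo_rules} - known
        if unknown:
            raise ConfigError(
                f"misinfo rule(s) reference unknown theme(s): {sorted(unknown)}"
            )

    def theme_names(self) -> list[str]:
        return [r.theme_name for r in self.theme_rules]

    def to_mapping(self) -> dict:
        def spec_map(spec: QuerySpec) -> dict:
            return {
                "standalone": sorted(spec.standalone_terms),
                "anchors": sorted(spec.concurrent_anchor_terms),
                "contexts": sorted(spec.concurrent_context_terms),
                "exclusions": sorted(spec.exclusion_terms),
                "auto_hashtag_variants": spec.auto_hashtag_variants,
            }

        return {
            "opposition": spec_map(self.opposition),
            "themes": [
                {"name": r.theme_name, **spec_map(r.query)} for r in self.theme_rules
            ],
            "misinfo": [
                {"name": r.category_name, "theme": r.parent_theme, **spec_map(r.query)}
                for r in self.misinfo_rules
            ],
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False, allow_unicode=True)


def rulebook_from_mapping(data: dict) -> Rulebook:
    if not isinstance(data, dict) or "opposition" not in data:
        raise ConfigError("rulebook must be a mapping with an 'opposition' section")
    opposition = spec_from_mapping(data["opposition"])
    themes = []
    for entry in data.get("themes", []):
        entry = dict(entry)
        name = entry.pop("name", None)
        if not name:
            raise ConfigError("theme rule missing 'name'")
        themes.append(ThemeRule(theme_name=name, query=spec_from_mapping(entry)))
    misinfo = []
    for entry in data.get("misinfo", []):
        entry = dict(entry)
        name = entry.pop("name", None)
        parent = entry.pop("theme", None)
        if not name or not parent:
            raise ConfigError("misinfo rule missing 'name' or 'theme'")
        misinfo.append(
            MisinfoRule(category_name=name, parent_theme=parent, query=spec_from_mapping(entry))
        )
    return Rulebook(opposition=opposition, theme_rules=tuple(themes), misinfo_rules=tuple(misinfo))


def load_rulebook(path) -> Rulebook:
    """Read the combined opposition/theme/misinfo rule config from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return rulebook_from_mapping(data)
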