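"""Boolean keyword-query dialect over tokenized post text.

The collection grammar has three positive-term roles and one veto role:

* **standalone** terms — a single occurrence collects the post;
* **concurrent** terms — an *anchor* term (an abbreviated vaccine form such as
  ``vax``) collects the post only together with a *context* term (a health
  condition or vaccine-discourse term);
* **exclusion** terms — a global NOT applied after any positive rule, used to
  drop veterinary/medication-instruction content.

A post matches iff::

    (any standalone present  OR  (any anchor present AND any context present))
    AND no exclusion term present

"Present" means the term's token sequence occurs contiguously in the
case-folded token stream, so ``vax`` never matches inside ``vaxxers``.  With
``auto_hashtag_variants`` each single-word term implies its ``#``-prefixed
hashtag form; variant expansion applies uniformly to all four roles.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .corpus import Corpus, Post
from .errors import ConfigError

__all__ = [
    "QuerySpec",
    "CompiledQuery",
    "tokenize",
    "compile_query",
    "match",
    "match_text",
    "collect",
    "load_query_spec",
]

# a '#' immediately followed by word characters forms a single hashtag token
_TOKEN_RE = re.compile(r"#\w+|\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Case-folded, NFC-normalized tokens in text order.

    Splits on non-word boundaries; ``#word`` is one hashtag token; empty text
    yields an empty list.
    """
    normalized = unicodedata.normalize("NFC", text).casefold()
    return _TOKEN_RE.findall(normalized)


def _normalize_term(term: str) -> str:
    return " ".join(tokenize(term))


class QuerySpec(BaseModel):
    """Declarative term lists for one boolean collection query.

    Terms are normalized (NFC, case-folded, tokenized and re-joined) on
    construction; duplicates collapse.  Positive-role terms must be disjoint
    from exclusion terms after normalization.
    """

    model_config = ConfigDict(frozen=True)

    standalone_terms: frozenset[str] = frozenset()
    concurrent_anchor_terms: frozenset[str] = frozenset()
    concurrent_context_terms: frozenset[str] = frozenset()
    exclusion_terms: frozenset[str] = frozenset()
    auto_hashtag_variants: bool = True

    @field_validator(
        "standalone_terms",
        "concurrent_anchor_terms",
        "concurrent_context_terms",
        "exclusion_terms",
        mode="before",
    )
    @classmethod
    def _normalize(cls, value):
        if isinstance(value, str):
            raise ValueError("term sets must be collections of strings, not one string")
        normalized = frozenset(_normalize_term(t) for t in value)
        if "" in normalized:
            raise ValueError("empty-string term (or term with no word characters)")
        return normalized

    @model_validator(mode="after")
    def _disjoint_from_exclusions(self):
        positive = (
            self.standalone_terms
            | self.concurrent_anchor_terms
            | self.concurrent_context_terms
        )
        overlap = positive & self.exclusion_terms
        if overlap:
            raise ValueError(
                f"terms present in both a positive role and the exclusion set: {sorted(overlap)}"
            )
        return self


def _expand(terms: frozenset[str], hashtags: bool) -> frozenset[tuple[str, ...]]:
    """Term strings -> token tuples, adding '#'-variants for single words."""
    out: set[tuple[str, ...]] = set()
    for term in terms:
        tokens = tuple(term.split(" "))
        out.add(tokens)
        if hashtags and len(tokens) == 1 and not tokens[0].startswith("#"):
            out.add(("#" + tokens[0],))
    return frozenset(out)


@dataclass(frozen=True)
class _Matcher:
    """Contiguous token-sequence matcher for one term role."""

    sequences: frozenset[tuple[str, ...]]
    _index: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        index: dict[str, list[tuple[str, ...]]] = {}
        for seq in self.sequences:
            index.setdefault(seq[0], []).append(seq)
        object.__setattr__(self, "_index", index)

    def present(self, tokens: list[str]) -> bool:
        index = self._index
        n = len(tokens)
        for i, tok in enumerate(tokens):
            for seq in index.get(tok, ()):
                k = len(seq)
                if k == 1 or (i + k <= n and tuple(tokens[i : i + k]) == seq):
                    return True
        return False


@dataclass(frozen=True)
class CompiledQuery:
    """Compiled matchers for the four term roles of a :class:`QuerySpec`."""

    standalone: _Matcher
    anchors: _Matcher
    contexts: _Matcher
    exclusions: _Matcher
    spec: QuerySpec

    def matches_tokens(self, tokens: list[str]) -> bool:
        positive = self.standalone.present(tokens) or (
            self.anchors.present(tokens) and self.contexts.present(tokens)
        )
        return positive and not self.exclusions.present(tokens)

    def term_inventory(self) -> dict[str, list[str]]:
        """Expanded (variant-including) term lists per role, for inspection."""
        return {
            role: sorted(" ".join(seq) for seq in matcher.sequences)
            for role, matcher in (
                ("standalone", self.standalone),
                ("concurrent_anchor", self.anchors),
                ("concurrent_context", self.contexts),
                ("exclusion", self.exclusions),
            )
        }


def compile_query(spec: QuerySpec) -> CompiledQuery:
    """Compile a spec into token-sequence matchers.

    Raises :class:`ConfigError` if concurrent context terms are given without
    any anchor terms (the pair rule would be unsatisfiable), and vice versa.
    """
    if spec.concurrent_context_terms and not spec.concurrent_anchor_terms:
        raise ConfigError("concurrent context terms given but anchor set is empty")
    if spec.concurrent_anchor_terms and not spec.concurrent_context_terms:
        raise ConfigError("concurrent anchor terms given but context set is empty")
    hashtags = spec.auto_hashtag_variants
    return CompiledQuery(
        standalone=_Matcher(_expand(spec.standalone_terms, hashtags)),
        anchors=_Matcher(_expand(spec.concurrent_anchor_terms, hashtags)),
        contexts=_Matcher(_expand(spec.concurrent_context_terms, hashtags)),
        exclusions=_Matcher(_expand(spec.exclusion_terms, hashtags)),
        spec=spec,
    )


def match_text(text: str, query: CompiledQuery) -> bool:
    return query.matches_tokens(tokenize(text))


def match(post: Post, query: CompiledQuery) -> bool:
    """True iff the post's text satisfies the boolean collection rule."""
    return match_text(post.text, query)


def collect(corpus: Corpus, query: CompiledQuery) -> Corpus:
    """Order-preserving sub-corpus of posts matching the query."""
    return corpus.subset(p for p in corpus if match(p, query))


_ROLE_KEYS = {
    "standalone": "standalone_terms",
    "standalone_terms": "standalone_terms",
    "anchors": "concurrent_anchor_terms",
    "concurrent_anchor_terms": "concurrent_anchor_terms",
    "contexts": "concurrent_context_terms",
    "concurrent_context_terms": "concurrent_context_terms",
    "exclusions": "exclusion_terms",
    "exclusion_terms": "exclusion_terms",
}


def spec_from_mapping(mapping: dict) -> QuerySpec:
    """Build a QuerySpec from a config mapping (short or long role names)."""
    kwargs: dict = {}
    for key, value in mapping.items():
        if key == "auto_hashtag_variants":
            kwargs[key] = bool(value)
        elif key in _ROLE_KEYS:
            kwargs[_ROLE_KEYS[key]] = value
        else:
            raise ConfigError(f"unknown query-spec key {key!r}")
    try:
        return QuerySpec(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_query_spec(path) -> QuerySpec:
    """Read one QuerySpec from a YAML file with one list per role."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of role -> term list")
    return spec_from_mapping(data)
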