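"""Boolean keyword-query semantics: tokenizing, matching, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_post
from naive_oracle import naive_match, naive_tokens
from vaxwatch.corpus import Corpus
from vaxwatch.errors import ConfigError
from vaxwatch.query import (
    QuerySpec,
    collect,
    compile_query,
    match,
    match_text,
    tokenize,
)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Vaccines CAUSE Harm", ["vaccines", "cause", "harm"]),
        ("#VaxInjury is real", ["#vaxinjury", "is", "real"]),
        ("", []),
        ("co-occur, right?", ["co", "occur", "right"]),
        ("niño VACUNA", ["niño", "vacuna"]),
        ("end#tag", ["end", "#tag"]),
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def _q(**kwargs):
    return compile_query(QuerySpec(**kwargs))


def test_standalone_single_mention_collects():
    q = _q(standalone_terms={"measles"})
    assert match_text("the measles outbreak continues", q)
    assert not match_text("nothing relevant here", q)


def test_hashtag_variant_expansion():
    q = _q(standalone_terms={"measles"})
    assert match_text("#measles outbreak", q)
    q_off = _q(standalone_terms={"measles"}, auto_hashtag_variants=False)
    assert not match_text("#measles outbreak", q_off)
    assert match_text("measles outbreak", q_off)


def test_concurrent_pair_requires_both():
    q = _q(
        concurrent_anchor_terms={"vax"},
        concurrent_context_terms={"measles", "autism"},
    )
    assert not match_text("the vax debate", q)
    assert not match_text("measles is spreading", q)
    assert match_text("the vax debate and measles", q)


def test_exclusion_vetoes_any_positive_match():
    q = _q(standalone_terms={"vaccine"}, exclusion_terms={"rabies"})
    assert match_text("vaccine mandates", q)
    assert not match_text("rabies vaccine for your dog", q)


def test_token_level_semantics_not_substring():
    q = _q(standalone_terms={"vax"})
    assert match_text("no vax for me", q)
    assert not match_text("the vaxxers are out", q)


def test_multiword_term_contiguous():
    q = _q(standalone_terms={"natural immunity"})
    assert match_text("I trust Natural Immunity more", q)
    assert not match_text("natural and strong immunity", q)
    # multi-word terms get no hashtag variant
    assert not match_text("#natural immunity", q)


def test_case_and_unicode_folding():
    # casefold equates ß with ss, beyond ASCII lowercasing
    q = _q(standalone_terms={"strasse"})
    assert match_text("die Straße ist lang", q)
    q2 = _q(standalone_terms={"impfgegner"})
    assert match_text("IMPFGEGNER unterwegs", q2)


def test_overlap_with_exclusions_is_config_error():
    with pytest.raises(ValueError):
        QuerySpec(standalone_terms={"vax"}, exclusion_terms={"vax"})


def test_context_without_anchor_is_config_error():
    with pytest.raises(ConfigError):
        compile_query(QuerySpec(concurrent_context_terms={"measles"}))
    with pytest.raises(ConfigError):
        compile_query(QuerySpec(concurrent_anchor_terms={"vax"}))


def test_empty_term_rejected():
    with pytest.raises(ValueError):
        QuerySpec(standalone_terms={""})
    with pytest.raises(ValueError):
        QuerySpec(standalone_terms={"?!"})


def test_compile_idempotent_and_duplicates_collapse():
    spec_a = QuerySpec(standalone_terms=["measles", "Measles", "MEASLES "])
    spec_b = QuerySpec(standalone_terms=["measles"])
    assert spec_a == spec_b
    texts = ["measles now", "#measles", "no match", "measly"]
    qa, qb = compile_query(spec_a), compile_query(spec_b)
    assert [match_text(t, qa) for t in texts] == [match_text(t, qb) for t in texts]


def test_collect_preserves_order_and_is_idempotent(small_corpus):
    q = _q(standalone_terms={"measles", "harm"})
    sub = collect(small_corpus, q)
    assert [p.post_id for p in sub] == ["p1", "p2", "p3"]
    assert collect(sub, q).posts == sub.posts


def test_collect_nothing(small_corpus):
    assert len(collect(small_corpus, _q(standalone_terms={"zebra"}))) == 0


# ---------------------------------------------------------------------------
# randomized oracle equivalence and monotonicity


_WORDS = [
    "vax", "vaxx", "jab", "measles", "mmr", "autism", "harm", "dose",
    "mandate", "school", "pharma", "natural", "detox", "flu", "shot",
    "rabies", "vet", "truth", "freedom", "risk",
]


def _random_instance(rng):
    def terms(max_n):
        n = rng.integers(0, max_n + 1)
        out = set()
        for _ in range(n):
            k = 1 if rng.random() < 0.8 else 2
            out.add(" ".join(rng.choice(_WORDS) for _ in range(k)))
        return out

    standalone = terms(6)
    anchors = terms(3)
    contexts = terms(4)
    if bool(anchors) != bool(contexts):
        anchors, contexts = set(), set()
    positive = standalone | anchors | contexts
    exclusions = {t for t in terms(3) if t not in positive}
    n_posts = int(rng.integers(1, 60))
    posts = []
    for i in range(n_posts):
        k = int(rng.integers(0, 9))
        words = [str(rng.choice(_WORDS)) for _ in range(k)]
        words = ["#" + w if rng.random() < 0.2 else w for w in words]
        posts.append(make_post(f"p{i}", "a", " ".join(words)))
    spec = QuerySpec(
        standalone_terms=standalone,
        concurrent_anchor_terms=anchors,
        concurrent_context_terms=contexts,
        exclusion_terms=exclusions,
    )
    return Corpus(tuple(posts)), spec


def _oracle_matches(corpus, spec):
    return [
        naive_match(
            p.text,
            spec.standalone_terms,
            spec.concurrent_anchor_terms,
            spec.concurrent_context_terms,
            spec.exclusion_terms,
            hashtags=spec.auto_hashtag_variants,
        )
        for p in corpus
    ]


def test_oracle_equivalence_random_instances():
    """Compiled matching equals naive token-scanning on random corpora/specs."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        corpus, spec = _random_instance(rng)
        q = compile_query(spec)
        assert [match(p, q) for p in corpus] == _oracle_matches(corpus, spec)


def test_exclusion_antitonicity_and_standalone_monotonicity():
    """Adding an exclusion term never grows, adding a standalone never
    shrinks, the matched set."""
    rng = np.random.default_rng(43)
    for _ in range(40):
        corpus, spec = _random_instance(rng)
        base = {p.post_id for p in collect(corpus, compile_query(spec))}
        extra = str(rng.choice(_WORDS))
        if extra not in spec.exclusion_terms:
            positive = (
                spec.standalone_terms
                | spec.concurrent_anchor_terms
                | spec.concurrent_context_terms
            )
            if extra not in positive:
                narrowed = spec.model_copy(
                    update={"exclusion_terms": spec.exclusion_terms | {extra}}
                )
                after = {p.post_id for p in collect(corpus, compile_query(narrowed))}
                assert after <= base
        if extra not in spec.exclusion_terms:
            widened = spec.model_copy(
                update={"standalone_terms": spec.standalone_terms | {extra}}
            )
            after = {p.post_id for p in collect(corpus, compile_query(widened))}
            assert after >= base


@settings(max_examples=60, deadline=None)
@given(st.text(max_size=60))
def test_match_case_invariance(text):
    q = _q(standalone_terms={"vax", "measles shot"}, exclusion_terms={"rabies"})
    assert match_text(text, q) == match_text(text.upper(), q)


@settings(max_examples=60, deadline=None)
@given(st.text(max_size=80))
def test_tokenize_agrees_with_naive_scanner(text):
    assert tokenize(text) == naive_tokens(text)
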