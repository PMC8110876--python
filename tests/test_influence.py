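"""Engagement accounting, monthly top-k ranking, impressions, partition."""

from datetime import datetime, timezone

import numpy as np
import pytest

from conftest import make_post
from vaxwatch.corpus import Corpus
from vaxwatch.errors import LinkageError
from vaxwatch.influence import (
    interaction_count,
    monthly_top_authors,
    partition_by_top_authors,
    potential_impressions,
    total_potential_impressions,
)
from vaxwatch.themes import TaggedPost


def _ts(month, day=10):
    return datetime(2019, month, day, tzinfo=timezone.utc)


def test_interaction_count_is_sum():
    assert interaction_count(make_post(likes=0, comments=0, shares=0)) == 0
    assert interaction_count(make_post(likes=3, comments=2, shares=5)) == 10


def test_corpus_total_interactions_matches_per_post_sum():
    rng = np.random.default_rng(1)
    posts = [
        make_post(
            f"p{i}", "a", "x",
            likes=int(rng.integers(0, 100)),
            comments=int(rng.integers(0, 100)),
            shares=int(rng.integers(0, 100)),
        )
        for i in range(200)
    ]
    total = sum(interaction_count(p) for p in posts)
    assert total == sum(p.likes + p.comments + p.shares for p in posts)


def test_short_pool_all_ranked_each_active_month():
    posts = [
        make_post("p1", "a", "x", timestamp=_ts(6), likes=5),
        make_post("p2", "b", "x", timestamp=_ts(6), likes=3),
        make_post("p3", "c", "x", timestamp=_ts(7), likes=1),
    ]
    reg = monthly_top_authors(Corpus(tuple(posts)), k=50)
    assert {s.author_id for s in reg.monthly[(2019, 6)]} == {"a", "b"}
    assert {s.author_id for s in reg.monthly[(2019, 7)]} == {"c"}
    assert reg.union == {"a", "b", "c"}


def test_dominant_author_tops_every_month():
    posts = []
    for month in range(6, 12):
        posts.append(
            make_post(f"d{month}", "dominant", "x", timestamp=_ts(month), likes=1000)
        )
        for j in range(3):
            posts.append(
                make_post(
                    f"p{month}{j}", f"minor{j}", "x", timestamp=_ts(month), likes=10
                )
            )
    reg = monthly_top_authors(Corpus(tuple(posts)), k=2)
    assert reg.months_as_top["dominant"] == 6
    for month in range(6, 12):
        assert reg.monthly[(2019, month)][0].author_id == "dominant"


def test_rank_tie_breaks_by_posts_then_author_id():
    posts = [
        make_post("p1", "bbb", "x", timestamp=_ts(6), likes=10),
        make_post("p2", "aaa", "x", timestamp=_ts(6), likes=5),
        make_post("p3", "aaa", "x", timestamp=_ts(6), likes=5),
        make_post("p4", "ccc", "x", timestamp=_ts(6), likes=10),
    ]
    reg = monthly_top_authors(Corpus(tuple(posts)), k=3)
    ranked = [s.author_id for s in reg.monthly[(2019, 6)]]
    # aaa: 10 interactions over 2 posts beats bbb/ccc (10 over 1) on n_posts
    assert ranked == ["aaa", "bbb", "ccc"]


def test_ranking_is_permutation_and_order_invariant():
    rng = np.random.default_rng(2)
    posts = [
        make_post(
            f"p{i}", f"a{int(rng.integers(0, 20))}", "x",
            timestamp=_ts(int(rng.integers(6, 12))),
            likes=int(rng.integers(0, 200)),
        )
        for i in range(300)
    ]
    reg1 = monthly_top_authors(Corpus(tuple(posts)), k=5)
    perm = rng.permutation(len(posts))
    reg2 = monthly_top_authors(Corpus(tuple(posts[i] for i in perm)), k=5)
    assert reg1.monthly == reg2.monthly
    for ranked in reg1.monthly.values():
        authors = [s.author_id for s in ranked]
        assert len(authors) == len(set(authors))
        assert [s.rank for s in ranked] == list(range(1, len(ranked) + 1))


def test_union_monotone_in_k():
    rng = np.random.default_rng(3)
    posts = [
        make_post(
            f"p{i}", f"a{int(rng.integers(0, 30))}", "x",
            timestamp=_ts(int(rng.integers(6, 12))),
            likes=int(rng.integers(0, 100)),
        )
        for i in range(200)
    ]
    corpus = Corpus(tuple(posts))
    previous = frozenset()
    for k in (1, 3, 10, 30):
        union = monthly_top_authors(corpus, k=k).union
        assert previous <= union
        previous = union


def test_deny_list_removes_authors_before_ranking():
    posts = [
        make_post("p1", "news", "x", timestamp=_ts(6), likes=1000),
        make_post("p2", "opp", "x", timestamp=_ts(6), likes=5),
    ]
    reg = monthly_top_authors(Corpus(tuple(posts)), k=1, deny_list={"news"})
    assert reg.union == {"opp"}


def test_potential_impressions():
    original = make_post("p1", "a", "x", author_followers=100)
    s1 = make_post("r1", "b", "x", is_retweet=True, retweet_of="p1", author_followers=10)
    s2 = make_post("r2", "c", "x", is_retweet=True, retweet_of="p1", author_followers=5)
    assert potential_impressions(original) == 100
    assert potential_impressions(original, [s1, s2]) == 115
    stray = make_post("r3", "d", "x", is_retweet=True, retweet_of="p9")
    with pytest.raises(LinkageError):
        potential_impressions(original, [stray])


def test_registry_level_impressions_equal_brute_force():
    rng = np.random.default_rng(4)
    posts = []
    for i in range(40):
        posts.append(
            make_post(
                f"p{i}", f"a{i % 5}", "x",
                timestamp=_ts(6),
                author_followers=int(rng.integers(0, 1000)),
            )
        )
    for j in range(30):
        posts.append(
            make_post(
                f"r{j}", f"a{j % 5}", "x",
                timestamp=_ts(7),
                is_retweet=True,
                retweet_of=f"p{int(rng.integers(0, 40))}",
                author_followers=int(rng.integers(0, 1000)),
            )
        )
    corpus = Corpus(tuple(posts))
    authors = {"a0", "a3"}
    by_id = corpus.by_id()
    brute = 0
    for p in corpus:
        if p.is_retweet or p.author_id not in authors:
            continue
        brute += p.author_followers + sum(
            q.author_followers for q in corpus if q.retweet_of == p.post_id
        )
    assert total_potential_impressions(corpus, authors) == brute


def _tagged(posts):
    return [TaggedPost(post=p, opposition=True) for p in posts]


def test_partition_law_and_empty_union():
    posts = [make_post(f"p{i}", f"a{i % 3}", "x", timestamp=_ts(6)) for i in range(9)]
    reg = monthly_top_authors(Corpus(tuple(posts)), k=1)
    top, other = partition_by_top_authors(_tagged(posts), reg)
    assert len(top) + len(other) == 9
    assert {tp.post.post_id for tp in top}.isdisjoint(
        tp.post.post_id for tp in other
    )
    empty_reg = monthly_top_authors(Corpus(()), k=5)
    top, other = partition_by_top_authors(_tagged(posts), empty_reg)
    assert top == [] and len(other) == 9


def test_top_k_union_matches_full_sort_oracle(sim_small):
    """Registry membership agrees with an independent full-sort per month."""
    _, corpus, truth, rulebook = sim_small
    from vaxwatch.query import compile_query
    from vaxwatch.themes import filter_opposition

    opp = filter_opposition(corpus, compile_query(rulebook.opposition))
    k = 10
    reg = monthly_top_authors(opp, k=k)
    oracle_union = set()
    months = {}
    for p in opp:
        months.setdefault((p.timestamp.year, p.timestamp.month), {}).setdefault(
            p.author_id, [0, 0]
        )
        months[(p.timestamp.year, p.timestamp.month)][p.author_id][0] += 1
        months[(p.timestamp.year, p.timestamp.month)][p.author_id][1] += (
            p.likes + p.comments + p.shares
        )
    for month, stats in months.items():
        ranked = sorted(
            stats.items(), key=lambda kv: (-kv[1][1], -kv[1][0], kv[0])
        )
        oracle_union.update(a for a, _ in ranked[:k])
    assert set(reg.union) == oracle_union
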