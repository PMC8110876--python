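from datetime import datetime, timezone

import pytest

from vaxwatch.corpus import Corpus, Post
from vaxwatch.simulate import SimConfig, emit_rulebook, generate


def make_post(
    post_id="p1",
    author_id="a1",
    text="hello world",
    timestamp=None,
    is_retweet=False,
    retweet_of=None,
    likes=0,
    comments=0,
    shares=0,
    author_followers=0,
):
    if timestamp is None:
        timestamp = datetime(2019, 7, 15, 12, 0, tzinfo=timezone.utc)
    return Post(
        post_id=post_id,
        author_id=author_id,
        text=text,
        timestamp=timestamp,
        is_retweet=is_retweet,
        retweet_of=retweet_of,
        likes=likes,
        comments=comments,
        shares=shares,
        author_followers=author_followers,
    )


@pytest.fixture
def post_factory():
    return make_post


@pytest.fixture
def small_corpus():
    posts = [
        make_post("p1", "alice", "vaccines cause harm they say"),
        make_post("p2", "bob", "#measles outbreak in the county", likes=3),
        make_post(
            "p3", "carol", "rt of the harm claim",
            is_retweet=True, retweet_of="p1", shares=1,
        ),
        make_post("p4", "alice", "lovely weather today", comments=2),
    ]
    return Corpus(tuple(posts))


@pytest.fixture(scope="session")
def sim_small():
    """A 3000-post synthetic corpus with rulebook, shared across tests."""
    config = SimConfig(n_posts=3000, n_authors=400, n_influencers=40, seed=7)
    corpus, truth = generate(config)
    return config, corpus, truth, emit_rulebook(config)
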