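"""Synthetic tweet-corpus generator with ground truth for every pipeline stage.

The generator emulates the statistical structure the surveillance analysis
assumes, so every downstream stage can be checked against planted truth:

* a six-month post stream (default window June–December 2019) with
  uniform-by-month timestamps;
* a small influencer subset authoring a majority share of opposition posts
  (default 129 accounts, 59.5% of opposition messages), with heavy-tailed
  per-influencer activity so the most prolific accounts dominate;
* heavy-tailed engagement (negative binomial counts, influencer posts
  receiving a large multiplier) and log-normal follower counts;
* retweet cascades: retweets copy the original's text, never precede it, and
  point at it via ``retweet_of``;
* multi-label theme keywords embedded in filler text per group-specific
  inclusion probabilities, with misinformation-category keywords nested under
  their parent theme;
* exclusion-term confounders (opposition vocabulary plus a veterinary term,
  so the boolean query must veto them) and near-miss vocabulary (tokens that
  merely contain a query term as a substring);
* an optional *noise mode* that plants a decoy token in non-opposition posts
  and adds it to the emitted rulebook, creating a known query precision below
  1 for exercising the validation gate.

``emit_rulebook`` returns keyword rules that exactly match the planted
vocabulary, so on clean posts classifier recall and precision are 1 by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .corpus import Corpus, DEFAULT_WINDOW, Post
from .errors import ConfigError
from .query import QuerySpec
from .themes import MisinfoRule, Rulebook, ThemeRule

__all__ = ["SimConfig", "GroundTruth", "generate", "emit_rulebook"]

# ---------------------------------------------------------------------------
# planted vocabulary
#
# All planted tokens are globally unique across roles so a keyword can only
# trigger the rule it was planted for.  Single words throughout, so hashtag
# variant expansion applies.

OPPOSITION_STANDALONE = (
    "vaccineinjury",
    "exvaxxer",
    "vaccinedamage",
    "learntherisk",
    "informedconsent",
)
OPPOSITION_ANCHORS = ("vax", "vaxx", "jab")
OPPOSITION_CONTEXTS = ("measles", "autism", "mmr", "hpv", "influenza")
EXCLUSION_TERMS = ("rabies", "heartworm", "veterinarian", "dosage")

#: Tokens that contain a query term as a substring but must never match
#: (word-level semantics: "vax" is not inside "vaxxers" at the token level).
NEAR_MISS_TOKENS = ("vaxxers", "jabber", "prevax", "mmrv")

#: Decoy token used by noise mode: planted only in non-opposition posts and
#: added to the noisy rulebook's standalone list.
NOISE_TOKEN = "wellnessjourney"

DEFAULT_THEME_VOCAB: dict[str, tuple[str, ...]] = {
    "health_effects": ("seizures", "paralysis", "vaccinereaction"),
    "pharma_industry": ("bigpharma", "merck", "gardasil"),
    "research_trials": ("retractedstudy", "pseudoscience", "cdcwhistleblower"),
    "policy": ("sb276", "mandates", "exemptionbill"),
    "ingredients": ("aluminum", "thimerosal", "adjuvants"),
    "family": ("parentalrights", "mychildmychoice"),
    "outbreaks": ("outbreakscare", "poliovirus"),
    "school": ("schoolentry", "noshotsnoschool"),
    "religion": ("religiousexemption", "faithexemption"),
    "natural_alternatives": ("homeopathy", "vaccinedetox"),
}

DEFAULT_MISINFO_VOCAB: dict[str, dict[str, tuple[str, ...]]] = {
    "health_effects": {
        "vaccine_deaths": ("vaersdeaths",),
        "autism_claims": ("autismcoverup",),
    },
    "pharma_industry": {"gardasil_lawsuits": ("gardasillawsuit",)},
    "ingredients": {
        "aluminum_toxicity": ("aluminumpoisoning",),
        "mercury_toxicity": ("mercurypoisoning",),
    },
}

#: Group-specific multi-label theme inclusion probabilities.  The defaults
#: follow the proportion structure of a real vaccine-opposition conversation:
#: one dominant health-effects theme, a mid tier around 14–19%, and a tail
#: under 5%, with the two groups differing most on research and ingredients.
DEFAULT_THEME_MIX_TOP: dict[str, float] = {
    "health_effects": 0.554,
    "pharma_industry": 0.169,
    "research_trials": 0.155,
    "policy": 0.150,
    "ingredients": 0.138,
    "family": 0.073,
    "outbreaks": 0.051,
    "school": 0.036,
    "religion": 0.032,
    "natural_alternatives": 0.009,
}
DEFAULT_THEME_MIX_OTHER: dict[str, float] = {
    "health_effects": 0.492,
    "pharma_industry": 0.189,
    "research_trials": 0.056,
    "policy": 0.177,
    "ingredients": 0.172,
    "family": 0.074,
    "outbreaks": 0.032,
    "school": 0.028,
    "religion": 0.023,
    "natural_alternatives": 0.016,
}

DEFAULT_MISINFO_MIX: dict[str, dict[str, float]] = {
    "health_effects": {"vaccine_deaths": 0.35, "autism_claims": 0.30},
    "pharma_industry": {"gardasil_lawsuits": 0.40},
    "ingredients": {"aluminum_toxicity": 0.30, "mercury_toxicity": 0.25},
}

FILLER_PHRASES = (
    "just catching up on the timeline this morning",
    "thinking a lot about this lately",
    "saw this on the news and had to share",
    "long thread incoming please read",
    "can everyone please pay attention to this",
    "another day another story",
    "this deserves way more attention",
    "sharing for anyone who missed it",
    "quiet afternoon so here are some thoughts",
    "what a week it has been",
    "posting this again because it matters",
    "friends please take a minute to read",
)

NEUTRAL_EXTRAS = (
    "weather is lovely today",
    "coffee first then everything else",
    "weekend plans are coming together",
    "traffic was unbelievable downtown",
    "new recipe turned out great",
    "the game last night was wild",
)


class SimConfig(BaseModel):
    """Parameters of the synthetic corpus; defaults are the study conditions.

    ``influencer_share`` is the target fraction of opposition posts authored
    by influencer accounts; ``theme_mix_*`` are per-theme multi-label
    inclusion probabilities (they need not sum to 1).  ``theme_coverage``, if
    set, fixes the probability that an opposition post carries at least one
    theme (themes then drawn conditional on nonempty).  ``rule_noise_rate``
    m > 0 plants the decoy token in non-opposition posts at a rate chosen so
    the noisy query's precision is about 1 - m.
    """

    model_config = ConfigDict(frozen=True)

    n_posts: int = Field(default=20_000, ge=0)
    n_authors: int = Field(default=2_000, ge=1)
    n_influencers: int = Field(default=129, ge=0)
    influencer_share: float = Field(default=0.595, ge=0.0, le=1.0)
    opposition_rate: float = Field(default=0.6, ge=0.0, le=1.0)
    theme_mix_top: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_THEME_MIX_TOP)
    )
    theme_mix_other: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_THEME_MIX_OTHER)
    )
    misinfo_mix: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MISINFO_MIX.items()}
    )
    theme_coverage: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    retweet_prob: float = Field(default=0.25, ge=0.0, lt=1.0)
    engagement_mean: float = Field(default=5.0, gt=0.0)
    engagement_dispersion: float = Field(default=0.35, gt=0.0)
    influencer_engagement_multiplier: float = Field(default=40.0, ge=1.0)
    retweet_engagement_factor: float = Field(default=0.15, gt=0.0)
    follower_scale: float = Field(default=200.0, gt=0.0)
    follower_sigma: float = Field(default=1.6, gt=0.0)
    influencer_follower_multiplier: float = Field(default=50.0, ge=1.0)
    influencer_activity_exponent: float = Field(default=1.5, ge=0.0)
    concurrent_marker_prob: float = Field(default=0.30, ge=0.0, le=1.0)
    hashtag_marker_prob: float = Field(default=0.25, ge=0.0, le=1.0)
    confounder_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    near_miss_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    rule_noise_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    window_start: datetime = DEFAULT_WINDOW[0]
    window_end: datetime = DEFAULT_WINDOW[1]
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        if self.n_influencers > self.n_authors:
            raise ValueError("n_influencers cannot exceed n_authors")
        if self.influencer_share > 0 and self.n_influencers == 0:
            raise ValueError("influencer_share > 0 requires n_influencers > 0")
        if self.influencer_share < 1 and self.n_influencers == self.n_authors:
            raise ValueError(
                "influencer_share < 1 requires at least one non-influencer author"
            )
        ws, we = self.window_start, self.window_end
        if ws.tzinfo is None:
            object.__setattr__(self, "window_start", ws.replace(tzinfo=timezone.utc))
        if we.tzinfo is None:
            object.__setattr__(self, "window_end", we.replace(tzinfo=timezone.utc))
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        known = set(DEFAULT_THEME_VOCAB)
        for name, mix in (("theme_mix_top", self.theme_mix_top),
                          ("theme_mix_other", self.theme_mix_other)):
            for theme, p in mix.items():
                if theme not in known:
                    raise ValueError(f"{name}: unknown theme {theme!r}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{theme!r}] must be in [0, 1]")
        if set(self.theme_mix_top) != set(self.theme_mix_other):
            raise ValueError("theme_mix_top and theme_mix_other must share themes")
        for theme, cats in self.misinfo_mix.items():
            if theme not in self.theme_mix_top:
                raise ValueError(f"misinfo_mix: theme {theme!r} not in theme mix")
            for cat, p in cats.items():
                if cat not in DEFAULT_MISINFO_VOCAB.get(theme, {}):
                    raise ValueError(
                        f"misinfo_mix: unknown category {cat!r} under {theme!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"misinfo_mix[{theme!r}][{cat!r}] not in [0, 1]")
        return self

    def themes(self) -> list[str]:
        return list(self.theme_mix_top)


@dataclass(frozen=True)
class GroundTruthRecord:
    opposition: bool
    themes: frozenset[str]
    misinfo: frozenset[tuple[str, str]]
    author_is_influencer: bool


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for every emitted post, keyed by post_id."""

    records: dict[str, GroundTruthRecord]
    influencers: frozenset[str]
    config: SimConfig

    def opposition_ids(self) -> list[str]:
        return [pid for pid, r in self.records.items() if r.opposition]

    def opposition_share(self) -> float:
        return sum(r.opposition for r in self.records.values()) / len(self.records)

    def influencer_share_of_opposition(self) -> float:
        """Fraction of opposition posts authored by influencer accounts."""
        opp = [r for r in self.records.values() if r.opposition]
        return sum(r.author_is_influencer for r in opp) / len(opp)

    def theme_shares(self, group: Optional[str] = None) -> dict[str, float]:
        """Planted per-theme proportions among opposition posts.

        ``group`` restricts to influencer-authored ('top') or other ('other')
        opposition posts.
        """
        opp = [r for r in self.records.values() if r.opposition]
        if group == "top":
            opp = [r for r in opp if r.author_is_influencer]
        elif group == "other":
            opp = [r for r in opp if not r.author_is_influencer]
        elif group is not None:
            raise ValueError("group must be 'top', 'other' or None")
        counts: dict[str, int] = {t: 0 for t in self.config.themes()}
        for r in opp:
            for t in r.themes:
                counts[t] += 1
        n = len(opp)
        return {t: c / n for t, c in counts.items()} if n else {t: 0.0 for t in counts}

    def to_jsonl(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for pid, r in self.records.items():
                fh.write(
                    json.dumps(
                        {
                            "post_id": pid,
                            "opposition": r.opposition,
                            "themes": sorted(r.themes),
                            "misinfo": sorted(map(list, r.misinfo)),
                            "author_is_influencer": r.author_is_influencer,
                        }
                    )
                )
                fh.write("\n")


def _month_segments(start: datetime, end: datetime) -> list[tuple[datetime, datetime]]:
    """Calendar-month segments covering [start, end), clipped to the window."""
    segments = []
    cursor = start
    while cursor < end:
        if cursor.month == 12:
            nxt = cursor.replace(year=cursor.year + 1, month=1, day=1,
                                 hour=0, minute=0, second=0, microsecond=0)
        else:
            nxt = cursor.replace(month=cursor.month + 1, day=1,
                                 hour=0, minute=0, second=0, microsecond=0)
        segments.append((cursor, min(nxt, end)))
        cursor = nxt
    return segments


def _draw_timestamps(rng, n: int, segments) -> list[datetime]:
    """Uniform-by-month: month chosen uniformly, time uniform within it."""
    out = []
    for _ in range(n):
        seg_start, seg_end = segments[rng.integers(len(segments))]
        span = int((seg_end - seg_start).total_seconds())
        # whole seconds so serialized timestamps round-trip exactly
        out.append(seg_start + timedelta(seconds=int(rng.integers(0, max(1, span)))))
    return out


def _neg_binomial(rng, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


class _Author:
    __slots__ = ("author_id", "is_influencer", "followers")

    def __init__(self, author_id, is_influencer, followers):
        self.author_id = author_id
        self.is_influencer = is_influencer
        self.followers = followers


def generate(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a synthetic corpus and its planted ground truth.

    Deterministic for a given config (all randomness flows from
    ``config.seed`` through one PCG64 generator).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # -- authors: influencers first, heavy-tailed activity weights among them
    authors: list[_Author] = []
    for i in range(cfg.n_authors):
        is_inf = i < cfg.n_influencers
        followers = float(
            rng.lognormal(mean=np.log(cfg.follower_scale), sigma=cfg.follower_sigma)
        )
        if is_inf:
            followers *= cfg.influencer_follower_multiplier
        authors.append(_Author(f"a{i + 1:05d}", is_inf, max(1, int(followers))))
    influencers = authors[: cfg.n_influencers]
    others = authors[cfg.n_influencers:]
    if influencers:
        w = np.arange(1, len(influencers) + 1, dtype=float) ** (
            -cfg.influencer_activity_exponent
        )
        influencer_weights = w / w.sum()
    else:
        influencer_weights = np.array([])

    themes = cfg.themes()
    mix_top = np.array([cfg.theme_mix_top[t] for t in themes])
    mix_other = np.array([cfg.theme_mix_other[t] for t in themes])
    # rate of decoy-token injection among non-opposition posts such that the
    # matched set is ~ (1 - m) opposition
    if cfg.rule_noise_rate > 0 and cfg.opposition_rate < 1:
        m, r = cfg.rule_noise_rate, cfg.opposition_rate
        noise_inject_rate = min(1.0, (m / (1 - m)) * (r / (1 - r)))
    else:
        noise_inject_rate = 0.0

    n_retweets = int(round(cfg.n_posts * cfg.retweet_prob))
    n_orig = cfg.n_posts - n_retweets
    if n_retweets > 0 and n_orig == 0:
        raise ConfigError("retweets require at least one original post")

    segments = _month_segments(cfg.window_start, cfg.window_end)
    timestamps = sorted(_draw_timestamps(rng, n_orig, segments))

    def pick_author(opposition: bool) -> _Author:
        if opposition and influencers and rng.random() < cfg.influencer_share:
            return influencers[rng.choice(len(influencers), p=influencer_weights)]
        pool = others if others else authors
        return pool[rng.integers(len(pool))]

    def draw_themes(is_influencer: bool) -> frozenset[str]:
        mix = mix_top if is_influencer else mix_other
        if cfg.theme_coverage is not None:
            if rng.random() >= cfg.theme_coverage:
                return frozenset()
            for _ in range(1000):  # conditional-on-nonempty rejection draw
                mask = rng.random(len(themes)) < mix
                if mask.any():
                    return frozenset(t for t, m in zip(themes, mask) if m)
            return frozenset({themes[int(np.argmax(mix))]})
        mask = rng.random(len(themes)) < mix
        return frozenset(t for t, m in zip(themes, mask) if m)

    def draw_misinfo(post_themes: frozenset[str]) -> frozenset[tuple[str, str]]:
        out = set()
        for theme in themes:  # fixed iteration order for determinism
            if theme in post_themes:
                for cat, p in cfg.misinfo_mix.get(theme, {}).items():
                    if rng.random() < p:
                        out.add((theme, cat))
        return frozenset(out)

    def opposition_marker() -> list[str]:
        if rng.random() < cfg.concurrent_marker_prob:
            anchor = OPPOSITION_ANCHORS[rng.integers(len(OPPOSITION_ANCHORS))]
            context = OPPOSITION_CONTEXTS[rng.integers(len(OPPOSITION_CONTEXTS))]
            return [anchor, context]
        term = OPPOSITION_STANDALONE[rng.integers(len(OPPOSITION_STANDALONE))]
        if rng.random() < cfg.hashtag_marker_prob:
            term = "#" + term
        return [term]

    def compose(parts: list[str]) -> str:
        order = rng.permutation(len(parts))
        return " ".join(parts[i] for i in order)

    posts: list[Post] = []
    truth: dict[str, GroundTruthRecord] = {}

    def engagement(author: _Author, retweet: bool) -> tuple[int, int, int]:
        mean = cfg.engagement_mean
        if author.is_influencer:
            mean *= cfg.influencer_engagement_multiplier
        if retweet:
            mean *= cfg.retweet_engagement_factor
        likes = _neg_binomial(rng, mean, cfg.engagement_dispersion)
        comments = _neg_binomial(rng, mean * 0.25, cfg.engagement_dispersion)
        shares = _neg_binomial(rng, mean * 0.35, cfg.engagement_dispersion)
        return likes, comments, shares

    originals: list[tuple[Post, GroundTruthRecord]] = []
    for i, ts in enumerate(timestamps):
        opposition = bool(rng.random() < cfg.opposition_rate)
        author = pick_author(opposition)
        parts = [FILLER_PHRASES[rng.integers(len(FILLER_PHRASES))]]
        post_themes: frozenset[str] = frozenset()
        post_misinfo: frozenset[tuple[str, str]] = frozenset()
        if opposition:
            parts.extend(opposition_marker())
            post_themes = draw_themes(author.is_influencer)
            for theme in themes:
                if theme in post_themes:
                    vocab = DEFAULT_THEME_VOCAB[theme]
                    parts.append(vocab[rng.integers(len(vocab))])
            post_misinfo = draw_misinfo(post_themes)
            for theme, cat in sorted(post_misinfo):
                vocab = DEFAULT_MISINFO_VOCAB[theme][cat]
                parts.append(vocab[rng.integers(len(vocab))])
        else:
            if rng.random() < cfg.confounder_rate:
                parts.extend(opposition_marker())
                parts.append(EXCLUSION_TERMS[rng.integers(len(EXCLUSION_TERMS))])
            if rng.random() < cfg.near_miss_rate:
                parts.append(NEAR_MISS_TOKENS[rng.integers(len(NEAR_MISS_TOKENS))])
            if noise_inject_rate and rng.random() < noise_inject_rate:
                parts.append(NOISE_TOKEN)
            else:
                parts.append(NEUTRAL_EXTRAS[rng.integers(len(NEUTRAL_EXTRAS))])
        likes, comments, shares = engagement(author, retweet=False)
        post = Post(
            post_id=f"p{i + 1:06d}",
            author_id=author.author_id,
            text=compose(parts),
            timestamp=ts,
            likes=likes,
            comments=comments,
            shares=shares,
            author_followers=author.followers,
        )
        record = GroundTruthRecord(
            opposition=opposition,
            themes=post_themes,
            misinfo=post_misinfo,
            author_is_influencer=author.is_influencer,
        )
        originals.append((post, record))

    posts.extend(p for p, _ in originals)
    truth.update({p.post_id: r for p, r in originals})

    for j in range(n_retweets):
        orig, orig_record = originals[int(rng.integers(len(originals)))]
        remaining = int((cfg.window_end - orig.timestamp).total_seconds())
        ts = orig.timestamp + timedelta(
            seconds=int(rng.integers(0, max(1, remaining)))
        )
        if ts >= cfg.window_end:
            ts = cfg.window_end - timedelta(seconds=1)
        author = pick_author(orig_record.opposition)
        likes, comments, shares = engagement(author, retweet=True)
        post = Post(
            post_id=f"r{j + 1:06d}",
            author_id=author.author_id,
            text=orig.text,
            timestamp=ts,
            is_retweet=True,
            retweet_of=orig.post_id,
            likes=likes,
            comments=comments,
            shares=shares,
            author_followers=author.followers,
        )
        posts.append(post)
        truth[post.post_id] = GroundTruthRecord(
            opposition=orig_record.opposition,
            themes=orig_record.themes,
            misinfo=orig_record.misinfo,
            author_is_influencer=author.is_influencer,
        )

    posts.sort(key=lambda p: (p.timestamp, p.post_id))
    truth = {p.post_id: truth[p.post_id] for p in posts}
    corpus = Corpus(tuple(posts), cfg.window_start, cfg.window_end)
    return corpus, GroundTruth(
        records=truth,
        influencers=frozenset(a.author_id for a in influencers),
        config=cfg,
    )


def emit_rulebook(config: SimConfig) -> Rulebook:
    """Keyword rules matching the planted vocabulary exactly.

    In noise mode (``rule_noise_rate`` > 0) the opposition query additionally
    lists the decoy token, creating a known precision shortfall.
    """
    standalone = set(OPPOSITION_STANDALONE)
    if config.rule_noise_rate > 0:
        standalone.add(NOISE_TOKEN)
    opposition = QuerySpec(
        standalone_terms=standalone,
        concurrent_anchor_terms=set(OPPOSITION_ANCHORS),
        concurrent_context_terms=set(OPPOSITION_CONTEXTS),
        exclusion_terms=set(EXCLUSION_TERMS),
    )
    theme_rules = tuple(
        ThemeRule(
            theme_name=theme,
            query=QuerySpec(standalone_terms=set(DEFAULT_THEME_VOCAB[theme])),
        )
        for theme in config.themes()
    )
    misinfo_rules = tuple(
        MisinfoRule(
            category_name=cat,
            parent_theme=theme,
            query=QuerySpec(standalone_terms=set(DEFAULT_MISINFO_VOCAB[theme][cat])),
        )
        for theme in config.themes()
        for cat in config.misinfo_mix.get(theme, {})
    )
    return Rulebook(
        opposition=opposition, theme_rules=theme_rules, misinfo_rules=misinfo_rules
    )
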