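"""Seeded synthetic post-corpus generator with a ground-truth ledger.

The generator emulates every statistical structure the surveillance pipeline
assumes, with known planted values: flavor keywords drawn from a configured
category distribution (optionally drifting linearly over months), promotional
posts recognisable by vendor-style handles or marketing vocabulary,
ambiguous-keyword posts using flavor names in non-flavor senses (with an
engineered per-keyword precision), off-topic posts that carry no e-cigarette
vocabulary at all, a configurable share of multi-flavor posts, and per-category
positive/neutral/negative sentiment mixes realised as phrases from the
deterministic lexicon in :mod:`flavorwatch.sentiment`, so the bundled stub
scorer recovers every planted valence exactly.

Every post appears exactly once in the ledger, which records the planted
keyword(s), taxonomy path, promotion status, relevance label for ambiguous
keywords, valence and month — the oracle for recovery tests. Generation is
fully reproducible from the seed through a single named RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import MonthKey, Post, month_range, write_posts
from .sentiment import PHRASE_VALENCE, classify_score
from .taxonomy import CATEGORIES, FlavorTaxonomy, bundled_taxonomy

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate", "labels_from_ledger"]

#: Planted share of flavor mentions per category: the surveillance conditions
#: the pipeline is validated under (fruit-dominant, sweets second, mixed rare).
DEFAULT_CATEGORY_DISTRIBUTION: Mapping[str, float] = {
    "fruit": 0.58,
    "sweets": 0.15,
    "beverage": 0.10,
    "menthol_or_mint": 0.08,
    "tobacco": 0.06,
    "others": 0.02,
    "mixed": 0.01,
}

#: Planted (positive, neutral, negative) post shares per category: the
#: candy-adjacent categories lean positive, tobacco and beverage negative,
#: the sparse categories are balanced.
DEFAULT_SENTIMENT_MIX: Mapping[str, tuple[float, float, float]] = {
    "fruit": (0.55, 0.25, 0.20),
    "sweets": (0.60, 0.20, 0.20),
    "beverage": (0.20, 0.30, 0.50),
    "tobacco": (0.20, 0.25, 0.55),
    "menthol_or_mint": (0.50, 0.30, 0.20),
    "mixed": (0.34, 0.33, 0.33),
    "others": (0.34, 0.33, 0.33),
}

#: Ambiguous flavor names planted in non-flavor senses, with the flavor-sense
#: probability (the engineered precision of the keyword) and the taxonomy
#: path their flavor sense belongs to. Both defaults sit below the 0.90
#: precision bar, matching how such names fare in labeled samples.
DEFAULT_NOISY_KEYWORDS: Mapping[str, float] = {"punch": 0.60, "contact": 0.65}

AMBIGUOUS_KEYWORD_PATHS: Mapping[str, tuple[str, str]] = {
    "punch": ("fruit", "others"),
    "contact": ("others", "others"),
}

_TOPIC_NOUNS = ("vape", "juul", "ecig", "e-cig")
_TOPIC_TAGS = ("vaping", "vapenation", "vapefam", "vapeon")

_NORMAL_TEMPLATES = (
    "Just refilled my {topic} with {kw} e-liquid. {phrase}.",
    "{phrase} — been running {kw} in the {topic} all week.",
    "Day three on the {kw} pods for my {topic}. {phrase}.",
    "Picked a bottle of {kw} for the {topic}. {phrase}.",
)
_HASHTAG_TEMPLATE = "Cloudy morning. #{tag} #{kw} — {phrase}."
_MULTI_TEMPLATE = "Mixing {kw} with {kw2} in the {topic} today. {phrase}."

_OFFTOPIC_TEMPLATES = (
    "Match got rained out again, maybe next weekend.",
    "Spent Saturday at the grapevine festival with family.",
    "New running shoes finally came in, legs are ready.",
)

_PROMO_HANDLE_PARTS = (
    ("Best", "Cloud", "Prime", "Mega"),
    ("Vape", "Ecig", "Juice"),
    ("Store", "Deals", "Supply"),
)
_PROMO_BODY_TEMPLATE = (
    "Big sale this week: 20% discount on {kw} e-liquid pods, free shipping over $30."
)
_PROMO_CLEAN_BODY_TEMPLATE = "New {kw} flavor just landed in our vape lineup, link in bio."

_NOISY_TEMPLATES: Mapping[str, Mapping[bool, str]] = {
    "punch": {
        True: "My {topic} tank is full of fruit punch today. {phrase}.",
        False: "Nearly wanted to punch the wall when my {topic} died mid-session. {phrase}.",
    },
    "contact": {
        True: "Finally tried the contact e-liquid everyone mentions on here. {phrase}.",
        False: "DM me for contact info about the local {topic} meetup. {phrase}.",
    },
}

_PHRASES_BY_LABEL: dict[str, tuple[str, ...]] = {"positive": (), "neutral": (), "negative": ()}
for _phrase, _valence in PHRASE_VALENCE.items():
    _PHRASES_BY_LABEL[classify_score(_valence)] += (_phrase,)


def _validate_probs(probs: Sequence[float], what: str) -> None:
    if any(p < 0 for p in probs):
        raise ValueError(f"{what}: probabilities must be non-negative")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"{what}: probabilities must sum to 1 (got {sum(probs)})")


@dataclass(frozen=True)
class GeneratorConfig:
    """All planted parameters of a synthetic corpus.

    ``monthly_trend`` maps categories to a relative linear drift over the
    date range: a category with slope s has its weight scaled by
    ``1 + s*(t - 1/2)`` for t running 0 -> 1 across the months (then
    renormalized within each month); None means stationary shares.
    ``noisy_keywords`` maps each planted ambiguous keyword to its flavor-sense
    probability, which is realised with exact counts so the keyword's sample
    precision equals it up to rounding.
    """

    seed: int
    n_posts: int = 20000
    date_range: tuple[str, str] = ("2013-01", "2019-04")
    platform: str = "reddit"
    category_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_DISTRIBUTION)
    )
    monthly_trend: Mapping[str, float] | None = None
    promo_fraction: float = 0.0
    noisy_keyword_fraction: float = 0.02
    offtopic_fraction: float = 0.05
    multi_flavor_fraction: float = 0.05
    sentiment_mix: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENTIMENT_MIX)
    )
    noisy_keywords: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISY_KEYWORDS)
    )

    def __post_init__(self) -> None:
        if self.n_posts < 0:
            raise ValueError("n_posts must be non-negative")
        _validate_probs(list(self.category_distribution.values()), "category_distribution")
        for cat, mix in self.sentiment_mix.items():
            _validate_probs(list(mix), f"sentiment_mix[{cat}]")
        for name in ("promo_fraction", "noisy_keyword_fraction", "offtopic_fraction",
                     "multi_flavor_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for kw, p in self.noisy_keywords.items():
            if kw not in AMBIGUOUS_KEYWORD_PATHS:
                raise ValueError(f"no ambiguity templates for noisy keyword {kw!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"noisy keyword precision for {kw!r} must be in [0, 1]")

    @classmethod
    def reddit_default(cls, seed: int, n_posts: int = 20000, **overrides) -> "GeneratorConfig":
        """Reddit-style longitudinal corpus: long date range, no promo posts,
        a mild upward fruit drift."""
        base = cls(
            seed=seed,
            n_posts=n_posts,
            date_range=("2013-01", "2019-04"),
            platform="reddit",
            promo_fraction=0.0,
            monthly_trend={"fruit": 0.2, "sweets": -0.2},
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def twitter_default(cls, seed: int, n_posts: int = 20000, **overrides) -> "GeneratorConfig":
        """Twitter-style snapshot corpus: short date range, promo posts on."""
        base = cls(
            seed=seed,
            n_posts=n_posts,
            date_range=("2019-05", "2019-08"),
            platform="twitter",
            promo_fraction=0.15,
        )
        return replace(base, **overrides) if overrides else base


@dataclass
class SyntheticCorpus:
    """Generated posts plus their ground truth.

    ``taxonomy`` is the bundled classification augmented with the planted
    ambiguous keywords (the shipped fixture itself is never modified).
    """

    posts: list[Post]
    ledger: pd.DataFrame
    taxonomy: FlavorTaxonomy
    config: GeneratorConfig

    def write(self, corpus_path: str | Path, ledger_path: str | Path | None = None) -> None:
        write_posts(self.posts, corpus_path)
        if ledger_path is not None:
            self.ledger.to_csv(ledger_path, index=False)


def _month_category_weights(
    config: GeneratorConfig, months: Sequence[MonthKey]
) -> np.ndarray:
    """(n_months, n_categories) row-stochastic planted category weights."""
    cats = list(config.category_distribution)
    base = np.array([config.category_distribution[c] for c in cats], dtype=float)
    weights = np.tile(base, (len(months), 1))
    if config.monthly_trend:
        t = np.linspace(0.0, 1.0, len(months)) if len(months) > 1 else np.array([0.5])
        for j, cat in enumerate(cats):
            slope = config.monthly_trend.get(cat, 0.0)
            weights[:, j] = base[j] * np.clip(1.0 + slope * (t - 0.5), 0.0, None)
    return weights / weights.sum(axis=1, keepdims=True)


def generate(config: GeneratorConfig, tax: FlavorTaxonomy | None = None) -> SyntheticCorpus:
    """Generate a corpus and its ground-truth ledger from a config.

    Deterministic given the seed: calling twice with the same config yields
    byte-identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    if tax is None:
        tax = bundled_taxonomy()
    for kw in config.noisy_keywords:
        if kw not in tax:
            cat, sub = AMBIGUOUS_KEYWORD_PATHS[kw]
            tax = tax.with_keyword(cat, sub, kw)

    n = config.n_posts
    months = [
        MonthKey.parse(m) if isinstance(m, str) else m
        for m in month_range(config.date_range[0], config.date_range[1])
    ]
    cats = list(config.category_distribution)
    month_weights = _month_category_weights(config, months)

    # Role plan: exact counts per role, shuffled; engineered fractions stay
    # exact so keyword precisions and funnel counts are predictable.
    n_off = round(config.offtopic_fraction * n)
    n_promo = round(config.promo_fraction * n)
    n_noisy = round(config.noisy_keyword_fraction * n)
    if n_off + n_promo + n_noisy > n:
        raise ValueError("offtopic + promo + noisy fractions exceed the corpus")
    roles = np.array(
        ["offtopic"] * n_off
        + ["promo"] * n_promo
        + ["noisy"] * n_noisy
        + ["normal"] * (n - n_off - n_promo - n_noisy)
    )
    rng.shuffle(roles)

    # Noisy plan: keywords round-robin, relevance with exact planted counts.
    noisy_kws = list(config.noisy_keywords)
    noisy_assignment: list[tuple[str, bool]] = []
    if noisy_kws and n_noisy:
        per_kw: dict[str, int] = {kw: 0 for kw in noisy_kws}
        for i in range(n_noisy):
            per_kw[noisy_kws[i % len(noisy_kws)]] += 1
        for kw, m_k in per_kw.items():
            n_rel = round(config.noisy_keywords[kw] * m_k)
            flags = np.array([True] * n_rel + [False] * (m_k - n_rel))
            rng.shuffle(flags)
            noisy_assignment.extend((kw, bool(f)) for f in flags)
        order = rng.permutation(len(noisy_assignment))
        noisy_assignment = [noisy_assignment[i] for i in order]

    posts: list[Post] = []
    records: list[dict] = []
    noisy_cursor = 0
    promo_index = 0
    for i, role in enumerate(roles):
        post_id = f"p{i:06d}"
        month_idx = int(rng.integers(0, len(months)))
        mk = months[month_idx]
        day = int(rng.integers(1, 29))
        timestamp = datetime(
            mk.year, mk.month, day,
            int(rng.integers(0, 24)), int(rng.integers(0, 60)), int(rng.integers(0, 60)),
            tzinfo=timezone.utc,
        )
        author = f"user_{int(rng.integers(0, 10 ** 7)):07d}"
        record = {
            "post_id": post_id,
            "role": role,
            "year": mk.year,
            "month": mk.month,
            "category": None,
            "subcategory": None,
            "keyword": None,
            "category2": None,
            "keyword2": None,
            "promo_stage": 0,
            "noisy_keyword": None,
            "is_relevant": None,
            "valence": np.nan,
            "sentiment_label": None,
        }

        if role == "offtopic":
            text = _OFFTOPIC_TEMPLATES[int(rng.integers(0, len(_OFFTOPIC_TEMPLATES)))]

        elif role == "promo":
            promo_index += 1
            kw = tax.keywords()[int(rng.integers(0, len(tax.keywords())))]
            stage = 1 if rng.random() < 0.5 else 2
            if stage == 1:
                parts = [p[int(rng.integers(0, len(p)))] for p in _PROMO_HANDLE_PARTS]
                author = "".join(parts) + str(promo_index)
                text = _PROMO_CLEAN_BODY_TEMPLATE.format(kw=kw)
            else:
                text = _PROMO_BODY_TEMPLATE.format(kw=kw)
            record.update(keyword=kw, promo_stage=stage)

        elif role == "noisy":
            kw, is_relevant = noisy_assignment[noisy_cursor]
            noisy_cursor += 1
            cat, sub = AMBIGUOUS_KEYWORD_PATHS[kw]
            label_probs = config.sentiment_mix.get(cat, (0.34, 0.33, 0.33))
            label = ("positive", "neutral", "negative")[
                int(rng.choice(3, p=np.asarray(label_probs) / sum(label_probs)))
            ]
            phrase_pool = _PHRASES_BY_LABEL[label]
            phrase = phrase_pool[int(rng.integers(0, len(phrase_pool)))]
            topic = _TOPIC_NOUNS[int(rng.integers(0, len(_TOPIC_NOUNS)))]
            text = _NOISY_TEMPLATES[kw][is_relevant].format(topic=topic, phrase=phrase)
            record.update(
                noisy_keyword=kw,
                is_relevant=is_relevant,
                valence=PHRASE_VALENCE[phrase],
                sentiment_label=label,
            )
            if is_relevant:
                record.update(category=cat, subcategory=sub, keyword=kw)

        else:  # normal flavor post
            cat_idx = int(rng.choice(len(cats), p=month_weights[month_idx]))
            cat = cats[cat_idx]
            cat_keywords = tax.keywords_of(cat)
            cat_keywords = tuple(k for k in cat_keywords if k not in config.noisy_keywords)
            kw = cat_keywords[int(rng.integers(0, len(cat_keywords)))]
            path = tax.path_of(kw)
            mix = config.sentiment_mix.get(cat, (0.34, 0.33, 0.33))
            label = ("positive", "neutral", "negative")[
                int(rng.choice(3, p=np.asarray(mix) / sum(mix)))
            ]
            phrase_pool = _PHRASES_BY_LABEL[label]
            phrase = phrase_pool[int(rng.integers(0, len(phrase_pool)))]
            topic = _TOPIC_NOUNS[int(rng.integers(0, len(_TOPIC_NOUNS)))]
            record.update(
                category=cat,
                subcategory=path.subcategory,
                keyword=kw,
                valence=PHRASE_VALENCE[phrase],
                sentiment_label=label,
            )
            if rng.random() < config.multi_flavor_fraction:
                for _ in range(10):
                    cat2_idx = int(rng.choice(len(cats), p=month_weights[month_idx]))
                    cat2 = cats[cat2_idx]
                    kws2 = tuple(
                        k for k in tax.keywords_of(cat2) if k not in config.noisy_keywords
                    )
                    kw2 = kws2[int(rng.integers(0, len(kws2)))]
                    if kw2 != kw:
                        break
                record.update(category2=cat2, keyword2=kw2)
                text = _MULTI_TEMPLATE.format(kw=kw, kw2=kw2, topic=topic, phrase=phrase)
            elif " " not in kw and rng.random() < 0.2:
                tag = _TOPIC_TAGS[int(rng.integers(0, len(_TOPIC_TAGS)))]
                text = _HASHTAG_TEMPLATE.format(tag=tag, kw=kw, phrase=phrase)
            else:
                template = _NORMAL_TEMPLATES[int(rng.integers(0, len(_NORMAL_TEMPLATES)))]
                text = template.format(topic=topic, kw=kw, phrase=phrase)

        posts.append(
            Post(id=post_id, platform=config.platform, author=author,
                 timestamp=timestamp, text=text)
        )
        records.append(record)

    ledger = pd.DataFrame(
        records,
        columns=[
            "post_id", "role", "year", "month", "category", "subcategory", "keyword",
            "category2", "keyword2", "promo_stage", "noisy_keyword", "is_relevant",
            "valence", "sentiment_label",
        ],
    )
    return SyntheticCorpus(posts=posts, ledger=ledger, taxonomy=tax, config=config)


def labels_from_ledger(
    corpus: SyntheticCorpus,
) -> list[tuple[str, Post, bool]]:
    """Export (keyword, post, is_relevant) labeled samples for the ambiguous
    keywords — the input the denoise harness would get from human labeling."""
    by_id = {p.id: p for p in corpus.posts}
    noisy = corpus.ledger.loc[corpus.ledger["noisy_keyword"].notna()]
    return [
        (row.noisy_keyword, by_id[row.post_id], bool(row.is_relevant))
        for row in noisy.itertuples()
    ]
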