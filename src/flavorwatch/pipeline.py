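"""End-to-end workflows: longitudinal trend analysis and sentiment analysis.

Two workflows mirror how flavor surveillance is run on the two platforms:

* :func:`run_trends` (Reddit-style): topic filter -> optional promotion
  filter -> flavor-mention extraction with an exclusion list -> monthly
  per-category counts -> within-month normalization -> per-category
  subcategory percentage tables.
* :func:`run_sentiment` (Twitter-style): topic filter -> two-step promotion
  filter -> single-flavor subset -> valence scoring -> per-category
  aggregation with a minimum-count filter -> positive-vs-negative
  two-proportion z-tests with Bonferroni correction.

Every stage logs its input/output/removed counts into a
:class:`RunManifest`, so the corpus funnel is fully auditable: at each stage
``n_in == n_out + n_removed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .corpus import MonthKey, Post
from .filtering import (
    KeywordSet,
    bundled_keyword_set,
    extract_mentions,
    filter_promotions,
    match_topic,
    single_flavor_subset,
)
from .sentiment import DEFAULT_MIN_COUNT, NEUTRAL_BAND, Scorer, aggregate_category, score_post
from .stats import DEFAULT_ALPHA, positive_vs_negative_tests
from .taxonomy import FlavorTaxonomy
from .trends import monthly_counts, normalize, subcategory_percentages

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "RunManifest", "TrendsResult",
           "SentimentResult", "run_trends", "run_sentiment"]


class PipelineError(RuntimeError):
    """A workflow failed; the message names the stage responsible."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow configuration; every analysis constant is a default here.

    ``apply_promo_filter`` defaults per platform conventions: promotion
    filtering is part of the Twitter workflow and off for Reddit-style trend
    runs (pass explicitly to override).
    """

    topic_keywords: KeywordSet = field(default_factory=lambda: bundled_keyword_set("topic"))
    promo_id_keywords: KeywordSet = field(default_factory=lambda: bundled_keyword_set("promo_id"))
    promo_body_keywords: KeywordSet = field(
        default_factory=lambda: bundled_keyword_set("promo_body")
    )
    excluded_flavors: tuple[str, ...] = ()
    apply_promo_filter: bool = False
    start: str | None = None
    end: str | None = None
    neutral_band: float = NEUTRAL_BAND
    min_category_count: int = DEFAULT_MIN_COUNT
    alpha: float = DEFAULT_ALPHA


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class RunManifest:
    """Auditable record of one workflow run."""

    workflow: str
    stages: list[StageCount] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append(StageCount(stage, n_in, n_out))
        log.info("stage %-22s in=%d out=%d removed=%d", stage, n_in, n_out, n_in - n_out)

    def as_dict(self) -> dict:
        return {
            "workflow": self.workflow,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "stages": [
                {"stage": s.stage, "n_in": s.n_in, "n_out": s.n_out, "n_removed": s.n_removed}
                for s in self.stages
            ],
        }


@dataclass
class TrendsResult:
    monthly: pd.DataFrame
    subcategory_tables: dict[str, pd.DataFrame]
    mentions: list
    manifest: RunManifest


@dataclass
class SentimentResult:
    summary: pd.DataFrame
    tests: pd.DataFrame
    scores: pd.DataFrame
    manifest: RunManifest


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _config_snapshot(config: PipelineConfig) -> dict:
    return {
        "n_topic_keywords": len(config.topic_keywords.keywords),
        "excluded_flavors": sorted(config.excluded_flavors),
        "apply_promo_filter": config.apply_promo_filter,
        "start": config.start,
        "end": config.end,
        "neutral_band": config.neutral_band,
        "min_category_count": config.min_category_count,
        "alpha": config.alpha,
    }


def _front_stages(
    posts: Sequence[Post], config: PipelineConfig, manifest: RunManifest
) -> list[Post]:
    """Topic filter, then (optionally) the two-step promotion filter."""
    on_topic = [p for p in posts if match_topic(p, config.topic_keywords)]
    manifest.record("topic_filter", len(posts), len(on_topic))
    if not on_topic:
        raise PipelineError("topic_filter", "no posts match the topic keywords")
    if not config.apply_promo_filter:
        return on_topic
    promo = filter_promotions(on_topic, config.promo_id_keywords, config.promo_body_keywords)
    manifest.record(
        "promo_filter_handle", len(on_topic), len(on_topic) - len(promo.removed_by_handle)
    )
    manifest.record(
        "promo_filter_body",
        len(on_topic) - len(promo.removed_by_handle),
        len(promo.retained),
    )
    if not promo.retained:
        raise PipelineError("promo_filter_body", "promotion filtering removed every post")
    return promo.retained


def run_trends(
    posts: Iterable[Post],
    tax: FlavorTaxonomy,
    config: PipelineConfig | None = None,
) -> TrendsResult:
    """Longitudinal trend workflow: monthly category counts and proportions."""
    config = config or PipelineConfig()
    posts = list(posts)
    manifest = RunManifest(
        workflow="trends", config=_config_snapshot(config), started=_now()
    )
    retained = _front_stages(posts, config, manifest)

    mentions = []
    flavor_posts = []
    for post in retained:
        found = extract_mentions(post, tax, config.excluded_flavors)
        if found:
            flavor_posts.append(post)
            mentions.extend(found)
    manifest.record("flavor_subset", len(retained), len(flavor_posts))
    manifest.record("mentions", len(flavor_posts), len(mentions))

    if not mentions:
        log.warning("no flavor mentions found; trend table will be all zeros")
        if config.start is None or config.end is None:
            months = sorted({(p.timestamp.year, p.timestamp.month) for p in retained})
            start = config.start or f"{months[0][0]:04d}-{months[0][1]:02d}"
            end = config.end or f"{months[-1][0]:04d}-{months[-1][1]:02d}"
        else:
            start, end = config.start, config.end
        table = monthly_counts([], {p.id: p for p in retained}, start=start, end=end)
    else:
        table = monthly_counts(
            mentions, {p.id: p for p in retained}, start=config.start, end=config.end
        )
    table = normalize(table)
    subcategory_tables = {
        category: subcategory_percentages(mentions, category, tax)
        for category in tax.category_names
    }
    manifest.finished = _now()
    return TrendsResult(
        monthly=table,
        subcategory_tables=subcategory_tables,
        mentions=mentions,
        manifest=manifest,
    )


def run_sentiment(
    posts: Iterable[Post],
    tax: FlavorTaxonomy,
    scorer: Scorer,
    config: PipelineConfig | None = None,
) -> SentimentResult:
    """Sentiment workflow: per-category score summaries and z-tests."""
    if config is None:
        config = PipelineConfig(apply_promo_filter=True)
    posts = list(posts)
    manifest = RunManifest(
        workflow="sentiment", config=_config_snapshot(config), started=_now()
    )
    retained = _front_stages(posts, config, manifest)

    singles = single_flavor_subset(retained, tax, config.excluded_flavors)
    manifest.record("single_flavor_subset", len(retained), len(singles))
    if not singles:
        raise PipelineError("single_flavor_subset", "no single-flavor posts remain")

    rows = []
    for post in singles:
        mention = extract_mentions(post, tax, config.excluded_flavors)[0]
        scored = score_post(post, scorer, config.neutral_band)
        rows.append(
            {
                "post_id": post.id,
                "category": mention.path.category,
                "keyword": mention.canonical,
                "score": scored.score,
                "label": scored.label,
            }
        )
    scores = pd.DataFrame(rows)
    summary = aggregate_category(scores, min_count=config.min_category_count)
    n_kept = int((~summary["flagged"]).sum())
    manifest.record("category_min_count", len(summary), n_kept)
    tests = positive_vs_negative_tests(summary, alpha=config.alpha)
    manifest.finished = _now()
    return SentimentResult(summary=summary, tests=tests, scores=scores, manifest=manifest)
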