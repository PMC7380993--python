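"""Synthetic corpus generator: determinism, planted structure, ledger."""

import io
import math

import numpy as np
import pytest

from flavorwatch.corpus import write_posts
from flavorwatch.filtering import bundled_keyword_set, filter_promotions, match_topic
from flavorwatch.synth import (
    DEFAULT_CATEGORY_DISTRIBUTION,
    GeneratorConfig,
    generate,
    labels_from_ledger,
)


def corpus_bytes(corpus, tmp_path, name):
    path = tmp_path / name
    write_posts(corpus.posts, path)
    return path.read_bytes()


class TestConfig:
    def test_bad_distribution_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, category_distribution={"fruit": 0.7, "mixed": 0.7})

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, promo_fraction=1.5)

    def test_unknown_noisy_keyword_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(seed=0, noisy_keywords={"zzz": 0.5})


class TestGenerate:
    def test_same_seed_is_byte_identical(self, tmp_path):
        config = GeneratorConfig.twitter_default(seed=7, n_posts=400)
        a = corpus_bytes(generate(config), tmp_path, "a.jsonl")
        b = corpus_bytes(generate(config), tmp_path, "b.jsonl")
        assert a == b

    def test_different_seed_differs(self, tmp_path):
        a = corpus_bytes(generate(GeneratorConfig.reddit_default(seed=1, n_posts=200)),
                         tmp_path, "a.jsonl")
        b = corpus_bytes(generate(GeneratorConfig.reddit_default(seed=2, n_posts=200)),
                         tmp_path, "b.jsonl")
        assert a != b

    def test_ledger_covers_every_post_exactly_once(self):
        corpus = generate(GeneratorConfig.reddit_default(seed=3, n_posts=500))
        assert len(corpus.ledger) == 500
        assert sorted(corpus.ledger["post_id"]) == sorted(p.id for p in corpus.posts)
        assert corpus.ledger["post_id"].is_unique

    def test_planted_category_share_within_binomial_error(self):
        """Empirical fruit share of flavor posts is within 3 SE of the
        planted 0.58 (stationary config)."""
        n = 1000
        corpus = generate(
            GeneratorConfig(seed=7, n_posts=n, promo_fraction=0.0,
                            noisy_keyword_fraction=0.0, offtopic_fraction=0.0,
                            multi_flavor_fraction=0.0, date_range=("2019-01", "2019-04"))
        )
        share = (corpus.ledger["category"] == "fruit").mean()
        p = DEFAULT_CATEGORY_DISTRIBUTION["fruit"]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(share - p) <= 3 * se

    def test_promo_fraction_zero_means_promo_filter_removes_nothing(self):
        corpus = generate(
            GeneratorConfig(seed=5, n_posts=300, promo_fraction=0.0,
                            date_range=("2019-01", "2019-02"))
        )
        result = filter_promotions(
            corpus.posts, bundled_keyword_set("promo_id"), bundled_keyword_set("promo_body")
        )
        assert result.n_removed == 0

    def test_planted_promo_posts_are_caught_by_their_planted_stage(self):
        corpus = generate(GeneratorConfig.twitter_default(seed=11, n_posts=600))
        result = filter_promotions(
            corpus.posts, bundled_keyword_set("promo_id"), bundled_keyword_set("promo_body")
        )
        ledger = corpus.ledger.set_index("post_id")
        for post in result.removed_by_handle:
            assert ledger.loc[post.id, "promo_stage"] == 1
        for post in result.removed_by_body:
            assert ledger.loc[post.id, "promo_stage"] == 2
        removed = {p.id for p in result.removed_by_handle} | {p.id for p in result.removed_by_body}
        assert removed == set(ledger.index[ledger["promo_stage"] > 0])

    def test_offtopic_posts_fail_topic_filter_and_only_they_do(self):
        corpus = generate(GeneratorConfig.reddit_default(seed=13, n_posts=400))
        topic = bundled_keyword_set("topic")
        ledger = corpus.ledger.set_index("post_id")
        for post in corpus.posts:
            expected = ledger.loc[post.id, "role"] != "offtopic"
            assert match_topic(post, topic) is expected

    def test_noisy_relevance_counts_are_engineered_exactly(self):
        config = GeneratorConfig(
            seed=17, n_posts=1000, noisy_keyword_fraction=0.2,
            noisy_keywords={"punch": 0.5, "contact": 0.95},
            date_range=("2019-01", "2019-02"),
        )
        corpus = generate(config)
        noisy = corpus.ledger[corpus.ledger["noisy_keyword"].notna()]
        assert len(noisy) == 200
        for kw, target in config.noisy_keywords.items():
            group = noisy[noisy["noisy_keyword"] == kw]
            assert group["is_relevant"].mean() == pytest.approx(target, abs=0.01)

    def test_labels_export_matches_ledger(self):
        corpus = generate(GeneratorConfig.reddit_default(seed=19, n_posts=400))
        labels = labels_from_ledger(corpus)
        n_noisy = int(corpus.ledger["noisy_keyword"].notna().sum())
        assert len(labels) == n_noisy
        assert all(kw in {"punch", "contact"} for kw, _, _ in labels)

    def test_planted_valences_readable_by_stub_scorer(self):
        from flavorwatch.sentiment import PhraseLexiconScorer

        corpus = generate(GeneratorConfig.twitter_default(seed=23, n_posts=400))
        scorer = PhraseLexiconScorer()
        ledger = corpus.ledger.set_index("post_id")
        checked = 0
        for post in corpus.posts:
            planted = ledger.loc[post.id, "valence"]
            if not np.isnan(planted):
                assert scorer.score(post.text) == planted
                checked += 1
        assert checked > 100

    def test_monthly_trend_drift_shifts_shares(self):
        config = GeneratorConfig(
            seed=29, n_posts=6000, promo_fraction=0.0, noisy_keyword_fraction=0.0,
            offtopic_fraction=0.0, multi_flavor_fraction=0.0,
            date_range=("2013-01", "2018-12"), monthly_trend={"fruit": 0.6},
        )
        corpus = generate(config)
        ledger = corpus.ledger
        first = ledger[ledger["year"] <= 2014]
        last = ledger[ledger["year"] >= 2017]
        assert (last["category"] == "fruit").mean() > (first["category"] == "fruit").mean()
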