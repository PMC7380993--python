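"""Topic matching, promotion filtering, mention extraction, keyword vetting."""

import random

import pytest
from hypothesis import given, strategies as st

from flavorwatch.filtering import (
    KeywordSet,
    bundled_keyword_set,
    denoise_keywords,
    evaluate_keyword,
    extract_mentions,
    filter_promotions,
    match_topic,
    single_flavor_subset,
)


@pytest.fixture(scope="module")
def topic():
    return bundled_keyword_set("topic")


class TestKeywordSet:
    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            KeywordSet("x", ())

    def test_rejects_duplicates_after_normalization(self):
        with pytest.raises(ValueError):
            KeywordSet("x", ("Vape", "vape"))


class TestMatchTopic:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("I love my JUUL", True),
            ("grapevine festival", False),            # token boundary
            ("#vaping all day", True),                # hashtag stripped
            ("my e-cig broke", True),
            ("suprematism and escapism", False),      # no substring hits
            ("VapeNation represent", True),
            ("", False),
        ],
    )
    def test_examples(self, make_post, topic, text, expected):
        assert match_topic(make_post(text), topic) is expected


@pytest.fixture(scope="module")
def kws():
    return bundled_keyword_set("promo_id"), bundled_keyword_set("promo_body")


class TestFilterPromotions:
    def test_two_steps_and_count_conservation(self, make_post, kws):
        id_kws, body_kws = kws
        posts = [
            make_post("new mango pods in stock", id="a", author="BestVapeStore"),
            make_post("20% discount this week", id="b", author="jane_doe"),
            make_post("this mango pod is great", id="c", author="jane_doe"),
            make_post("free shipping on everything", id="d", author="bob"),
        ]
        result = filter_promotions(posts, id_kws, body_kws)
        assert [p.id for p in result.removed_by_handle] == ["a"]
        assert sorted(p.id for p in result.removed_by_body) == ["b", "d"]
        assert [p.id for p in result.retained] == ["c"]
        assert len(result.retained) + result.n_removed == len(posts)

    def test_handle_match_is_substring_not_token(self, make_post, kws):
        id_kws, body_kws = kws
        post = make_post("hello", author="megadealer99")
        result = filter_promotions([post], id_kws, body_kws)
        assert result.removed_by_handle == [post]

    def test_handle_checked_before_body(self, make_post, kws):
        # a post failing both criteria is attributed to step 1
        id_kws, body_kws = kws
        post = make_post("big sale now", author="VapeStore")
        result = filter_promotions([post], id_kws, body_kws)
        assert result.removed_by_handle == [post]
        assert result.removed_by_body == []


class TestExtractMentions:
    def test_multiple_mentions_resolved(self, make_post, taxonomy):
        mentions = extract_mentions(make_post("strawberry custard all day"), taxonomy)
        assert [(m.keyword, tuple(m.path)) for m in mentions] == [
            ("strawberry", ("fruit", "berry", "strawberry")),
            ("custard", ("sweets", "dessert", "custard")),
        ]

    def test_longest_match_wins(self, make_post, taxonomy):
        mentions = extract_mentions(make_post("love that cotton candy vibe"), taxonomy)
        assert [m.keyword for m in mentions] == ["cotton candy"]

    def test_no_mentions(self, make_post, taxonomy):
        assert extract_mentions(make_post("no flavors here"), taxonomy) == []

    def test_span_points_into_original_text(self, make_post, taxonomy):
        text = "#vaping #Strawberry and ice cream"
        mentions = extract_mentions(make_post(text), taxonomy)
        for m in mentions:
            assert text[m.span[0]:m.span[1]].lower() == m.keyword
        assert [m.keyword for m in mentions] == ["strawberry", "ice cream"]

    def test_excluding_long_keyword_exposes_short_one(self, make_post, taxonomy):
        post = make_post("ice cream forever")
        assert [m.keyword for m in extract_mentions(post, taxonomy)] == ["ice cream"]
        assert [m.keyword for m in extract_mentions(post, taxonomy, {"ice cream"})] == ["cream"]

    def test_alias_matches_map_to_canonical(self, make_post, taxonomy):
        (m,) = extract_mentions(make_post("fresh strawberries today"), taxonomy)
        assert m.keyword == "strawberries"
        assert m.canonical == "strawberry"
        assert m.path.subcategory == "berry"

    def test_excluded_monotonicity(self, make_post, taxonomy):
        """Enlarging the exclusion set never increases the mention count."""
        rng = random.Random(3)
        keywords = list(taxonomy.keywords())
        # keywords separated by filler so exclusion cannot expose shorter
        # keywords hidden inside adjacent compounds
        posts = [
            make_post(" then some ".join(rng.sample(keywords, 4)), id=f"p{i}")
            for i in range(20)
        ]
        # excluding a compound keyword can expose keywords nested inside it
        # (by design), so monotonicity is asserted for atomic keywords
        atomic = [
            k for k in keywords
            if not any(other != k and other in k for other in keywords)
        ]
        excluded: set = set()
        last = [len(extract_mentions(p, taxonomy, excluded)) for p in posts]
        for kw in rng.sample(atomic, 30):
            excluded.add(kw)
            now = [len(extract_mentions(p, taxonomy, excluded)) for p in posts]
            assert all(a <= b for a, b in zip(now, last))
            last = now


class TestEvaluateKeyword:
    def make_samples(self, make_post, keyword, tp, fp, fn, tn=0):
        """Labeled sample with planted confusion counts for `keyword`."""
        samples = []
        i = 0
        for _ in range(tp):
            samples.append((make_post(f"my {keyword} juice rules", id=f"s{i}"), True)); i += 1
        for _ in range(fp):
            samples.append((make_post(f"unrelated {keyword} usage", id=f"s{i}"), False)); i += 1
        for _ in range(fn):
            # labeled relevant but text does not trigger a token-boundary match
            samples.append((make_post(f"misspelled {keyword}ish thing", id=f"s{i}"), True)); i += 1
        for _ in range(tn):
            samples.append((make_post("nothing here", id=f"s{i}"), False)); i += 1
        return samples

    @pytest.mark.parametrize(
        "tp, fp, fn, precision, recall, decision",
        [
            (18, 2, 2, 0.90, 0.90, "keep"),
            (19, 1, 10, 0.95, 19 / 29, "exclude"),
            (15, 5, 0, 0.75, 1.0, "exclude"),
        ],
    )
    def test_threshold_rule(self, make_post, taxonomy, tp, fp, fn, precision, recall, decision):
        tax = taxonomy.with_keyword("fruit", "others", "punch")
        samples = self.make_samples(make_post, "punch", tp, fp, fn)
        result = evaluate_keyword("punch", samples, tax)
        assert (result.tp, result.fp, result.fn) == (tp, fp, fn)
        assert result.precision == pytest.approx(precision)
        assert result.recall == pytest.approx(recall)
        assert result.decision == decision

    def test_degenerate_counts_mean_exclude(self, make_post, taxonomy):
        tax = taxonomy.with_keyword("fruit", "others", "punch")
        samples = [(make_post("nothing relevant at all"), False)]
        result = evaluate_keyword("punch", samples, tax)
        assert result.precision is None and result.recall is None
        assert result.decision == "exclude"

    def test_empty_sample_is_an_error(self, taxonomy):
        with pytest.raises(ValueError):
            evaluate_keyword("punch", [], taxonomy)

    def test_matches_brute_force_confusion_matrix(self, make_post, taxonomy):
        """Evaluation agrees with a direct confusion-matrix computation on a
        randomized labeled corpus over several real keywords."""
        rng = random.Random(11)
        keywords = ["mango", "custard", "menthol"]
        posts, labels = [], {}
        for i in range(120):
            kw = rng.choice(keywords)
            present = rng.random() < 0.7
            relevant = rng.random() < 0.6
            text = f"I tried {kw} today" if present else f"nothing about {kw}ness"
            post = make_post(text, id=f"r{i}")
            posts.append((kw, post, relevant))
        evals, _ = denoise_keywords(posts, taxonomy)
        for ev in evals:
            tp = sum(1 for kw, p, rel in posts
                     if kw == ev.keyword and rel and f"{kw} today" in p.text)
            fp = sum(1 for kw, p, rel in posts
                     if kw == ev.keyword and not rel and f"{kw} today" in p.text)
            fn = sum(1 for kw, p, rel in posts
                     if kw == ev.keyword and rel and f"{kw} today" not in p.text)
            assert (ev.tp, ev.fp, ev.fn) == (tp, fp, fn)


class TestSingleFlavorSubset:
    def test_rules(self, make_post, taxonomy):
        posts = [
            make_post("this mango pod is great", id="one"),
            make_post("mango and menthol together", id="two"),
            make_post("mango mango mango", id="repeat"),
            make_post("no flavors at all", id="none"),
        ]
        kept = single_flavor_subset(posts, taxonomy)
        assert [p.id for p in kept] == ["one", "repeat"]

    def test_alias_and_canonical_count_once(self, make_post, taxonomy):
        post = make_post("strawberry or strawberries, always")
        assert single_flavor_subset([post], taxonomy) == [post]

    def test_order_independence(self, make_post, taxonomy):
        posts = [make_post(t, id=str(i)) for i, t in enumerate(
            ["mango pod", "mango and menthol", "custard love", "nothing"]
        )]
        forward = {p.id for p in single_flavor_subset(posts, taxonomy)}
        backward = {p.id for p in single_flavor_subset(posts[::-1], taxonomy)}
        assert forward == backward


@given(st.text(alphabet=st.characters(codec="ascii"), max_size=80))
def test_match_topic_never_crashes_on_arbitrary_text(text):
    from datetime import datetime, timezone

    from flavorwatch.corpus import Post

    post = Post(id="h", platform="other", author="a",
                timestamp=datetime(2019, 1, 1, tzinfo=timezone.utc), text=text)
    match_topic(post, bundled_keyword_set("topic"))
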