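"""Staged corpus reduction: topic matching, promotion removal, flavor-mention
extraction, and precision/recall-based keyword denoising.

Matching semantics (shared by every stage that looks at post bodies): text is
lower-cased, a ``#`` introducing a hashtag is stripped so that ``#vaping``
matches the keyword ``vaping``, and keywords match at Unicode word
boundaries only — ``vape`` does not match inside ``grapevine``. Multi-word
keywords match across single spaces. Flavor extraction is longest-match
first and non-overlapping, so ``cotton candy`` wins over ``candy``.

Ambiguous flavor names (e.g. ``punch``, ``contact``) are vetted against
labeled samples: a keyword is kept only if its sample precision is at least
0.90 and its recall at least 0.75; everything else joins the exclusion set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import Post
from .taxonomy import FlavorTaxonomy, TaxonomyPath, classify_term, normalize_keyword

__all__ = [
    "KeywordSet",
    "FlavorMention",
    "KeywordEval",
    "PromotionFilterResult",
    "load_keyword_set",
    "bundled_keyword_set",
    "match_topic",
    "filter_promotions",
    "extract_mentions",
    "evaluate_keyword",
    "denoise_keywords",
    "single_flavor_subset",
]

PRECISION_THRESHOLD = 0.90
RECALL_THRESHOLD = 0.75


@dataclass(frozen=True)
class KeywordSet:
    """A named list of lower-cased keywords (non-empty, duplicate-free)."""

    name: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"keyword set {self.name!r} is empty")
        normalized = tuple(normalize_keyword(k) for k in self.keywords)
        if len(set(normalized)) != len(normalized):
            raise ValueError(f"keyword set {self.name!r} contains duplicates")
        object.__setattr__(self, "keywords", normalized)


def load_keyword_set(path: str | Path, name: str | None = None) -> KeywordSet:
    """Read a one-keyword-per-line config file ('#' lines are comments)."""
    path = Path(path)
    keywords = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return KeywordSet(name or path.stem, tuple(keywords))


def bundled_keyword_set(which: str) -> KeywordSet:
    """Packaged default keyword lists: 'topic', 'promo_id', or 'promo_body'."""
    from importlib import resources

    filename = {
        "topic": "topic_keywords.txt",
        "promo_id": "promo_id_keywords.txt",
        "promo_body": "promo_body_keywords.txt",
    }[which]
    text = resources.files("flavorwatch.data").joinpath(filename).read_text("utf-8")
    keywords = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return KeywordSet(which, tuple(keywords))


@dataclass(frozen=True)
class FlavorMention:
    """One matched flavor keyword inside one post.

    ``keyword`` is the matched surface form (lower-cased); ``canonical`` the
    taxonomy keyword it resolves to (differs only for aliases); ``span`` the
    0-based half-open character offsets into the original post text.
    """

    post_id: str
    keyword: str
    canonical: str
    path: TaxonomyPath
    span: tuple[int, int]


@dataclass(frozen=True)
class KeywordEval:
    """Precision/recall of one flavor keyword on a labeled sample."""

    keyword: str
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    decision: str  # "keep" | "exclude"


@dataclass
class PromotionFilterResult:
    """Two-step promotion filter output with per-step removal counts."""

    retained: list[Post]
    removed_by_handle: list[Post] = field(default_factory=list)
    removed_by_body: list[Post] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_by_handle) + len(self.removed_by_body)


# -- text normalization and matcher compilation --------------------------


def _strip_hashtags(text: str) -> tuple[str, list[int]]:
    """Remove '#' characters that introduce hashtags, keeping an offset map
    from stripped-text indices back to original-text indices."""
    lowered = text.lower()
    out: list[str] = []
    idx_map: list[int] = []
    for i, ch in enumerate(lowered):
        if (
            ch == "#"
            and i + 1 < len(lowered)
            and (lowered[i + 1].isalnum() or lowered[i + 1] == "_")
            and (i == 0 or not (lowered[i - 1].isalnum() or lowered[i - 1] == "_"))
        ):
            continue
        out.append(ch)
        idx_map.append(i)
    return "".join(out), idx_map


def _compile_matcher(surfaces: Iterable[str]) -> re.Pattern[str]:
    # Longer alternatives first so the regex engine realises longest-match
    # at each position; finditer then yields non-overlapping matches.
    ordered = sorted(set(surfaces), key=lambda s: (-len(s), s))
    alternation = "|".join(re.escape(s) for s in ordered)
    return re.compile(rf"(?<!\w)(?:{alternation})(?!\w)")


_MATCHER_CACHE: dict[frozenset[str], re.Pattern[str]] = {}


def _matcher(surfaces: Iterable[str]) -> re.Pattern[str]:
    key = frozenset(surfaces)
    try:
        return _MATCHER_CACHE[key]
    except KeyError:
        pattern = _compile_matcher(key)
        if len(_MATCHER_CACHE) > 64:
            _MATCHER_CACHE.clear()
        _MATCHER_CACHE[key] = pattern
        return pattern


# -- stages ---------------------------------------------------------------


def match_topic(post: Post, kws: KeywordSet) -> bool:
    """True iff at least one topic keyword matches the post text at token
    boundaries (case-insensitive, leading '#' stripped)."""
    stripped, _ = _strip_hashtags(post.text)
    return _matcher(kws.keywords).search(stripped) is not None


def filter_promotions(
    posts: Iterable[Post], id_kws: KeywordSet, body_kws: KeywordSet
) -> PromotionFilterResult:
    """Remove promotional posts in two observable steps.

    Step 1 drops posts whose author handle contains any account keyword as a
    case-insensitive substring (vendor handles embed words like ``store`` or
    product terms directly). Step 2 drops remaining posts whose body matches
    a promotion keyword at token boundaries. Input count is conserved:
    ``len(retained) + len(removed_by_handle) + len(removed_by_body)`` equals
    the input size.
    """
    result = PromotionFilterResult(retained=[])
    body_matcher = _matcher(body_kws.keywords)
    for post in posts:
        handle = post.author.lower()
        if any(kw in handle for kw in id_kws.keywords):
            result.removed_by_handle.append(post)
            continue
        stripped, _ = _strip_hashtags(post.text)
        if body_matcher.search(stripped):
            result.removed_by_body.append(post)
        else:
            result.retained.append(post)
    return result


def extract_mentions(
    post: Post,
    tax: FlavorTaxonomy,
    excluded: Iterable[str] = (),
) -> list[FlavorMention]:
    """All flavor-keyword matches in a post, resolved to taxonomy paths.

    Matches are non-overlapping and longest-first; keywords (or aliases whose
    canonical keyword) in ``excluded`` do not participate in matching at all,
    so excluding a long keyword can legitimately expose a shorter one.
    """
    excluded_set = {normalize_keyword(k) for k in excluded}
    surface_to_canonical = {
        surface: canonical
        for surface, canonical in tax.match_terms().items()
        if canonical not in excluded_set and surface not in excluded_set
    }
    if not surface_to_canonical:
        return []
    stripped, idx_map = _strip_hashtags(post.text)
    mentions = []
    for m in _matcher(surface_to_canonical).finditer(stripped):
        surface = m.group(0)
        canonical = surface_to_canonical[surface]
        start, end = m.start(), m.end()
        span = (idx_map[start], idx_map[end - 1] + 1)
        mentions.append(
            FlavorMention(
                post_id=post.id,
                keyword=surface,
                canonical=canonical,
                path=classify_term(tax.standardize(canonical), tax),
                span=span,
            )
        )
    return mentions


def evaluate_keyword(
    keyword: str,
    labeled: Sequence[tuple[Post, bool]],
    tax: FlavorTaxonomy,
    precision_threshold: float = PRECISION_THRESHOLD,
    recall_threshold: float = RECALL_THRESHOLD,
) -> KeywordEval:
    """Score one flavor keyword against a labeled sample.

    Each sample pairs a post with a human judgement of whether the keyword is
    used in a flavor sense there. A predicted positive is a post where
    :func:`extract_mentions` matches the keyword. A keyword is kept only if
    precision >= 0.90 and recall >= 0.75 on the sample; undefined ratios
    (zero denominators) force exclusion.
    """
    if not labeled:
        raise ValueError("labeled sample is empty")
    keyword = normalize_keyword(keyword)
    tp = fp = fn = 0
    for post, is_relevant in labeled:
        matched = any(m.canonical == keyword for m in extract_mentions(post, tax))
        if matched and is_relevant:
            tp += 1
        elif matched and not is_relevant:
            fp += 1
        elif not matched and is_relevant:
            fn += 1
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    keep = (
        precision is not None
        and recall is not None
        and precision >= precision_threshold
        and recall >= recall_threshold
    )
    return KeywordEval(
        keyword=keyword,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        decision="keep" if keep else "exclude",
    )


def denoise_keywords(
    labeled: Sequence[tuple[str, Post, bool]],
    tax: FlavorTaxonomy,
    precision_threshold: float = PRECISION_THRESHOLD,
    recall_threshold: float = RECALL_THRESHOLD,
) -> tuple[list[KeywordEval], set[str]]:
    """Vet every keyword present in a labeled sample; return (evals, excluded).

    ``labeled`` rows are (keyword, post, is_relevant). Keywords failing the
    precision/recall rule are collected into the exclusion set consumed by
    :func:`extract_mentions`.
    """
    by_keyword: dict[str, list[tuple[Post, bool]]] = {}
    for keyword, post, is_relevant in labeled:
        by_keyword.setdefault(normalize_keyword(keyword), []).append((post, bool(is_relevant)))
    evals = [
        evaluate_keyword(kw, samples, tax, precision_threshold, recall_threshold)
        for kw, samples in sorted(by_keyword.items())
    ]
    excluded = {e.keyword for e in evals if e.decision == "exclude"}
    return evals, excluded


def single_flavor_subset(
    posts: Iterable[Post],
    tax: FlavorTaxonomy,
    excluded: Iterable[str] = (),
) -> list[Post]:
    """Posts mentioning exactly one distinct flavor (repeats of it allowed).

    Distinctness is judged on the canonical keyword, so a post using a flavor
    name and its alias still counts as single-flavor.
    """
    excluded = tuple(excluded)
    subset = []
    for post in posts:
        canonicals = {m.canonical for m in extract_mentions(post, tax, excluded)}
        if len(canonicals) == 1:
            subset.append(post)
    return subset
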