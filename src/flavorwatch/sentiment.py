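"""Valence scoring and three-way sentiment classification of posts.

A scorer is anything with a ``score(text) -> float`` method returning a
compound valence in [-1, +1]. Scores are mapped to labels with the standard
lexicon-analyzer thresholds: [-1.00, -0.05] is negative, the open interval
(-0.05, +0.05) is neutral, and [+0.05, +1.00] is positive — the +/-0.05
boundaries themselves count as polar, not neutral.

Two scorers are bundled: :class:`VaderScorer`, a thin adapter over the VADER
compound score for real corpora (requires the optional ``vader`` extra), and
:class:`PhraseLexiconScorer`, a small deterministic phrase lexicon that the
synthetic corpus generator writes against, so pipeline-level sentiment tests
have exact planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .corpus import Post

__all__ = [
    "NEUTRAL_BAND",
    "PHRASE_VALENCE",
    "SentimentScore",
    "Scorer",
    "PhraseLexiconScorer",
    "VaderScorer",
    "classify_score",
    "score_post",
    "aggregate_category",
]

#: Half-width of the neutral band around zero.
NEUTRAL_BAND = 0.05

#: Minimum posts for a category to enter comparative sentiment analysis.
DEFAULT_MIN_COUNT = 300

LABELS = ("positive", "neutral", "negative")


@runtime_checkable
class Scorer(Protocol):
    def score(self, text: str) -> float: ...


@dataclass(frozen=True)
class SentimentScore:
    post_id: str
    score: float
    label: str


def classify_score(score: float, neutral_band: float = NEUTRAL_BAND) -> str:
    """Map a valence in [-1, 1] to negative/neutral/positive.

    The three intervals partition [-1, 1]: [-1, -band] -> negative,
    (-band, +band) -> neutral, [+band, +1] -> positive.
    """
    if not -1.0 <= score <= 1.0:
        raise ValueError(f"valence {score} outside [-1, 1]")
    if score <= -neutral_band:
        return "negative"
    if score >= neutral_band:
        return "positive"
    return "neutral"


def score_post(post: Post, scorer: Scorer, neutral_band: float = NEUTRAL_BAND) -> SentimentScore:
    """Score one post and attach its three-way label.

    A scorer returning a value outside [-1, 1] violates the scorer contract
    and raises ``ValueError``.
    """
    value = float(scorer.score(post.text))
    return SentimentScore(post_id=post.id, score=value, label=classify_score(value, neutral_band))


# -- bundled scorers ------------------------------------------------------

#: Phrase lexicon shared with the synthetic corpus generator. Each phrase is
#: short, contains no flavor or topic keyword, and carries a fixed valence.
PHRASE_VALENCE: Mapping[str, float] = {
    "absolutely love it": 0.62,
    "tastes amazing": 0.55,
    "really enjoying this one": 0.38,
    "would recommend": 0.30,
    "hits just right": 0.21,
    "not sure yet": 0.02,
    "just picked this up": 0.0,
    "anyone tried this": 0.0,
    "arrived yesterday": -0.02,
    "kind of underwhelming": -0.22,
    "really disappointed": -0.41,
    "tastes awful": -0.58,
    "absolutely hate it": -0.66,
}


class PhraseLexiconScorer:
    """Deterministic lexicon scorer over a fixed phrase table.

    Returns the valence of the first known phrase found in the text (scanning
    in phrase-table order), or 0.0 when no phrase is present. Intended for
    synthetic corpora whose texts embed exactly one lexicon phrase.
    """

    def __init__(self, lexicon: Mapping[str, float] = PHRASE_VALENCE) -> None:
        self.lexicon = dict(lexicon)

    def score(self, text: str) -> float:
        lowered = text.lower()
        for phrase, valence in self.lexicon.items():
            if phrase in lowered:
                return valence
        return 0.0


class VaderScorer:
    """Adapter over the VADER compound score (optional ``vader`` extra)."""

    def __init__(self) -> None:
        try:
            from vaderSentiment.vaderSentiment import SentimentIntensityAnalyzer
        except ImportError as exc:  # pragma: no cover - extra not installed
            raise ImportError(
                "VaderScorer requires the optional dependency vaderSentiment; "
                "install flavorwatch[vader]"
            ) from exc
        self._analyzer = SentimentIntensityAnalyzer()

    def score(self, text: str) -> float:  # pragma: no cover - extra not installed
        return float(self._analyzer.polarity_scores(text)["compound"])


# -- aggregation ----------------------------------------------------------


def aggregate_category(
    scored: pd.DataFrame,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Per-category sentiment summary.

    ``scored`` needs columns ``category``, ``score``, ``label``. Returns one
    row per category with post count, mean and sample (n-1) standard
    deviation of the scores, per-label counts, label proportions (normalized
    by the category post count, so they sum to 1), and ``flagged`` marking
    categories below ``min_count`` — mirroring the practice of dropping
    sparse categories from comparative analysis.
    """
    required = {"category", "score", "label"}
    if not required.issubset(scored.columns):
        raise ValueError(f"scored frame must have columns {sorted(required)}")
    rows = []
    for category, group in scored.groupby("category", sort=True):
        n = len(group)
        n_pos = int((group["label"] == "positive").sum())
        n_neu = int((group["label"] == "neutral").sum())
        n_neg = int((group["label"] == "negative").sum())
        rows.append(
            {
                "category": category,
                "n_posts": n,
                "mean_score": float(group["score"].mean()),
                "sd_score": float(group["score"].std(ddof=1)) if n > 1 else np.nan,
                "n_pos": n_pos,
                "n_neu": n_neu,
                "n_neg": n_neg,
                "prop_pos": n_pos / n,
                "prop_neu": n_neu / n,
                "prop_neg": n_neg / n,
                "flagged": n < min_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_posts",
            "mean_score",
            "sd_score",
            "n_pos",
            "n_neu",
            "n_neg",
            "prop_pos",
            "prop_neu",
            "prop_neg",
            "flagged",
        ],
    )
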