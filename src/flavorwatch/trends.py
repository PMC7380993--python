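"""Monthly per-category flavor-mention counting and normalization.

Counts are mention-level (a post matching flavors from several categories
contributes one count per distinct matched keyword), bucketed by UTC
calendar month and normalized within each month by the monthly total so
that category shares are comparable across months of very different
activity. The category axis is fixed to the seven taxonomy categories so
every month has the same rows.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import MonthKey, Post, month_of, month_range
from .filtering import FlavorMention
from .taxonomy import CATEGORIES, FlavorTaxonomy

log = logging.getLogger(__name__)

__all__ = [
    "TrendsError",
    "monthly_counts",
    "normalize",
    "subcategory_percentages",
    "percentage_table",
    "round2_half_up",
]


class TrendsError(ValueError):
    """Raised for inconsistent trend inputs (e.g. unknown post ids)."""


def monthly_counts(
    mentions: Iterable[FlavorMention],
    posts: Mapping[str, Post] | Iterable[Post],
    start: MonthKey | str | None = None,
    end: MonthKey | str | None = None,
    categories: Sequence[str] = CATEGORIES,
) -> pd.DataFrame:
    """Mention counts per (month, category).

    Returns a DataFrame with columns ``year, month, category, count`` covering
    every month in [start, end] (defaulting to the span of the data) crossed
    with every category, zeros included. A mention whose post id is absent
    from ``posts`` is an error.
    """
    if not isinstance(posts, Mapping):
        posts = {p.id: p for p in posts}
    counts: dict[tuple[MonthKey, str], int] = {}
    months_seen: set[MonthKey] = set()
    for mention in mentions:
        try:
            post = posts[mention.post_id]
        except KeyError:
            raise TrendsError(f"mention references unknown post id {mention.post_id!r}")
        key = month_of(post)
        months_seen.add(key)
        counts[(key, mention.path.category)] = counts.get((key, mention.path.category), 0) + 1
    if start is None or end is None:
        if not months_seen:
            raise TrendsError("no mentions and no explicit month range given")
        ordered = sorted(months_seen)
        start = start or ordered[0]
        end = end or ordered[-1]
    rows = [
        {
            "year": mk.year,
            "month": mk.month,
            "category": cat,
            "count": counts.get((mk, cat), 0),
        }
        for mk in month_range(start, end)
        for cat in categories
    ]
    return pd.DataFrame(rows, columns=["year", "month", "category", "count"])


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Fill per-month category proportions.

    Adds ``proportion`` (count / monthly total) and ``empty_month`` (True for
    months with zero total, whose proportions are reported as 0). Within any
    non-empty month the proportions sum to 1.
    """
    out = table.copy()
    totals = out.groupby(["year", "month"])["count"].transform("sum")
    out["empty_month"] = totals == 0
    out["proportion"] = 0.0
    nonzero = ~out["empty_month"]
    out.loc[nonzero, "proportion"] = out.loc[nonzero, "count"] / totals[nonzero]
    n_empty = out.loc[out["empty_month"], ["year", "month"]].drop_duplicates().shape[0]
    if n_empty:
        log.warning("%d month(s) had zero flavor mentions; proportions set to 0", n_empty)
    return out


def round2_half_up(numerator: int, denominator: int) -> float:
    """Exact half-up rounding of 100*numerator/denominator to 2 decimals."""
    scaled = Fraction(100 * numerator, denominator) * 100
    return math.floor(scaled + Fraction(1, 2)) / 100


def percentage_table(counts: Mapping[str, int]) -> pd.DataFrame:
    """Percent distribution over a mapping of label -> count.

    Percentages are 100*count/total rounded half-up to two decimals; rows are
    ordered by descending count then label. An empty (or all-zero) mapping
    yields an empty table.
    """
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["subcategory", "count", "percent"])
    rows = [
        {"subcategory": label, "count": n, "percent": round2_half_up(n, total)}
        for label, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["subcategory", "count", "percent"])


def subcategory_percentages(
    mentions: Iterable[FlavorMention],
    category: str,
    tax: FlavorTaxonomy | None = None,
) -> pd.DataFrame:
    """Within-category percent distribution of mentions over subcategories.

    When a taxonomy is supplied, subcategories with zero mentions are still
    listed (count 0); otherwise only observed subcategories appear.
    """
    counts: dict[str, int] = {}
    if tax is not None:
        counts = {sub: 0 for sub in tax.subcategories_of(category)}
    for mention in mentions:
        if mention.path.category == category:
            counts[mention.path.subcategory] = counts.get(mention.path.subcategory, 0) + 1
    return percentage_table(counts)
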