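"""Two-proportion z-tests with Bonferroni correction.

Within each flavor category the share of positive posts is compared with the
share of negative posts using the textbook pooled-variance two-proportion
z-test (no continuity correction), two-sided. Family-wise error over the
categories tested is controlled by Bonferroni: p_adj = min(1, m * p), with
significance declared at p_adj < alpha (strict).

Treating the positive and negative counts of the same category as two
independent samples (each with the category post total as its denominator)
is statistically loose — the two proportions share a denominator and are
negatively correlated — but it is the comparison the surveillance design
calls for, and it is what this module implements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ZTestResult", "two_prop_ztest", "bonferroni", "positive_vs_negative_tests"]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ZTestResult:
    z: float  # nan when degenerate
    p_raw: float
    degenerate: bool = False


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(phat*(1-phat)*(1/n1 + 1/n2)) with
    phat = (x1+x2)/(n1+n2). When the pooled proportion is 0 or 1 the
    statistic is undefined; the result is flagged degenerate with p_raw = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(z=math.nan, p_raw=1.0, degenerate=True)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p_raw = 2.0 * sps.norm.sf(abs(z))
    return ZTestResult(z=z, p_raw=float(p_raw))


def bonferroni(
    p_values: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjust a family of p-values.

    Returns (p_adj, significant) with p_adj = min(1, m*p) for m = len(p_values)
    and significance at p_adj < alpha (strict, so a p_adj exactly equal to
    alpha is not significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p_adj = np.minimum(1.0, p * p.size)
    return p_adj, p_adj < alpha


def positive_vs_negative_tests(
    summary: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Compare positive vs negative post shares within each category.

    ``summary`` is the per-category frame from
    :func:`flavorwatch.sentiment.aggregate_category`; rows with
    ``flagged=True`` (sparse categories) are dropped before testing, and the
    Bonferroni multiplier m is the number of categories actually tested.
    ``direction`` is positive_dominant / negative_dominant for significant
    results (by sign of z) and none otherwise.
    """
    tested = summary.loc[~summary["flagged"]].reset_index(drop=True)
    results = [
        two_prop_ztest(int(row.n_pos), int(row.n_posts), int(row.n_neg), int(row.n_posts))
        for row in tested.itertuples()
    ]
    p_adj, significant = bonferroni([r.p_raw for r in results], alpha=alpha)
    out = pd.DataFrame(
        {
            "category": tested["category"],
            "n_posts": tested["n_posts"],
            "prop_pos": tested["prop_pos"],
            "prop_neg": tested["prop_neg"],
            "z": [r.z for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adj": p_adj if len(results) else [],
            "significant": significant if len(results) else [],
            "degenerate": [r.degenerate for r in results],
        }
    )
    def _direction(row: pd.Series) -> str:
        if not row["significant"] or row["degenerate"]:
            return "none"
        return "positive_dominant" if row["z"] > 0 else "negative_dominant"

    out["direction"] = out.apply(_direction, axis=1) if len(out) else pd.Series(dtype=str)
    return out
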