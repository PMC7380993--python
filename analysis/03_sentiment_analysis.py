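#!/usr/bin/env python
"""Category-level sentiment analysis on the synthetic Twitter-style corpus.

Runs the sentiment workflow — topic filter, two-step promotion filter,
single-flavor subset, deterministic stub scoring, per-category aggregation,
positive-vs-negative two-proportion z-tests with Bonferroni correction —
and writes the per-post scores, category summary, test table and stage
manifest under results/. Run 01_simulate_corpora.py first.
"""

import json
from pathlib import Path

import pandas as pd

from flavorwatch.corpus import read_posts
from flavorwatch.filtering import denoise_keywords
from flavorwatch.pipeline import PipelineConfig, run_sentiment
from flavorwatch.sentiment import PhraseLexiconScorer
from flavorwatch.synth import AMBIGUOUS_KEYWORD_PATHS
from flavorwatch.taxonomy import bundled_taxonomy

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def main() -> None:
    posts = list(read_posts(ROOT / "scratch" / "synthetic_twitter.jsonl"))
    ledger = pd.read_csv(ROOT / "scratch" / "ledger_twitter.csv")
    by_id = {p.id: p for p in posts}

    tax = bundled_taxonomy()
    for kw, (cat, sub) in AMBIGUOUS_KEYWORD_PATHS.items():
        tax = tax.with_keyword(cat, sub, kw)
    noisy = ledger[ledger["noisy_keyword"].notna()]
    labeled = [
        (row.noisy_keyword, by_id[row.post_id], bool(row.is_relevant))
        for row in noisy.itertuples()
    ]
    _, excluded = denoise_keywords(labeled, tax)

    result = run_sentiment(
        posts, tax, PhraseLexiconScorer(),
        PipelineConfig(apply_promo_filter=True, excluded_flavors=tuple(sorted(excluded))),
    )
    RESULTS.mkdir(exist_ok=True)
    result.scores.to_csv(RESULTS / "post_scores.csv", index=False)
    result.summary.to_csv(RESULTS / "category_sentiment.csv", index=False)
    result.tests.to_csv(RESULTS / "proportion_tests.csv", index=False)
    (RESULTS / "manifest_sentiment.json").write_text(
        json.dumps(result.manifest.as_dict(), indent=2)
    )

    print("corpus funnel:")
    for s in result.manifest.stages:
        print(f"  {s.stage:<22} in={s.n_in:>6} out={s.n_out:>6} removed={s.n_removed:>6}")
    print("\nper-category sentiment (flagged categories excluded from tests):")
    cols = ["category", "n_posts", "mean_score", "prop_pos", "prop_neg", "flagged"]
    print(result.summary[cols].to_string(index=False))
    print("\npositive-vs-negative z-tests (Bonferroni-adjusted):")
    cols = ["category", "z", "p_adj", "significant", "direction"]
    print(result.tests[cols].to_string(index=False))


if __name__ == "__main__":
    main()
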