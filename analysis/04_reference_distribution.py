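#!/usr/bin/env python
"""Percentage distribution of the reference Reddit flavor-mention counts.

Feeds the bundled per-category and per-subcategory mention counts from the
large-scale Reddit surveillance corpus through the exact half-up percentage
tables and writes them under results/. This is the printed-count companion
to the synthetic trend analysis: it shows the distribution machinery on
real-corpus magnitudes.
"""

import io
from importlib import resources
from pathlib import Path

import pandas as pd

from flavorwatch.trends import percentage_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def load(name: str) -> pd.DataFrame:
    text = resources.files("flavorwatch.data").joinpath(name).read_text("utf-8")
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    categories = load("reddit_category_counts.tsv")
    cat_table = percentage_table(dict(zip(categories["category"], categories["count"])))
    cat_table = cat_table.rename(columns={"subcategory": "category"})
    cat_table.to_csv(RESULTS / "reference_category_percentages.csv", index=False)
    print("category distribution (share of all flavor mentions):")
    print(cat_table.to_string(index=False))

    subcounts = load("reddit_subcategory_counts.tsv")
    frames = []
    for category, group in subcounts.groupby("category", sort=False):
        table = percentage_table(dict(zip(group["subcategory"], group["count"])))
        table.insert(0, "category", category)
        frames.append(table)
        top = table.iloc[0]
        print(f"\n{category}: dominant subcategory is {top['subcategory']} "
              f"({top['percent']:.2f}% of {int(group['count'].sum())} mentions)")
    pd.concat(frames).to_csv(RESULTS / "reference_subcategory_percentages.csv", index=False)
    print(f"\ntables -> {RESULTS}")


if __name__ == "__main__":
    main()
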