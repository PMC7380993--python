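#!/usr/bin/env python
"""Generate the two synthetic study corpora with ground-truth ledgers.

Produces a Reddit-style longitudinal corpus (Jan 2013 - Apr 2019, no
promotional posts, mild upward fruit drift) and a Twitter-style snapshot
corpus (May - Aug 2019, 15% promotional posts), each 20,000 posts, under
scratch/ (corpora are bulky, regenerable artifacts); a compact role/category
summary of the planted ground truth goes to results/.
"""

from pathlib import Path

import pandas as pd

from flavorwatch.synth import GeneratorConfig, generate

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 20_19


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    summaries = []
    for name, config in [
        ("reddit", GeneratorConfig.reddit_default(seed=SEED, n_posts=20_000)),
        ("twitter", GeneratorConfig.twitter_default(seed=SEED + 1, n_posts=20_000)),
    ]:
        corpus = generate(config)
        corpus.write(SCRATCH / f"synthetic_{name}.jsonl", SCRATCH / f"ledger_{name}.csv")
        roles = corpus.ledger["role"].value_counts()
        cats = corpus.ledger.loc[
            corpus.ledger["role"] == "normal", "category"
        ].value_counts(normalize=True)
        print(f"{name}: {len(corpus.posts)} posts -> scratch/synthetic_{name}.jsonl")
        print(f"  roles: {{{', '.join(f'{k}: {int(v)}' for k, v in roles.items())}}}")
        print(f"  planted flavor shares: "
              + ", ".join(f"{c}={v:.3f}" for c, v in cats.items()))
        for role, count in roles.items():
            summaries.append({"corpus": name, "kind": "role", "key": role, "value": count})
        for cat, share in cats.items():
            summaries.append(
                {"corpus": name, "kind": "planted_share", "key": cat,
                 "value": round(float(share), 4)}
            )
    pd.DataFrame(summaries).to_csv(RESULTS / "simulation_summary.csv", index=False)
    print(f"ground-truth summary -> {RESULTS / 'simulation_summary.csv'}")


if __name__ == "__main__":
    main()
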