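# Methods

## The surveillance problem

E-liquid (the flavored nicotine solution vaporized by e-cigarettes) is sold
under thousands of flavor names. Monitoring which flavor families dominate
social-media discussion, how that evolves, and whether users speak of them
positively or negatively gives regulators a cheap, timely complement to
surveys. `flavorwatch` implements that monitoring pipeline over post corpora
in JSON-lines form and validates it end to end on synthetic corpora with
known planted structure.

## Flavor taxonomy and term classification

The classification is three-level: 7 major categories (fruit, sweets,
beverage, tobacco, menthol_or_mint, mixed, others), subcategories within
each (e.g. fruit → berry / tropical / citrus / melon / mixed_fruit /
others), and specific flavor keywords at the leaves. Two categories are
structural and mandatory: `mixed` for flavors whose configured ingredients
span ≥ 2 distinct non-`others` categories, and `others` for anything
unresolvable. Classification of a term is total and deterministic: keyword
in the taxonomy → its stored path; configured ingredients in ≥ 2 categories
→ (mixed, mixed, term); exactly one implied category → that category's
catch-all subcategory; otherwise (others, others, term).

Design choices made where the design was open:

* **Config format.** One tab-separated row per keyword
  (category, subcategory, keyword, optional aliases, optional ingredient
  categories) — hand-editable and diff-able. Validation is strict: a
  keyword under two paths, a missing fallback category, an empty level, or
  an alias colliding with a keyword is an error, never a warning.
* **Multi-ingredient detection is config-driven only.** Compound names are
  not parsed automatically; a flavor is "mixed" because its config row says
  so (mirroring that real flavor→ingredient assignment is a manual,
  catalog-driven step). The bundled fixture carries four concrete
  two-ingredient flavors (e.g. `strawberry mint` = fruit + menthol_or_mint)
  to exercise this path.
* **Bundled fixture scope.** The fixture reproduces a published seven-
  category flavor table's printed keywords (~110 leaves with a few plural
  aliases); real deployments would extend it from vendor catalogs. The
  `menthol or mint` category is stored as `menthol_or_mint` with `menthol`
  and `mint` subcategories.

## Matching semantics

All body matching lower-cases the text, strips `#` where it introduces a
hashtag (so `#vaping` matches `vaping`, with mention spans mapped back to
the original text), and requires Unicode word boundaries — `vape` never
matches inside `grapevine`. Multi-word keywords match across single spaces.
Flavor extraction is longest-match-first and non-overlapping (`cotton
candy` beats hypothetical shorter matches at the same position), and alias
matches resolve to their canonical keyword. Substring matching without
boundaries is exactly the failure mode the denoise step exists to repair,
so boundaries are the default everywhere; author-handle screening in the
promotion filter is deliberately substring-based instead, because vendor
handles concatenate words (`BestVapeStore`).

A consequence of longest-match extraction worth knowing: excluding a
compound keyword (e.g. `ice cream`) legitimately exposes a shorter keyword
nested inside it (`cream`), so mention counts are monotone in the exclusion
set only for atomic keywords.

## Corpus reduction stages

1. **Topic filter**: keep posts matching ≥ 1 of 20 e-cigarette keywords
   (`vape`, `juul`, `e-liquid`, …; shipped as editable config).
2. **Promotion filter** (two observable steps, used for Twitter-style
   corpora): drop posts whose author handle contains a promotion keyword
   (`store`, `deal`, `supply`, product terms) as a substring; then drop
   posts whose body matches marketing vocabulary (`customer`, `promotion`,
   `discount`, `sale`, `free shipping`) at token boundaries. The body list
   ships with exactly those five terms and is user-extensible. Whether the
   promotion filter runs is a per-platform toggle (on for Twitter-style
   corpora, off for Reddit-style trend runs, where no promotion screening
   is part of the workflow).
3. **Keyword denoising**: ambiguous flavor names (`punch`, `contact`) are
   evaluated on labeled samples (post, is-the-usage-a-flavor). Predicted
   positive = the extractor matches the keyword. Keep iff precision ≥ 0.90
   **and** recall ≥ 0.75; undefined ratios (zero denominators) exclude.
   Excluded keywords are removed from matching entirely.
4. **Single-flavor subset** (sentiment workflow only): keep posts with
   exactly one *distinct* canonical flavor keyword (repeats and aliases of
   the same flavor count once), so each scored post maps to one category.

Every stage records input/output/removed counts in a run manifest
(`n_in = n_out + n_removed` at each stage), making the corpus funnel fully
auditable.

## Trends

Counting is mention-level: a post matching flavors in several categories
contributes one count per distinct matched keyword. Counts are bucketed by
UTC calendar month (both major platform archives deliver UTC timestamps;
no local-time interpretation is ever applied) over a fixed 7-category axis,
with explicit zero rows for quiet months. Normalization divides each
month's category counts by that month's total mention count; all-zero
months are flagged and reported as zero proportions with a warning.
Percentage tables round 100·count/total half-up to two decimals using exact
rational arithmetic, so printed-count inputs reproduce published two-decimal
tables bit-for-bit.

## Sentiment

A scorer is an injected contract: any object with `score(text) -> float in
[−1, 1]` (violations raise). Labels follow the standard compound-score
thresholds — negative on [−1, −0.05], neutral on the open interval
(−0.05, +0.05), positive on [+0.05, +1]; the boundaries are polar. Two
scorers ship: an adapter over the VADER compound score (optional extra, for
real corpora), and a deterministic phrase-lexicon stub keyed to the
13-phrase table the synthetic generator writes with, so validation never
depends on a third-party lexicon's exact weights.

Per-category aggregation reports n, mean, sample (n−1) SD (the convention
choice is immaterial at surveillance sample sizes), label counts and
proportions (normalized by the category total, summing to 1), and flags
categories below a minimum post count — default 300, reflecting that
miscellaneous categories (mixed, others) typically fall one-to-two orders
of magnitude below the majors and are excluded from comparative testing.

## Hypothesis testing

Within each unflagged category the positive share is compared with the
negative share by the pooled-variance two-proportion z-test without
continuity correction (the textbook default of standard statistical
packages), two-sided, with both arms' denominators equal to the category
post total. Treating the two shares of the same sample as independent arms
is statistically loose — they share a denominator and are negatively
correlated, making the test conservative in the direction of interest —
but it is the comparison this surveillance design specifies, and it is
documented rather than silently "fixed". Degenerate pooled proportions
(0 or 1) are flagged with p = 1. Bonferroni adjustment uses m = number of
categories actually tested; significance is strict p_adj < α (α = 0.05).
Implementation agreement with an independent reference (statsmodels'
pooled test) is part of the test suite (≤ 1e-8 over random configurations),
as is null calibration (rejection 0.05 ± 0.01 at n = 200 per arm, 10,000
replicates).

## Synthetic corpus generator

The generator is first-class, tested code and defines the validation
conditions. Defaults: 20,000 posts; planted category distribution fruit
0.58, sweets 0.15, beverage 0.10, menthol_or_mint 0.08, tobacco 0.06,
others 0.02, mixed 0.01 (the fruit-dominant profile characteristic of
flavor discussion); per-category sentiment mixes positive-leaning for
fruit/sweets/menthol_or_mint (pos−neg ≈ +0.3) and negative-leaning for
beverage/tobacco; off-topic fraction 0.05; multi-flavor fraction 0.05;
promotional fraction 0.15 for Twitter-style corpora and 0 for Reddit-style
ones; ambiguous-keyword fraction 0.02 with `punch` and `contact` planted at
flavor-sense probabilities 0.60/0.65 (both below the 0.90 precision bar, as
such names fare in practice). The Reddit-style preset spans Jan 2013–Apr
2019 with a mild linear fruit-up/sweets-down drift; the Twitter-style
preset spans May–Aug 2019.

Mechanics: role counts (off-topic / promo / noisy / normal) are exact, then
shuffled; ambiguous-keyword relevance uses exact planted counts so sample
precision equals the configured value up to rounding; categories, months,
keywords, templates and sentiment phrases are drawn from one named
`numpy` generator threaded through everything — same seed, byte-identical
corpus. Texts are short template sentences that deliberately exercise the
matcher: hashtag topic tags, multi-word keywords, token-boundary traps
(`grapevine`), and vendor-style handles. Each post embeds exactly one
phrase from the sentiment lexicon, so the stub scorer recovers planted
valences exactly; multi-flavor posts draw their second keyword from the
same category distribution, keeping the mention-level category shares at
their planted values in expectation.

What the generator does *not* emulate — and hence what passing tests do not
show: real linguistic variation (misspellings, slang, sarcasm, emoji),
correlated posting behaviour (threads, reposts, bursts beyond the planted
drift), platform metadata quirks, or a real lexicon's scoring noise.
Recovery results validate the pipeline's bookkeeping and statistics, not
the field accuracy of any particular sentiment lexicon on vaping text.

## Problem sizes and numerical choices

End-to-end validation uses 20,000-post corpora (mention-level binomial SEs
≈ 0.004 at the fruit share, comfortably separating all planted categories
at 3 SE), 10,000 replicates for null calibration, and 10,000-point grids
for the threshold partition. Proportions use plain floating point;
percentage rounding uses `fractions.Fraction` for exact half-up ties.
Degenerate inputs are first-class: empty months are flagged rather than
dropped, empty categories yield empty tables, zero-denominator
precision/recall excludes the keyword, and degenerate z-tests are flagged
with p = 1.

## Known limitations

* The bundled taxonomy covers a published table's printed exemplar keywords,
  not a full vendor-catalog flavor list; coverage of real corpora depends on
  extending it.
* Published reference percentage tables are reproduced from their printed
  counts; a handful of published cells follow truncation rather than
  rounding and differ by 0.01 from the half-up values this package computes.
* The positive-vs-negative test's independence assumption is inherited from
  the surveillance design (see above).
* Reddit-scale real corpora (millions of posts) are out of scope for the
  bundled analyses; the pipeline streams posts but holds mentions and
  tables in memory, which is ample at the 10⁴–10⁶ mention scale.
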