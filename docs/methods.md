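# Methods

## The scoring model

A rubric is a two-level weighted checklist: categories partition items,
and each item awards an integer score between 0 and its maximum. Binary
items (max 1) record presence/absence of a practice; scaled items grade
degree. There is no weighting beyond the per-item maxima and no partial
credit between integers. Category subtotals, the grand total, and the
percentage are pure sums — the model's value is in the instrument
(which items, which maxima), not in the arithmetic, which is why rubrics
are data (YAML/JSON documents) rather than code.

The packaged NAIIS dQAS rubric has 34 items in 5 categories with maxima
38 (data validity), 5 (reliability), 9 (precision), 8 (timeliness) and
21 (integrity), total 81. The published record does not list per-item
maxima; they are reconstructed from the fact that the NAIIS assessment
attained full marks on every item except the data-entry-sample ratio
(2 of a stated maximum 3) and the Database Transparency Index (2 of a
stated maximum 4). Setting every other item's maximum equal to its
achieved score reproduces all five published category maxima exactly,
which is the consistency check the fixture relies on. The precision
category is encoded with the three itemized rows (VMR, OMR, duplicate
ratio) whose maxima 4+4+1 reconcile with the category maximum of 9,
although a count of "4 items" also circulates for that category.

### Classification bands

Band thresholds are inclusive lower bounds on the unrounded percentage:
Exceptional ≥95, Outstanding [90, 95), Excellent [85, 90), Very Good
[80, 85), Good [75, 80), Fair [65, 75), Poor [0, 65). Treating each
threshold as inclusive-lower closes the nominal gaps between bands
quoted as, e.g., "90%–94%" and "≥95%", so the bands tile [0, 100].
Score ranges per band are *derived* from the thresholds
(`minimum_score_for_band` = ⌈threshold · max/100⌉, giving 77 and 73 for
Exceptional and Outstanding on 81 points) rather than stored, because
published score-range renderings of these bands are internally
inconsistent while the percentage thresholds are not. Classification
uses the unrounded percentage; only display rounds, half-up, to one
decimal.

## Data-driven metrics

Definitions for the missingness ratios are a genuine design choice; the
instrument names them without formalizing them. The defaults are:

- **VMR** = mean over variables of the per-variable missing-cell
  fraction; **OMR** is the row-wise dual. Both live in [0, 1], are each
  equal to the overall missing-cell fraction (so they satisfy a
  cell-count conservation property used in tests), and reduce to each
  other under transposition. An alternative "fraction of
  variables/rows with any missingness" definition is available via a
  flag, since some audits use that stricter reading.
- **Duplicate ratio** = (rows − distinct rows)/rows, with full-record
  exact equality after whitespace trimming. Probabilistic or key-based
  record linkage is deliberately out of scope: the metric is a
  database-hygiene signal, not a deduplication tool.
- **DESR** = 1000 · personnel / records-per-day. Records entered per
  day is used as the denominator; it is the only reading consistent
  with the NAIIS worked value of 13 per 1000 from 18 staff and 1380
  records/day.

Missing-value tokens are configurable (default: empty cell, `NA`, `.`)
because export dialects vary; cells are compared after trimming.

### Metric-to-score maps

Cut-points mapping a metric value to an item score are deployment
policy, so they ship as editable YAML (`[lower, upper, score]` half-open
intervals; the final upper bound is treated as closed so a ratio of
exactly 1 is mapped). The default DESR map — [0,5)→0, [5,10)→1,
[10,20)→2, [20,∞)→3 — is calibrated to the one fixed point available:
a DESR of 13 must score 2 on the 0–3 scale, and a higher DESR (better
staffing) must never score lower. The VMR/OMR defaults step down at
1%, 5%, 10% and 20% missingness, conventional audit thresholds; the
duplicate map gives its single point only below 1% duplication.
Monotonicity in the declared direction is enforced at load time.

## e-Delphi consensus

Panelists rate each candidate metric on four criteria (relevance,
measurability, clarity, conciseness) with a 7-point Likert scale.
Aggregation averages the four criteria within each panelist, then
averages panelists; the escalation rule instead uses the four-criterion
*sum* (4–28 per panelist), averaged over panelists, with metrics above
20 points referred to an additional reviewer when they fail two-reviewer
consensus — the threshold is configurable. Ranks are dense and ties
share a rank. The median cut-off keeps metrics rated at or above the
group median; the median of an even-sized list is the midpoint of the
two central order statistics, and ties at the median are included, so
the retained set is never empty. The number of rounds is a parameter
(real uses run three or more); an optional stop rule (retained set
unchanged between rounds) exists but is off by default. Panelist
identifiers are salted-hashed at ingest with a run-scoped salt, so
rounds link without raw identities persisting.

The three rules (consensus, escalation, median cut-off) are exposed
separately rather than fused into one pipeline, because how a study
composes them across internal and external panels is a protocol choice,
not a property of the rules.

## Synthetic data

The generator emulates exactly the structure the metrics assume:
per-cell independent Bernoulli missingness at `missing_rate`, and
duplication by replacing the last ⌊duplicate_rate · n⌋ rows with uniform
draws from the earlier rows. Missingness is applied *before* the copy
so injected duplicates are exact duplicates at any missing rate, which
keeps the expected duplicate ratio analytically known
(⌊duplicate_rate · n⌋/n). Copied cells are marginally Bernoulli but
correlated with their source row, slightly inflating the variance of
the realized missing fraction; recovery tests use a 3-standard-error
band that absorbs this. Panel sheets draw integer-rounded Gaussian
noise around a per-metric latent quality, clipped to 1–7.

What the generator does **not** emulate: questionnaire content,
structured (non-ignorable) missingness, near-duplicates from data-entry
error, sampling weights, or rater-specific Delphi biases (leniency,
anchoring). Passing recovery tests therefore shows the estimators are
correct under independence, not that real survey exports are this
well-behaved.

Default check sizes — 2000×10 tables for recovery, 50 panelists for
median-cut-off separation, 200 randomized cases per property — are
chosen so that binomial standard errors are small relative to the
effects checked while the whole suite runs in seconds.

## Numerical and degenerate-input choices

- Percentage arithmetic is exact integer division rendered through
  `Decimal` for the half-up display rounding; classification never sees
  a rounded value.
- A rubric with zero maximum total is rejected before scoring.
- Empty tables profile to all-zero fractions; ratios over zero rows are
  errors, not NaNs.
- `score_metric` rejects values outside the mapped range and NaN rather
  than clamping: an out-of-range metric value signals a mis-specified
  map, which an audit tool should surface.
- In the workflow, a supplied score conflicting with a computed
  data-driven score is an error by default; the computed value wins
  only under an explicit flag, and the override is logged. The tool
  never infers judgment items.

## Known limitations

- Duplicate detection is exact-match only; a single corrected keystroke
  hides a duplicate.
- The rubric model supports one consolidated response per database; it
  does not reconcile multiple independent assessors.
- The Delphi engine reproduces the selection *rules*; the actual
  historical panel ratings behind the NAIIS instrument are not public,
  so no end-to-end re-derivation of the 34-item set is possible, and
  the engine is validated on toy and synthetic panels instead.
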