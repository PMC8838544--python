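# dqas — Database Quality Assurance Score toolkit

`dqas` scores the technical quality of survey databases against weighted
rubrics, with the instrument developed for the 2018 Nigeria AIDS Indicator
and Impact Survey (NAIIS) — the largest population-based HIV survey
conducted to date — shipped as the canonical example. It is aimed at data
managers, independent study monitors, and survey methodologists who need a
reproducible, auditable quality score for a database rather than an ad-hoc
checklist.

## What it computes

**Rubric scoring.** A rubric is an ordered set of categories, each holding
items with integer maxima. For an assessment awarding score $s_i \in
[0, m_i]$ on item $i$, the toolkit reports per-category subtotals, the
grand total $T = \sum_i s_i$, the percentage $P = 100\,T / \sum_i m_i$, and
an ordinal classification from percentage bands (Exceptional $\ge 95$,
Outstanding $[90, 95)$, Excellent $[85, 90)$, Very Good $[80, 85)$, Good
$[75, 80)$, Fair $[65, 75)$, Poor $[0, 65)$). The packaged NAIIS dQAS
rubric has 34 items in 5 categories (data validity, database reliability,
database precision, timeliness, database integrity) with maxima
38/5/9/8/21 and a grand maximum of 81.

**Data-driven metrics.** Four rubric items are computed directly from
data rather than judged:

- **VMR / OMR** — variable / observation missing ratio: the mean
  per-column / per-row missing-cell fraction of a tabular export;
- **duplicate ratio** — fraction of records that are exact copies of an
  earlier record;
- **DESR** — data-entry-sample ratio, $1000 \cdot
  \text{personnel} / \text{records per day}$: staffing adequacy of the
  data-entry operation.

Metric values map to item scores through configurable interval maps.

**e-Delphi consensus.** The expert-panel procedure used to construct such
instruments: 7-point Likert ratings on four criteria (relevance,
measurability, clarity, conciseness), averaged per metric and ranked;
two-reviewer consensus with escalation of highly rated leftovers; and the
group-median inclusion cut-off applied over anonymous iterative rounds.

## Worked example

```sh
$ dqas score
Quality assessment: naiis-dqas
--------------------------------
Data validity          37 / 38
Database reliability    5 / 5
Database precision      9 / 9
Timeliness              8 / 8
Database integrity     19 / 21
--------------------------------
Total                  78 / 81
Percentage: 96.3%
Classification: Exceptional
```

The NAIIS database lost one point on the data-entry-sample ratio (18 entry
staff at 1380 records/day gives a DESR of 13 per 1000, scoring 2 of 3) and
two points on the Database Transparency Index (2 of 4, reflecting limited
assessor access), for a total of 78 of 81 — 96.3%, the "Exceptional" band,
whose floor on an 81-point rubric is 77 points.

The same numbers are available from the library:

```python
from dqas import naiis_rubric, naiis_response, score_assessment
report = score_assessment(naiis_rubric(), naiis_response())
report.total, report.display_percentage, report.classification
# (78, 96.3, 'Exceptional')
```

Other entry points: `dqas profile --table export.csv` (VMR/OMR/duplicate
metrics), `dqas desr --personnel 18 --records-per-day 1380`, `dqas delphi
--ratings sheet.csv --round 1`, and `dqas synth table|panel` for seeded
synthetic inputs.

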