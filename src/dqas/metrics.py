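"""Data-driven quality metrics over tabular survey exports.

The database-precision items of the dQAS are computable directly from an
export rather than judged:

* **VMR** (variable missing ratio) — missingness summarized over columns;
  by default the mean per-variable missing fraction.
* **OMR** (observation missing ratio) — the row-wise dual of VMR.
* **Duplicate ratio** — fraction of records that are exact copies of an
  earlier record (rows minus distinct rows, over rows).
* **DESR** (data-entry-sample ratio) — data-management personnel per 1000
  records entered per day: ``1000 * n_personnel / records_per_day``. The
  NAIIS operation ran 18 entry staff at 1380 records/day, a DESR of 13
  per 1000 which scores 2 of 3 under the default map.

Metric values are mapped to rubric item scores through configurable
interval maps (:class:`MetricScoreMap`); cut-points are deployment policy,
so they ship as editable data with sensible defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "DataTable",
    "DatasetProfile",
    "ThroughputRecord",
    "MetricScoreMap",
    "profile_table",
    "vmr",
    "omr",
    "duplicate_ratio",
    "desr",
    "score_metric",
    "default_metric_maps",
    "load_metric_maps",
]

DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "."})


@dataclass(frozen=True)
class DataTable:
    """A delimiter-separated survey export held as strings.

    Cells are compared after whitespace trimming; a trimmed cell equal to a
    missing token counts as missing. All rows must have one cell per
    variable (ragged exports are rejected at construction).
    """

    variables: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("table must have at least one variable")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.variables):
                raise ValueError(
                    f"ragged row {i}: {len(row)} cells, expected {len(self.variables)}"
                )

    @classmethod
    def from_records(
        cls,
        variables: Sequence[str],
        rows: Iterable[Sequence[object]],
        missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    ) -> "DataTable":
        return cls(
            variables=tuple(str(v) for v in variables),
            rows=tuple(tuple(str(c) for c in row) for row in rows),
            missing_tokens=frozenset(missing_tokens),
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        delimiter: str = ",",
        missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    ) -> "DataTable":
        """Read a header-rowed delimited file (RFC 4180 quoting via pandas)."""
        df = pd.read_csv(
            path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=False
        )
        return cls.from_records(df.columns, df.itertuples(index=False), missing_tokens)

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        pd.DataFrame(list(self.rows), columns=list(self.variables)).to_csv(
            path, sep=delimiter, index=False
        )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def _trimmed(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows), columns=range(self.n_vars), dtype=str)
        if df.empty:
            df = pd.DataFrame(columns=range(self.n_vars), dtype=str)
        return df.apply(lambda s: s.str.strip())


@dataclass(frozen=True)
class DatasetProfile:
    """Missingness and duplication summary of one export."""

    n_rows: int
    n_vars: int
    per_variable_missing_fraction: tuple[float, ...]
    per_row_missing_fraction: tuple[float, ...]
    n_duplicate_rows: int

    def __post_init__(self) -> None:
        for f in (*self.per_variable_missing_fraction, *self.per_row_missing_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"missing fraction {f} outside [0, 1]")
        if self.n_rows >= 1 and self.n_duplicate_rows > self.n_rows - 1:
            raise ValueError("more duplicates than rows minus one")

    @property
    def n_missing_cells(self) -> int:
        # Conservation: column-wise and row-wise totals agree by construction.
        return round(sum(self.per_variable_missing_fraction) * self.n_rows)


@dataclass(frozen=True)
class ThroughputRecord:
    """Data-entry staffing and throughput of a survey operation."""

    n_personnel: int
    records_per_day: float
    n_days: int | None = None

    def __post_init__(self) -> None:
        if self.n_personnel < 1:
            raise ValueError("n_personnel must be >= 1")
        if not self.records_per_day > 0:
            raise ValueError("records_per_day must be positive")

    @property
    def personnel_days(self) -> int | None:
        return None if self.n_days is None else self.n_personnel * self.n_days

    @property
    def total_entries(self) -> float | None:
        return None if self.n_days is None else self.records_per_day * self.n_days


def profile_table(table: DataTable) -> DatasetProfile:
    """Compute missingness fractions and the exact-duplicate row count.

    Duplicates are full-record equality after trimming whitespace; the count
    is ``rows - distinct rows``.
    """
    if table.n_vars == 0:
        raise ValueError("cannot profile a table with zero variables")
    if table.n_rows == 0:
        return DatasetProfile(
            n_rows=0,
            n_vars=table.n_vars,
            per_variable_missing_fraction=tuple(0.0 for _ in table.variables),
            per_row_missing_fraction=(),
            n_duplicate_rows=0,
        )
    df = table._trimmed()
    missing = df.isin(table.missing_tokens)
    per_var = tuple(float(f) for f in missing.mean(axis=0))
    per_row = tuple(float(f) for f in missing.mean(axis=1))
    n_distinct = len(df.drop_duplicates())
    return DatasetProfile(
        n_rows=table.n_rows,
        n_vars=table.n_vars,
        per_variable_missing_fraction=per_var,
        per_row_missing_fraction=per_row,
        n_duplicate_rows=table.n_rows - n_distinct,
    )


def vmr(
    profile: DatasetProfile,
    definition: Literal["mean_fraction", "any_missing"] = "mean_fraction",
) -> float:
    """Variable missing ratio.

    ``mean_fraction`` (default): mean over variables of the per-variable
    missing fraction — equals the overall missing-cell fraction.
    ``any_missing``: fraction of variables with at least one missing cell.
    """
    if profile.n_vars < 1:
        raise ValueError("profile has no variables")
    fracs = profile.per_variable_missing_fraction
    if definition == "any_missing":
        return sum(f > 0 for f in fracs) / profile.n_vars
    return float(sum(fracs) / profile.n_vars)


def omr(
    profile: DatasetProfile,
    definition: Literal["mean_fraction", "any_missing"] = "mean_fraction",
) -> float:
    """Observation missing ratio: the row-wise dual of :func:`vmr`."""
    if profile.n_rows < 1:
        raise ValueError("profile has no rows")
    fracs = profile.per_row_missing_fraction
    if definition == "any_missing":
        return sum(f > 0 for f in fracs) / profile.n_rows
    return float(sum(fracs) / profile.n_rows)


def duplicate_ratio(profile: DatasetProfile) -> float:
    """Fraction of records that are exact copies of an earlier record."""
    if profile.n_rows < 1:
        raise ValueError("profile has no rows")
    return profile.n_duplicate_rows / profile.n_rows


def desr(throughput: ThroughputRecord) -> float:
    """Data-entry-sample ratio: personnel per 1000 records entered per day."""
    return 1000.0 * throughput.n_personnel / throughput.records_per_day


@dataclass(frozen=True)
class MetricScoreMap:
    """Map metric values to integer item scores via half-open intervals.

    ``intervals`` is a sequence of ``(lower, upper, score)`` with
    ``lower <= value < upper``; intervals must partition a contiguous range.
    ``direction`` documents (and lets tests check) the monotone sense of the
    map: DESR maps are non-decreasing in the value, ratio maps non-increasing.
    """

    metric: str
    intervals: tuple[tuple[float, float, int], ...]
    direction: Literal["higher_is_better", "lower_is_better"] = "lower_is_better"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("metric map needs at least one interval")
        prev_upper: float | None = None
        for lower, upper, score in self.intervals:
            if not lower < upper:
                raise ValueError(f"empty interval [{lower}, {upper})")
            if prev_upper is not None and lower != prev_upper:
                raise ValueError("intervals must be contiguous and ordered")
            if score < 0:
                raise ValueError("scores must be non-negative")
            prev_upper = upper
        scores = [s for _, _, s in self.intervals]
        monotone = (
            all(a <= b for a, b in zip(scores, scores[1:]))
            if self.direction == "higher_is_better"
            else all(a >= b for a, b in zip(scores, scores[1:]))
        )
        if not monotone:
            raise ValueError(f"scores not monotone for direction {self.direction!r}")

    @property
    def lower_bound(self) -> float:
        return self.intervals[0][0]

    @property
    def upper_bound(self) -> float:
        return self.intervals[-1][1]

    @property
    def max_score(self) -> int:
        return max(s for _, _, s in self.intervals)


def score_metric(value: float, score_map: MetricScoreMap) -> int:
    """Integer score of the interval containing ``value``.

    The final interval's upper bound is treated as inclusive so a value at
    the top of a closed range (e.g. a ratio of exactly 1) is still mapped.
    """
    if math.isnan(value):
        raise ValueError("cannot score NaN")
    if value < score_map.lower_bound or value > score_map.upper_bound:
        raise ValueError(
            f"{score_map.metric} value {value} outside mapped range "
            f"[{score_map.lower_bound}, {score_map.upper_bound}]"
        )
    for lower, upper, score in score_map.intervals:
        if lower <= value < upper:
            return score
    return score_map.intervals[-1][2]  # value == upper_bound


def _maps_from_doc(doc: dict) -> dict[str, MetricScoreMap]:
    maps: dict[str, MetricScoreMap] = {}
    for name, spec in doc.items():
        intervals = tuple(
            (
                float(lo),
                math.inf if str(hi) == "inf" else float(hi),
                int(score),
            )
            for lo, hi, score in spec["intervals"]
        )
        maps[name] = MetricScoreMap(
            metric=name,
            intervals=intervals,
            direction=spec.get("direction", "lower_is_better"),
        )
    return maps


def load_metric_maps(path: str | Path) -> dict[str, MetricScoreMap]:
    """Load metric score maps from a YAML/JSON file."""
    doc = yaml.safe_load(Path(path).read_text())
    return _maps_from_doc(doc)


def default_metric_maps() -> dict[str, MetricScoreMap]:
    """The packaged default maps for desr/vmr/omr/duplicate_ratio."""
    text = resources.files("dqas.data").joinpath("default_metric_maps.yaml").read_text()
    return _maps_from_doc(yaml.safe_load(text))
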