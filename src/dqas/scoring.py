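"""Score assessments against a rubric and classify the percentage result.

The classification bands follow the dQAS convention: Exceptional (>=95%),
Outstanding (90-94%), Excellent (85-89%), Very Good (80-84%), Good (75-79%),
Fair (65-74%), Poor (<65%). Thresholds are inclusive lower bounds on the
real line, so the bands tile [0, 100] without gaps; classification uses the
unrounded percentage, and only display rounds to one decimal (half-up).
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from pydantic import BaseModel, Field

from .rubric import AssessmentResponse, Rubric, validate_response

__all__ = [
    "ClassificationBands",
    "CategoryScore",
    "ScoreReport",
    "InvalidResponseError",
    "DEFAULT_BANDS",
    "score_assessment",
    "classify",
    "minimum_score_for_band",
    "render_report",
    "report_from_json",
]


class InvalidResponseError(ValueError):
    """Raised when an assessment response fails rubric validation."""

    def __init__(self, violations: Sequence) -> None:
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid assessment response: {lines}")


class ClassificationBands(BaseModel):
    """Ordered (label, inclusive minimum percentage) pairs, best first."""

    bands: list[tuple[str, float]]

    def model_post_init(self, __context) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        thresholds = [t for _, t in self.bands]
        if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("band thresholds must be strictly decreasing")
        if thresholds[-1] != 0:
            raise ValueError("lowest band must start at 0 so bands cover [0, 100]")

    def labels(self) -> list[str]:
        return [label for label, _ in self.bands]

    def threshold(self, label: str) -> float:
        for lbl, thr in self.bands:
            if lbl == label:
                return thr
        raise KeyError(f"unknown band label {label!r}")

    def rank(self, label: str) -> int:
        """0 = best band; larger is worse."""
        return self.labels().index(label)


DEFAULT_BANDS = ClassificationBands(
    bands=[
        ("Exceptional", 95.0),
        ("Outstanding", 90.0),
        ("Excellent", 85.0),
        ("Very Good", 80.0),
        ("Good", 75.0),
        ("Fair", 65.0),
        ("Poor", 0.0),
    ]
)


class CategoryScore(BaseModel):
    category_id: str
    label: str
    subtotal: int
    max_subtotal: int


class ScoreReport(BaseModel):
    rubric_name: str
    per_category: list[CategoryScore]
    total: int
    max_total: int
    percentage: float  # unrounded; use display_percentage for the 1-dp form
    classification: str
    metadata: dict = Field(default_factory=dict)

    @property
    def display_percentage(self) -> float:
        """Percentage rounded half-up to one decimal, as reported."""
        exact = Decimal(self.total * 100) / Decimal(self.max_total)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify(percentage: float, bands: ClassificationBands = DEFAULT_BANDS) -> str:
    """Label of the highest band whose threshold <= percentage."""
    if not (0.0 <= percentage <= 100.0):
        raise ValueError(f"percentage {percentage} outside [0, 100]")
    for label, threshold in bands.bands:
        if percentage >= threshold:
            return label
    raise AssertionError("bands do not cover [0, 100]")  # unreachable by construction


def minimum_score_for_band(
    rubric: Rubric, label: str, bands: ClassificationBands = DEFAULT_BANDS
) -> int:
    """Smallest integer total reaching the band, i.e. ceil(threshold * max / 100).

    On the 81-point NAIIS rubric, "Exceptional" (>=95%) requires 77 points
    and "Outstanding" (>=90%) requires 73.
    """
    threshold = bands.threshold(label)
    return math.ceil(threshold * rubric.max_total / 100.0)


def score_assessment(
    rubric: Rubric,
    response: AssessmentResponse,
    bands: ClassificationBands = DEFAULT_BANDS,
) -> ScoreReport:
    """Compute per-category subtotals, total, percentage and classification.

    The response must validate cleanly against the rubric; otherwise an
    :class:`InvalidResponseError` listing every violation is raised.
    """
    violations = validate_response(rubric, response)
    if violations:
        raise InvalidResponseError(violations)
    if rubric.max_total <= 0:
        raise ValueError("rubric has zero maximum total; nothing to score")
    per_category = []
    for cat in rubric.categories:
        subtotal = sum(response.scores[i.item_id] for i in cat.items)
        per_category.append(
            CategoryScore(
                category_id=cat.category_id,
                label=cat.label,
                subtotal=subtotal,
                max_subtotal=cat.max_subtotal,
            )
        )
    total = sum(c.subtotal for c in per_category)
    percentage = 100.0 * total / rubric.max_total
    return ScoreReport(
        rubric_name=rubric.name,
        per_category=per_category,
        total=total,
        max_total=rubric.max_total,
        percentage=percentage,
        classification=classify(percentage, bands),
        metadata=dict(response.metadata),
    )


def render_report(report: ScoreReport, format: str = "text") -> str:
    """Render a score report as human-readable text or round-trippable JSON."""
    if format == "json":
        return json.dumps(report.model_dump(), indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r} (expected 'text' or 'json')")
    width = max(len(c.label) for c in report.per_category)
    lines = [
        f"Quality assessment: {report.rubric_name}",
        "-" * (width + 12),
    ]
    for cat in report.per_category:
        lines.append(f"{cat.label:<{width}}  {cat.subtotal:>3} / {cat.max_subtotal}")
    lines.append("-" * (width + 12))
    lines.append(f"{'Total':<{width}}  {report.total:>3} / {report.max_total}")
    lines.append(f"Percentage: {report.display_percentage}%")
    lines.append(f"Classification: {report.classification}")
    return "\n".join(lines)


def report_from_json(text: str) -> ScoreReport:
    """Inverse of ``render_report(report, 'json')``."""
    return ScoreReport.model_validate(json.loads(text))
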