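"""Rubric data model for database quality-assurance instruments.

A rubric is an ordered set of superordinate categories, each holding ordered
scored items with integer maxima. Rubrics are *data*: a new instrument is a
new YAML/JSON document, never a subclass. The canonical NAIIS dQAS rubric
(34 items, 5 categories, maximum total 81) ships as package data and is
returned by :func:`naiis_rubric`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Literal

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ScoreScale",
    "RubricItem",
    "RubricCategory",
    "Rubric",
    "AssessmentResponse",
    "Violation",
    "RubricError",
    "load_rubric",
    "load_response",
    "naiis_rubric",
    "naiis_response",
    "validate_response",
]

_DATA_PACKAGE = "dqas.data"


class RubricError(ValueError):
    """Raised when a rubric or response document fails validation."""


class ScoreScale(BaseModel):
    """Scoring scale of a single item.

    ``binary`` items are present/absent checks scored 1/0; ``scaled`` items
    award graded credit from 0 up to ``max_score``.
    """

    kind: Literal["binary", "scaled"]
    min_score: int = 0
    max_score: int = Field(ge=1)

    @model_validator(mode="after")
    def _check_consistency(self) -> "ScoreScale":
        if self.min_score != 0:
            raise ValueError("min_score must be 0")
        if self.kind == "binary" and self.max_score != 1:
            raise ValueError("binary scale requires max_score == 1")
        if self.kind == "scaled" and self.max_score < 2:
            raise ValueError("scaled scale requires max_score >= 2")
        return self

    @classmethod
    def from_max(cls, max_score: int) -> "ScoreScale":
        kind = "binary" if max_score == 1 else "scaled"
        return cls(kind=kind, max_score=max_score)


class RubricItem(BaseModel):
    item_id: str = Field(min_length=1)
    label: str
    category_id: str
    scale: ScoreScale
    description: str | None = None

    @property
    def max_score(self) -> int:
        return self.scale.max_score


class RubricCategory(BaseModel):
    category_id: str = Field(min_length=1)
    label: str
    items: list[RubricItem] = Field(min_length=1)
    max_subtotal: int

    @model_validator(mode="after")
    def _check_subtotal(self) -> "RubricCategory":
        computed = sum(i.max_score for i in self.items)
        if self.max_subtotal != computed:
            raise ValueError(
                f"category {self.category_id!r}: declared max_subtotal "
                f"{self.max_subtotal} != computed {computed}"
            )
        return self


class Rubric(BaseModel):
    name: str
    version: str = "1.0"
    categories: list[RubricCategory] = Field(min_length=1)
    max_total: int

    @model_validator(mode="after")
    def _check_total(self) -> "Rubric":
        computed = sum(c.max_subtotal for c in self.categories)
        if self.max_total != computed:
            raise ValueError(
                f"rubric {self.name!r}: declared max_total {self.max_total} "
                f"!= computed {computed}"
            )
        seen: set[str] = set()
        for item in self.iter_items():
            if item.item_id in seen:
                raise ValueError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
        return self

    def iter_items(self) -> Iterator[RubricItem]:
        for cat in self.categories:
            yield from cat.items

    @property
    def n_items(self) -> int:
        return sum(len(c.items) for c in self.categories)

    def item(self, item_id: str) -> RubricItem:
        for it in self.iter_items():
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def to_dict(self) -> dict[str, Any]:
        """Plain-document form that :func:`load_rubric` round-trips."""
        return {
            "name": self.name,
            "version": self.version,
            "categories": [
                {
                    "category_id": c.category_id,
                    "label": c.label,
                    "items": [
                        {
                            "item_id": i.item_id,
                            "label": i.label,
                            "max_score": i.max_score,
                            **({"description": i.description} if i.description else {}),
                        }
                        for i in c.items
                    ],
                }
                for c in self.categories
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


class AssessmentResponse(BaseModel):
    """One consolidated set of awarded scores for one evaluated database."""

    rubric_name: str = ""
    scores: dict[str, int]
    metadata: dict[str, Any] = Field(default_factory=dict)


class Violation(BaseModel):
    item_id: str
    kind: Literal["missing", "extra", "out_of_range", "non_integer"]
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.kind}] {self.item_id}: {self.message}"


def _parse_document(source: str | Path) -> Any:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source
        p = Path(source)
        try:
            if p.is_file():
                text = p.read_text()
        except OSError:
            pass
    try:
        return yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise RubricError(f"cannot parse rubric document: {exc}") from exc


def rubric_from_dict(doc: dict[str, Any]) -> Rubric:
    """Build a validated :class:`Rubric` from a plain document.

    Per-item maxima are mandatory; category subtotals and the grand maximum
    are recomputed and, when the document declares them
    (``declared_max_subtotal`` / ``declared_max_total``), checked against the
    declared values.
    """
    if not isinstance(doc, dict) or "categories" not in doc:
        raise RubricError("rubric document must be a mapping with a 'categories' list")
    categories: list[RubricCategory] = []
    for cdoc in doc["categories"]:
        items = []
        for idoc in cdoc.get("items", []):
            try:
                max_score = int(idoc["max_score"])
            except (KeyError, TypeError, ValueError) as exc:
                raise RubricError(
                    f"item {idoc.get('item_id', '?')!r}: invalid or missing max_score"
                ) from exc
            items.append(
                RubricItem(
                    item_id=str(idoc["item_id"]),
                    label=str(idoc.get("label", idoc["item_id"])),
                    category_id=str(cdoc["category_id"]),
                    scale=ScoreScale.from_max(max_score),
                    description=idoc.get("description"),
                )
            )
        computed_sub = sum(i.max_score for i in items)
        declared_sub = cdoc.get("declared_max_subtotal")
        if declared_sub is not None and int(declared_sub) != computed_sub:
            raise RubricError(
                f"category {cdoc['category_id']!r}: declared max_subtotal "
                f"{declared_sub} != computed {computed_sub}"
            )
        categories.append(
            RubricCategory(
                category_id=str(cdoc["category_id"]),
                label=str(cdoc.get("label", cdoc["category_id"])),
                items=items,
                max_subtotal=computed_sub,
            )
        )
    computed_total = sum(c.max_subtotal for c in categories)
    declared_total = doc.get("declared_max_total")
    if declared_total is not None and int(declared_total) != computed_total:
        raise RubricError(
            f"rubric {doc.get('name', '?')!r}: declared max_total "
            f"{declared_total} != computed {computed_total}"
        )
    try:
        return Rubric(
            name=str(doc.get("name", "unnamed")),
            version=str(doc.get("version", "1.0")),
            categories=categories,
            max_total=computed_total,
        )
    except ValueError as exc:
        raise RubricError(str(exc)) from exc


def load_rubric(source: str | Path) -> Rubric:
    """Load a rubric from a YAML/JSON file path or document text."""
    return rubric_from_dict(_parse_document(source))


def load_response(source: str | Path) -> AssessmentResponse:
    """Load an assessment response (``scores: {item_id: int}``) document."""
    doc = _parse_document(source)
    if not isinstance(doc, dict) or "scores" not in doc:
        raise RubricError("response document must be a mapping with a 'scores' mapping")
    return AssessmentResponse(
        rubric_name=str(doc.get("rubric_name", "")),
        scores={str(k): v for k, v in doc["scores"].items()},
        metadata=doc.get("metadata") or {},
    )


def _read_packaged(name: str) -> str:
    return resources.files(_DATA_PACKAGE).joinpath(name).read_text()


def naiis_rubric() -> Rubric:
    """The packaged NAIIS dQAS rubric: 34 items, 5 categories, max total 81."""
    return load_rubric(_read_packaged("naiis_rubric.yaml"))


def naiis_response() -> AssessmentResponse:
    """The consolidated NAIIS database assessment (total 78 of 81)."""
    return load_response(_read_packaged("naiis_response.yaml"))


def validate_response(rubric: Rubric, response: AssessmentResponse) -> list[Violation]:
    """Check a response against a rubric; returns violations, never raises.

    A clean response awards exactly one integer score in ``[0, max]`` for
    every rubric item and nothing else.
    """
    violations: list[Violation] = []
    item_ids = {i.item_id: i for i in rubric.iter_items()}
    for item_id, item in item_ids.items():
        if item_id not in response.scores:
            violations.append(
                Violation(item_id=item_id, kind="missing", message="no score awarded")
            )
            continue
        value = response.scores[item_id]
        if isinstance(value, bool) or not isinstance(value, int):
            violations.append(
                Violation(
                    item_id=item_id,
                    kind="non_integer",
                    message=f"awarded score {value!r} is not an integer",
                )
            )
            continue
        if not (0 <= value <= item.max_score):
            violations.append(
                Violation(
                    item_id=item_id,
                    kind="out_of_range",
                    message=f"awarded {value}, allowed range [0, {item.max_score}]",
                )
            )
    for item_id in response.scores:
        if item_id not in item_ids:
            violations.append(
                Violation(
                    item_id=item_id,
                    kind="extra",
                    message="score for an item not in the rubric",
                )
            )
    return violations
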