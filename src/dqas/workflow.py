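"""End-to-end assessment workflow: fill data-driven items, score, report.

The only items the toolkit will compute for the assessor are the
data-driven ones — VMR, OMR, duplicate ratio (from a supplied export) and
DESR (from staffing/throughput figures). Judgment items must always be
supplied; their ranges are validated but never inferred. When an assessor
supplies a score for a data-driven item *and* the data are available, a
disagreement is an error unless ``prefer_computed`` is set, in which case
the computed score wins and the conflict is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import metrics as dm
from .rubric import AssessmentResponse, Rubric, load_response, load_rubric, naiis_response, naiis_rubric
from .scoring import (
    DEFAULT_BANDS,
    ClassificationBands,
    ScoreReport,
    render_report,
    report_from_json,
    score_assessment,
)

__all__ = ["RunConfig", "AssessmentResult", "run_full_assessment", "emit_report"]

logger = logging.getLogger("dqas")

#: rubric item id -> metric name in the score-map file
DATA_DRIVEN_ITEMS = {
    "vmr": "vmr",
    "omr": "omr",
    "duplicate_ratio": "duplicate_ratio",
    "desr": "desr",
}


@dataclass
class RunConfig:
    """Inputs for one full assessment run.

    ``rubric`` / ``response`` accept file paths or the packaged aliases
    ``"naiis"`` / ``"naiis-2019"``.
    """

    rubric: str = "naiis"
    response: str = "naiis-2019"
    table: str | None = None
    throughput: dm.ThroughputRecord | None = None
    metric_maps: str | None = None
    bands: ClassificationBands = field(default_factory=lambda: DEFAULT_BANDS)
    output_dir: str | None = None
    prefer_computed: bool = False
    missing_tokens: frozenset[str] = dm.DEFAULT_MISSING_TOKENS
    seed: int = 0


@dataclass
class AssessmentResult:
    report: ScoreReport
    profile: dm.DatasetProfile | None
    computed_items: dict[str, int]
    metric_values: dict[str, float]


def _load_rubric_arg(arg: str) -> Rubric:
    return naiis_rubric() if arg == "naiis" else load_rubric(Path(arg))


def _load_response_arg(arg: str) -> AssessmentResponse:
    return naiis_response() if arg == "naiis-2019" else load_response(Path(arg))


def _maps_digest(maps: dict[str, dm.MetricScoreMap]) -> str:
    canon = json.dumps(
        {k: [list(iv) for iv in v.intervals] for k, v in sorted(maps.items())},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_full_assessment(config: RunConfig) -> AssessmentResult:
    """Compute data-driven item scores, merge, and score the assessment.

    Every data-driven rubric item must either carry a supplied score or be
    computable from the supplied table/throughput; otherwise the run fails
    naming the item.
    """
    rubric = _load_rubric_arg(config.rubric)
    response = _load_response_arg(config.response)
    maps = (
        dm.load_metric_maps(config.metric_maps)
        if config.metric_maps
        else dm.default_metric_maps()
    )
    logger.info(
        "run_full_assessment rubric=%s version=%s metric_maps=%s",
        rubric.name,
        rubric.version,
        _maps_digest(maps),
    )

    profile: dm.DatasetProfile | None = None
    metric_values: dict[str, float] = {}
    if config.table is not None:
        table = dm.DataTable.from_csv(config.table, missing_tokens=config.missing_tokens)
        profile = dm.profile_table(table)
        metric_values["vmr"] = dm.vmr(profile)
        metric_values["omr"] = dm.omr(profile)
        metric_values["duplicate_ratio"] = dm.duplicate_ratio(profile)
    if config.throughput is not None:
        metric_values["desr"] = dm.desr(config.throughput)

    rubric_item_ids = {i.item_id for i in rubric.iter_items()}
    scores = dict(response.scores)
    computed_items: dict[str, int] = {}
    for item_id, metric_name in DATA_DRIVEN_ITEMS.items():
        if item_id not in rubric_item_ids:
            continue
        have_value = metric_name in metric_values
        have_supplied = item_id in scores
        if have_value:
            computed = dm.score_metric(metric_values[metric_name], maps[metric_name])
            computed_items[item_id] = computed
            if have_supplied and scores[item_id] != computed:
                if not config.prefer_computed:
                    raise ValueError(
                        f"item {item_id!r}: supplied score {scores[item_id]} "
                        f"conflicts with computed score {computed} "
                        f"(metric value {metric_values[metric_name]:.4g}); "
                        "pass prefer_computed to accept the computed score"
                    )
                logger.warning(
                    "item %s: supplied %d overridden by computed %d",
                    item_id,
                    scores[item_id],
                    computed,
                )
            scores[item_id] = computed
        elif not have_supplied:
            raise ValueError(
                f"data-driven item {item_id!r} has no supplied score and no "
                "table/throughput to compute it from"
            )

    merged = AssessmentResponse(
        rubric_name=response.rubric_name, scores=scores, metadata=response.metadata
    )
    report = score_assessment(rubric, merged, config.bands)
    return AssessmentResult(
        report=report,
        profile=profile,
        computed_items=computed_items,
        metric_values=metric_values,
    )


REPORT_SCHEMA_VERSION = 1


def emit_report(
    result: AssessmentResult, output_dir: str | Path, basename: str = "dqas_report"
) -> dict[str, Path]:
    """Write deterministic text and JSON reports; returns the paths.

    The JSON document is schema-versioned and, re-read, reconstructs an
    equal in-memory :class:`~dqas.scoring.ScoreReport`.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "report": result.report.model_dump(),
        "metric_values": dict(sorted(result.metric_values.items())),
        "computed_items": dict(sorted(result.computed_items.items())),
    }
    if result.profile is not None:
        doc["profile"] = {
            "n_rows": result.profile.n_rows,
            "n_vars": result.profile.n_vars,
            "n_duplicate_rows": result.profile.n_duplicate_rows,
        }
    json_path = out / f"{basename}.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    text_path = out / f"{basename}.txt"
    text_path.write_text(render_report(result.report, "text") + "\n")
    return {"json": json_path, "text": text_path}


def read_report(path: str | Path) -> ScoreReport:
    """Load the ScoreReport embedded in an emitted JSON document."""
    doc = json.loads(Path(path).read_text())
    return report_from_json(json.dumps(doc["report"]))
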