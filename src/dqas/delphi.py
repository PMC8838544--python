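"""e-Delphi consensus engine for expert metric selection.

Implements the aggregation rules used to construct the dQAS instrument:
panelists rate each candidate metric on four criteria (relevance,
measurability, clarity, conciseness) with a 7-point Likert scale (1 = Poor,
7 = Excellent). Ratings are averaged per metric, metrics are ranked, and
three selection rules are exposed separately so a pipeline can compose
them:

* ``consensus_select`` — a metric is included when at least two reviewers
  independently select it; an unselected metric whose point total exceeds
  the escalation threshold (default 20 of a possible 28) is referred to an
  additional reviewer rather than dropped.
* ``median_cutoff`` — metrics rated at or above the group median are kept.
* ``run_round`` — one anonymous iteration: aggregate, cut, and emit the
  group summary fed back to panelists before the next round.

Panelist identifiers are salted-hashed at ingest so rounds link without the
raw identities ever persisting.
"""

from __future__ import annotations

import hashlib
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CRITERIA",
    "LIKERT_MIN",
    "LIKERT_MAX",
    "CandidateMetric",
    "Rating",
    "MetricScore",
    "ConsensusResult",
    "RoundResult",
    "RatingError",
    "anonymize_panelist",
    "aggregate_ratings",
    "consensus_select",
    "median_cutoff",
    "run_round",
]

CRITERIA: tuple[str, ...] = ("relevance", "measurability", "clarity", "conciseness")
LIKERT_MIN, LIKERT_MAX = 1, 7


class RatingError(ValueError):
    """Raised on out-of-scale ratings or incomplete criterion sets."""


@dataclass(frozen=True)
class CandidateMetric:
    metric_id: str
    label: str = ""
    tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class Rating:
    """One panelist's Likert rating of one metric on one criterion."""

    panelist_id: str
    metric_id: str
    criterion: str
    value: int

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise RatingError(
                f"unknown criterion {self.criterion!r}; expected one of {CRITERIA}"
            )
        if not (LIKERT_MIN <= self.value <= LIKERT_MAX):
            raise RatingError(
                f"rating {self.value} outside Likert scale "
                f"[{LIKERT_MIN}, {LIKERT_MAX}]"
            )


@dataclass(frozen=True)
class MetricScore:
    """Aggregate of all panelists' ratings of one metric.

    ``mean_rating`` averages the four criteria within each panelist, then
    averages panelists. ``total_points`` is the four-criterion sum (range
    4-28 per panelist), averaged over panelists; it drives the escalation
    rule. Ranks are dense and descending in ``mean_rating`` (rank 1 = best,
    ties share a rank).
    """

    metric_id: str
    mean_rating: float
    total_points: float
    rank: int = 0


@dataclass(frozen=True)
class ConsensusResult:
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    escalated: tuple[str, ...]
    round_number: int = 1


@dataclass(frozen=True)
class RoundResult:
    """Outcome of one Delphi round, including the feedback summary."""

    round_number: int
    scores: tuple[MetricScore, ...]
    included: tuple[str, ...]
    excluded: tuple[str, ...]
    group_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    comments: tuple[str, ...] = ()


def anonymize_panelist(panelist_id: str, salt: str) -> str:
    """Salted short hash; the salt is run-scoped so rounds link."""
    digest = hashlib.sha256(f"{salt}:{panelist_id}".encode()).hexdigest()
    return digest[:12]


def aggregate_ratings(ratings: Sequence[Rating]) -> list[MetricScore]:
    """Average each metric's ratings over criteria, then over panelists.

    Every (panelist, metric) pair must carry all four criterion ratings
    exactly once; incomplete or duplicated pairs raise :class:`RatingError`.
    The result is sorted best-first with dense shared-tie ranks.
    """
    if not ratings:
        raise RatingError("no ratings supplied")
    by_pair: dict[tuple[str, str], dict[str, int]] = {}
    for r in ratings:
        cell = by_pair.setdefault((r.panelist_id, r.metric_id), {})
        if r.criterion in cell:
            raise RatingError(
                f"duplicate rating: panelist {r.panelist_id!r}, metric "
                f"{r.metric_id!r}, criterion {r.criterion!r}"
            )
        cell[r.criterion] = r.value
    for (panelist, metric), cell in by_pair.items():
        missing = [c for c in CRITERIA if c not in cell]
        if missing:
            raise RatingError(
                f"incomplete criterion set for panelist {panelist!r}, metric "
                f"{metric!r}: missing {missing}"
            )
    per_metric: dict[str, list[dict[str, int]]] = {}
    for (_, metric), cell in by_pair.items():
        per_metric.setdefault(metric, []).append(cell)
    scores = []
    for metric_id, cells in per_metric.items():
        panelist_means = [sum(c.values()) / len(CRITERIA) for c in cells]
        panelist_totals = [sum(c.values()) for c in cells]
        scores.append(
            MetricScore(
                metric_id=metric_id,
                mean_rating=statistics.fmean(panelist_means),
                total_points=statistics.fmean(panelist_totals),
            )
        )
    scores.sort(key=lambda s: (-s.mean_rating, s.metric_id))
    ranked: list[MetricScore] = []
    rank = 0
    prev_mean: float | None = None
    for s in scores:
        if prev_mean is None or s.mean_rating != prev_mean:
            rank += 1
            prev_mean = s.mean_rating
        ranked.append(MetricScore(s.metric_id, s.mean_rating, s.total_points, rank))
    return ranked


def consensus_select(
    selections: Mapping[str, Iterable[str]],
    scores: Sequence[MetricScore],
    escalation_threshold: float = 20.0,
    round_number: int = 1,
) -> ConsensusResult:
    """Two-reviewer consensus with escalation of highly scored leftovers.

    A metric selected by >= 2 reviewers is included. A metric not reaching
    consensus whose ``total_points`` exceeds ``escalation_threshold`` is
    escalated to an additional reviewer; everything else is excluded.
    """
    if len(selections) < 2:
        raise ValueError("consensus requires at least two reviewers")
    known = {s.metric_id for s in scores}
    points = {s.metric_id: s.total_points for s in scores}
    votes: dict[str, int] = {m: 0 for m in known}
    for reviewer, chosen in selections.items():
        for metric_id in set(chosen):
            if metric_id not in known:
                raise KeyError(
                    f"reviewer {reviewer!r} selected unknown metric {metric_id!r}"
                )
            votes[metric_id] += 1
    included, escalated, excluded = [], [], []
    for s in scores:  # preserve rank order in the output
        if votes[s.metric_id] >= 2:
            included.append(s.metric_id)
        elif points[s.metric_id] > escalation_threshold:
            escalated.append(s.metric_id)
        else:
            excluded.append(s.metric_id)
    return ConsensusResult(
        included=tuple(included),
        excluded=tuple(excluded),
        escalated=tuple(escalated),
        round_number=round_number,
    )


def median_cutoff(scores: Sequence[MetricScore]) -> tuple[list[str], list[str]]:
    """Keep metrics rated at or above the group median mean rating.

    The median of an even-sized list is the midpoint of the two central
    order statistics. Ties at the median are included, so the included set
    is never empty for non-empty input.
    """
    if not scores:
        raise ValueError("median_cutoff requires at least one metric")
    cutoff = statistics.median(s.mean_rating for s in scores)
    included = [s.metric_id for s in scores if s.mean_rating >= cutoff]
    excluded = [s.metric_id for s in scores if s.mean_rating < cutoff]
    return included, excluded


def run_round(
    ratings: Sequence[Rating],
    round_number: int = 1,
    prior_summary: Mapping[str, Mapping[str, float]] | None = None,
    comments: Sequence[str] = (),
    salt: str = "dqas-delphi",
) -> RoundResult:
    """Run one e-Delphi round: aggregate, apply the median cut-off, summarize.

    Round 1 takes no prior summary; later rounds require the previous
    round's aggregate (panelists reconsider against it). Ratings are
    re-keyed to salted-hashed panelist ids before aggregation; a hash
    collision between distinct panelists aborts the round.
    """
    if round_number < 1:
        raise ValueError("round_number starts at 1")
    if round_number == 1 and prior_summary is not None:
        raise ValueError("round 1 takes no prior summary")
    if round_number >= 2 and prior_summary is None:
        raise ValueError(f"round {round_number} requires the prior round's summary")
    if not ratings:
        raise RatingError(f"no ratings submitted for round {round_number}")
    anon_of: dict[str, str] = {}
    for r in ratings:
        anon = anonymize_panelist(r.panelist_id, salt)
        prior_owner = next((p for p, a in anon_of.items() if a == anon), None)
        if prior_owner is not None and prior_owner != r.panelist_id:
            raise ValueError(f"anonymized identifier collision on {anon!r}")
        anon_of[r.panelist_id] = anon
    anon_ratings = [
        Rating(anon_of[r.panelist_id], r.metric_id, r.criterion, r.value)
        for r in ratings
    ]
    scores = aggregate_ratings(anon_ratings)
    included, excluded = median_cutoff(scores)
    summary = {
        s.metric_id: {
            "mean_rating": s.mean_rating,
            "total_points": s.total_points,
            "rank": float(s.rank),
        }
        for s in scores
    }
    return RoundResult(
        round_number=round_number,
        scores=tuple(scores),
        included=tuple(included),
        excluded=tuple(excluded),
        group_summary=summary,
        comments=tuple(comments),
    )
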