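"""e-Delphi consensus engine: aggregation, selection rules, rounds."""

import itertools
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dqas.delphi import (
    CRITERIA,
    MetricScore,
    Rating,
    RatingError,
    aggregate_ratings,
    consensus_select,
    median_cutoff,
    run_round,
)


def sheet(values_by_panelist_metric):
    """Build ratings from {(panelist, metric): (r, m, c, co)} tuples."""
    ratings = []
    for (p, m), values in values_by_panelist_metric.items():
        for criterion, v in zip(CRITERIA, values):
            ratings.append(Rating(p, m, criterion, v))
    return ratings


class TestAggregateRatings:
    def test_single_panelist_all_sevens(self):
        [score] = aggregate_ratings(sheet({("p1", "m1"): (7, 7, 7, 7)}))
        assert (score.mean_rating, score.total_points, score.rank) == (7.0, 28.0, 1)

    def test_mixed_criterion_values(self):
        [score] = aggregate_ratings(sheet({("p1", "m1"): (1, 3, 5, 7)}))
        assert (score.mean_rating, score.total_points) == (4.0, 16.0)

    def test_two_panelists_average(self):
        ratings = sheet({("p1", "m1"): (7, 7, 7, 7), ("p2", "m1"): (1, 1, 1, 1)})
        [score] = aggregate_ratings(ratings)
        assert score.mean_rating == 4.0
        assert score.total_points == 16.0

    def test_dense_ranks_with_shared_ties(self):
        ratings = sheet(
            {
                ("p1", "a"): (7, 7, 7, 7),
                ("p1", "b"): (5, 5, 5, 5),
                ("p1", "c"): (5, 5, 5, 5),
                ("p1", "d"): (2, 2, 2, 2),
            }
        )
        ranks = {s.metric_id: s.rank for s in aggregate_ratings(ratings)}
        assert ranks == {"a": 1, "b": 2, "c": 2, "d": 3}

    def test_incomplete_criterion_set_rejected(self):
        ratings = sheet({("p1", "m1"): (7, 7, 7, 7)})[:3]
        with pytest.raises(RatingError, match="incomplete"):
            aggregate_ratings(ratings)

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(RatingError, match="Likert"):
            Rating("p1", "m1", "clarity", 8)

    def test_record_order_and_relabeling_invariance(self):
        base = sheet({("p1", "m1"): (3, 4, 5, 6), ("p2", "m1"): (7, 6, 5, 4)})
        relabeled = [
            Rating({"p1": "x9", "p2": "x1"}[r.panelist_id], r.metric_id, r.criterion, r.value)
            for r in reversed(base)
        ]
        a, b = aggregate_ratings(base), aggregate_ratings(relabeled)
        assert [(s.metric_id, s.mean_rating, s.total_points) for s in a] == [
            (s.metric_id, s.mean_rating, s.total_points) for s in b
        ]


def scores_of(means):
    return [MetricScore(m, mean, mean * 4.0) for m, mean in means.items()]


class TestConsensusSelect:
    def test_two_reviewer_agreement_includes(self):
        result = consensus_select(
            {"A": {"m1"}, "B": {"m1"}}, scores_of({"m1": 5.0})
        )
        assert result.included == ("m1",)

    def test_unselected_high_scorer_escalates(self):
        # total_points 22 > 20 but no reviewer chose it
        result = consensus_select({"A": set(), "B": set()}, scores_of({"m1": 5.5}))
        assert result.escalated == ("m1",)

    def test_single_vote_low_scorer_excluded(self):
        result = consensus_select({"A": {"m1"}, "B": set()}, scores_of({"m1": 3.75}))
        assert result.excluded == ("m1",)

    def test_partition_property(self):
        means = {"a": 6.0, "b": 5.5, "c": 3.0, "d": 2.0}
        result = consensus_select({"A": {"a", "c"}, "B": {"a"}}, scores_of(means))
        combined = set(result.included) | set(result.excluded) | set(result.escalated)
        assert combined == set(means)
        assert len(result.included) + len(result.excluded) + len(result.escalated) == 4

    def test_unknown_metric_in_selection_rejected(self):
        with pytest.raises(KeyError):
            consensus_select({"A": {"ghost"}, "B": set()}, scores_of({"m1": 5.0}))

    def test_fewer_than_two_reviewers_rejected(self):
        with pytest.raises(ValueError):
            consensus_select({"A": {"m1"}}, scores_of({"m1": 5.0}))

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_enlarging_a_selection_never_shrinks_inclusion(self, data):
        metric_ids = ["m0", "m1", "m2", "m3"]
        means = {m: data.draw(st.floats(1, 7), label=m) for m in metric_ids}
        sel = {
            r: set(data.draw(st.lists(st.sampled_from(metric_ids), max_size=4), label=r))
            for r in ("A", "B", "C")
        }
        extra = data.draw(st.sampled_from(metric_ids), label="extra")
        before = consensus_select(sel, scores_of(means))
        enlarged = {**sel, "A": sel["A"] | {extra}}
        after = consensus_select(enlarged, scores_of(means))
        assert set(before.included) <= set(after.included)


class TestMedianCutoff:
    def test_toy_values(self):
        included, excluded = median_cutoff(scores_of({"a": 2.0, "b": 4.0, "c": 6.0}))
        assert set(included) == {"b", "c"} and excluded == ["a"]

    def test_all_equal_all_included(self):
        included, excluded = median_cutoff(scores_of({"a": 3.0, "b": 3.0, "c": 3.0}))
        assert set(included) == {"a", "b", "c"} and excluded == []

    def test_single_metric_included(self):
        included, excluded = median_cutoff(scores_of({"only": 1.0}))
        assert included == ["only"] and excluded == []

    def test_even_count_uses_midpoint_median(self):
        included, _ = median_cutoff(scores_of({"a": 2.0, "b": 4.0, "c": 5.0, "d": 7.0}))
        # median = 4.5: only c and d reach it
        assert set(included) == {"c", "d"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            median_cutoff([])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(1, 7), min_size=1, max_size=9))
    def test_never_empty_and_at_least_half_when_distinct(self, means):
        scores = scores_of({f"m{i}": v for i, v in enumerate(means)})
        included, excluded = median_cutoff(scores)
        assert included
        if len(set(means)) == len(means):
            assert len(included) >= -(-len(means) // 2)  # ceil(n/2)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1, 7), min_size=1, max_size=5))
    def test_matches_exhaustive_hand_computation(self, means):
        """Oracle: recompute inclusion by direct comparison with the median."""
        scores = scores_of({f"m{i}": v for i, v in enumerate(means)})
        included, excluded = median_cutoff(scores)
        med = statistics.median(means)
        for s in scores:
            assert (s.metric_id in included) == (s.mean_rating >= med)
            assert (s.metric_id in excluded) == (s.mean_rating < med)


class TestRunRound:
    def panel(self):
        return sheet(
            {
                ("p1", "a"): (7, 6, 7, 6),
                ("p1", "b"): (3, 3, 4, 2),
                ("p2", "a"): (6, 6, 6, 7),
                ("p2", "b"): (2, 3, 3, 3),
            }
        )

    def test_identical_rounds_are_stable(self):
        r1 = run_round(self.panel(), round_number=1)
        r2 = run_round(self.panel(), round_number=2, prior_summary=r1.group_summary)
        assert r1.included == r2.included

    def test_rerating_to_group_mean_is_a_fixed_point(self):
        r1 = run_round(self.panel(), round_number=1)
        rerated = []
        for metric_id, stats in r1.group_summary.items():
            mean = round(stats["mean_rating"])
            for p in ("p1", "p2"):
                for criterion in CRITERIA:
                    rerated.append(Rating(p, metric_id, criterion, int(mean)))
        r2 = run_round(rerated, round_number=2, prior_summary=r1.group_summary)
        assert set(r2.included) == set(r1.included)

    def test_empty_participation_errors(self):
        r1 = run_round(self.panel(), round_number=1)
        with pytest.raises(RatingError, match="no ratings"):
            run_round([], round_number=2, prior_summary=r1.group_summary)

    def test_later_round_requires_prior_summary(self):
        with pytest.raises(ValueError, match="prior"):
            run_round(self.panel(), round_number=2)
        with pytest.raises(ValueError, match="no prior"):
            run_round(self.panel(), round_number=1, prior_summary={})

    def test_panelist_ids_are_anonymized(self):
        r1 = run_round(self.panel(), round_number=1)
        # raw identifiers never appear anywhere in the round result
        assert "p1" not in repr(r1) and "p2" not in repr(r1)


class TestExhaustiveToyOracle:
    def test_small_panel_hand_computation(self):
        """<=3 panelists x <=3 metrics: verify every aggregate by hand."""
        values = {
            ("p1", "a"): (7, 7, 6, 6),  # total 26, mean 6.5
            ("p2", "a"): (5, 5, 5, 5),  # total 20, mean 5.0
            ("p1", "b"): (4, 4, 4, 4),
            ("p2", "b"): (2, 2, 2, 2),
            ("p1", "c"): (1, 1, 1, 2),
            ("p2", "c"): (1, 1, 1, 1),
        }
        scores = {s.metric_id: s for s in aggregate_ratings(sheet(values))}
        assert scores["a"].mean_rating == pytest.approx((6.5 + 5.0) / 2)
        assert scores["a"].total_points == pytest.approx(23.0)
        assert scores["b"].mean_rating == pytest.approx(3.0)
        assert scores["c"].mean_rating == pytest.approx((1.25 + 1.0) / 2)
        assert [scores[m].rank for m in "abc"] == [1, 2, 3]
        included, excluded = median_cutoff(list(scores.values()))
        assert set(included) == {"a", "b"} and excluded == ["c"]
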