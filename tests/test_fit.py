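"""Constraint-solver tests, including exhaustive-enumeration oracles on
reduced instances."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from seamount_ebsa import (
    CASE_STUDY_THREAT_SCORES,
    InfeasibleConstraintsError,
    ScoreConstraint,
    case_study_constraints,
    case_study_fixtures,
    default_impact_matrix,
    fit_impact_matrix,
    threat_score,
    validate_matrix,
)


@pytest.fixture(scope="module")
def fitted():
    return fit_impact_matrix(case_study_constraints())


class TestCaseStudySystem:
    def test_reproduces_every_published_score_exactly(self, fitted):
        for rec in case_study_fixtures():
            res = threat_score(rec, fitted)
            assert res.score_2dp == CASE_STUDY_THREAT_SCORES[rec.name]

    def test_fitted_matrix_is_valid(self, fitted):
        assert validate_matrix(fitted).errors == []

    def test_canonical_solution_matches_packaged_default(self, fitted):
        shipped = default_impact_matrix()
        assert fitted.activities == shipped.activities
        assert fitted.groups == shipped.groups
        assert np.array_equal(fitted.values, shipped.values)

    def test_unconstrained_mineral_row_keeps_prior(self, fitted):
        assert fitted.row("mineral_extraction") == {
            "physical_habitat": 5, "corals_and_sponges": 5, "groundfish": 3,
            "large_pelagics": 1, "air_breathing_visitors": 1,
        }


class TestSingleConstraints:
    def test_pelagic_longline_row_sums_to_13(self):
        m = fit_impact_matrix(
            [ScoreConstraint(frozenset({"longline_pelagic"}), 2.6)]
        )
        row = m.row("longline_pelagic")
        assert sum(row.values()) == 13
        # canonical: smallest cells first, mass pushed to the last groups
        assert list(row.values()) == [1, 1, 1, 5, 5]

    def test_empty_activity_set_with_nonunit_score_is_infeasible(self):
        with pytest.raises(InfeasibleConstraintsError):
            fit_impact_matrix([ScoreConstraint(frozenset(), 2.0)])

    def test_contradictory_scores_reported_as_core(self):
        cons = [
            ScoreConstraint(frozenset({"trawl_bottom"}), 2.0, "a"),
            ScoreConstraint(frozenset({"trawl_bottom"}), 3.0, "b"),
        ]
        with pytest.raises(InfeasibleConstraintsError) as err:
            fit_impact_matrix(cons)
        assert len(err.value.core) == 2

    def test_non_integer_target_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_impact_matrix(
                [ScoreConstraint(frozenset({"trawl_bottom"}), 2.55)]
            )


# ---------------------------------------------------------------------------
# exhaustive oracle on reduced instances


def oracle_canonical(constraints, activities, groups, rating_range):
    """Enumerate every matrix; return the (min total sum, lexicographic)
    satisfying assignment over constrained cells, or None."""
    rmin, rmax = rating_range
    constrained = [
        a for a in activities
        if any(a in c.present_activities for c in constraints)
    ]
    n_cells = len(constrained) * len(groups)
    best = None
    for flat in itertools.product(range(rmin, rmax + 1), repeat=n_cells):
        grid = {
            (a, g): flat[i * len(groups) + j]
            for i, a in enumerate(constrained)
            for j, g in enumerate(groups)
        }
        ok = True
        for c in constraints:
            total = sum(
                max(grid[(a, g)] for a in c.present_activities) for g in groups
            )
            if total != c.target_sum(len(groups), rating_range):
                ok = False
                break
        if ok:
            key = (sum(flat), flat)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def _reduced_instances():
    """Seeded random reduced systems: <=3 activities x <=3 groups,
    ratings 1..3, targets derived from a hidden true matrix (feasible) or
    drawn freely (sometimes infeasible)."""
    rng = np.random.default_rng(20240817)
    activities = ("gear_a", "gear_b", "gear_c")
    groups = ("benthos", "fish", "pelagos")
    cases = []
    for _ in range(8):
        true = rng.integers(1, 4, size=(3, 3))
        sets = []
        while not sets or set().union(*sets) != set(activities):
            k = int(rng.integers(1, 4))
            sets.append(frozenset(rng.choice(activities, size=k, replace=False)))
        cons = []
        for s in sets:
            rows = [true[activities.index(a)] for a in s]
            total = int(np.max(rows, axis=0).sum())
            cons.append(ScoreConstraint(s, total / 3))
        cases.append(cons)
    for _ in range(4):  # free targets, may be infeasible
        k = int(rng.integers(1, 4))
        s = frozenset(rng.choice(activities, size=k, replace=False))
        total = int(rng.integers(3, 10))
        cases.append([ScoreConstraint(s, total / 3)])
    return activities, groups, cases


class TestSolverAgainstExhaustiveOracle:
    def test_feasibility_and_canonical_choice_agree(self):
        activities, groups, cases = _reduced_instances()
        for cons in cases:
            expected = oracle_canonical(cons, activities, groups, (1, 3))
            try:
                m = fit_impact_matrix(
                    cons, activities=activities, groups=groups,
                    rating_range=(1, 3),
                )
            except InfeasibleConstraintsError:
                assert expected is None
                continue
            assert expected is not None
            constrained = [
                a for a in activities
                if any(a in c.present_activities for c in cons)
            ]
            got = tuple(
                m.rating(a, g) for a in constrained for g in groups
            )
            assert got == expected
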