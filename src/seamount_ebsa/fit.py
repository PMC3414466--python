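"""Reconstruction of an impact matrix from published threat scores.

The expert-elicited gear-impact ratings behind the threat score are often
not published as a table, while the per-seamount scores they produce are.
Each published score pins down one constraint on the matrix: for a seamount
with present-activity set A and threat score T,

    sum over groups g of  max_{a in A} M[a, g]  =  n_groups * T

with every cell an integer rating (1..5 on the standard scale).
:func:`fit_impact_matrix` solves this system exactly and returns a
canonical member of the (generally underdetermined) feasible set.

Canonical choice ("min_sum_lex", the default): among all satisfying
matrices, the one of minimal total rating sum — the matrix positing no more
impact than the published scores force — and, among those, the
lexicographically smallest reading cells activity-by-activity then
group-by-group.  It is computed in three exact steps:

1. feasibility and the lexicographic incumbent, by depth-first backtracking
   over the cells with interval propagation on each constraint's achievable
   sum of group maxima;
2. the minimal total sum, by enumerating all realizable per-group
   maxima vectors (columns are interchangeable, so one enumeration serves
   every group) and a small exact multiset search over the groups;
3. the canonical matrix, by re-running the backtracking search constrained
   to that exact total — ascending-value DFS in cell order returns the
   lexicographically smallest solution first.

Activities that appear in no constraint keep a documented prior row.  The
shipped default matrix is the canonical solution for the eight case-study
constraints plus the standalone pelagic-longline score of 2.6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .catalog import default_catalogs
from .threats import RATING_MAX, RATING_MIN

#: prior rows for activities not constrained by any published score.
#: Seafloor mineral extraction: very high impact on the physical habitat and
#: on habitat-forming corals/sponges, medium on groundfish, very low on the
#: pelagic groups.  Any other unconstrained activity defaults to all-1.
PRIOR_ROWS: dict[str, tuple[int, ...]] = {
    "mineral_extraction": (5, 5, 3, 1, 1),
}

#: published per-seamount mean threat scores (the matrix-fitting targets)
CASE_STUDY_THREAT_SCORES: dict[str, float] = {
    "Sedlo": 2.60,
    "Condor": 3.60,
    "Rosemary": 5.00,
    "Anton Dohrn": 3.60,
    "Josephine": 5.00,
    "Gorringe": 4.60,
    "Bowie": 2.40,
    "Cobb": 2.60,
}

#: the standalone published single-gear score: pelagic longlining alone
#: yields a threat score of 2.6
PELAGIC_LONGLINE_SCORE = 2.60

#: largest column-enumeration size for the exact minimum-sum step; beyond
#: this the solver falls back to branch-and-bound on the cells
_ENUM_LIMIT = 600_000


class InfeasibleConstraintsError(ValueError):
    """No rating matrix satisfies the given score constraints."""

    def __init__(self, core: list["ScoreConstraint"]):
        self.core = core
        labels = [c.label or sorted(c.present_activities) for c in core]
        super().__init__(f"no impact matrix satisfies the constraint subset: {labels}")


@dataclass(frozen=True)
class ScoreConstraint:
    """(present activities, published threat score) pair."""

    present_activities: frozenset[str]
    target_score: float
    label: str | None = None

    def target_sum(self, n_groups: int, rating_range=(RATING_MIN, RATING_MAX)) -> int:
        """The implied integer sum of group maxima (n_groups x score)."""
        rmin, rmax = rating_range
        raw = n_groups * self.target_score
        total = round(raw)
        if abs(raw - total) > n_groups * 0.005:
            raise ValueError(
                f"constraint {self.label or set(self.present_activities)}: "
                f"{n_groups} x {self.target_score} is not close to an integer"
            )
        if not n_groups * rmin <= total <= n_groups * rmax:
            raise ValueError(
                f"constraint {self.label or set(self.present_activities)}: "
                f"target score {self.target_score} outside the {rmin}..{rmax} scale"
            )
        return int(total)


def case_study_constraints() -> list[ScoreConstraint]:
    """Constraints from the eight case studies plus the standalone
    pelagic-longline score."""
    from .fixtures import case_study_fixtures
    from .threats import present_activities

    out = [
        ScoreConstraint(
            frozenset(present_activities(rec)),
            CASE_STUDY_THREAT_SCORES[rec.name],
            label=rec.name,
        )
        for rec in case_study_fixtures()
    ]
    out.append(
        ScoreConstraint(
            frozenset({"longline_pelagic"}), PELAGIC_LONGLINE_SCORE,
            label="pelagic longline alone",
        )
    )
    return out


def fit_impact_matrix(
    constraints: list[ScoreConstraint],
    *,
    activities: tuple[str, ...] | None = None,
    groups: tuple[str, ...] | None = None,
    prior_rows: dict[str, tuple[int, ...]] | None = None,
    tie_break: str = "min_sum_lex",
    rating_range: tuple[int, int] = (RATING_MIN, RATING_MAX),
):
    """Find the canonical integer impact matrix satisfying *constraints*.

    Parameters
    ----------
    constraints
        Score constraints; every activity id they mention must be in the
        activity catalog.
    activities, groups
        Row/column catalogs; default: the nine activities and five groups.
    prior_rows
        Rows for activities untouched by any constraint
        (default :data:`PRIOR_ROWS`, all-1 for activities not listed there).
    tie_break
        ``"min_sum_lex"`` (canonical: minimal total sum, then lexicographic
        over activities then groups) or ``"lex"`` (first lexicographic
        solution regardless of total sum).
    rating_range
        Inclusive integer rating bounds, normally (1, 5).

    Raises
    ------
    InfeasibleConstraintsError
        When no matrix exists; carries a minimal unsatisfiable subset.
    """
    from .threats import ImpactMatrix

    if activities is None or groups is None:
        _, threat_defs, group_defs = default_catalogs()
        activities = activities or tuple(t.id for t in threat_defs)
        groups = groups or tuple(g.id for g in group_defs)
    if tie_break not in ("min_sum_lex", "lex"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    rmin, rmax = rating_range

    n_groups = len(groups)
    for c in constraints:
        unknown = c.present_activities - set(activities)
        if unknown:
            raise KeyError(f"constraint mentions unknown activities: {sorted(unknown)}")
        c.target_sum(n_groups, rating_range)  # validates

    # constraints over an empty activity set are decided immediately
    hard = []
    for c in constraints:
        if not c.present_activities:
            if c.target_sum(n_groups, rating_range) != n_groups * rmin:
                raise InfeasibleConstraintsError([c])
        else:
            hard.append(c)

    constrained = [a for a in activities if any(a in c.present_activities for c in hard)]
    cells = [(a, g) for a in constrained for g in groups]  # lexicographic order

    solution = _solve(cells, hard, groups, tie_break, rating_range, constrained)
    if solution is None:
        raise InfeasibleConstraintsError(
            _minimal_core(cells, hard, groups, rating_range)
        )

    prior_rows = {**PRIOR_ROWS, **(prior_rows or {})}
    values = np.full((len(activities), len(groups)), rmin, dtype=int)
    for a, row in prior_rows.items():
        if a in activities and a not in constrained:
            if len(row) != n_groups:
                raise ValueError(f"prior row for {a!r} has wrong length")
            values[activities.index(a)] = row
    for (a, g), v in zip(cells, solution):
        values[activities.index(a), groups.index(g)] = v
    return ImpactMatrix(tuple(activities), tuple(groups), values)


# --------------------------------------------------------------------------
# search internals


def _solve(cells, constraints, groups, tie_break, rating_range, constrained):
    """Return the canonical value tuple for *cells*, or None if infeasible."""
    lex = _search(cells, constraints, groups, rating_range)
    if lex is None or tie_break == "lex":
        return lex
    best_total = _min_total_sum(
        constraints, constrained, groups, rating_range, upper=sum(lex)
    )
    if best_total >= sum(lex):
        return lex
    exact = _search(cells, constraints, groups, rating_range, budget=best_total)
    assert exact is not None, "exact-total search must succeed at the proven optimum"
    return exact


def _min_total_sum(constraints, constrained, groups, rating_range, upper):
    """Exact minimal total rating sum over the constrained cells.

    The score constraints treat the ecological groups symmetrically, so
    every group's column draws from the same set of realizable per-group
    maxima vectors.  Enumerate all columns once, reduce to unique maxima
    vectors with their cheapest realizing column mass, then search for a
    multiset of one vector per group whose componentwise sums hit every
    constraint's target with minimal total mass.  Falls back to
    branch-and-bound over the cells when the column enumeration would be
    too large.
    """
    rmin, rmax = rating_range
    span = rmax - rmin + 1
    n_act = len(constrained)
    n_groups = len(groups)
    if span ** n_act > _ENUM_LIMIT:
        sol = _search(
            [(a, g) for a in constrained for g in groups],
            constraints, groups, rating_range, minimize=True,
        )
        return sum(sol)

    columns = np.stack(
        np.meshgrid(*[np.arange(rmin, rmax + 1, dtype=np.int16)] * n_act,
                    indexing="ij"),
        axis=-1,
    ).reshape(-1, n_act)
    mass = columns.sum(axis=1)
    member_idx = [
        [constrained.index(a) for a in sorted(c.present_activities)]
        for c in constraints
    ]
    maxima = np.stack([columns[:, idx].max(axis=1) for idx in member_idx], axis=1)

    # cheapest column mass per unique maxima vector
    order = np.lexsort(np.column_stack([maxima, mass]).T[::-1])
    maxima, mass = maxima[order], mass[order]
    first = np.ones(len(maxima), dtype=bool)
    first[1:] = (maxima[1:] != maxima[:-1]).any(axis=1)
    vectors, cost = maxima[first], mass[first]

    by_cost = np.argsort(cost, kind="stable")
    vectors, cost = vectors[by_cost], cost[by_cost]
    targets = np.array(
        [c.target_sum(n_groups, rating_range) for c in constraints], dtype=np.int64
    )

    best = upper

    def rec(level, start, deficit, acc):
        nonlocal best
        remaining = n_groups - level
        if remaining == 0:
            if not deficit.any():
                best = min(best, acc)
            return
        lo_next = (deficit - vectors >= rmin * (remaining - 1)).all(axis=1)
        hi_next = (deficit - vectors <= rmax * (remaining - 1)).all(axis=1)
        ok = np.nonzero(lo_next & hi_next)[0]
        ok = ok[ok >= start]  # multiset: nondecreasing candidate index
        for i in ok:
            nxt = acc + cost[i]
            if nxt + (remaining - 1) * cost[i] >= best:
                continue  # cost is sorted ascending from index i onward
            rec(level + 1, i, deficit - vectors[i], nxt)

    rec(0, 0, targets, 0)
    return int(best)


def _search(cells, constraints, groups, rating_range, budget=None, minimize=False):
    """DFS over cell values in lexicographic cell order.

    Plain mode returns the first (= lexicographically smallest) satisfying
    assignment, or None.  ``budget`` requires the values to sum to exactly
    that total; the first solution found is then the lexicographically
    smallest of that total sum.  ``minimize=True`` runs branch-and-bound on
    the total (used only as a fallback for instances too large to
    enumerate).

    Propagation: for every (constraint, group) pair track the maximum
    assigned rating and the number of still-unassigned cells, giving an
    achievable interval for each constraint's sum of group maxima; a branch
    dies when any target leaves its interval.  The total lower bound adds
    to the floor of the unassigned cells the largest per-constraint deficit
    (target minus currently achievable minimum), since lifting a group
    maximum by one costs at least one unit of cell mass.
    """
    rmin, rmax = rating_range
    n = len(cells)
    n_constraints = len(constraints)
    n_groups = len(groups)
    targets = [c.target_sum(n_groups, rating_range) for c in constraints]

    cg_cells: dict[tuple[int, int], list[int]] = {}
    cell_touch: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for ci, c in enumerate(constraints):
        for gi, g in enumerate(groups):
            idxs = [
                k for k, (a, gg) in enumerate(cells)
                if gg == g and a in c.present_activities
            ]
            cg_cells[(ci, gi)] = idxs
            for k in idxs:
                cell_touch[k].append((ci, gi))

    max_assigned = {key: 0 for key in cg_cells}
    unassigned = {key: len(v) for key, v in cg_cells.items()}

    def cg_bounds(key):
        m, u = max_assigned[key], unassigned[key]
        if u == 0:
            return m, m
        return max(m, rmin), rmax

    lo = [0] * n_constraints
    hi = [0] * n_constraints
    for ci in range(n_constraints):
        for gi in range(n_groups):
            a, b = cg_bounds((ci, gi))
            lo[ci] += a
            hi[ci] += b

    values = [0] * n
    best: dict = {"sum": None, "values": None}

    def feasible():
        return all(lo[ci] <= targets[ci] <= hi[ci] for ci in range(n_constraints))

    def rec(k, assigned_sum):
        if k == n:
            if all(lo[ci] == targets[ci] for ci in range(n_constraints)):
                if not minimize:
                    return True
                if best["sum"] is None or assigned_sum < best["sum"]:
                    best["sum"] = assigned_sum
                    best["values"] = tuple(values)
            return False
        remaining = n - k - 1
        for v in range(rmin, rmax + 1):
            if budget is not None:
                rest = budget - assigned_sum - v
                if rest < remaining * rmin or rest > remaining * rmax:
                    continue
            trail = []
            for key in cell_touch[k]:
                ci = key[0]
                old = cg_bounds(key)
                trail.append((key, max_assigned[key]))
                max_assigned[key] = max(max_assigned[key], v)
                unassigned[key] -= 1
                new = cg_bounds(key)
                lo[ci] += new[0] - old[0]
                hi[ci] += new[1] - old[1]
            ok = feasible()
            if ok and (budget is not None or
                       (minimize and best["sum"] is not None)):
                deficit = max(
                    (targets[ci] - lo[ci] for ci in range(n_constraints)),
                    default=0,
                )
                bound = assigned_sum + v + remaining * rmin + max(0, deficit)
                if budget is not None and bound > budget:
                    ok = False
                if minimize and best["sum"] is not None and bound >= best["sum"]:
                    ok = False
            if ok:
                values[k] = v
                if rec(k + 1, assigned_sum + v):
                    return True
            for key, old_max in reversed(trail):
                ci = key[0]
                new = cg_bounds(key)
                max_assigned[key] = old_max
                unassigned[key] += 1
                old = cg_bounds(key)
                lo[ci] += old[0] - new[0]
                hi[ci] += old[1] - new[1]
        return False

    if not feasible():
        return None
    if rec(0, 0):
        return tuple(values)
    return best["values"] if minimize else None


def _minimal_core(cells, constraints, groups, rating_range):
    """Deletion-based minimal unsatisfiable constraint subset."""
    core = list(constraints)
    i = 0
    while i < len(core):
        trial = core[:i] + core[i + 1:]
        trial_cells = [
            (a, g) for (a, g) in cells
            if any(a in c.present_activities for c in trial)
        ]
        if trial and _search(trial_cells, trial, groups, rating_range) is None:
            core = trial
        else:
            i += 1
    return core
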