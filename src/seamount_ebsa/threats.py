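"""Threat scoring from an activity-by-ecological-group impact matrix.

Each of the nine human activities (eight fishing gears and seafloor mineral
extraction) carries an expert-elicited integer impact rating, 1 (very low)
to 5 (very high), against each of five ecological groups.  A seamount's
threat score TS is the mean over the groups of the *maximum* rating among
the activities present there; a group touched by no present activity
contributes 1, so TS = 1 exactly when no activity is present.  Categories:
none (TS = 1), low (1 < TS <= 3), high (TS > 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._round import round_half_up
from .catalog import (
    SeamountRecord,
    Status,
    ValidationReport,
    default_catalogs,
)

RATING_MIN, RATING_MAX = 1, 5
#: category boundaries on the threat score
THREAT_NONE = 1.0
THREAT_LOW_MAX = 3.0


@dataclass(frozen=True)
class ImpactMatrix:
    """Integer impact ratings, activities (rows) x ecological groups (cols)."""

    activities: tuple[str, ...]
    groups: tuple[str, ...]
    values: np.ndarray  # shape (len(activities), len(groups)), dtype int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))
        if self.values.shape != (len(self.activities), len(self.groups)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.activities)} activities x {len(self.groups)} groups"
            )

    def rating(self, activity: str, group: str) -> int:
        return int(
            self.values[self.activities.index(activity), self.groups.index(group)]
        )

    def row(self, activity: str) -> dict[str, int]:
        i = self.activities.index(activity)
        return {g: int(v) for g, v in zip(self.groups, self.values[i])}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.activities), columns=list(self.groups)
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "activity"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImpactMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            tuple(str(a) for a in df.index),
            tuple(str(g) for g in df.columns),
            df.to_numpy(dtype=int),
        )

    @classmethod
    def from_dict(cls, rows: dict[str, dict[str, int]]) -> "ImpactMatrix":
        activities = tuple(rows)
        groups = tuple(next(iter(rows.values())))
        values = np.array(
            [[rows[a][g] for g in groups] for a in activities], dtype=int
        )
        return cls(activities, groups, values)


@dataclass(frozen=True)
class ThreatResult:
    """Threat score for one seamount."""

    group_maxima: dict[str, int]
    score: float  # unrounded mean of the group maxima
    category: str  # "none" | "low" | "high"

    @property
    def score_2dp(self) -> float:
        return round_half_up(self.score, 2)


def validate_matrix(
    matrix: ImpactMatrix, catalogs: tuple | None = None
) -> ValidationReport:
    """Check dimensions, id coverage and rating range of an impact matrix."""
    _, threats, groups = catalogs or default_catalogs()
    rep = ValidationReport()
    want_acts = tuple(t.id for t in threats)
    want_groups = tuple(g.id for g in groups)
    if set(matrix.activities) != set(want_acts):
        rep.errors.append(
            f"activities {sorted(matrix.activities)} do not match the catalog's "
            f"{len(want_acts)} activities"
        )
    if set(matrix.groups) != set(want_groups):
        rep.errors.append(
            f"groups {sorted(matrix.groups)} do not match the catalog's "
            f"{len(want_groups)} ecological groups"
        )
    if not np.issubdtype(matrix.values.dtype, np.integer):
        rep.errors.append("ratings must be integers")
    bad = (matrix.values < RATING_MIN) | (matrix.values > RATING_MAX)
    for i, j in zip(*np.nonzero(bad)):
        rep.errors.append(
            f"rating {matrix.values[i, j]} at ({matrix.activities[i]}, "
            f"{matrix.groups[j]}) outside {RATING_MIN}..{RATING_MAX}"
        )
    return rep


def present_activities(record: SeamountRecord) -> list[str]:
    """Ids of activities recorded present (data-deficient counts as absent)."""
    return [t for t, o in record.threats.items() if o.status is Status.PRESENT]


def group_max_impacts(
    record: SeamountRecord, matrix: ImpactMatrix
) -> dict[str, int]:
    """Per-group maximum impact among the activities present on *record*.

    Groups reached by no present activity get 1 (the very-low floor), so an
    unexploited seamount scores TS = 1 rather than 0.
    """
    present = present_activities(record)
    unknown = [a for a in present if a not in matrix.activities]
    if unknown:
        raise KeyError(f"activities not in impact matrix: {unknown}")
    maxima = {}
    for g in matrix.groups:
        ratings = [matrix.rating(a, g) for a in present]
        maxima[g] = max(ratings) if ratings else 1
    return maxima


def threat_score(
    record: SeamountRecord,
    matrix: ImpactMatrix,
    none_value: float = THREAT_NONE,
    low_max: float = THREAT_LOW_MAX,
) -> ThreatResult:
    """Mean-of-maxima threat score with its none/low/high category."""
    maxima = group_max_impacts(record, matrix)
    score = float(np.mean(list(maxima.values())))
    if score <= none_value:
        category = "none"
    elif score <= low_max:
        category = "low"
    else:
        category = "high"
    return ThreatResult(maxima, score, category)
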