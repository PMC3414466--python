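"""The eight published case-study seamount records.

Six Atlantic seamounts (Sedlo, Condor, Rosemary, Anton Dohrn, Josephine,
Gorringe) and two Gulf of Alaska seamounts (Bowie, Cobb), transcribed
verbatim from the published assessment tables: presence/absence (or data
deficiency) of each EBSA indicator and human activity, together with its
evidence grade.
"""

from __future__ import annotations

from .catalog import Observation, Quality, SeamountRecord, Status

_P = Status.PRESENT
_A = Status.ABSENT
_DD = Status.DATA_DEFICIENT
_NA = Status.NOT_APPLICABLE
_H, _M, _L = Quality.HIGH, Quality.MEDIUM, Quality.LOW

# Per seamount: indicator rows in table order, then threat rows in table
# order.  Cell = (status, quality); quality is None for DD / NA cells.
_INDICATOR_ROWS = (
    "vents",
    "macrophytes",
    "cold_water_corals",
    "sponge_aggregations",
    "aggregating_fishes",
    "threatened_bottom_fishes",
    "threatened_air_breathing",
    "air_breathing",
    "threatened_visiting_pelagics",
    "visiting_pelagics",
    "naturalness",
    "shallow_depth",
)

_THREAT_ROWS = (
    "gillnet_bottom",
    "hook_and_line",
    "longline_bottom",
    "longline_pelagic",
    "pots_and_traps",
    "purse_seine",
    "trawl_bottom",
    "trawl_midwater",
    "mineral_extraction",
)

_CASES: dict[str, tuple[tuple, tuple]] = {
    "Sedlo": (
        ((_A, _L), (_A, _H), (_P, _H), (_P, _H), (_P, _H), (_P, _H),
         (_P, _M), (_NA, None), (_P, _L), (_NA, None), (_P, _H), (_P, _H)),
        ((_A, _H), (_A, _M), (_A, _M), (_P, _L), (_A, _M), (_A, _H),
         (_A, _H), (_A, _H), (_A, _H)),
    ),
    "Condor": (
        ((_A, _M), (_A, _M), (_P, _H), (_P, _H), (_P, _M), (_P, _M),
         (_NA, None), (_P, _M), (_P, _M), (_NA, None), (_A, _M), (_P, _H)),
        ((_A, _M), (_P, _M), (_P, _M), (_P, _M), (_A, _M), (_A, _M),
         (_A, _M), (_A, _M), (_A, _M)),
    ),
    "Rosemary": (
        ((_DD, None), (_A, _H), (_P, _L), (_DD, None), (_P, _H), (_P, _H),
         (_NA, None), (_P, _M), (_DD, None), (_DD, None), (_A, _M), (_P, _H)),
        ((_P, _M), (_A, _M), (_P, _M), (_P, _M), (_P, _M), (_A, _M),
         (_P, _M), (_P, _M), (_DD, None)),
    ),
    "Anton Dohrn": (
        ((_DD, None), (_A, _H), (_P, _M), (_P, _L), (_P, _H), (_P, _H),
         (_P, _M), (_NA, None), (_DD, None), (_DD, None), (_A, _L), (_P, _H)),
        ((_A, _M), (_A, _M), (_P, _M), (_A, _M), (_P, _M), (_A, _M),
         (_P, _M), (_A, _M), (_DD, None)),
    ),
    "Josephine": (
        ((_DD, None), (_A, _L), (_P, _M), (_P, _M), (_P, _H), (_P, _M),
         (_P, _M), (_NA, None), (_DD, None), (_DD, None), (_A, _M), (_P, _M)),
        ((_P, _L), (_DD, None), (_P, _L), (_P, _L), (_DD, None), (_DD, None),
         (_P, _L), (_P, _L), (_A, _H)),
    ),
    "Gorringe": (
        ((_DD, None), (_P, _H), (_P, _M), (_P, _L), (_P, _M), (_P, _M),
         (_P, _H), (_NA, None), (_DD, None), (_DD, None), (_A, _M), (_P, _H)),
        ((_DD, None), (_DD, None), (_P, _M), (_DD, None), (_P, _L), (_P, _L),
         (_P, _L), (_P, _L), (_DD, None)),
    ),
    "Bowie": (
        ((_A, _M), (_P, _M), (_A, _M), (_A, _M), (_P, _M), (_P, _M),
         (_P, _M), (_NA, None), (_P, _M), (_NA, None), (_A, _M), (_P, _H)),
        ((_A, _M), (_P, _M), (_P, _M), (_A, _M), (_P, _M), (_A, _M),
         (_A, _M), (_A, _M), (_A, _M)),
    ),
    "Cobb": (
        ((_DD, None), (_P, _M), (_A, _M), (_A, _M), (_P, _M), (_P, _M),
         (_P, _M), (_NA, None), (_P, _M), (_NA, None), (_A, _H), (_P, _H)),
        ((_P, _M), (_DD, None), (_P, _H), (_DD, None), (_P, _H), (_DD, None),
         (_A, _H), (_P, _H), (_DD, None)),
    ),
}


def case_study_fixtures() -> list[SeamountRecord]:
    """Return the eight case-study records in publication order."""
    out = []
    for name, (ind_cells, thr_cells) in _CASES.items():
        indicators = {
            rid: Observation(status, quality)
            for rid, (status, quality) in zip(_INDICATOR_ROWS, ind_cells)
        }
        threats = {
            rid: Observation(status, quality)
            for rid, (status, quality) in zip(_THREAT_ROWS, thr_cells)
        }
        out.append(SeamountRecord(name, indicators, threats))
    return out


def fixture(name: str) -> SeamountRecord:
    """Return one case-study record by seamount name."""
    for rec in case_study_fixtures():
        if rec.name == name:
            return rec
    raise KeyError(name)
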