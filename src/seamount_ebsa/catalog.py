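"""Indicator and threat catalogs, seamount assessment records, validation.

The assessment vocabulary mirrors the published framework: ten EBSA
indicator *slots* (two of which are OR-pairs, scored either as a threatened
variant or a plain variant, never both), nine human activities (eight
fishing gears plus seafloor mineral extraction) and five potentially
threatened ecological groups.

A :class:`SeamountRecord` stores one observation per indicator *member*
(twelve keys: pair variants are separate rows, as in the source tables) and
one per activity.  Slot-level resolution — one pair = one slot — is done by
:func:`slots` and :func:`resolve_slot`; all weight and data-deficiency
arithmetic downstream is slot-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Status(str, enum.Enum):
    """Observation status of an indicator or activity on a seamount."""

    PRESENT = "present"
    ABSENT = "absent"
    DATA_DEFICIENT = "data_deficient"
    #: legal only for the unscored member of an OR-pair
    NOT_APPLICABLE = "not_applicable"


class Quality(str, enum.Enum):
    """Evidence grade of an observation (high/medium/low)."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"

    @property
    def weight(self) -> float:
        """Numeric uncertainty weight: high 0, medium 0.5, low 1."""
        return {Quality.HIGH: 0.0, Quality.MEDIUM: 0.5, Quality.LOW: 1.0}[self]


class Typology(str, enum.Enum):
    BENTHIC = "benthic"
    BENTHOPELAGIC = "benthopelagic"
    PELAGIC = "pelagic"
    HISTORICAL = "historical"
    GEOLOGICAL = "geological"


class PairRole(str, enum.Enum):
    THREATENED_VARIANT = "threatened_variant"
    PLAIN_VARIANT = "plain_variant"


@dataclass(frozen=True)
class IndicatorDef:
    """One indicator catalog entry (an OR-pair contributes two entries)."""

    id: str
    typology: Typology
    weight: int
    pair_id: str | None = None
    pair_role: PairRole | None = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"indicator {self.id}: weight must be positive")
        if (self.pair_id is None) != (self.pair_role is None):
            raise ValueError(f"indicator {self.id}: pair_id and pair_role go together")


@dataclass(frozen=True)
class ThreatDef:
    """One human activity (fishing gear or mining)."""

    id: str
    kind: str  # "fishing" | "mining"


@dataclass(frozen=True)
class EcologicalGroup:
    """One of the five potentially threatened ecosystem components."""

    id: str


@dataclass(frozen=True)
class Observation:
    """Status plus (for scored observations) an evidence grade."""

    status: Status
    quality: Quality | None = None


@dataclass(frozen=True)
class Slot:
    """A scoring slot: a single indicator or one OR-pair."""

    id: str
    typology: Typology
    members: tuple[IndicatorDef, ...]

    @property
    def max_weight(self) -> int:
        return max(m.weight for m in self.members)

    @property
    def is_pair(self) -> bool:
        return len(self.members) > 1


@dataclass
class SeamountRecord:
    """One seamount's indicator and threat observations."""

    name: str
    indicators: dict[str, Observation] = field(default_factory=dict)
    threats: dict[str, Observation] = field(default_factory=dict)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# --------------------------------------------------------------------------
# default catalogs

_INDICATORS: tuple[IndicatorDef, ...] = (
    IndicatorDef("vents", Typology.BENTHIC, 3),
    IndicatorDef("macrophytes", Typology.BENTHIC, 3),
    IndicatorDef("cold_water_corals", Typology.BENTHIC, 3),
    IndicatorDef("sponge_aggregations", Typology.BENTHIC, 3),
    IndicatorDef("aggregating_fishes", Typology.BENTHOPELAGIC, 2),
    IndicatorDef("threatened_bottom_fishes", Typology.BENTHOPELAGIC, 1),
    IndicatorDef("threatened_air_breathing", Typology.PELAGIC, 2,
                 "air_breathing_pair", PairRole.THREATENED_VARIANT),
    IndicatorDef("air_breathing", Typology.PELAGIC, 1,
                 "air_breathing_pair", PairRole.PLAIN_VARIANT),
    IndicatorDef("threatened_visiting_pelagics", Typology.PELAGIC, 2,
                 "visiting_pelagics_pair", PairRole.THREATENED_VARIANT),
    IndicatorDef("visiting_pelagics", Typology.PELAGIC, 1,
                 "visiting_pelagics_pair", PairRole.PLAIN_VARIANT),
    IndicatorDef("naturalness", Typology.HISTORICAL, 1),
    IndicatorDef("shallow_depth", Typology.GEOLOGICAL, 1),
)

_THREATS: tuple[ThreatDef, ...] = (
    ThreatDef("gillnet_bottom", "fishing"),
    ThreatDef("hook_and_line", "fishing"),
    ThreatDef("longline_bottom", "fishing"),
    ThreatDef("longline_pelagic", "fishing"),
    ThreatDef("pots_and_traps", "fishing"),
    ThreatDef("purse_seine", "fishing"),
    ThreatDef("trawl_bottom", "fishing"),
    ThreatDef("trawl_midwater", "fishing"),
    ThreatDef("mineral_extraction", "mining"),
)

_GROUPS: tuple[EcologicalGroup, ...] = (
    EcologicalGroup("physical_habitat"),
    EcologicalGroup("corals_and_sponges"),
    EcologicalGroup("groundfish"),
    EcologicalGroup("large_pelagics"),
    EcologicalGroup("air_breathing_visitors"),
)


def default_catalogs() -> tuple[
    tuple[IndicatorDef, ...], tuple[ThreatDef, ...], tuple[EcologicalGroup, ...]
]:
    """Return the default (indicator, threat, ecological group) catalogs.

    Ten indicator slots (four benthic of weight 3, two benthopelagic of
    weights 2 and 1, two pelagic OR-pairs weighted 2-or-1, naturalness and
    shallow depth of weight 1 each; maximum total weight 21), nine human
    activities and five ecological groups.
    """
    return _INDICATORS, _THREATS, _GROUPS


def slots(indicators: tuple[IndicatorDef, ...] | None = None) -> tuple[Slot, ...]:
    """Group an indicator catalog into scoring slots (one per OR-pair)."""
    if indicators is None:
        indicators = _INDICATORS
    out: list[Slot] = []
    seen: dict[str, list[IndicatorDef]] = {}
    for ind in indicators:
        key = ind.pair_id or ind.id
        if key in seen:
            seen[key].append(ind)
        else:
            seen[key] = [ind]
            out.append(ind)  # placeholder to keep first-appearance order
    result = []
    for ind in out:
        key = ind.pair_id or ind.id
        members = tuple(seen[key])
        result.append(Slot(key, members[0].typology, members))
    return tuple(result)


def max_weight_sum(indicators: tuple[IndicatorDef, ...] | None = None) -> int:
    """Maximum achievable weight sum over all slots (21 for the default)."""
    return sum(s.max_weight for s in slots(indicators))


def resolve_slot(
    record: SeamountRecord, slot: Slot
) -> tuple[Status, IndicatorDef | None, Quality | None]:
    """Collapse a slot's member observations into one slot-level observation.

    Returns ``(status, scored_member, quality)``; *scored_member* is the
    member definition whose weight applies when the slot is present.  A pair
    whose scored rows are all data-deficient resolves to a single
    data-deficient slot.  Raises ``KeyError`` when no member of the slot
    appears in the record and ``ValueError`` when more than one member is
    scored (records should be validated first).
    """
    entries = [
        (m, record.indicators[m.id])
        for m in slot.members
        if m.id in record.indicators
        and record.indicators[m.id].status is not Status.NOT_APPLICABLE
    ]
    if not entries:
        raise KeyError(f"record {record.name!r}: no observation for slot {slot.id!r}")
    scored = [(m, o) for m, o in entries if o.status in (Status.PRESENT, Status.ABSENT)]
    if len(scored) > 1:
        raise ValueError(
            f"record {record.name!r}: both members of pair {slot.id!r} are scored"
        )
    if scored:
        member, obs = scored[0]
        return obs.status, member, obs.quality
    # remaining entries are data-deficient
    return Status.DATA_DEFICIENT, None, None


def validate_record(
    record: SeamountRecord,
    catalogs: tuple | None = None,
) -> ValidationReport:
    """Structural validation of a seamount record against the catalogs.

    Errors: missing slots/activities, unknown ids, both OR-pair members
    scored, not-applicable outside a pair, evidence grade present on a
    data-deficient observation or missing on a scored one.  A seamount
    recorded as natural (naturalness present) while some activity is present
    is internally inconsistent but occurs in published assessments, so it is
    reported as a warning, not an error.
    """
    indicators, threats, _ = catalogs or default_catalogs()
    rep = ValidationReport()
    member_ids = {i.id: i for i in indicators}
    threat_ids = {t.id for t in threats}

    for key in record.indicators:
        if key not in member_ids:
            rep.errors.append(f"unknown indicator id {key!r}")
    for key in record.threats:
        if key not in threat_ids:
            rep.errors.append(f"unknown threat id {key!r}")

    def check_obs(where: str, obs: Observation) -> None:
        if obs.status in (Status.PRESENT, Status.ABSENT):
            if obs.quality is None:
                rep.errors.append(f"{where}: scored observation lacks a quality grade")
        elif obs.quality is not None:
            rep.errors.append(f"{where}: {obs.status.value} observation carries a quality grade")

    for slot in slots(indicators):
        entries = [
            (m, record.indicators[m.id])
            for m in slot.members
            if m.id in record.indicators
        ]
        live = [(m, o) for m, o in entries if o.status is not Status.NOT_APPLICABLE]
        if not slot.is_pair:
            for m, o in entries:
                if o.status is Status.NOT_APPLICABLE:
                    rep.errors.append(
                        f"indicator {m.id!r}: not_applicable is legal only inside an OR-pair"
                    )
        if not live:
            rep.errors.append(f"missing indicator slot {slot.id!r}")
            continue
        scored = [(m, o) for m, o in live if o.status in (Status.PRESENT, Status.ABSENT)]
        if len(scored) > 1:
            rep.errors.append(f"both members of OR-pair {slot.id!r} are scored")
        for m, o in live:
            check_obs(f"indicator {m.id!r}", o)

    for t in threats:
        if t.id not in record.threats:
            rep.errors.append(f"missing threat {t.id!r}")
            continue
        obs = record.threats[t.id]
        if obs.status is Status.NOT_APPLICABLE:
            rep.errors.append(f"threat {t.id!r}: not_applicable is not a threat status")
        check_obs(f"threat {t.id!r}", obs)

    nat = record.indicators.get("naturalness")
    if nat is not None and nat.status is Status.PRESENT:
        active = [
            t for t, o in record.threats.items() if o.status is Status.PRESENT
        ]
        if active:
            rep.warnings.append(
                "naturalness is present although activities are present: "
                + ", ".join(sorted(active))
            )
    return rep
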