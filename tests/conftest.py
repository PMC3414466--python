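from __future__ import annotations

import itertools

import pytest

from seamount_ebsa import (
    Config,
    Observation,
    Quality,
    SeamountRecord,
    Status,
    case_study_fixtures,
    default_catalogs,
    slots,
)

#: printed case-study values: (ebsa score, ebsa category, ebsa U,
#: threat score, threat category, threat U, portfolio cell)
PRINTED = {
    "Sedlo": (3.86, "high", 0.25, 2.60, "low", 0.28, "highE_lowT"),
    "Condor": (3.48, "high", 0.35, 3.60, "high", 0.50, "highE_highT"),
    "Rosemary": (2.52, "low", 0.59, 5.00, "high", 0.61, "lowE_highT"),
    "Anton Dohrn": (3.29, "high", 0.58, 3.60, "high", 0.61, "highE_highT"),
    "Josephine": (3.29, "high", 0.70, 5.00, "high", 1.16, "highE_highT"),
    "Gorringe": (3.86, "high", 0.58, 4.60, "high", 1.34, "highE_highT"),
    "Bowie": (3.10, "high", 0.45, 2.40, "low", 0.50, "highE_lowT"),
    "Cobb": (3.10, "high", 0.49, 2.60, "low", 0.54, "highE_lowT"),
}


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def by_name() -> dict[str, SeamountRecord]:
    return {rec.name: rec for rec in case_study_fixtures()}


def make_record(
    name: str = "synthetic",
    present_indicators: dict[str, bool] | None = None,
    present_threats: dict[str, bool] | None = None,
    quality: Quality = Quality.HIGH,
) -> SeamountRecord:
    """Fully specified record: chosen items present, everything else absent.

    For pair slots the key is the chosen member id; the other member is
    marked not-applicable.
    """
    indicators, threats, _ = default_catalogs()
    present_indicators = present_indicators or {}
    present_threats = present_threats or {}
    rec = SeamountRecord(name)
    for slot in slots(indicators):
        chosen = [m for m in slot.members if m.id in present_indicators]
        if slot.is_pair:
            member = chosen[0] if chosen else slot.members[0]
            status = (
                Status.PRESENT
                if chosen and present_indicators[member.id]
                else Status.ABSENT
            )
            rec.indicators[member.id] = Observation(status, quality)
            for other in slot.members:
                if other is not member:
                    rec.indicators[other.id] = Observation(Status.NOT_APPLICABLE)
        else:
            status = (
                Status.PRESENT
                if present_indicators.get(slot.id, False)
                else Status.ABSENT
            )
            rec.indicators[slot.id] = Observation(status, quality)
    for t in threats:
        status = (
            Status.PRESENT if present_threats.get(t.id, False) else Status.ABSENT
        )
        rec.threats[t.id] = Observation(status, quality)
    return rec


def all_indicator_patterns():
    """Every slot configuration of the default catalog.

    Non-pair slots are present/absent; pair slots absent, present-plain or
    present-threatened: 2^8 x 3^2 = 2304 patterns, yielded as the
    present-indicator mapping accepted by :func:`make_record`.
    """
    indicators, _, _ = default_catalogs()
    slot_list = slots(indicators)
    choices = []
    for slot in slot_list:
        if slot.is_pair:
            threatened = max(slot.members, key=lambda m: m.weight)
            plain = min(slot.members, key=lambda m: m.weight)
            choices.append([None, (plain.id, True), (threatened.id, True)])
        else:
            choices.append([None, (slot.id, True)])
    for combo in itertools.product(*choices):
        yield dict(c for c in combo if c is not None)
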