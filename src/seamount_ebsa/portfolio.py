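"""Conservation-portfolio classification and the dummy-seamount simulator.

Crossing the low/high EBSA-likelihood category with the low/high threat
category yields four portfolio cells that support different management
strategies: pristine valuable areas (high EBSA, low threat) for
precautionary protection, impacted valuable areas (high EBSA, high threat)
for recovery, and so on.  A threat category of "none" counts as low threat.

The simulator draws hypothetical seamounts with independently random
indicator and activity presences, which exercises the full scoring pipeline
and shows how the framework distributes arbitrary configurations over the
four cells.  Because the EBSA score is a deterministic function of the
presence pattern, the probability of a high EBSA likelihood under the
simulation law is also computable exactly by enumeration
(:func:`exact_high_ebsa_probability`), which the simulated fraction must
approach.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np

from .catalog import (
    Observation,
    Quality,
    SeamountRecord,
    Status,
    default_catalogs,
    max_weight_sum,
    slots,
)
from .ebsa import EBSA_LOW_MAX, ebsa_score
from .threats import ImpactMatrix, threat_score


class PortfolioCell(str, enum.Enum):
    LOW_EBSA_LOW_THREAT = "lowE_lowT"
    LOW_EBSA_HIGH_THREAT = "lowE_highT"
    HIGH_EBSA_LOW_THREAT = "highE_lowT"
    HIGH_EBSA_HIGH_THREAT = "highE_highT"


def portfolio_class(ebsa_category: str, threat_category: str) -> PortfolioCell:
    """Map (low/high EBSA, none/low/high threat) to a portfolio cell."""
    if ebsa_category not in ("low", "high"):
        raise ValueError(f"unknown EBSA category {ebsa_category!r}")
    if threat_category not in ("none", "low", "high"):
        raise ValueError(f"unknown threat category {threat_category!r}")
    high_e = ebsa_category == "high"
    high_t = threat_category == "high"  # "none" folds into the low side
    return {
        (False, False): PortfolioCell.LOW_EBSA_LOW_THREAT,
        (False, True): PortfolioCell.LOW_EBSA_HIGH_THREAT,
        (True, False): PortfolioCell.HIGH_EBSA_LOW_THREAT,
        (True, True): PortfolioCell.HIGH_EBSA_HIGH_THREAT,
    }[(high_e, high_t)]


@dataclass(frozen=True)
class SimulationConfig:
    """Dummy-seamount generator settings.

    Each indicator slot is independently present with probability
    *p_indicator*; a present OR-pair slot is its threatened variant with
    probability *p_threatened_variant*; each activity is present with
    probability *p_threat*.  All quality grades are high — the dummy test
    probes the scoring geometry, not the uncertainty bookkeeping.
    """

    n: int
    p_indicator: float = 0.5
    p_threatened_variant: float = 0.5
    p_threat: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("p_indicator", "p_threatened_variant", "p_threat"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def simulate_dummy_seamounts(
    cfg: SimulationConfig, catalogs: tuple | None = None
) -> list[SeamountRecord]:
    """Draw ``cfg.n`` random seamount records (reproducible under seed)."""
    indicators, threats, _ = catalogs or default_catalogs()
    rng = np.random.default_rng(cfg.seed)
    slot_list = slots(indicators)
    records = []
    for i in range(cfg.n):
        ind: dict[str, Observation] = {}
        for slot in slot_list:
            present = rng.random() < cfg.p_indicator
            if slot.is_pair:
                threatened = rng.random() < cfg.p_threatened_variant
                chosen = slot.members[0 if threatened else 1]
                other = slot.members[1 if threatened else 0]
                ind[chosen.id] = Observation(
                    Status.PRESENT if present else Status.ABSENT, Quality.HIGH
                )
                ind[other.id] = Observation(Status.NOT_APPLICABLE)
            else:
                ind[slot.id] = Observation(
                    Status.PRESENT if present else Status.ABSENT, Quality.HIGH
                )
        thr = {
            t.id: Observation(
                Status.PRESENT if rng.random() < cfg.p_threat else Status.ABSENT,
                Quality.HIGH,
            )
            for t in threats
        }
        records.append(SeamountRecord(f"dummy_{i:04d}", ind, thr))
    return records


def portfolio_proportions(
    records: list[SeamountRecord],
    matrix: ImpactMatrix,
    catalogs: tuple | None = None,
) -> dict[PortfolioCell, float]:
    """Fraction of *records* in each portfolio cell (sums to 1)."""
    indicators, _, _ = catalogs or default_catalogs()
    counts = {cell: 0 for cell in PortfolioCell}
    for rec in records:
        e = ebsa_score(rec, indicators)
        t = threat_score(rec, matrix)
        counts[portfolio_class(e.category, t.category)] += 1
    n = len(records)
    if n == 0:
        return {cell: 0.0 for cell in PortfolioCell}
    return {cell: c / n for cell, c in counts.items()}


def exact_high_ebsa_probability(
    p_indicator: float = 0.5,
    p_threatened_variant: float = 0.5,
    catalogs: tuple | None = None,
    low_max: float = EBSA_LOW_MAX,
) -> float:
    """Exact P(EBSA category = high) under the simulation law.

    Enumerates every slot configuration — each OR-pair has three states
    (absent, present-plain, present-threatened) and every other slot two —
    and sums the probabilities of weight totals W with 1 + 4 W / W_max
    above *low_max*.  For the default catalog this is a sum over
    2^8 x 3^2 = 2304 patterns.
    """
    indicators, _, _ = catalogs or default_catalogs()
    p, q = p_indicator, p_threatened_variant
    slot_states: list[list[tuple[float, int]]] = []
    for slot in slots(indicators):
        if slot.is_pair:
            threatened = next(
                m for m in slot.members if m.weight == slot.max_weight
            )
            plain = next(m for m in slot.members if m is not threatened)
            slot_states.append(
                [(1 - p, 0), (p * q, threatened.weight), (p * (1 - q), plain.weight)]
            )
        else:
            slot_states.append([(1 - p, 0), (p, slot.members[0].weight)])
    wmax = max_weight_sum(indicators)
    total = 0.0
    for combo in itertools.product(*slot_states):
        prob = 1.0
        w = 0
        for pr, wt in combo:
            prob *= pr
            w += wt
        if 1.0 + 4.0 * w / wmax > low_max:
            total += prob
    return total
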