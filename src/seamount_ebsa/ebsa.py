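"""EBSA likelihood scoring.

A seamount's likelihood of qualifying as an Ecologically or Biologically
Significant Area is scored from the weighted presence of ten indicator
slots.  With W the sum of the weights of the indicators present and W_max
the maximum achievable sum (21 for the default catalog, counting the
threatened variant of each OR-pair), the score is

    S = 1 + 4 * W / W_max

so S ranges from 1 (nothing present) to 5 (everything present, threatened
variants).  Data-deficient slots contribute nothing to W: the score is a
likelihood given positive evidence, and missing evidence is carried
separately by the data-uncertainty index.  Scores <= 3 are categorised as
low likelihood, > 3 as high.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import round_half_up
from .catalog import (
    IndicatorDef,
    SeamountRecord,
    Status,
    Typology,
    default_catalogs,
    max_weight_sum,
    resolve_slot,
    slots,
)

#: category boundary: scores <= this are "low"
EBSA_LOW_MAX = 3.0


@dataclass(frozen=True)
class EbsaResult:
    """EBSA likelihood score for one seamount."""

    present_weight_sum: int
    score: float  # unrounded
    category: str  # "low" | "high"
    component_profile: dict[str, float]

    @property
    def score_2dp(self) -> float:
        return round_half_up(self.score, 2)


def present_weight_sum(
    record: SeamountRecord,
    indicators: tuple[IndicatorDef, ...] | None = None,
) -> int:
    """Sum of the weights of the indicators present on *record*.

    An OR-pair contributes the weight of whichever variant is scored
    present (2 threatened, 1 plain); absent and data-deficient slots
    contribute 0.
    """
    if indicators is None:
        indicators, _, _ = default_catalogs()
    total = 0
    for slot in slots(indicators):
        status, member, _ = resolve_slot(record, slot)
        if status is Status.PRESENT:
            total += member.weight
    return total


def ebsa_score(
    record: SeamountRecord,
    indicators: tuple[IndicatorDef, ...] | None = None,
    low_max: float = EBSA_LOW_MAX,
) -> EbsaResult:
    """Score *record*'s EBSA likelihood on the 1-5 scale."""
    if indicators is None:
        indicators, _, _ = default_catalogs()
    w = present_weight_sum(record, indicators)
    wmax = max_weight_sum(indicators)
    score = 1.0 + 4.0 * w / wmax
    category = "low" if score <= low_max else "high"
    return EbsaResult(w, score, category, ebsa_component_profile(record, indicators))


def ebsa_component_profile(
    record: SeamountRecord,
    indicators: tuple[IndicatorDef, ...] | None = None,
) -> dict[str, float]:
    """Proportion of indicators present per typology, on a 0-5 scale.

    For each typology (benthic, benthopelagic, pelagic, historical,
    geological): 5 x (slots present) / (slots in the typology), an OR-pair
    counting as one slot.  These are the EBSA axes of the per-seamount
    radar summaries.
    """
    if indicators is None:
        indicators, _, _ = default_catalogs()
    totals: dict[str, int] = {t.value: 0 for t in Typology}
    present: dict[str, int] = {t.value: 0 for t in Typology}
    for slot in slots(indicators):
        totals[slot.typology.value] += 1
        status, _, _ = resolve_slot(record, slot)
        if status is Status.PRESENT:
            present[slot.typology.value] += 1
    return {
        t: (5.0 * present[t] / n if n else 0.0)
        for t, n in totals.items()
        if n > 0
    }
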