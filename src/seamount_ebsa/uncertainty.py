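"""Evidence-based data-uncertainty index and error bounds.

Every scored observation carries an evidence grade — high (weight 0),
medium (0.5) or low (1) — and unscored slots are data-deficient.  For a
record and a domain (the ten indicator slots or the nine activities):

    DQ_mean = mean grade weight over the scored slots
    DD      = (data-deficient slots) / (total slots)
    U       = DQ_mean + DD

U is 0 when everything is scored at high quality and approaches 2 when
nothing is known; it is drawn as a symmetric, unclipped error bar
``score +/- U``.  The index is additive bookkeeping of evidence, not a
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import round_half_up
from .catalog import (
    SeamountRecord,
    Status,
    default_catalogs,
    resolve_slot,
    slots,
)


@dataclass(frozen=True)
class UncertaintyResult:
    """Data-uncertainty index for one record and one domain."""

    dq_mean: float
    dd: float

    @property
    def u(self) -> float:
        return self.dq_mean + self.dd

    @property
    def u_2dp(self) -> float:
        return round_half_up(self.u, 2)


def _domain_items(
    record: SeamountRecord, domain: str, catalogs: tuple | None
) -> list[tuple[Status, object]]:
    """(status, quality) per slot of the requested domain."""
    indicators, threats, _ = catalogs or default_catalogs()
    if domain == "ebsa":
        out = []
        for slot in slots(indicators):
            status, _, quality = resolve_slot(record, slot)
            out.append((status, quality))
        return out
    if domain == "threat":
        out = []
        for t in threats:
            obs = record.threats[t.id]
            out.append((obs.status, obs.quality))
        return out
    raise ValueError(f"domain must be 'ebsa' or 'threat', got {domain!r}")


def data_deficiency(
    record: SeamountRecord, domain: str, catalogs: tuple | None = None
) -> float:
    """Fraction of the domain's slots that are data-deficient.

    The denominator is the slot count — 10 for the EBSA domain (an OR-pair
    is one slot) and 9 for the threat domain with the default catalogs.
    """
    items = _domain_items(record, domain, catalogs)
    dd = sum(1 for status, _ in items if status is Status.DATA_DEFICIENT)
    return dd / len(items)


def uncertainty_index(
    record: SeamountRecord, domain: str, catalogs: tuple | None = None
) -> UncertaintyResult:
    """Data-uncertainty index U = mean DQ weight + DD fraction.

    When no slot at all is scored, the mean grade weight is defined as 1
    (the worst grade), so a fully data-deficient record attains the
    limiting maximum U = 2.
    """
    items = _domain_items(record, domain, catalogs)
    graded = [q.weight for status, q in items
              if status in (Status.PRESENT, Status.ABSENT)]
    dq_mean = sum(graded) / len(graded) if graded else 1.0
    dd = sum(1 for status, _ in items if status is Status.DATA_DEFICIENT)
    return UncertaintyResult(dq_mean, dd / len(items))


def error_bounds(score: float, u: UncertaintyResult | float) -> tuple[float, float]:
    """(score - U, score + U), deliberately unclipped.

    Bounds may leave the 1..5 scale (up to two units either side); plotting
    layers may clip visually, reported numbers are raw.
    """
    uu = u.u if isinstance(u, UncertaintyResult) else float(u)
    return score - uu, score + uu
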