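"""End-to-end assessment of one seamount record.

:func:`assess` composes the EBSA likelihood score, the threat score, the
two data-uncertainty indices with their error bounds, and the portfolio
classification into a single :class:`AssessmentResult`, plus the component
profiles used by radar summaries (EBSA typology proportions on 0-5; per
ecological group the maximum impact among present activities on 1-5).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import round_half_up
from .catalog import SeamountRecord, validate_record
from .ebsa import EbsaResult, ebsa_score
from .io import Config
from .portfolio import PortfolioCell, portfolio_class
from .threats import ThreatResult, threat_score
from .uncertainty import UncertaintyResult, error_bounds, uncertainty_index


@dataclass(frozen=True)
class AssessmentResult:
    """Complete assessment of one seamount."""

    name: str
    ebsa: EbsaResult
    threat: ThreatResult
    ebsa_uncertainty: UncertaintyResult
    threat_uncertainty: UncertaintyResult
    portfolio: PortfolioCell

    def to_dict(self, decimals: int = 2) -> dict:
        """JSON-ready dict: displayed values rounded, full precision under
        ``raw``."""
        r = lambda x: round_half_up(x, decimals)  # noqa: E731
        e_lo, e_hi = error_bounds(self.ebsa.score, self.ebsa_uncertainty)
        t_lo, t_hi = error_bounds(self.threat.score, self.threat_uncertainty)
        return {
            "seamount": self.name,
            "W": self.ebsa.present_weight_sum,
            "ebsa_score": r(self.ebsa.score),
            "ebsa_category": self.ebsa.category,
            "component_profile": {
                k: r(v) for k, v in self.ebsa.component_profile.items()
            },
            "threat_score": r(self.threat.score),
            "threat_category": self.threat.category,
            "group_maxima": dict(self.threat.group_maxima),
            "ebsa_uncertainty": {
                "DQ": r(self.ebsa_uncertainty.dq_mean),
                "DD": r(self.ebsa_uncertainty.dd),
                "U": r(self.ebsa_uncertainty.u),
                "lower": r(e_lo),
                "upper": r(e_hi),
            },
            "threat_uncertainty": {
                "DQ": r(self.threat_uncertainty.dq_mean),
                "DD": r(self.threat_uncertainty.dd),
                "U": r(self.threat_uncertainty.u),
                "lower": r(t_lo),
                "upper": r(t_hi),
            },
            "portfolio": self.portfolio.value,
            "raw": {
                "ebsa_score": self.ebsa.score,
                "threat_score": self.threat.score,
                "ebsa_U": self.ebsa_uncertainty.u,
                "threat_U": self.threat_uncertainty.u,
                "ebsa_bounds": [e_lo, e_hi],
                "threat_bounds": [t_lo, t_hi],
                "component_profile": dict(self.ebsa.component_profile),
            },
        }


def assess(record: SeamountRecord, config: Config | None = None
           ) -> AssessmentResult:
    """Assess one record under *config* (defaults reproduce the published
    settings).  Raises ``ValueError`` naming the seamount when the record
    is structurally invalid."""
    config = config or Config()
    indicators, _, _ = config.catalogs
    report = validate_record(record, config.catalogs)
    if not report.ok:
        raise ValueError(
            f"record {record.name!r} is invalid: " + "; ".join(report.errors)
        )
    try:
        e = ebsa_score(record, indicators, low_max=config.ebsa_low_max)
        t = threat_score(
            record, config.matrix,
            none_value=config.threat_none, low_max=config.threat_low_max,
        )
        ue = uncertainty_index(record, "ebsa", config.catalogs)
        ut = uncertainty_index(record, "threat", config.catalogs)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"assessing {record.name!r}: {exc}") from exc
    return AssessmentResult(
        record.name, e, t, ue, ut, portfolio_class(e.category, t.category)
    )


def assess_all(records: list[SeamountRecord], config: Config | None = None
               ) -> list[AssessmentResult]:
    config = config or Config()
    return [assess(rec, config) for rec in records]
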