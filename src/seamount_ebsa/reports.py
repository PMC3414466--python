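"""Result serialization and plot-data exports.

The portfolio scatter export carries one row per seamount with the threat
score on x, the EBSA score on y and the uncertainty indices as symmetric
error-bar half-widths; the radar export carries both per-seamount profiles
(EBSA typology proportions, 0-5; per-group maximum impacts, 1-5) as
labelled axis/value pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .assess import AssessmentResult


def results_to_json(results: list[AssessmentResult], path: str | Path,
                    decimals: int = 2) -> None:
    payload = [r.to_dict(decimals) for r in results]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def results_from_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def results_to_csv(results: list[AssessmentResult], path: str | Path,
                   decimals: int = 2) -> None:
    """One row per seamount with the headline scores and categories."""
    rows = []
    for r in results:
        d = r.to_dict(decimals)
        rows.append({
            "seamount": d["seamount"],
            "ebsa_score": d["ebsa_score"],
            "ebsa_category": d["ebsa_category"],
            "ebsa_U": d["ebsa_uncertainty"]["U"],
            "threat_score": d["threat_score"],
            "threat_category": d["threat_category"],
            "threat_U": d["threat_uncertainty"]["U"],
            "portfolio": d["portfolio"],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def scatter_data(results: list[dict] | list[AssessmentResult]) -> pd.DataFrame:
    """Portfolio scatter rows: x=threat, y=ebsa, xerr/yerr=U, cell."""
    dicts = [r.to_dict() if isinstance(r, AssessmentResult) else r
             for r in results]
    return pd.DataFrame([
        {
            "seamount": d["seamount"],
            "x": d["threat_score"],
            "y": d["ebsa_score"],
            "xerr": d["threat_uncertainty"]["U"],
            "yerr": d["ebsa_uncertainty"]["U"],
            "cell": d["portfolio"],
        }
        for d in dicts
    ])


def radar_data(results: list[dict] | list[AssessmentResult]) -> pd.DataFrame:
    """Radar rows: per seamount, EBSA typology axes then threat group axes."""
    dicts = [r.to_dict() if isinstance(r, AssessmentResult) else r
             for r in results]
    rows = []
    for d in dicts:
        for axis, value in d["component_profile"].items():
            rows.append({"seamount": d["seamount"], "profile": "ebsa",
                         "axis": axis, "value": value})
        for axis, value in d["group_maxima"].items():
            rows.append({"seamount": d["seamount"], "profile": "threat",
                         "axis": axis, "value": value})
    return pd.DataFrame(rows)
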