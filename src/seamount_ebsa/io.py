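"""File formats: record CSV/JSON, impact-matrix CSV, configuration.

Record CSV is long-form, one row per observation::

    seamount,domain,item_id,status,quality

with ``domain`` in {indicator, threat}, ``status`` in {present, absent, DD}
and ``quality`` in {H, M, L} (empty for data-deficient rows).  The unscored
member of an OR-pair is omitted; readers restore it as not-applicable so
records round-trip exactly.  The JSON form carries the same content, one
object per seamount.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .catalog import (
    Observation,
    Quality,
    SeamountRecord,
    Status,
    default_catalogs,
    slots,
)
from .ebsa import EBSA_LOW_MAX
from .fit import ScoreConstraint
from .threats import THREAT_LOW_MAX, THREAT_NONE, ImpactMatrix, validate_matrix

_STATUS_OUT = {
    Status.PRESENT: "present",
    Status.ABSENT: "absent",
    Status.DATA_DEFICIENT: "DD",
}
_STATUS_IN = {
    "present": Status.PRESENT,
    "absent": Status.ABSENT,
    "dd": Status.DATA_DEFICIENT,
    "data_deficient": Status.DATA_DEFICIENT,
}
_QUALITY_OUT = {Quality.HIGH: "H", Quality.MEDIUM: "M", Quality.LOW: "L"}
_QUALITY_IN = {
    "h": Quality.HIGH, "m": Quality.MEDIUM, "l": Quality.LOW,
    "high": Quality.HIGH, "medium": Quality.MEDIUM, "low": Quality.LOW,
}


class RecordSchemaError(ValueError):
    """A record file does not conform to the record schema."""


def _obs_rows(record: SeamountRecord):
    for domain, obs_map in (("indicator", record.indicators),
                            ("threat", record.threats)):
        for item_id, obs in obs_map.items():
            if obs.status is Status.NOT_APPLICABLE:
                continue
            yield {
                "seamount": record.name,
                "domain": domain,
                "item_id": item_id,
                "status": _STATUS_OUT[obs.status],
                "quality": _QUALITY_OUT[obs.quality] if obs.quality else "",
            }


def _parse_obs(status: str, quality: str, where: str) -> Observation:
    skey = str(status).strip().lower()
    if skey not in _STATUS_IN:
        raise RecordSchemaError(f"{where}: unknown status {status!r}")
    st = _STATUS_IN[skey]
    qkey = str(quality).strip().lower()
    q = None
    if qkey and qkey != "nan":
        if qkey not in _QUALITY_IN:
            raise RecordSchemaError(f"{where}: unknown quality {quality!r}")
        q = _QUALITY_IN[qkey]
    return Observation(st, q)


def _fill_not_applicable(record: SeamountRecord, catalogs: tuple | None) -> None:
    """Mark the unscored member of each half-filled OR-pair not-applicable."""
    indicators, _, _ = catalogs or default_catalogs()
    for slot in slots(indicators):
        if not slot.is_pair:
            continue
        entries = [m for m in slot.members if m.id in record.indicators]
        scored = [
            m for m in entries
            if record.indicators[m.id].status in (Status.PRESENT, Status.ABSENT)
        ]
        if len(scored) == 1 and len(entries) < len(slot.members):
            for m in slot.members:
                if m.id not in record.indicators:
                    record.indicators[m.id] = Observation(Status.NOT_APPLICABLE)


def records_to_csv(records: list[SeamountRecord], path: str | Path) -> None:
    rows = [row for rec in records for row in _obs_rows(rec)]
    pd.DataFrame(rows, columns=["seamount", "domain", "item_id", "status",
                                "quality"]).to_csv(path, index=False)


def records_from_csv(path: str | Path, catalogs: tuple | None = None
                     ) -> list[SeamountRecord]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise RecordSchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    required = ["seamount", "domain", "item_id", "status", "quality"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordSchemaError(f"{path}: missing columns {missing}")
    records: dict[str, SeamountRecord] = {}
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # header is line 1
        name = row["seamount"]
        rec = records.setdefault(name, SeamountRecord(name))
        obs = _parse_obs(row["status"], row["quality"], where)
        domain = str(row["domain"]).strip().lower()
        if domain == "indicator":
            rec.indicators[row["item_id"]] = obs
        elif domain == "threat":
            rec.threats[row["item_id"]] = obs
        else:
            raise RecordSchemaError(f"{where}: unknown domain {row['domain']!r}")
    out = list(records.values())
    for rec in out:
        _fill_not_applicable(rec, catalogs)
    return out


def records_to_json(records: list[SeamountRecord], path: str | Path) -> None:
    payload = []
    for rec in records:
        obj: dict = {"name": rec.name, "indicators": {}, "threats": {}}
        for row in _obs_rows(rec):
            entry = {"status": row["status"]}
            if row["quality"]:
                entry["quality"] = row["quality"]
            obj[row["domain"] + "s"][row["item_id"]] = entry
        payload.append(obj)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def records_from_json(path: str | Path, catalogs: tuple | None = None
                      ) -> list[SeamountRecord]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise RecordSchemaError(f"{path}: cannot parse JSON ({exc})") from exc
    if not isinstance(payload, list):
        raise RecordSchemaError(f"{path}: expected a list of seamount objects")
    out = []
    for obj in payload:
        rec = SeamountRecord(obj["name"])
        for domain, target in (("indicators", rec.indicators),
                               ("threats", rec.threats)):
            for item_id, entry in obj.get(domain, {}).items():
                target[item_id] = _parse_obs(
                    entry.get("status", ""), entry.get("quality", ""),
                    f"{path}:{obj['name']}:{item_id}",
                )
        _fill_not_applicable(rec, catalogs)
        out.append(rec)
    return out


def load_records(path: str | Path, catalogs: tuple | None = None
                 ) -> list[SeamountRecord]:
    """Read records from CSV or JSON, dispatching on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return records_from_json(path, catalogs)
    return records_from_csv(path, catalogs)


# --------------------------------------------------------------------------
# packaged data

def packaged_fixture_path(form: str = "csv") -> Path:
    """Path of the packaged case-study record file (``csv`` or ``json``)."""
    name = {"csv": "case_studies.csv", "json": "case_studies.json"}[form]
    return Path(resources.files("seamount_ebsa").joinpath("data", name))


def default_impact_matrix() -> ImpactMatrix:
    """The shipped default activity-by-group impact matrix.

    The canonical constraint-solver reconstruction from the published
    case-study threat scores (see :mod:`seamount_ebsa.fit`); users may
    substitute a region-specific matrix via :class:`Config`.
    """
    path = resources.files("seamount_ebsa").joinpath(
        "data", "default_impact_matrix.csv"
    )
    return ImpactMatrix.from_csv(Path(path))


def load_constraints(path: str | Path) -> list[ScoreConstraint]:
    """Read matrix-fit constraints: JSON list of {activities, score}."""
    payload = json.loads(Path(path).read_text())
    out = []
    for i, obj in enumerate(payload):
        out.append(
            ScoreConstraint(
                frozenset(obj["activities"]),
                float(obj["score"]),
                label=obj.get("label", f"constraint {i}"),
            )
        )
    return out


# --------------------------------------------------------------------------
# configuration

@dataclass
class Config:
    """Assessment configuration; the defaults reproduce the published
    behaviour exactly."""

    matrix: ImpactMatrix = None  # type: ignore[assignment]
    catalogs: tuple = None  # type: ignore[assignment]
    ebsa_low_max: float = EBSA_LOW_MAX
    threat_none: float = THREAT_NONE
    threat_low_max: float = THREAT_LOW_MAX
    decimals: int = 2
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.catalogs is None:
            self.catalogs = default_catalogs()
        if self.matrix is None:
            self.matrix = default_impact_matrix()
        report = validate_matrix(self.matrix, self.catalogs)
        if not report.ok:
            raise ValueError("invalid impact matrix: " + "; ".join(report.errors))


def load_config(path: str | Path | None) -> Config:
    """Build a :class:`Config` from a YAML/JSON file (or defaults)."""
    if path is None:
        return Config()
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    kwargs: dict = {}
    if "matrix" in raw:
        m = raw["matrix"]
        if isinstance(m, str):
            kwargs["matrix"] = ImpactMatrix.from_csv(path.parent / m)
        else:
            kwargs["matrix"] = ImpactMatrix.from_dict(m)
    if "indicators" in raw:
        from .catalog import IndicatorDef, PairRole, Typology

        indicators = tuple(
            IndicatorDef(
                d["id"], Typology(d["typology"]), int(d["weight"]),
                d.get("pair_id"),
                PairRole(d["pair_role"]) if d.get("pair_role") else None,
            )
            for d in raw["indicators"]
        )
        _, threats, groups = default_catalogs()
        kwargs["catalogs"] = (indicators, threats, groups)
    thresholds = raw.get("thresholds", {})
    if "ebsa_low_max" in thresholds:
        kwargs["ebsa_low_max"] = float(thresholds["ebsa_low_max"])
    if "threat_none" in thresholds:
        kwargs["threat_none"] = float(thresholds["threat_none"])
    if "threat_low_max" in thresholds:
        kwargs["threat_low_max"] = float(thresholds["threat_low_max"])
    if "decimals" in raw:
        kwargs["decimals"] = int(raw["decimals"])
    if "simulation" in raw:
        kwargs["simulation"] = dict(raw["simulation"])
    return Config(**kwargs)
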