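"""CSV readers/writers and run-configuration loading.

Column contract (invented here and documented; the source database's
physical schema is proprietary): five UTF-8 CSV tables with ISO-8601
dates.  Malformed rows are quarantined to a rejects table with a reason
code, never dropped silently; accepted + quarantined always equals the
input row count.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .types import ConfigError, RunConfig

log = logging.getLogger(__name__)

#: fixed header set per table
COLUMNS: dict[str, list[str]] = {
    "patients": [
        "patient_id", "sex", "birth_year", "postal_code",
        "emr_system", "deceased", "inactive",
    ],
    "encounters": ["patient_id", "encounter_date"],
    "measurements": ["patient_id", "kind", "value", "measure_date"],
    "conditions": ["patient_id", "hypertension", "diabetes", "copd"],
    "risk_factors": [
        "patient_id", "entry_date", "name_text", "value_text", "status_text",
    ],
}

_NA_MARKERS = {"", "na", "n/a", "null", "nan", "none", "."}
_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}

REJECT_COLUMNS = ["table", "row", "reason", "raw"]


@dataclasses.dataclass
class Tables:
    patients: pd.DataFrame
    encounters: pd.DataFrame
    measurements: pd.DataFrame
    conditions: pd.DataFrame
    risk_factors: pd.DataFrame
    rejects: pd.DataFrame


class ColumnContractError(ValueError):
    """A required column is absent from an input file."""


def _is_na(cell: str) -> bool:
    return cell.strip().lower() in _NA_MARKERS


def _parse_date(cell: str) -> dt.date | None:
    """ISO date, time component truncated. Raises ValueError if malformed."""
    s = cell.strip()
    if _is_na(s):
        return None
    ts = pd.Timestamp(s)  # raises on garbage
    return ts.date()


def _parse_bool(cell: str) -> bool:
    s = cell.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unrecognized boolean {cell!r}")


def _read_raw(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS[table] if c not in df.columns]
    if missing:
        raise ColumnContractError(
            f"{table}: missing required column(s) {missing} in {path}"
        )
    return df[COLUMNS[table]]


def _quarantine(rejects: list, table: str, idx: int, reason: str, row) -> None:
    rejects.append(
        {"table": table, "row": int(idx), "reason": reason,
         "raw": "|".join(str(v) for v in row)}
    )


def read_tables(paths: Mapping[str, str | Path] | str | Path) -> Tables:
    """Read the five EMR tables, enforcing the column contract.

    ``paths`` is either a directory containing ``<table>.csv`` files or a
    mapping from table name to file path.  Returns typed DataFrames plus a
    rejects table; every input row is accounted for.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f"{t}.csv" for t in COLUMNS}
    rejects: list[dict] = []
    out: dict[str, pd.DataFrame] = {}

    for table in COLUMNS:
        raw = _read_raw(Path(paths[table]), table)
        rows = []
        for idx, row in enumerate(raw.itertuples(index=False)):
            rec = dict(zip(COLUMNS[table], row))
            try:
                rows.append(_coerce_row(table, rec))
            except ValueError as exc:
                _quarantine(rejects, table, idx, str(exc), row)
        out[table] = pd.DataFrame(rows, columns=COLUMNS[table])
        log.info("%s: %d accepted, %d rejected", table, len(rows),
                 len(raw) - len(rows))

    return Tables(
        patients=out["patients"],
        encounters=out["encounters"],
        measurements=out["measurements"],
        conditions=out["conditions"],
        risk_factors=out["risk_factors"],
        rejects=pd.DataFrame(rejects, columns=REJECT_COLUMNS),
    )


def _coerce_row(table: str, rec: dict[str, str]) -> dict:
    pid = rec["patient_id"].strip()
    if not pid:
        raise ValueError("empty patient_id")
    rec = dict(rec)
    rec["patient_id"] = pid

    if table == "patients":
        rec["sex"] = rec["sex"].strip().upper() if not _is_na(rec["sex"]) else ""
        if rec["sex"] not in ("F", "M", ""):
            raise ValueError(f"unrecognized sex {rec['sex']!r}")
        if _is_na(rec["birth_year"]):
            raise ValueError("missing birth_year")
        rec["birth_year"] = int(rec["birth_year"])
        rec["postal_code"] = (
            "" if _is_na(rec["postal_code"]) else rec["postal_code"].strip().upper()
        )
        rec["emr_system"] = rec["emr_system"].strip() or "other"
        rec["deceased"] = _parse_bool(rec["deceased"])
        rec["inactive"] = _parse_bool(rec["inactive"])
    elif table == "encounters":
        d = _parse_date(rec["encounter_date"])
        if d is None:
            raise ValueError("missing encounter_date")
        rec["encounter_date"] = d
    elif table == "measurements":
        kind = rec["kind"].strip().lower()
        if kind not in ("bmi", "sbp", "dbp"):
            raise ValueError(f"unrecognized measurement kind {rec['kind']!r}")
        rec["kind"] = kind
        value = float(rec["value"])
        if not value > 0:
            raise ValueError("measurement value must be > 0")
        rec["value"] = value
        d = _parse_date(rec["measure_date"])
        if d is None:
            raise ValueError("missing measure_date")
        rec["measure_date"] = d
    elif table == "conditions":
        for flag in ("hypertension", "diabetes", "copd"):
            rec[flag] = _parse_bool(rec[flag])
    elif table == "risk_factors":
        # entry_date may be legitimately absent (kept, flagged as NaT);
        # a malformed non-empty date quarantines the row.
        rec["entry_date"] = _parse_date(rec["entry_date"])
        for f in ("name_text", "value_text", "status_text"):
            rec[f] = "" if rec[f] is None else str(rec[f])
    return rec


def write_tables(tables: Tables, out_dir: str | Path) -> None:
    """Write all tables (and rejects) as CSVs with ISO dates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in COLUMNS:
        getattr(tables, name).to_csv(out / f"{name}.csv", index=False)
    tables.rejects.to_csv(out / "rejects.csv", index=False)


def write_classified(classified: pd.DataFrame, path: str | Path) -> None:
    """Write classifier output; read-back equals what was written."""
    if "calculated_status" not in classified.columns:
        raise ValueError("every record must carry a calculated_status column")
    classified.to_csv(path, index=False)


def read_classified(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("window_start", "window_end"):
        if key in data and isinstance(data[key], str):
            data[key] = dt.date.fromisoformat(data[key])
    try:
        cfg = RunConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    try:
        return cfg.validate()
    except ConfigError as exc:
        # name the offending key for the operator
        raise ConfigError(f"invalid configuration: {exc}") from exc
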