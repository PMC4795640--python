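"""Patient CSV schema, validated reading, and report serialization.

The on-disk format is a UTF-8 comma-separated table with a header row; the
empty string is the sole missing-value token.  Reading is defensive in the
way a clinical-data pipeline must be: every row either becomes a valid
record or lands in a rejection log with its row number and reason, and the
accounting ``included + rejected + self-discharged = total`` is asserted on
every run (self-discharged rows are loaded but flagged excluded from
analysis, mirroring the study's exclusion handling).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bands import ADMISSIBLE_RANGES, AVPU_LEVELS
from .records import ER_FLAGS, OUTCOMES, SOURCES

logger = logging.getLogger(__name__)

__all__ = ["PATIENT_COLUMNS", "ReadResult", "read_patients", "write_patients",
           "write_report", "format_value"]

#: Ordered column spec of the patient CSV.
PATIENT_COLUMNS = (
    "id", "age", "sex", "service", "surgical_phase", "trauma", "hiv", "source",
    "attendant", "days_pre_enrollment", "sbp", "dbp", "pulse", "rr", "temp",
    "avpu", "spo2", "er_hr_doc", "er_bp_doc", "er_rr_doc", "er_spo2_doc",
    "er_gcs_doc", "outcome7",
)

#: Columns that may be blank (missing token: empty string).
OPTIONAL_COLUMNS = {"dbp", "spo2"}

_BOOL_COLUMNS = ("trauma", "attendant") + tuple(f"er_{f}_doc" for f in ER_FLAGS)
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


@dataclass
class ReadResult:
    """Validated patient table plus the rejection/exclusion log."""

    records: pd.DataFrame           # rows passing validation (incl. self-discharged)
    log: pd.DataFrame               # columns: row, id, disposition, reason
    n_input: int

    @property
    def analyzed(self) -> pd.DataFrame:
        """Rows entering analysis: valid and not self-discharged."""
        return self.records[self.records["outcome7"] != "self_discharged"]

    @property
    def n_rejected(self) -> int:
        return int((self.log["disposition"] == "rejected").sum())

    @property
    def n_self_discharged(self) -> int:
        return int((self.records["outcome7"] == "self_discharged").sum())


def _parse_bool(raw: str, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{column}: not a boolean: {raw!r}")


def _validate_row(row: pd.Series) -> dict:
    out: dict = {}
    missing_vitals = [v for v in ("sbp", "pulse", "rr", "temp", "avpu")
                      if str(row.get(v, "")).strip() == ""]
    if missing_vitals:
        raise ValueError(f"incomplete vital signs: missing {missing_vitals}")
    out["id"] = str(row["id"]).strip()
    if not out["id"]:
        raise ValueError("id: empty")
    out["age"] = float(row["age"])
    if out["age"] < 18:
        raise ValueError(f"age: {out['age']} below 18")
    for column, allowed in (
        ("sex", ("male", "female")),
        ("service", ("medical", "surgical")),
        ("surgical_phase", ("preoperative", "postoperative", "not_applicable")),
        ("hiv", ("positive", "negative", "unknown")),
        ("source", SOURCES),
        ("outcome7", OUTCOMES),
    ):
        value = str(row[column]).strip()
        if value not in allowed:
            raise ValueError(f"{column}: {value!r} not in {allowed}")
        out[column] = value
    if (out["surgical_phase"] != "not_applicable") != (out["service"] == "surgical"):
        raise ValueError("surgical_phase inconsistent with service")
    for column in _BOOL_COLUMNS:
        out[column] = _parse_bool(row[column], column)
    out["days_pre_enrollment"] = float(row["days_pre_enrollment"])
    if out["days_pre_enrollment"] < 0:
        raise ValueError("days_pre_enrollment: negative")
    for vital in ("sbp", "pulse", "rr", "temp"):
        value = float(row[vital])
        lo, hi = ADMISSIBLE_RANGES[vital]
        if not math.isfinite(value) or not (lo <= value <= hi):
            raise ValueError(f"{vital}: {value} outside admissible [{lo}, {hi}]")
        out[vital] = value
    avpu = str(row["avpu"]).strip().upper()
    if avpu not in AVPU_LEVELS:
        raise ValueError(f"avpu: {avpu!r} not in {AVPU_LEVELS}")
    out["avpu"] = avpu
    for column in OPTIONAL_COLUMNS:
        raw = str(row.get(column, "")).strip()
        out[column] = float(raw) if raw else np.nan
    if not np.isnan(out["spo2"]) and not (0 <= out["spo2"] <= 100):
        raise ValueError(f"spo2: {out['spo2']} outside [0, 100]")
    return out


def read_patients(path) -> ReadResult:
    """Read and validate a patient CSV.

    Every input row is accounted for: valid rows (including self-discharged
    ones, which are flagged excluded-from-analysis), or a rejection-log
    entry carrying the row number and the first validation failure.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - fatal with message per contract
        raise OSError(f"cannot read patient CSV {path}: {exc}") from exc
    raw.columns = [c.strip().lower() for c in raw.columns]
    unknown = [c for c in raw.columns
               if c not in PATIENT_COLUMNS and not c.startswith("mews_")]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    required = [c for c in PATIENT_COLUMNS if c not in OPTIONAL_COLUMNS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"patient CSV missing required columns: {missing}")
    rows, log = [], []
    for i, (_, row) in enumerate(raw.iterrows()):
        rownum = i + 2  # 1-based with header
        try:
            parsed = _validate_row(row)
        except (ValueError, KeyError) as exc:
            log.append({"row": rownum, "id": str(row.get("id", "")),
                        "disposition": "rejected", "reason": str(exc)})
            continue
        if parsed["outcome7"] == "self_discharged":
            log.append({"row": rownum, "id": parsed["id"],
                        "disposition": "excluded_from_analysis",
                        "reason": "self-discharged before day 7"})
        rows.append(parsed)
    records = pd.DataFrame(rows, columns=list(PATIENT_COLUMNS))
    log_frame = pd.DataFrame(log, columns=["row", "id", "disposition", "reason"])
    result = ReadResult(records=records, log=log_frame, n_input=len(raw))
    assert len(result.analyzed) + result.n_rejected + result.n_self_discharged \
        == result.n_input
    return result


def write_patients(frame: pd.DataFrame, path) -> None:
    """Write a patient table in the canonical column order, '' for missing."""
    cols = [c for c in PATIENT_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in PATIENT_COLUMNS]
    frame[cols + extra].to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def format_value(x, kind: str = "ratio") -> str:
    """Report-layer rounding: proportions to 4 decimals, ratios to 2."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if kind == "proportion":
        return f"{x:.4f}"
    if kind == "p":
        return "<0.0001" if x < 1e-4 else f"{x:.4f}"
    return f"{x:.2f}"


def summaries_to_frame(summaries: Sequence) -> pd.DataFrame:
    """Tabulate PrognosticSummary objects (full precision)."""
    rows = []
    for s in summaries:
        t = s.table
        rows.append({
            "cutoff": s.cutoff,
            "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
            "sensitivity": s.sensitivity, "specificity": s.specificity,
            "ppv": s.ppv,
            "lr_plus": s.lr_plus.point,
            "lr_plus_low": s.lr_plus.ci.lower, "lr_plus_high": s.lr_plus.ci.upper,
            "nne": s.nne,
            "or": s.or_.point, "or_low": s.or_.ci.lower, "or_high": s.or_.ci.upper,
            "or_p": s.or_.p, "or_corrected": s.or_.corrected,
        })
    return pd.DataFrame(rows)


_PROPORTION_COLS = {"sensitivity", "specificity", "ppv"}
_P_COLS = {"or_p", "p"}


def _formatted(frame: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for column in frame.columns:
        series = frame[column]
        if series.dtype.kind not in "fc":
            out[column] = series.astype(str)
        elif column in _PROPORTION_COLS:
            out[column] = series.map(lambda v: format_value(v, "proportion"))
        elif column in _P_COLS:
            out[column] = series.map(lambda v: format_value(v, "p"))
        else:
            out[column] = series.map(format_value)
    return pd.DataFrame(out)


def write_report(summaries: Sequence, model_results: Optional[dict], path,
                 fmt: str = "tsv") -> None:
    """Serialize a prognostic report (and optional model results).

    ``tsv``: human-readable, rounded per the reporting policy (proportions
    to 4 decimals, ratios to 2).  ``json``: full precision, round-trips
    losslessly via :func:`read_report_json`.
    """
    path = Path(path)
    frame = summaries_to_frame(summaries)
    if fmt == "json":
        payload = {"prognostics": frame.to_dict(orient="records")}
        if model_results:
            payload["model"] = model_results
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        lines = [_formatted(frame).to_csv(sep="\t", index=False)]
        if model_results:
            lines.append("# model\n")
            lines.append(json.dumps(model_results, indent=2, sort_keys=True) + "\n")
        path.write_text("".join(lines))
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
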