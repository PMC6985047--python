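"""Case-level domain types and tabular readers/writers.

Input is a header-ed CSV/TSV of diagnosed cases; output is the
per-stratum summary table (JSON or CSV) with the columns n, median age,
early/late modes, mixing proportions, selected model and delta-AIC.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AgeRangeWarning, RowParseError, SchemaError

__all__ = [
    "CaseRecord",
    "StratumSummary",
    "DEFAULT_COLUMN_MAP",
    "read_cases",
    "write_cases",
    "write_summaries",
    "read_summaries",
]

#: canonical field -> expected column header
DEFAULT_COLUMN_MAP = {
    "case_id": "case_id",
    "age": "age",
    "er_percent": "er_percent",
    "esr1_raw": "esr1",
    "pam50": "pam50",
    "race": "race",
    "grade": "grade",
    "tumor_size": "tumor_size",
    "node_status": "node_status",
}

#: strings treated as missing, beyond the empty cell
_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}

#: the study ascertainment window, used only to warn
AGE_RANGE = (20.0, 74.0)


@dataclass
class CaseRecord:
    """One diagnosed case: age at diagnosis plus molecular attributes."""

    case_id: str
    age: float
    er_percent: Optional[float] = None
    esr1_raw: Optional[float] = None
    pam50: Optional[str] = None
    race: Optional[str] = None
    grade: Optional[int] = None
    tumor_size: Optional[float] = None
    node_status: Optional[str] = None

    def __post_init__(self):
        if self.age is None or not math.isfinite(self.age):
            raise ValueError(f"case {self.case_id!r}: age must be finite")
        if self.er_percent is not None and not (
            0.0 <= self.er_percent <= 100.0
        ):
            raise ValueError(
                f"case {self.case_id!r}: er_percent {self.er_percent} "
                "outside [0, 100]"
            )


@dataclass
class StratumSummary:
    """One output row: the mixture-model summary of a stratum."""

    stratum_label: str
    n: int
    median_age: float
    mode_early: Optional[float]
    mode_late: Optional[float]
    p_early: float
    p_late: float
    selected_model: str
    delta_aic: float

    def __post_init__(self):
        if abs(self.p_early + self.p_late - 1.0) > 1e-12:
            raise ValueError(
                f"p_early + p_late must be 1, got "
                f"{self.p_early} + {self.p_late}"
            )
        if (
            self.mode_early is not None
            and self.mode_late is not None
            and not self.mode_early < self.mode_late
        ):
            raise ValueError(
                f"mode_early ({self.mode_early}) must precede "
                f"mode_late ({self.mode_late})"
            )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


def _parse_float(value):
    if _is_missing(value):
        return None
    return float(value)


def _parse_int(value):
    if _is_missing(value):
        return None
    return int(float(value))


def _parse_str(value):
    if _is_missing(value):
        return None
    return str(value).strip()


def read_cases(
    path,
    column_map: Optional[dict] = None,
    *,
    sep: Optional[str] = None,
    strict_age: bool = False,
    age_range=AGE_RANGE,
):
    """Read a case table into a list of :class:`CaseRecord`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    column_map
        Mapping from canonical field names (keys of
        ``DEFAULT_COLUMN_MAP``) to the file's column headers; unmapped
        optional fields default to their canonical header and are left
        missing when absent.
    sep
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.txt`` -> tab, else comma).
    strict_age
        When true, unparseable or out-of-range ages raise
        :class:`RowParseError` naming the offending rows instead of the
        default warn-and-keep (out-of-range) behavior.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if cmap["age"] not in df.columns:
        raise SchemaError(
            f"mandatory age column {cmap['age']!r} not found; "
            f"available: {list(df.columns)}"
        )

    bad_rows = []
    records = []
    lo, hi = age_range
    n_out_of_range = 0
    for i, row in enumerate(df.to_dict(orient="records")):
        raw_age = row.get(cmap["age"])
        try:
            age = _parse_float(raw_age)
            if age is None or not math.isfinite(age):
                raise ValueError(f"missing/non-finite age {raw_age!r}")
        except (ValueError, TypeError):
            bad_rows.append(i)
            continue
        if not (lo <= age <= hi):
            n_out_of_range += 1
            if strict_age:
                bad_rows.append(i)
                continue
        case_id = _parse_str(row.get(cmap["case_id"]))
        records.append(
            CaseRecord(
                case_id=case_id if case_id is not None else f"row{i}",
                age=age,
                er_percent=_parse_float(row.get(cmap["er_percent"])),
                esr1_raw=_parse_float(row.get(cmap["esr1_raw"])),
                pam50=_parse_str(row.get(cmap["pam50"])),
                race=_parse_str(row.get(cmap["race"])),
                grade=_parse_int(row.get(cmap["grade"])),
                tumor_size=_parse_float(row.get(cmap["tumor_size"])),
                node_status=_parse_str(row.get(cmap["node_status"])),
            )
        )

    if bad_rows:
        raise RowParseError(
            f"{len(bad_rows)} row(s) with unusable age values "
            f"(0-based data rows: {bad_rows[:20]})",
            rows=bad_rows,
        )
    if n_out_of_range:
        warnings.warn(
            f"{n_out_of_range} age(s) outside [{lo}, {hi}] kept "
            "(use strict_age to reject)",
            AgeRangeWarning,
            stacklevel=2,
        )
    return records


def write_cases(records: Sequence[CaseRecord], path, *, sep=","):
    """Write case records back to CSV/TSV with canonical headers."""
    path = Path(path)
    fields = list(DEFAULT_COLUMN_MAP)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(DEFAULT_COLUMN_MAP[f] for f in fields)
        for rec in records:
            d = asdict(rec)
            writer.writerow("" if d[f] is None else d[f] for f in fields)
    return path


_SUMMARY_FIELDS = [
    "stratum_label",
    "n",
    "median_age",
    "mode_early",
    "mode_late",
    "p_early",
    "p_late",
    "selected_model",
    "delta_aic",
]


def write_summaries(summaries: Sequence[StratumSummary], path):
    """Serialize stratum summaries, round-trip safe to full precision.

    ``.json`` paths get a JSON array of objects; anything else a CSV
    with one row per stratum (floats printed with ``repr`` precision).
    """
    if not summaries:
        raise ValueError("summaries must be non-empty")
    path = Path(path)
    rows = [asdict(s) for s in summaries]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_SUMMARY_FIELDS)
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {
                        k: ("" if v is None else repr(v) if isinstance(v, float) else v)
                        for k, v in row.items()
                    }
                )
    return path


def read_summaries(path):
    """Inverse of :func:`write_summaries`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        out.append(
            StratumSummary(
                stratum_label=str(row["stratum_label"]),
                n=int(row["n"]),
                median_age=float(row["median_age"]),
                mode_early=_parse_float(row["mode_early"]),
                mode_late=_parse_float(row["mode_late"]),
                p_early=float(row["p_early"]),
                p_late=float(row["p_late"]),
                selected_model=str(row["selected_model"]),
                delta_aic=float(row["delta_aic"]),
            )
        )
    return out
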