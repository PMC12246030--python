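"""Reading and validating fill / person tables.

Dates are accepted either as integer day indices or as ISO-8601 dates and
are converted to integer day offsets from a configurable epoch at the single
point of entry; everything downstream works on integer days.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_EPOCH = dt.date(1970, 1, 1)

FILL_COLUMNS = ("person_id", "drug_class", "drug_code", "drug_category", "days_supply")
PERSON_COLUMNS = ("person_id",)


def to_day(value, epoch: dt.date = DEFAULT_EPOCH) -> float:
    """Convert an ISO date string, date or integer to a day index (NaN passes through)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return float("nan")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, dt.date):
        return float((value - epoch).days)
    s = str(value).strip()
    if not s:
        return float("nan")
    try:
        return float(int(s))
    except ValueError:
        return float((dt.date.fromisoformat(s) - epoch).days)


def parse_day(value, epoch: dt.date = DEFAULT_EPOCH) -> int:
    d = to_day(value, epoch)
    if pd.isna(d):
        raise ValueError(f"cannot parse day value {value!r}")
    return int(d)


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def _day_column(df: pd.DataFrame, day_col: str, date_col: str, epoch: dt.date, what: str):
    if day_col in df.columns:
        return df[day_col].map(lambda v: to_day(v, epoch))
    if date_col in df.columns:
        return df[date_col].map(lambda v: to_day(v, epoch))
    raise ValueError(f"{what} needs a {day_col!r} or {date_col!r} column")


def read_fills(
    path: str | Path, epoch: dt.date = DEFAULT_EPOCH
) -> tuple[pd.DataFrame, dict]:
    """Load and validate a dispensation table.

    Rows with non-positive or missing ``days_supply`` are rejected and
    counted; duplicate ``(person_id, drug_class, fill_day, drug_code)`` rows
    are merged with summed supply.  Returns the clean table and a report of
    what was dropped, so data loss is auditable.
    """
    df = pd.read_csv(path)
    _require(df, FILL_COLUMNS, "fills table")
    n_raw = len(df)
    df = df.copy()
    df["fill_day"] = _day_column(df, "fill_day", "fill_date", epoch, "fills table")
    df["days_supply"] = pd.to_numeric(df["days_supply"], errors="coerce")
    bad = df["days_supply"].isna() | (df["days_supply"] < 1) | df["fill_day"].isna()
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("rejected %d malformed fill row(s)", n_rejected)
    df = df.loc[~bad]
    key = ["person_id", "drug_class", "fill_day", "drug_code"]
    n_dup = int(df.duplicated(key).sum())
    if n_dup:
        log.info("merged %d same-day duplicate fill row(s) (supplies summed)", n_dup)
        df = (
            df.groupby(key + ["drug_category"], as_index=False)["days_supply"].sum()
        )
    df["fill_day"] = df["fill_day"].astype(int)
    df["days_supply"] = df["days_supply"].astype(int)
    df = df.sort_values(["person_id", "fill_day"], ignore_index=True)
    report = {"rows_read": n_raw, "rows_rejected": n_rejected, "rows_merged": n_dup}
    return df, report


def read_persons(
    path: str | Path, epoch: dt.date = DEFAULT_EPOCH
) -> tuple[pd.DataFrame, dict]:
    """Load the person table; empty death/emigration cells mean 'absent'."""
    df = pd.read_csv(path)
    _require(df, PERSON_COLUMNS, "persons table")
    df = df.copy()
    if df["person_id"].duplicated().any():
        raise ValueError("persons table contains duplicate person_id values")
    for col, date_col in (
        ("birth_day", "birth_date"),
        ("death_day", "death_date"),
        ("emigration_day", "emigration_date"),
    ):
        if col in df.columns or date_col in df.columns:
            df[col] = _day_column(df, col, date_col, epoch, "persons table")
    report = {"rows_read": len(df)}
    return df, report
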