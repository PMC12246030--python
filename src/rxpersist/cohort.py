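"""New-user cohort assembly, censoring and subgroup labels.

A cohort is defined per drug class with a new-user design: a person enters on
the day of their first-ever fill of the class (the index date), provided that
day lies inside the inclusion window.  The washout covers the person's entire
available fill history, so anyone with an earlier fill of the class — even
long before the window — is not a new user and is excluded.  Follow-up runs
from the index date to the earliest of death, emigration and the
administrative end of study.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

END_EVENT = "event"
END_DEATH = "death"
END_EMIGRATION = "emigration"
END_ADMIN = "admin_censor"

#: default precedence when censoring events fall on the same day
DEFAULT_TIE_ORDER = (END_DEATH, END_EMIGRATION, END_ADMIN)

BMI_LABELS = ("normal", "overweight", "obese1", "obese23")
BMI_CUTOFFS = (25.0, 30.0, 35.0)  # kg/m^2 boundaries between the four classes


def censor_day(
    index_day: int,
    death_day: float | None,
    emigration_day: float | None,
    study_end_day: int,
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER,
) -> tuple[int, str]:
    """Earliest of death, emigration and administrative end of study.

    Ties on the same day are resolved by ``tie_order`` (death before
    emigration before administrative censoring by default).  A censoring
    event on the index day itself is moved to the end of that day, so
    follow-up always has positive length.
    """
    candidates: dict[str, int] = {END_ADMIN: int(study_end_day)}
    if death_day is not None and not pd.isna(death_day):
        candidates[END_DEATH] = int(death_day)
    if emigration_day is not None and not pd.isna(emigration_day):
        candidates[END_EMIGRATION] = int(emigration_day)
    rank = {reason: i for i, reason in enumerate(tie_order)}
    reason = min(candidates, key=lambda r: (candidates[r], rank[r]))
    return max(candidates[reason], index_day + 1), reason


def assemble_new_users(
    fills: pd.DataFrame,
    persons: pd.DataFrame,
    drug_class: str,
    inclusion_window: tuple[int, int],
    study_end_day: int,
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER,
) -> pd.DataFrame:
    """Build the new-user cohort for one drug class.

    Parameters
    ----------
    fills
        All dispensations, with columns ``person_id``, ``drug_class`` and
        ``fill_day``.  The full fill history is used as washout.
    persons
        One row per person with columns ``person_id`` and optional
        ``death_day`` / ``emigration_day``.
    inclusion_window
        Inclusive day range ``(first, last)`` within which the first-ever
        fill must fall.
    study_end_day
        Administrative end of follow-up.

    Returns
    -------
    DataFrame with columns ``person_id, drug_class, index_day,
    follow_up_end_day, end_reason``, one row per included person.
    """
    lo, hi = inclusion_window
    if lo > hi:
        raise ValueError("inclusion window must satisfy first <= last")
    class_fills = fills.loc[fills["drug_class"] == drug_class]
    known = set(persons["person_id"])
    unknown = ~class_fills["person_id"].isin(known)
    if unknown.any():
        log.warning(
            "%d fill(s) reference unknown person_id values and were dropped",
            int(unknown.sum()),
        )
        class_fills = class_fills.loc[~unknown]
    if class_fills.empty:
        return pd.DataFrame(
            columns=[
                "person_id",
                "drug_class",
                "index_day",
                "follow_up_end_day",
                "end_reason",
            ]
        )
    first_fill = class_fills.groupby("person_id")["fill_day"].min()
    in_window = first_fill[(first_fill >= lo) & (first_fill <= hi)]
    p = persons.set_index("person_id")
    rows = []
    for person_id, index_day in in_window.items():
        person = p.loc[person_id]
        death = person.get("death_day")
        emig = person.get("emigration_day")
        # dead or emigrated strictly before the index fill: not at risk
        if death is not None and not pd.isna(death) and death < index_day:
            continue
        if emig is not None and not pd.isna(emig) and emig < index_day:
            continue
        end_day, reason = censor_day(
            int(index_day), death, emig, study_end_day, tie_order
        )
        rows.append((person_id, drug_class, int(index_day), end_day, reason))
    out = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "drug_class",
            "index_day",
            "follow_up_end_day",
            "end_reason",
        ],
    )
    return out.sort_values("person_id", ignore_index=True)


def bmi_category(bmi: float | None) -> str:
    """Four-class BMI label with boundaries at 25, 30 and 35 kg/m^2."""
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        return "missing"
    idx = int(np.searchsorted(BMI_CUTOFFS, bmi, side="right"))
    return BMI_LABELS[idx]


def calendar_year(index_day: int, epoch: dt.date) -> int:
    """Calendar year of a day index counted from ``epoch``."""
    return (epoch + dt.timedelta(days=int(index_day))).year


def assign_subgroups(
    index_day: int,
    covariates: Mapping[str, object],
    epoch: dt.date = dt.date(1970, 1, 1),
) -> dict[str, str]:
    """Deterministic subgroup labels for one cohort entry.

    Produces a BMI class (from a numeric ``bmi`` or a precomputed
    ``bmi_category``), presence/absence labels for the ASCVD, CKD and heart
    failure comorbidities, and the calendar year of initiation.  Missing
    covariates yield the label ``"missing"``; no imputation is attempted.
    """
    labels: dict[str, str] = {}
    if "bmi" in covariates:
        labels["bmi"] = bmi_category(covariates["bmi"])  # type: ignore[arg-type]
    elif "bmi_category" in covariates:
        cat = covariates["bmi_category"]
        labels["bmi"] = str(cat) if cat is not None and not pd.isna(cat) else "missing"
    else:
        labels["bmi"] = "missing"
    for name, tag in (("ascvd", "ASCVD"), ("ckd", "CKD"), ("hf", "HF")):
        value = covariates.get(name)
        if value is None or pd.isna(value):
            labels[name] = "missing"
        else:
            labels[name] = f"{tag}+" if bool(value) else f"{tag}-"
    labels["year"] = str(calendar_year(index_day, epoch))
    return labels
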