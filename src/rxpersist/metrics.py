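"""Adherence (proportion of days covered) and population coverage (PPC).

PDC is a per-patient measure over the first year of treatment: the number of
days with drug supply on hand within ``[index, index + 365)``, divided by
365.  It is computed on raw supply coverage — the grace period never counts
as covered time — and only for patients who survive the full window.

The proportion of patients covered (PPC) is a population curve: at each
evaluation time after initiation, the share of initiators who are alive,
still in the country (and, by default, still under administrative follow-up)
whose grace-extended treatment is ongoing — counting patients who have
discontinued and reinitiated any number of times.  Unlike a cumulative
discontinuation incidence, PPC is only weakly sensitive to the grace period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .episodes import CoverageSegment, TreatmentEpisode


@dataclass(frozen=True)
class PDCResult:
    person_id: object
    days_covered: int
    window_days: int = 365

    @property
    def pdc(self) -> float:
        return self.days_covered / self.window_days


def proportion_days_covered(
    segments: Sequence[CoverageSegment],
    index_day: int,
    window_days: int = 365,
    person_id: object = None,
) -> PDCResult:
    """Days of drug supply within the first ``window_days`` after the index fill.

    ``segments`` must be raw supply coverage (no grace extension).  Supply
    stockpiled past the end of the window does not count: days covered are
    capped at ``window_days``.  Eligibility (alive at ``index + window``) is
    the caller's responsibility, since it needs the person record.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    w_start, w_end = index_day, index_day + window_days
    covered = 0
    for seg in segments:
        covered += max(0, min(seg.end_day, w_end) - max(seg.start_day, w_start))
    return PDCResult(person_id, min(covered, window_days), window_days)


def pdc_summary(results: Sequence[PDCResult]) -> dict[str, float]:
    """Distribution summary of 1-year adherence, on the percent scale.

    Returns the share of patients at or above the 80%, 90% and 100%
    days-covered thresholds, plus mean, SD, median and IQR of PDC x 100.
    """
    if not results:
        raise ValueError("pdc_summary requires at least one result")
    pdc = np.array([r.pdc for r in results])
    pct = pdc * 100.0
    q25, q50, q75 = np.percentile(pct, [25, 50, 75])
    return {
        "n": len(results),
        "share_ge_80": 100.0 * float(np.mean(pdc >= 0.80)),
        "share_ge_90": 100.0 * float(np.mean(pdc >= 0.90)),
        "share_100": 100.0 * float(np.mean(pdc >= 1.0)),
        "mean": float(np.mean(pct)),
        "sd": float(np.std(pct, ddof=1)) if len(results) > 1 else 0.0,
        "median": float(q50),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
    }


@dataclass(frozen=True)
class PPCCurve:
    """Proportion of patients covered on a grid of days since initiation."""

    grace_days: int
    eval_days: np.ndarray
    covered_count: np.ndarray
    at_risk_count: np.ndarray

    @property
    def ppc(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.at_risk_count > 0, self.covered_count / self.at_risk_count, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grace_days": self.grace_days,
                "eval_day": self.eval_days,
                "covered": self.covered_count,
                "at_risk": self.at_risk_count,
                "ppc": self.ppc,
            }
        )


def proportion_patients_covered(
    episodes_by_person: Mapping[object, Sequence[TreatmentEpisode]],
    cohort: pd.DataFrame,
    persons: pd.DataFrame,
    grace_days: int,
    eval_days: Sequence[int],
    study_end_day: int,
    require_admin_coverage: bool = True,
) -> PPCCurve:
    """Share of eligible initiators with ongoing treatment at each time point.

    A person counts as covered at ``t`` days after their index date if some
    treatment episode (built with the *same* ``grace_days``) spans
    ``index + t``, i.e. supply-plus-grace has not yet run out — regardless of
    how many discontinuation/reinitiation cycles preceded it.  The
    denominator holds persons alive and not emigrated at ``index + t``;
    with ``require_admin_coverage`` (default) it additionally drops persons
    whose administrative follow-up is shorter than ``t``, so late initiators
    do not deflate the late part of the curve.
    """
    for eps in episodes_by_person.values():
        for ep in eps:
            if ep.grace_days != grace_days:
                raise ValueError(
                    f"episodes built with grace {ep.grace_days}, requested {grace_days}"
                )
    eval_days = np.asarray(eval_days, dtype=int)
    p = persons.set_index("person_id")
    covered = np.zeros(len(eval_days), dtype=int)
    at_risk = np.zeros(len(eval_days), dtype=int)
    for row in cohort.itertuples(index=False):
        person = p.loc[row.person_id]
        death = person.get("death_day")
        emig = person.get("emigration_day")
        abs_t = row.index_day + eval_days
        eligible = np.ones(len(eval_days), dtype=bool)
        if death is not None and not pd.isna(death):
            eligible &= abs_t < death
        if emig is not None and not pd.isna(emig):
            eligible &= abs_t < emig
        if require_admin_coverage:
            eligible &= abs_t <= study_end_day
        at_risk += eligible
        eps = episodes_by_person.get(row.person_id, ())
        if eps:
            starts = np.array([ep.start_day for ep in eps])
            ends = np.array([ep.grace_end_day for ep in eps])
            on_rx = ((abs_t[:, None] >= starts) & (abs_t[:, None] < ends)).any(axis=1)
            covered += eligible & on_rx
    return PPCCurve(grace_days, eval_days, covered, at_risk)
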