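"""End-to-end study orchestration: from fill streams to persistence estimates.

:func:`run_study` wires the pipeline together for one drug class:

1. new-user cohort assembly (index dates, censoring);
2. stockpiled coverage segments and grace-period episodes, for every grace
   period requested;
3. time-to-discontinuation and time-to-reinitiation records and their
   Aalen–Johansen cumulative incidences;
4. proportion-of-patients-covered curves across grace periods;
5. 1-year proportion-of-days-covered adherence summary;
6. 3-year trajectory classification and switching summary;
7. sex- and age-adjusted Fine–Gray models for discontinuation.

Everything is deterministic given the input tables and configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import assemble_new_users
from .episodes import (
    CoverageSegment,
    TreatmentEpisode,
    build_coverage,
    classify_trajectory,
    derive_episodes,
    detect_switches,
    discontinuation_followup,
    reinitiation_followup,
    summarize_trajectories,
    TrajectorySummary,
)
from .io import read_fills, read_persons
from .metrics import (
    PPCCurve,
    pdc_summary,
    proportion_days_covered,
    proportion_patients_covered,
)
from .survstats import CIFEstimate, FGFit, aalen_johansen, fine_gray_fit

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one study run (one drug class)."""

    drug_class: str = "GLP1"
    fills_path: str | None = None
    persons_path: str | None = None
    inclusion_window: tuple[int, int] = (0, 1825)
    study_end_day: int = 2190
    grace_days: int = 90  # headline grace period
    grace_list: tuple[int, ...] = (60, 90, 180, 365)
    ppc_grace_list: tuple[int, ...] = (30, 60, 90, 180, 365)
    horizon_days: int = 1095
    max_events: int = 5
    eval_step: int = 30
    eval_max: int = 1825
    event_time: str = "disc_day"  # or "supply_end"
    pdc_window: int = 365
    require_admin_coverage: bool = True
    fg_extra_covariates: tuple[str, ...] = ("bmi_category",)
    epoch: str = "1970-01-01"
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if any(g <= 0 for g in set(self.grace_list) | set(self.ppc_grace_list)):
            raise ValueError("grace periods must be positive")
        if self.grace_days not in self.grace_list:
            raise ValueError("grace_days must be one of grace_list")
        for attr in ("fills_path", "persons_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("inclusion_window", "grace_list", "ppc_grace_list", "fg_extra_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyResult:
    """Bundle of every output of one study run."""

    config: RunConfig
    cohort: pd.DataFrame
    segments: dict[object, list[CoverageSegment]]
    episodes: dict[int, dict[object, list[TreatmentEpisode]]]  # grace -> person -> eps
    cif_discontinuation: dict[int, CIFEstimate]
    cif_reinitiation: dict[int, CIFEstimate]
    ppc_curves: dict[int, PPCCurve]
    pdc: dict[str, float]
    trajectory_summary: TrajectorySummary
    fg_fits: dict[str, FGFit]
    report: dict[str, object]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        main = self.config.grace_days
        rows = []
        for pid, eps in self.episodes[main].items():
            for ep in eps:
                rows.append(
                    (pid, ep.episode_index, ep.start_day, ep.supply_end_day,
                     ep.discontinuation_day, ep.status)
                )
        pd.DataFrame(
            rows,
            columns=["person_id", "episode_index", "start_day", "supply_end_day",
                     "discontinuation_day", "status"],
        ).to_csv(out / "episodes.csv", index=False)
        for name, group in (
            ("cif_discontinuation", self.cif_discontinuation),
            ("cif_reinitiation", self.cif_reinitiation),
        ):
            for g, est in group.items():
                pd.DataFrame(
                    {"time": est.times, "cif": est.cif, "ci_low": est.ci_low,
                     "ci_high": est.ci_high}
                ).to_csv(out / f"{name}_grace{g}.csv", index=False)
        pd.concat(
            [c.to_frame() for c in self.ppc_curves.values()], ignore_index=True
        ).to_csv(out / "ppc.csv", index=False)
        with open(out / "pdc.json", "w") as fh:
            json.dump(self.pdc, fh, indent=2)
        ts = self.trajectory_summary
        with open(out / "trajectories.json", "w") as fh:
            json.dump(
                {
                    "n": ts.n,
                    "discontinued": [ts.n_discontinued, ts.pct_discontinued],
                    "continued": [ts.n_continued, ts.pct_continued],
                    "died_or_emigrated": [ts.n_died_or_emigrated, ts.pct_died_or_emigrated],
                    "ever_switched": [ts.n_ever_switched, ts.pct_ever_switched],
                    "reinitiated_among_discontinued": [
                        ts.n_reinitiated_among_discontinued,
                        ts.pct_reinitiated_among_discontinued,
                    ],
                    "initiators": dict(ts.initiator_counts),
                    "first_switches": {
                        f"{a}->{b}": v for (a, b), v in ts.first_switch_counts.items()
                    },
                    "all_switches": {
                        f"{a}->{b}": v for (a, b), v in ts.switch_matrix.items()
                    },
                },
                fh,
                indent=2,
            )
        with open(out / "finegray.json", "w") as fh:
            json.dump({k: fit.summary() for k, fit in self.fg_fits.items()}, fh, indent=2)
        manifest = {
            "package": "rxpersist",
            "version": __version__,
            "config": self.config.to_dict(),
            "report": self.report,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def _person_day(row, col) -> int | None:
    v = row.get(col)
    if v is None or pd.isna(v):
        return None
    return int(v)


def build_design(
    persons: pd.DataFrame,
    extra: str | None = None,
    category_orders: dict[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Numeric design matrix: male indicator + age-band dummies (+ one extra).

    Categorical covariates are dummy-coded against their first level; the
    default level orders put the clinically natural reference first
    (youngest age band, normal BMI).
    """
    orders = {
        "age_band": ("lt50", "50_69", "ge70"),
        "bmi_category": ("normal", "overweight", "obese1", "obese23"),
    }
    if category_orders:
        orders.update(category_orders)
    cols: dict[str, np.ndarray] = {}
    cols["male"] = (persons["sex"] == "male").to_numpy(dtype=float)
    for covar in ["age_band"] + ([extra] if extra else []):
        if covar not in persons.columns:
            raise KeyError(f"covariate column {covar!r} not in persons table")
        series = persons[covar]
        if series.dtype == bool or set(series.dropna().unique()) <= {True, False}:
            cols[covar] = series.to_numpy(dtype=float)
            continue
        levels = orders.get(covar) or tuple(sorted(series.dropna().unique()))
        for level in levels[1:]:
            cols[f"{covar}_{level}"] = (series == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=persons.index)
    return X, tuple(X.columns)


def run_study(
    config: RunConfig,
    fills: pd.DataFrame | None = None,
    persons: pd.DataFrame | None = None,
) -> StudyResult:
    """Execute the full persistence analysis for one drug class."""
    config.validate()
    epoch = dt.date.fromisoformat(config.epoch)
    report: dict[str, object] = {}
    if fills is None:
        if config.fills_path is None:
            raise ValueError("run_study needs fills (table or fills_path)")
        fills, fill_report = read_fills(config.fills_path, epoch)
        report["fills"] = fill_report
    if persons is None:
        if config.persons_path is None:
            raise ValueError("run_study needs persons (table or persons_path)")
        persons, person_report = read_persons(config.persons_path, epoch)
        report["persons"] = person_report

    cohort = assemble_new_users(
        fills, persons, config.drug_class, config.inclusion_window, config.study_end_day
    )
    report["cohort_size"] = int(len(cohort))
    if cohort.empty:
        raise ValueError("empty cohort: no new users in the inclusion window")

    pindex = persons.set_index("person_id")
    class_fills = fills.loc[fills["drug_class"] == config.drug_class]
    by_person = dict(tuple(class_fills.groupby("person_id")))

    segments: dict[object, list[CoverageSegment]] = {}
    switches: dict[object, list] = {}
    n_posthumous = 0
    person_meta: dict[object, dict] = {}
    for row in cohort.itertuples(index=False):
        prow = pindex.loc[row.person_id]
        death = _person_day(prow, "death_day")
        emig = _person_day(prow, "emigration_day")
        limit = min(
            d for d in (death, emig, config.study_end_day + 1) if d is not None
        )
        pf = by_person[row.person_id]
        keep = pf["fill_day"] < limit
        n_posthumous += int((~keep).sum())
        pf = pf.loc[keep].sort_values("fill_day")
        segments[row.person_id] = build_coverage(
            pf["fill_day"].to_numpy(), pf["days_supply"].to_numpy(), stockpiling=True
        )
        switches[row.person_id] = detect_switches(
            pf["fill_day"].tolist(),
            pf["drug_code"].tolist(),
            pf["drug_category"].tolist(),
        )
        person_meta[row.person_id] = {
            "death": death,
            "emig": emig,
            "index": row.index_day,
            "follow_up_end": row.follow_up_end_day,
            "initial_category": pf["drug_category"].iloc[0] if len(pf) else None,
        }
    if n_posthumous:
        log.warning(
            "dropped %d fill(s) dated after death/emigration/study end", n_posthumous
        )
    report["fills_after_censoring_dropped"] = n_posthumous

    all_graces = sorted(set(config.grace_list) | set(config.ppc_grace_list))
    episodes: dict[int, dict[object, list[TreatmentEpisode]]] = {}
    for g in all_graces:
        episodes[g] = {
            pid: derive_episodes(segs, g, person_meta[pid]["follow_up_end"])
            for pid, segs in segments.items()
        }

    cif_disc: dict[int, CIFEstimate] = {}
    cif_reinit: dict[int, CIFEstimate] = {}
    fg_records: pd.DataFrame | None = None
    for g in config.grace_list:
        disc_rows = []
        reinit_rows = []
        for pid, eps in episodes[g].items():
            meta = person_meta[pid]
            t, e = discontinuation_followup(
                eps, meta["index"], meta["death"], meta["emig"],
                config.study_end_day, config.event_time,
            )
            disc_rows.append((pid, t, e))
            for rt, re_ in reinitiation_followup(
                eps, meta["death"], meta["emig"], config.study_end_day, first_only=True
            ):
                reinit_rows.append((pid, rt, re_))
        disc_df = pd.DataFrame(disc_rows, columns=["person_id", "time", "event"])
        cif_disc[g] = aalen_johansen(disc_df["time"], disc_df["event"], cause=1)
        if reinit_rows:
            reinit_df = pd.DataFrame(reinit_rows, columns=["person_id", "time", "event"])
            cif_reinit[g] = aalen_johansen(reinit_df["time"], reinit_df["event"], cause=1)
        if g == config.grace_days:
            fg_records = disc_df

    eval_days = np.arange(0, config.eval_max + 1, config.eval_step)
    ppc_curves = {
        g: proportion_patients_covered(
            episodes[g], cohort, persons, g, eval_days,
            config.study_end_day, config.require_admin_coverage,
        )
        for g in config.ppc_grace_list
    }

    pdc_results = []
    for pid, segs in segments.items():
        meta = person_meta[pid]
        if meta["death"] is not None and meta["death"] < meta["index"] + config.pdc_window:
            continue  # died within the adherence window
        pdc_results.append(
            proportion_days_covered(segs, meta["index"], config.pdc_window, pid)
        )
    pdc = pdc_summary(pdc_results)

    traj_paths = []
    for pid, eps in episodes[config.grace_days].items():
        meta = person_meta[pid]
        if meta["index"] > config.study_end_day - config.horizon_days:
            continue  # not enough potential follow-up for the full horizon
        traj_paths.append(
            classify_trajectory(
                eps, switches[pid], meta["index"], meta["death"], meta["emig"],
                config.horizon_days, config.max_events,
                initial_category=meta["initial_category"],
            )
        )
    trajectory_summary = summarize_trajectories(traj_paths)
    report["trajectory_cohort_size"] = trajectory_summary.n

    fg_fits: dict[str, FGFit] = {}
    cohort_persons = pindex.loc[cohort["person_id"]].reset_index()
    assert fg_records is not None
    fg_records = fg_records.set_index("person_id").loc[cohort["person_id"]]
    base_X, base_names = build_design(cohort_persons)
    fg_fits["sex_age"] = fine_gray_fit(
        fg_records["time"].to_numpy(),
        fg_records["event"].to_numpy(),
        base_X.to_numpy(),
        names=base_names,
    )
    for covar in config.fg_extra_covariates:
        X, names = build_design(cohort_persons, extra=covar)
        fg_fits[covar] = fine_gray_fit(
            fg_records["time"].to_numpy(),
            fg_records["event"].to_numpy(),
            X.to_numpy(),
            names=names,
        )

    result = StudyResult(
        config=config,
        cohort=cohort,
        segments=segments,
        episodes=episodes,
        cif_discontinuation=cif_disc,
        cif_reinitiation=cif_reinit,
        ppc_curves=ppc_curves,
        pdc=pdc,
        trajectory_summary=trajectory_summary,
        fg_fits=fg_fits,
        report=report,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
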