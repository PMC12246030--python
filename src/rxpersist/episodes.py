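"""Drug-coverage segments, grace-period treatment episodes, switches and trajectories.

The exposure model works at the drug-class level on integer day indices with
half-open intervals ``[start, end)``:

* Each dispensation contributes ``days_supply`` days of drug.  When a refill
  arrives before the previous supply runs out, the surplus is *stockpiled*:
  the patient is assumed to finish the old supply first, so the new supply
  starts the day the pooled supply would otherwise have been exhausted.
* Contiguous (or stockpiled) supply forms :class:`CoverageSegment` s.
* Segments separated by at most ``grace_days`` belong to one
  :class:`TreatmentEpisode`.  A longer gap closes the episode; the
  discontinuation day is defined as the estimated end of supply plus the
  grace period.  The next segment's start is the reinitiation day.
* Filling a different drug code within the same class is a switch and never
  interrupts an episode (supplies pool across drugs of one class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DISCONTINUED = "discontinued"
ONGOING = "ongoing_at_censor"

#: Terminal states of a 3-year trajectory.
T_DISCONTINUED = "discontinued"
T_CONTINUED = "continued"
T_DIED_OR_EMIGRATED = "died_or_emigrated"


@dataclass(frozen=True)
class CoverageSegment:
    """A maximal interval of continuous drug supply, ``[start_day, end_day)``."""

    start_day: int
    end_day: int
    n_fills: int = 1

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError("end_day must exceed start_day")

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


@dataclass(frozen=True)
class TreatmentEpisode:
    """A grace-extended on-treatment period.

    ``discontinuation_day = supply_end_day + grace_days`` is only meaningful
    (and only set) when the episode ends in an observed discontinuation; an
    episode whose supply-plus-grace outlasts follow-up is ``ongoing_at_censor``.
    """

    episode_index: int  # 1-based per person
    start_day: int
    supply_end_day: int
    grace_days: int
    status: str
    discontinuation_day: int | None = None
    reinitiation_day: int | None = None

    @property
    def grace_end_day(self) -> int:
        """Day the grace period runs out (exclusive end of on-treatment time)."""
        return self.supply_end_day + self.grace_days


@dataclass(frozen=True)
class SwitchEvent:
    day: int
    from_code: str
    to_code: str
    from_category: str
    to_category: str

    def __post_init__(self) -> None:
        if self.from_code == self.to_code:
            raise ValueError("a switch requires different drug codes")


def resolve_days_supply(
    drug_code: str,
    quantity: float,
    supply_table: Mapping[str, float],
    default: float | None = None,
) -> int:
    """Days of supply for ``quantity`` dispensed package units of ``drug_code``.

    ``supply_table`` maps a drug code to estimated days of supply per package
    unit.  Codes missing from the table fall back to ``default`` days per
    unit; with no default the record is unresolvable and a ``KeyError`` is
    raised so the caller can reject (and count) it rather than silently
    treating it as zero supply.
    """
    if quantity <= 0:
        raise ValueError(f"dispensed quantity must be positive, got {quantity}")
    per_unit = supply_table.get(drug_code, default)
    if per_unit is None:
        raise KeyError(f"no days-of-supply estimate for drug code {drug_code!r}")
    days = int(round(quantity * per_unit))
    return max(days, 1)


def _combine_same_day(fill_days: Sequence[int], supplies: Sequence[int]):
    """Sort fills and sum supplies dispensed on the same day."""
    combined: dict[int, list[int]] = {}
    for d, s in zip(fill_days, supplies):
        if s < 1:
            raise ValueError("days_supply must be >= 1")
        if d in combined:
            combined[d][0] += s
            combined[d][1] += 1
        else:
            combined[d] = [s, 1]
    return sorted((d, s, k) for d, (s, k) in combined.items())


def build_coverage(
    fill_days: Sequence[int],
    supplies: Sequence[int],
    stockpiling: bool = True,
) -> list[CoverageSegment]:
    """Turn one person's class-level fills into disjoint coverage segments.

    With ``stockpiling`` (the default), an early refill is consumed only after
    the running supply is exhausted, so total covered days equal the total
    days dispensed.  Without stockpiling each fill covers
    ``[fill_day, fill_day + days_supply)`` and overlapping supply is wasted
    (intervals are unioned).
    """
    if len(fill_days) != len(supplies):
        raise ValueError("fill_days and supplies must have equal length")
    segments: list[list[int]] = []  # [start, end, n_fills]
    for day, supply, k in _combine_same_day(fill_days, supplies):
        if segments and day <= segments[-1][1]:
            seg = segments[-1]
            if stockpiling:
                seg[1] += supply
            else:
                seg[1] = max(seg[1], day + supply)
            seg[2] += k
        else:
            segments.append([day, day + supply, k])
    return [CoverageSegment(s, e, k) for s, e, k in segments]


def derive_episodes(
    segments: Sequence[CoverageSegment],
    grace_days: int,
    follow_up_end_day: int,
) -> list[TreatmentEpisode]:
    """Group coverage segments into grace-extended treatment episodes.

    Consecutive segments separated by a gap of at most ``grace_days`` belong
    to the same episode.  A longer gap closes the episode with an observed
    discontinuation at ``supply_end + grace_days`` and marks the next
    segment's start as the reinitiation day.  An episode whose
    supply-plus-grace extends beyond ``follow_up_end_day`` is ongoing at
    censoring: the discontinuation, if any, is not observed in follow-up.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    if not segments:
        return []
    groups: list[list[CoverageSegment]] = [[segments[0]]]
    for prev, cur in zip(segments, segments[1:]):
        if cur.start_day <= prev.end_day:
            raise ValueError("segments must be disjoint and sorted")
        if cur.start_day - prev.end_day <= grace_days:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    episodes: list[TreatmentEpisode] = []
    for i, group in enumerate(groups):
        start = group[0].start_day
        supply_end = group[-1].end_day
        disc = supply_end + grace_days
        if disc > follow_up_end_day:
            status, disc_day = ONGOING, None
        else:
            status, disc_day = DISCONTINUED, disc
        reinit = groups[i + 1][0].start_day if i + 1 < len(groups) else None
        episodes.append(
            TreatmentEpisode(
                episode_index=i + 1,
                start_day=start,
                supply_end_day=supply_end,
                grace_days=grace_days,
                status=status,
                discontinuation_day=disc_day,
                reinitiation_day=reinit,
            )
        )
    return episodes


# event codes shared with the competing-risks estimators
EVENT_CENSORED = 0
EVENT_OF_INTEREST = 1
EVENT_COMPETING_DEATH = 2


def _censor(day_candidates: list[tuple[int, int]]) -> tuple[int, int]:
    """Earliest (day, event_code); ties resolved by the given order."""
    return min(day_candidates, key=lambda t: (t[0], _TIE_RANK[t[1]]))


# event of interest wins a same-day tie with death (the person reached the
# event day); death wins over administrative censoring
_TIE_RANK = {EVENT_OF_INTEREST: 0, EVENT_COMPETING_DEATH: 1, EVENT_CENSORED: 2}


def discontinuation_followup(
    episodes: Sequence[TreatmentEpisode],
    index_day: int,
    death_day: int | None,
    emigration_day: int | None,
    study_end_day: int,
    event_time: str = "disc_day",
) -> tuple[int, int]:
    """Time-to-first-discontinuation record ``(time, event)`` for one person.

    Follow-up runs from the index date to the first of discontinuation
    (event 1), death (competing event 2), or emigration / administrative end
    of study (censored, 0).  ``event_time="supply_end"`` dates the
    discontinuation at the estimated end of supply instead of the default
    supply-end-plus-grace.
    """
    if event_time not in ("disc_day", "supply_end"):
        raise ValueError("event_time must be 'disc_day' or 'supply_end'")
    candidates = [(study_end_day, EVENT_CENSORED)]
    if death_day is not None:
        candidates.append((int(death_day), EVENT_COMPETING_DEATH))
    if emigration_day is not None:
        candidates.append((int(emigration_day), EVENT_CENSORED))
    if episodes and episodes[0].status == DISCONTINUED:
        ep = episodes[0]
        day = ep.discontinuation_day if event_time == "disc_day" else ep.supply_end_day
        candidates.append((day, EVENT_OF_INTEREST))
    day, event = _censor(candidates)
    # same-day fill and censoring: follow to the end of the index day
    return max(day - index_day, 1), event


def reinitiation_followup(
    episodes: Sequence[TreatmentEpisode],
    death_day: int | None,
    emigration_day: int | None,
    study_end_day: int,
    first_only: bool = True,
) -> list[tuple[int, int]]:
    """Time-to-reinitiation records, one per observed discontinuation.

    Each record starts the day treatment was discontinued and ends at the
    first of reinitiation (event 1), death (2), or emigration /
    administrative censoring (0).  By default only the first discontinuation
    per person is followed.
    """
    records: list[tuple[int, int]] = []
    for ep in episodes:
        if ep.status != DISCONTINUED:
            continue
        candidates = [(study_end_day, EVENT_CENSORED)]
        if death_day is not None:
            candidates.append((int(death_day), EVENT_COMPETING_DEATH))
        if emigration_day is not None:
            candidates.append((int(emigration_day), EVENT_CENSORED))
        if ep.reinitiation_day is not None:
            candidates.append((ep.reinitiation_day, EVENT_OF_INTEREST))
        day, event = _censor(candidates)
        records.append((max(day - ep.discontinuation_day, 1), event))
        if first_only:
            break
    return records


def detect_switches(
    fill_days: Sequence[int],
    drug_codes: Sequence[str],
    drug_categories: Sequence[str],
) -> list[SwitchEvent]:
    """Within-class switches: every fill whose code differs from the previous one.

    Code changes inside a residual "other" category still count as switches
    (with ``from_category == to_category``); they are just not broken down
    further.
    """
    order = sorted(range(len(fill_days)), key=lambda i: fill_days[i])
    switches: list[SwitchEvent] = []
    for prev, cur in zip(order, order[1:]):
        if drug_codes[cur] != drug_codes[prev]:
            switches.append(
                SwitchEvent(
                    day=int(fill_days[cur]),
                    from_code=drug_codes[prev],
                    to_code=drug_codes[cur],
                    from_category=drug_categories[prev],
                    to_category=drug_categories[cur],
                )
            )
    return switches


@dataclass(frozen=True)
class TrajectoryPath:
    """One person's event path over a fixed horizon after initiation."""

    events: tuple[tuple[int, str, str | None], ...]  # (day, kind, detail)
    terminal_state: str
    initial_category: str | None = None
    ever_switched: bool = False
    ever_reinitiated: bool = False
    first_switch_to: str | None = None
    switch_pairs: tuple[tuple[str, str], ...] = ()


def classify_trajectory(
    episodes: Sequence[TreatmentEpisode],
    switches: Sequence[SwitchEvent],
    index_day: int,
    death_day: int | None,
    emigration_day: int | None,
    horizon_days: int = 1095,
    max_events: int = 5,
    initial_category: str | None = None,
) -> TrajectoryPath:
    """Order a person's treatment events within ``horizon_days`` of initiation.

    The path records, time-ordered and truncated at ``max_events``: the first
    within-class switch, each discontinuation, each reinitiation, and death or
    emigration; a final ``continued`` marker is appended when treatment is
    ongoing at the horizon.  The terminal state at the horizon is computed
    before truncation.
    """
    h_end = index_day + horizon_days
    de_day: int | None = None
    for d in (death_day, emigration_day):
        if d is not None and d < h_end:
            de_day = int(d) if de_day is None else min(de_day, int(d))
    cutoff = h_end if de_day is None else de_day

    events: list[tuple[int, int, str, str | None]] = []  # (day, rank, kind, detail)
    in_horizon = sorted(
        (s for s in switches if s.day < cutoff), key=lambda s: s.day
    )
    if in_horizon:
        first = in_horizon[0]
        events.append((first.day, 1, "switch", first.to_category))
    for ep in episodes:
        if ep.status == DISCONTINUED and ep.discontinuation_day < cutoff:
            events.append((ep.discontinuation_day, 2, "discontinuation", None))
            if ep.reinitiation_day is not None and ep.reinitiation_day < cutoff:
                events.append((ep.reinitiation_day, 0, "reinitiation", None))
    if de_day is not None:
        events.append((de_day, 3, "death_or_emigration", None))
        terminal = T_DIED_OR_EMIGRATED
    else:
        on_treatment = any(
            ep.start_day <= h_end - 1 < ep.grace_end_day for ep in episodes
        )
        if on_treatment:
            events.append((h_end - 1, 4, "continued", None))
            terminal = T_CONTINUED
        else:
            terminal = T_DISCONTINUED
    events.sort(key=lambda e: (e[0], e[1]))
    path = tuple((d, kind, detail) for d, _, kind, detail in events[:max_events])
    return TrajectoryPath(
        events=path,
        terminal_state=terminal,
        initial_category=initial_category,
        ever_switched=bool(in_horizon),
        ever_reinitiated=any(k == "reinitiation" for _, _, k, _ in events),
        first_switch_to=in_horizon[0].to_category if in_horizon else None,
        switch_pairs=tuple((s.from_category, s.to_category) for s in in_horizon),
    )


def _pct(count: int, denom: int) -> float:
    """Percentage to one decimal; 0.0 for an empty denominator."""
    return round(100.0 * count / denom, 1) if denom else 0.0


@dataclass(frozen=True)
class TrajectorySummary:
    """Cohort-level trajectory counts with percentages to one decimal."""

    n: int
    n_discontinued: int
    n_continued: int
    n_died_or_emigrated: int
    n_ever_switched: int
    n_reinitiated_among_discontinued: int
    initiator_counts: Mapping[str, int] = field(default_factory=dict)
    first_switch_counts: Mapping[tuple[str, str], int] = field(default_factory=dict)
    switch_matrix: Mapping[tuple[str, str], int] = field(default_factory=dict)

    @property
    def pct_discontinued(self) -> float:
        return _pct(self.n_discontinued, self.n)

    @property
    def pct_continued(self) -> float:
        return _pct(self.n_continued, self.n)

    @property
    def pct_died_or_emigrated(self) -> float:
        return _pct(self.n_died_or_emigrated, self.n)

    @property
    def pct_ever_switched(self) -> float:
        return _pct(self.n_ever_switched, self.n)

    @property
    def pct_reinitiated_among_discontinued(self) -> float:
        return _pct(self.n_reinitiated_among_discontinued, self.n_discontinued)

    def pct_first_switch(self, from_category: str, to_category: str) -> float:
        """First switches from one category to another, as a percentage of
        all initiators of the source category."""
        return _pct(
            self.first_switch_counts.get((from_category, to_category), 0),
            self.initiator_counts.get(from_category, 0),
        )

    @classmethod
    def from_counts(
        cls,
        n: int,
        n_discontinued: int,
        n_continued: int,
        n_died_or_emigrated: int,
        n_ever_switched: int,
        n_reinitiated_among_discontinued: int,
        initiator_counts: Mapping[str, int] | None = None,
        first_switch_counts: Mapping[tuple[str, str], int] | None = None,
    ) -> "TrajectorySummary":
        return cls(
            n=n,
            n_discontinued=n_discontinued,
            n_continued=n_continued,
            n_died_or_emigrated=n_died_or_emigrated,
            n_ever_switched=n_ever_switched,
            n_reinitiated_among_discontinued=n_reinitiated_among_discontinued,
            initiator_counts=dict(initiator_counts or {}),
            first_switch_counts=dict(first_switch_counts or {}),
        )


def summarize_trajectories(paths: Iterable[TrajectoryPath]) -> TrajectorySummary:
    """Aggregate trajectory paths into terminal-state and switching counts."""
    paths = list(paths)
    n_disc = sum(p.terminal_state == T_DISCONTINUED for p in paths)
    n_cont = sum(p.terminal_state == T_CONTINUED for p in paths)
    n_died = sum(p.terminal_state == T_DIED_OR_EMIGRATED for p in paths)
    n_switched = sum(p.ever_switched for p in paths)
    n_reinit = sum(
        p.ever_reinitiated for p in paths if p.terminal_state == T_DISCONTINUED
    )
    initiators: dict[str, int] = {}
    first_switch: dict[tuple[str, str], int] = {}
    matrix: dict[tuple[str, str], int] = {}
    for p in paths:
        if p.initial_category is not None:
            initiators[p.initial_category] = initiators.get(p.initial_category, 0) + 1
            if p.first_switch_to is not None:
                key = (p.initial_category, p.first_switch_to)
                first_switch[key] = first_switch.get(key, 0) + 1
        for pair in p.switch_pairs:
            matrix[pair] = matrix.get(pair, 0) + 1
    return TrajectorySummary(
        n=len(paths),
        n_discontinued=n_disc,
        n_continued=n_cont,
        n_died_or_emigrated=n_died,
        n_ever_switched=n_switched,
        n_reinitiated_among_discontinued=n_reinit,
        initiator_counts=initiators,
        first_switch_counts=first_switch,
        switch_matrix=matrix,
    )
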