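import numpy as np
import pytest

from rxpersist.episodes import CoverageSegment
from rxpersist.simulate import SimConfig, simulate_registry


@pytest.fixture(scope="session")
def small_registry():
    """A small synthetic register shared across tests (deterministic)."""
    cfg = SimConfig(n_patients=300, seed=20240901)
    fills, persons, truth = simulate_registry(cfg)
    return cfg, fills, persons, truth


def random_fill_stream(rng: np.random.Generator, max_fills: int = 8):
    """A random per-person fill stream: (fill_days, supplies)."""
    n = int(rng.integers(1, max_fills + 1))
    days = np.sort(rng.choice(np.arange(0, 1000), size=n, replace=False))
    supplies = rng.integers(1, 121, size=n)
    return days.tolist(), supplies.tolist()


def scan_episodes_daily(segments, grace, follow_up_end_day):
    """Independent day-by-day scanner for episode construction.

    Walks the calendar one day at a time tracking covered/uncovered streaks;
    used as an oracle against the interval-based implementation.  Returns
    tuples (start, supply_end, discontinuation_day_or_None, reinit_or_None).
    """
    covered = set()
    for seg in segments:
        covered.update(range(seg.start_day, seg.end_day))
    if not covered:
        return []
    episodes = []
    run = None  # [first covered day, last covered day]
    streak = 0
    horizon = max(covered) + grace + 2
    for t in range(min(covered), horizon):
        if t in covered:
            if run is None:
                run = [t, t]
            else:
                run[1] = t
            streak = 0
        elif run is not None:
            streak += 1
            if streak > grace:
                supply_end = run[1] + 1
                disc = supply_end + grace
                episodes.append(
                    [run[0], supply_end, disc if disc <= follow_up_end_day else None]
                )
                run = None
    if run is not None:
        supply_end = run[1] + 1
        disc = supply_end + grace
        episodes.append(
            [run[0], supply_end, disc if disc <= follow_up_end_day else None]
        )
    out = []
    for i, (start, supply_end, disc) in enumerate(episodes):
        reinit = episodes[i + 1][0] if i + 1 < len(episodes) else None
        out.append((start, supply_end, disc, reinit))
    return out


def segments_from_fills(days, supplies):
    """Reference stockpiled coverage built day-by-day from a supply counter."""
    remaining = 0.0
    covered = []
    events = sorted(zip(days, supplies))
    t = events[0][0]
    idx = 0
    while idx < len(events) or remaining > 0:
        while idx < len(events) and events[idx][0] == t:
            remaining += events[idx][1]
            idx += 1
        if remaining > 0:
            covered.append(t)
            remaining -= 1
            t += 1
        elif idx < len(events):
            t = events[idx][0]
    segs = []
    for d in covered:
        if segs and d == segs[-1][1]:
            segs[-1][1] = d + 1
        else:
            segs.append([d, d + 1])
    return [CoverageSegment(s, e) for s, e in segs]
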