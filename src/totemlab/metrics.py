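"""Behavioral measures computed from event logs.

Every measure is recomputed from the serialized event stream alone, so the
same code applies to live simulation output and to logs read back from
disk.  The tidy participant table produced here is the direct input of the
stats module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EventLog, SessionResult
from .landscape import TotemScoreParams, final_score


class MetricError(ValueError):
    pass


MISSING = float("nan")


@dataclass(frozen=True)
class ReproductionTime:
    """Latest first-reproduction time among inherited items, or missing."""

    seconds: float
    complete: bool
    n_inherited: int
    n_reproduced: int


def _inherited_items(events: EventLog) -> list[str]:
    inh = events.of_type("inherit")
    if not inh:
        raise MetricError("session has no inherit event")
    return list(inh[0].payload["items"])


def time_to_reproduce_inherited(events: EventLog) -> ReproductionTime:
    """Seconds until the last inherited item is first reproduced.

    The time attributed to a participant is the timestamp of the inherited
    item they reproduced at the latest time.  If not every inherited item
    was reproduced the value is missing and flagged.
    """
    inherited = _inherited_items(events)
    if not inherited:
        raise MetricError("no items were inherited (first generation)")
    first_prod: dict[str, int] = {}
    targets = set(inherited)
    for e in events.of_type("discover"):
        item = e.payload["item"]
        if item in targets and item not in first_prod:
            first_prod[item] = e.t
    complete = len(first_prod) == len(targets)
    seconds = float(max(first_prod.values())) if complete else MISSING
    return ReproductionTime(
        seconds=seconds,
        complete=complete,
        n_inherited=len(targets),
        n_reproduced=len(first_prod),
    )


def monitoring_count(events: EventLog) -> int:
    """Number of record switches (the proxy for social-learning cost)."""
    return len(events.of_type("observe_switch"))


def combinations_in_window(events: EventLog, window: tuple[float, float]) -> int:
    """Number of workshop attempts with time in [start, end)."""
    start, end = window
    return sum(1 for e in events.of_type("try") if start <= e.t < end)


def novelty_probability(
    participant_events: EventLog,
    unit_logs: list[tuple[EventLog, int]],
    participant: str | None = None,
    successes_only: bool = False,
) -> tuple[int, int]:
    """(novel, total) combination counts for one unit member.

    ``unit_logs`` holds (event log, global time offset in seconds) for every
    member of the chain or group, including the focal participant; offsets
    place chain generations one after another on a common timeline, while
    group members share offset 0.  An attempt is novel iff its canonical key
    was not attempted by any *other* member strictly earlier on the common
    timeline.
    """
    if participant is None:
        tries = participant_events.of_type("try")
        if not tries:
            return (0, 0)
        participant = tries[0].participant

    own_off = None
    for log, off in unit_logs:
        if any(e.participant == participant for e in log.events):
            own_off = off
            break
    if own_off is None:
        raise MetricError(f"participant {participant} not found in unit logs")

    etype = "discover" if successes_only else "try"
    others: list[tuple[int, tuple[str, ...]]] = []
    for log, off in unit_logs:
        for e in log.of_type(etype):
            if e.participant == participant:
                continue
            key = tuple(e.payload["key"])
            others.append((e.t + off, key))
    others.sort(key=lambda x: x[0])

    own = [
        (e.t + own_off, tuple(e.payload["key"]))
        for e in participant_events.of_type(etype)
    ]
    own.sort(key=lambda x: x[0])

    seen: set[tuple[str, ...]] = set()
    j = 0
    novel = 0
    for t, key in own:
        while j < len(others) and others[j][0] < t:
            seen.add(others[j][1])
            j += 1
        if key not in seen:
            novel += 1
    return novel, len(own)


def score_trajectory(
    events: EventLog, params: TotemScoreParams | None = None
) -> list[tuple[int, float]]:
    """(time, running final score) after every scoring-relevant event."""
    params = params or TotemScoreParams()
    best = 0.0
    n_items = 0
    out = [(0, 0.0)]
    for e in events:
        if e.etype == "discover":
            n_items += 1
        elif e.etype == "totem":
            best = max(best, float(e.payload["score"]))
        else:
            continue
        out.append((e.t, final_score(best, n_items, params)))
    return out


def score_at(
    accumulated_minutes: float,
    lineage: list[SessionResult],
    group_size: int = 1,
    params: TotemScoreParams | None = None,
) -> float:
    """Lineage score at a stated accumulated (pooled) learner-time.

    For groups, a session of t minutes with k members counts as k*t
    accumulated minutes, so the requested time maps to t = acc/k within the
    single session.  For chains and repeated individuals the accumulated
    time is the running sum of session durations; a time falling at a
    session boundary returns that session's final score, a time inside a
    session returns the running score at that moment.
    """
    acc_s = accumulated_minutes * 60.0 * (1.0 / group_size)
    spans = [r.plan.duration_s for r in lineage]
    if acc_s > sum(spans) + 1e-9:
        raise MetricError(
            f"accumulated time {accumulated_minutes} min exceeds lineage span"
        )
    elapsed = 0.0
    for r, span in zip(lineage, spans):
        if acc_s <= elapsed + span + 1e-9:
            within = acc_s - elapsed
            if within >= span - 1e-9:
                return float(r.final_score)
            traj = score_trajectory(r.events, params)
            score = 0.0
            for t, s in traj:
                if t <= within:
                    score = s
                else:
                    break
            return float(score)
        elapsed += span
    return float(lineage[-1].final_score)  # pragma: no cover


# ---------------------------------------------------------------------------
# Tidy tables
# ---------------------------------------------------------------------------


def participant_row(result: SessionResult, unit_logs=None) -> dict:
    ev = result.events
    duration = result.plan.duration_s
    half = duration / 2
    row = {
        "design": result.plan.design,
        "unit": result.plan.unit,
        "participant": result.plan.participant,
        "generation": result.plan.generation,
        "session_minutes": duration // 60,
        "final_score": result.final_score,
        "best_totem": result.best_totem,
        "n_new_items": result.n_new_items,
        "items_inherited": len(result.inherited_items),
        "monitoring": monitoring_count(ev),
        "combinations": combinations_in_window(ev, (0, duration)),
        "combinations_h1": combinations_in_window(ev, (0, half)),
        "combinations_h2": combinations_in_window(ev, (half, duration)),
        "time_to_reproduce_s": MISSING,
        "reproduction_complete": True,
    }
    if duration > 1500:
        # mid-session snapshot after 25 min, for accumulated-time comparisons
        traj = score_trajectory(ev)
        row["score_at_25min"] = max(
            (s for t, s in traj if t <= 1500), default=0.0
        )
    if result.inherited_items:
        rt = time_to_reproduce_inherited(ev)
        row["time_to_reproduce_s"] = rt.seconds
        row["reproduction_complete"] = rt.complete
    if unit_logs is not None:
        novel, total = novelty_probability(ev, unit_logs)
        row["novel_combinations"] = novel
        row["total_combinations"] = total
    return row


def participant_table(experiment) -> pd.DataFrame:
    """One row per participant-session, with unit-level novelty filled in."""
    rows = []
    for unit in experiment.units:
        sessions = experiment.unit_sessions(unit)
        unit_logs = [
            (r.events, r.plan.global_offset_s) for r in sessions
        ]
        social = experiment.plan.design in ("chain", "group")
        for r in sessions:
            rows.append(participant_row(r, unit_logs if social else None))
    return pd.DataFrame(rows)


def experiment_tables(experiments: list) -> pd.DataFrame:
    """Concatenate participant tables of several cohort runs."""
    return pd.concat(
        [participant_table(e) for e in experiments], ignore_index=True
    )
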