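"""The four experimental designs: orchestration, inheritance, and timing.

* extended_individual: one continuous 50-minute session.
* repeated_individual: four 25-minute sessions, each inheriting the
  participant's own innovation record; practice carries over.
* chain: four generations of 25 minutes; each generation inherits the
  record of the previous participant in the chain.
* group: one 25-minute session played simultaneously by 2 or 4 members who
  can observe each other's records, refreshed on a 10-second cadence.

Every stochastic draw uses a hierarchical seed (experiment -> unit ->
session), recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agents import Action, AgentPolicy, AgentSession, ExperienceState, effort_multiplier
from .engine import (
    EngineError,
    GameState,
    InnovationRecord,
    SessionPlan,
    SessionResult,
    build_totem,
    empty_record,
    end_session,
    observe_record,
    start_session,
    try_combination,
)
from .landscape import TechTree

DESIGNS = ("extended_individual", "repeated_individual", "chain", "group")

GROUP_SYNC_S = 10  # peers' records and scores refresh every 10 s

#: cohort sizes of the study: 41 extended individuals, 59 repeated
#: individuals, 53 chains of four, 53 groups of two, 38 groups of four
DEFAULT_COHORTS = {
    "extended_individual": 41,
    "repeated_individual": 59,
    "chain": 53,
    "group2": 53,
    "group4": 38,
}


class ConditionError(ValueError):
    pass


@dataclass(frozen=True)
class CohortPlan:
    """Who plays when, for how long, inheriting from whom."""

    design: str
    session_minutes: int
    n_sessions: int
    n_units: int
    group_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ConditionError(f"unknown design {self.design!r}")
        if self.design == "group" and self.group_size not in (2, 4):
            raise ConditionError("group_size must be 2 or 4")
        if self.session_minutes <= 0 or self.n_units <= 0:
            raise ConditionError("session_minutes and n_units must be positive")

    @property
    def duration_s(self) -> int:
        return self.session_minutes * 60

    @property
    def n_participants(self) -> int:
        if self.design == "group":
            return self.n_units * self.group_size
        if self.design == "chain":
            return self.n_units * self.n_sessions
        return self.n_units

    def accumulated_minutes(self) -> int:
        """Pooled learner-time per lineage/unit, the Fig.-2 comparison axis."""
        if self.design == "group":
            return self.session_minutes * self.group_size
        return self.session_minutes * self.n_sessions


def make_cohort_plan(
    design: str, params: dict | None = None, seed: int = 0
) -> CohortPlan:
    """Deterministic plan with the study's session structure and cohort sizes."""
    params = dict(params or {})
    group_size = int(params.pop("group_size", 2))
    if design == "extended_individual":
        defaults = dict(session_minutes=50, n_sessions=1,
                        n_units=DEFAULT_COHORTS["extended_individual"])
    elif design == "repeated_individual":
        defaults = dict(session_minutes=25, n_sessions=4,
                        n_units=DEFAULT_COHORTS["repeated_individual"])
    elif design == "chain":
        defaults = dict(session_minutes=25, n_sessions=4,
                        n_units=DEFAULT_COHORTS["chain"])
    elif design == "group":
        if group_size not in (2, 4):
            raise ConditionError("group_size must be 2 or 4")
        defaults = dict(session_minutes=25, n_sessions=1,
                        n_units=DEFAULT_COHORTS[f"group{group_size}"])
    else:
        raise ConditionError(f"unknown design {design!r}")
    defaults.update(params)
    return CohortPlan(design=design, group_size=group_size, seed=seed, **defaults)


def transmit_record(source: SessionResult) -> InnovationRecord:
    """The full record passed to the next session: recipes only, verbatim."""
    if not source.complete:
        raise ConditionError("cannot transmit an incomplete session")
    return source.record.copy()


@dataclass
class ExperimentLog:
    """All session results of one cohort run, plus the seed manifest."""

    plan: CohortPlan
    sessions: dict[tuple[str, int, str], SessionResult] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def add(self, unit: str, generation: int, result: SessionResult) -> None:
        self.sessions[(unit, generation, result.plan.participant)] = result

    def unit_sessions(self, unit: str) -> list[SessionResult]:
        out = [r for (u, g, p), r in self.sessions.items() if u == unit]
        return sorted(out, key=lambda r: (r.plan.generation, r.plan.participant))

    @property
    def units(self) -> list[str]:
        return sorted({u for (u, g, p) in self.sessions})

    def results(self) -> list[SessionResult]:
        return [self.sessions[k] for k in sorted(self.sessions)]


# ---------------------------------------------------------------------------
# Session runners
# ---------------------------------------------------------------------------


def _charge(policy, action: Action, state: GameState) -> int:
    """Clock cost of an action: duration divided by the effort multiplier."""
    mult = effort_multiplier(policy, float(state.clock))
    return max(1, round(action.seconds / mult))


def _execute(agent: AgentSession, state: GameState, action: Action,
             snapshot_provider=None):
    if action.kind == "try":
        result = try_combination(state, action.items)
        agent.notify(state, action, result)
    elif action.kind == "totem":
        build_totem(state, action.items)
        agent.notify(state, action)
    elif action.kind == "observe":
        snapshot = None
        if snapshot_provider is not None:
            snapshot = snapshot_provider(action.target, state.clock)
        view = observe_record(state, action.target, snapshot)
        agent.notify(state, action)
        if snapshot is not None and isinstance(view, InnovationRecord):
            agent.learn_from_snapshot(state, view)
    else:  # idle
        agent.notify(state, action)


def run_session(
    agent: AgentSession,
    plan: SessionPlan,
    inherited: InnovationRecord | None,
    tree: TechTree,
) -> SessionResult:
    """Run one solo session (individual or chain generation) to completion."""
    state = start_session(plan, inherited, tree)
    agent.experience.new_session(agent.policy.carryover)
    agent.start(state)
    while state.clock < plan.duration_s:
        action = agent.act(state)
        dt = _charge(agent.policy, action, state)
        if state.clock + dt >= plan.duration_s:
            state.clock = plan.duration_s
            break
        state.advance(dt)
        _execute(agent, state, action)
    return end_session(state)


def record_snapshot_at(
    record: InnovationRecord, now: int, sync_s: int = GROUP_SYNC_S
) -> InnovationRecord:
    """A peer's record as visible at time ``now`` under periodic refresh.

    Only entries discovered at or before the last sync point (the largest
    multiple of ``sync_s`` not exceeding ``now``) are visible, so a
    discovery at t=103 s becomes visible to others at t=110 s.
    """
    sync_t = (int(now) // sync_s) * sync_s
    return InnovationRecord(
        record.owner, [e for e in record.entries if e.t <= sync_t]
    )


def run_group_session(
    agents: list[AgentSession],
    plans: list[SessionPlan],
    tree: TechTree,
) -> list[SessionResult]:
    """Run a group session with members interleaved on a shared clock.

    Members act independently; observing a peer returns that peer's record
    as of the last 10-second sync point, never their live state.
    """
    states = [start_session(p, None, tree) for p in plans]
    by_pid = {p.participant: s for p, s in zip(plans, states)}
    for a, s in zip(agents, states):
        a.experience.new_session(a.policy.carryover)
        a.start(s)

    def snapshot_provider(target: str, now: int) -> InnovationRecord:
        return record_snapshot_at(by_pid[target].record, now)

    duration = plans[0].duration_s
    # event queue keyed by each member's next decision time
    next_t = [0] * len(agents)
    pending: list[tuple[Action, int] | None] = [None] * len(agents)
    while True:
        i = min(range(len(agents)), key=lambda j: (next_t[j], j))
        if next_t[i] >= duration:
            break
        state = states[i]
        if pending[i] is None:
            state.clock = next_t[i]
            action = agents[i].act(state)
            dt = _charge(agents[i].policy, action, state)
            if next_t[i] + dt >= duration:
                next_t[i] = duration
                continue
            pending[i] = (action, next_t[i] + dt)
            next_t[i] += dt
        else:
            action, done_t = pending[i]
            state.clock = done_t
            _execute(agents[i], state, action, snapshot_provider)
            pending[i] = None
    results = []
    for s in states:
        s.clock = duration
        results.append(end_session(s))
    return results


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_experiment(
    plan: CohortPlan,
    policy: AgentPolicy,
    tree: TechTree,
    seed: int | None = None,
) -> ExperimentLog:
    """Execute all sessions of a cohort with the design's topology."""
    master = np.random.SeedSequence(plan.seed if seed is None else seed)
    unit_seeds = master.spawn(plan.n_units)
    log = ExperimentLog(plan=plan, manifest={
        "design": plan.design,
        "seed": plan.seed if seed is None else seed,
        "unit_seeds": [_derive_seed(s) for s in unit_seeds],
    })
    duration = plan.duration_s

    for u in range(plan.n_units):
        unit = f"{plan.design}-{plan.group_size}-{u:03d}" if plan.design == "group" \
            else f"{plan.design}-{u:03d}"
        u_ss = unit_seeds[u]

        if plan.design == "group":
            pids = [f"{unit}-m{m}" for m in range(plan.group_size)]
            member_seeds = u_ss.spawn(plan.group_size)
            agents = []
            plans = []
            for pid, ss in zip(pids, member_seeds):
                others = tuple(p for p in pids if p != pid)
                plans.append(SessionPlan(
                    participant=pid, duration_s=duration, design="group",
                    generation=1, unit=unit, visible=others,
                ))
                agents.append(AgentSession(
                    policy, ExperienceState(),
                    np.random.default_rng(ss), tree,
                ))
            for result in run_group_session(agents, plans, tree):
                log.add(unit, 1, result)
            continue

        design = plan.design
        carry = design == "repeated_individual"
        run_policy = replace(policy, carryover=carry) \
            if policy.carryover != carry else policy
        session_seeds = u_ss.spawn(plan.n_sessions)
        inherited: InnovationRecord | None = None
        experience = ExperienceState()
        prev_pid: str | None = None
        for g in range(1, plan.n_sessions + 1):
            if design == "chain":
                pid = f"{unit}-g{g}"
                experience = ExperienceState()  # a fresh participant each generation
            else:
                pid = unit
            sp = SessionPlan(
                participant=pid, duration_s=duration, design=design,
                generation=g, unit=unit,
                inherit_from=prev_pid,
                visible=(prev_pid,) if prev_pid else (),
                global_offset_s=(g - 1) * duration,
            )
            agent = AgentSession(
                run_policy, experience,
                np.random.default_rng(session_seeds[g - 1]), tree,
            )
            inh = inherited.copy(pid) if inherited is not None else empty_record(pid)
            result = run_session(agent, sp, inh, tree)
            log.add(unit, g, result)
            inherited = transmit_record(result)
            prev_pid = pid
    return log
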