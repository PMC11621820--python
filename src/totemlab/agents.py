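"""Synthetic participant policies.

Agents generate behavior with the statistical structure the analyses
assume:

* a power law of practice: actions get faster with accumulated experience,
  and reproducing a specific item gets faster each time the agent has
  personally produced it before;
* social-learning reproduction costs: reproducing an item known only from
  someone else's record requires consulting that record (a monitoring
  event plus a time overhead); familiar items need only a brief glance at
  the agent's own record;
* within-session motivation decay: beyond a threshold of continuous play
  the attempt rate decays smoothly (so a 50-minute session slows down in
  its second half while four separate 25-minute sessions do not);
* redundant exploration: exploratory combinations are drawn uniformly at
  random from the untried portion of the currently feasible combination
  space, so co-present group members duplicate each other's attempts far
  more than chain members who inherit a predecessor's frontier.

Exploration is lightly guided: a small "insight" fraction of exploratory
draws is directed at currently satisfiable, untried recipes, standing in
for the visual and semantic cues human players exploit.  Without it a
uniform searcher would rarely progress past the first recipe layer within
a 25-minute session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import numpy as np

from .engine import GameState, InnovationRecord
from .landscape import MAX_SLOTS, TechTree, canonical_combination, count_multisets


class AgentError(RuntimeError):
    pass


@dataclass(frozen=True)
class AgentPolicy:
    """Parameters governing synthetic participant behavior.

    Durations are in seconds; rates are per minute.  Defaults are calibrated
    so that a naive participant makes roughly 220 workshop attempts in a
    25-minute session, a 50-minute session shows a ~16% drop in attempts in
    its second half, and reproduction of an inherited record costs a novice
    about 25 s per item but a practiced owner only a few seconds.
    """

    base_action_seconds: float = 7.2
    learning_exponent: float = 0.02  # global power-law pacing over all actions
    min_action_seconds: float = 1.0
    reproduction_overhead: float = 18.0  # per consultation of an unfamiliar record
    familiar_overhead: float = 2.0  # glance at a record the agent already knows
    item_practice_exponent: float = 0.55  # per-item power law for reproduction
    motivation_halflife: float = 2400.0
    motivation_onset: float = 1500.0  # decay starts beyond 25 min of continuous play
    monitor_rate: float = 0.8  # spontaneous record checks per minute per visible peer
    monitor_seconds: float = 4.0
    totem_seconds: float = 4.0
    insight: float = 0.02  # share of exploratory draws guided to the frontier
    exploration: str = "uniform"  # or "complexity_biased"
    anchor_bias: float = 0.7  # anchored-draw share in complexity_biased mode
    action_jitter: float = 0.6  # lognormal sigma of per-action duration noise
    carryover: bool = False  # experience persists across the agent's own sessions

    def __post_init__(self):
        for name in (
            "base_action_seconds",
            "min_action_seconds",
            "motivation_halflife",
        ):
            if getattr(self, name) <= 0:
                raise AgentError(f"{name} must be positive")
        if self.learning_exponent < 0 or self.item_practice_exponent < 0:
            raise AgentError("practice exponents must be >= 0")
        if not 0 <= self.insight <= 1:
            raise AgentError("insight must lie in [0, 1]")
        if self.action_jitter < 0:
            raise AgentError("action_jitter must be >= 0")
        if self.exploration not in ("uniform", "complexity_biased"):
            raise AgentError(f"unknown exploration mode {self.exploration!r}")


@dataclass
class ExperienceState:
    """Accumulated practice of one agent across their own sessions."""

    total_actions: int = 0
    session_elapsed: float = 0.0
    production_counts: dict[str, int] = field(default_factory=dict)

    def record_action(self) -> None:
        self.total_actions += 1

    def record_production(self, item: str) -> None:
        self.production_counts[item] = self.production_counts.get(item, 0) + 1

    def times_produced(self, item: str) -> int:
        return self.production_counts.get(item, 0)

    def new_session(self, carryover: bool) -> None:
        self.session_elapsed = 0.0
        if not carryover:
            self.total_actions = 0
            self.production_counts = {}


def action_duration(policy: AgentPolicy, experience: ExperienceState | int) -> float:
    """Seconds per workshop action under the global power law of practice."""
    n = experience if isinstance(experience, int) else experience.total_actions
    if n < 0:
        raise AgentError("experience must be >= 0")
    dur = policy.base_action_seconds * (n + 1) ** (-policy.learning_exponent)
    return max(policy.min_action_seconds, dur)


def effort_multiplier(policy: AgentPolicy, session_elapsed: float) -> float:
    """Attempt-rate multiplier in (0, 1]; decays beyond the motivation onset."""
    if session_elapsed < 0:
        raise AgentError("session_elapsed must be >= 0")
    if session_elapsed <= policy.motivation_onset:
        return 1.0
    excess = session_elapsed - policy.motivation_onset
    return 0.5 ** (excess / policy.motivation_halflife)


def plan_reproduction(
    record: InnovationRecord, produced: set[str], tree: TechTree
) -> list[str]:
    """Topologically ordered minimal try-sequence reproducing a record.

    Returns the record items not yet produced, ordered so every item's
    ingredients are available (base, already produced, or earlier in the
    plan) when its turn comes.  Raises if any record item is unsatisfiable.
    """
    record.validate_against(tree)
    have = set(produced) | set(tree.base_ids)
    todo = [e.item for e in record.entries if e.item not in have]
    plan: list[str] = []
    remaining = list(todo)
    while remaining:
        progressed = False
        rest = []
        for item in remaining:
            if all(i in have for i in tree.recipes[item].key):
                plan.append(item)
                have.add(item)
                progressed = True
            else:
                rest.append(item)
        if not progressed:
            raise AgentError(f"record items {rest} are unsatisfiable from this state")
        remaining = rest
    return plan


@dataclass(frozen=True)
class Action:
    kind: str  # try | observe | totem | idle
    seconds: float
    items: tuple[str, ...] = ()
    target: str | None = None
    is_reproduction: bool = False


# size threshold below which the untried combination pool is enumerated
_SMALL_SPACE = 4000


class AgentSession:
    """Stateful per-session decision maker wrapping an AgentPolicy.

    Priorities each step: build a totem if a new log was just produced;
    otherwise work through the pending reproduction plan (consulting the
    source record when the item is unfamiliar); otherwise, in groups, check
    a peer's record when the monitoring clock says so; otherwise explore an
    untried feasible combination.
    """

    def __init__(
        self,
        policy: AgentPolicy,
        experience: ExperienceState,
        rng: np.random.Generator,
        tree: TechTree,
    ):
        self.policy = policy
        self.experience = experience
        self.rng = rng
        self.tree = tree
        self.repro_queue: list[str] = []
        self.repro_source: str | None = None
        self.pending_totem = False
        self.known_from_others: set[str] = set()  # items seen in peers' records
        self.next_monitor_s: float | None = None
        self._pool: list[tuple[str, ...]] | None = None
        self._pool_n_produced = -1
        self._last_discovered: str | None = None

    # -- setup -----------------------------------------------------------
    def start(self, state: GameState) -> None:
        if state.inherited.entries:
            self.repro_queue = plan_reproduction(
                state.inherited, state.produced, self.tree
            )
            self.repro_source = state.plan.inherit_from or state.participant
        if state.plan.visible and state.plan.design == "group":
            self._schedule_monitor(0.0, len(state.plan.visible))

    def _schedule_monitor(self, now: float, n_peers: int) -> None:
        rate = self.policy.monitor_rate * n_peers / 60.0
        if rate <= 0:
            self.next_monitor_s = None
        else:
            self.next_monitor_s = now + float(self.rng.exponential(1.0 / rate))

    def _jittered(self, action: Action) -> Action:
        """Multiplicative mean-one lognormal noise on action durations."""
        s = self.policy.action_jitter
        if s <= 0 or action.kind == "idle":
            return action
        factor = float(self.rng.lognormal(-0.5 * s * s, s))
        return replace(action, seconds=action.seconds * factor)

    # -- action selection -------------------------------------------------
    def act(self, state: GameState) -> Action:
        return self._jittered(self._choose(state))

    def _choose(self, state: GameState) -> Action:
        policy = self.policy
        if self.pending_totem:
            logs = self._best_totem_logs(state)
            if logs is not None:
                return Action("totem", policy.totem_seconds, items=logs)
            self.pending_totem = False

        if self.repro_queue:
            item = self.repro_queue[0]
            familiar = self.experience.times_produced(item) > 0
            source = self.repro_source or state.participant
            if not familiar and source != state.participant and state.view != source:
                return Action(
                    "observe", policy.reproduction_overhead, target=source,
                    is_reproduction=True,
                )
            key = self.tree.recipes[item].key
            dur = action_duration(policy, self.experience)
            if familiar:
                dur = policy.familiar_overhead + max(
                    policy.min_action_seconds,
                    dur
                    * (self.experience.times_produced(item) + 1)
                    ** (-policy.item_practice_exponent),
                )
            return Action("try", dur, items=key, is_reproduction=True)

        if (
            self.next_monitor_s is not None
            and state.clock >= self.next_monitor_s
            and state.plan.visible
        ):
            target = str(self.rng.choice(list(state.plan.visible)))
            return Action("observe", policy.monitor_seconds, target=target)

        combo = self._draw_exploration(state)
        if combo is None:
            return Action("idle", policy.base_action_seconds)
        return Action("try", action_duration(policy, self.experience), items=combo)

    # -- feedback ---------------------------------------------------------
    def notify(self, state: GameState, action: Action, result=None) -> None:
        """Update internal state after the runner executed ``action``."""
        self.experience.record_action()
        self.experience.session_elapsed = float(state.clock)
        if action.kind == "try":
            if result is not None and result.success:
                self.experience.record_production(result.product)
                if result.new_item:
                    self._last_discovered = result.product
                    if result.product in self.tree.log_values:
                        self.pending_totem = True
            if action.is_reproduction and self.repro_queue:
                if result is not None and result.success:
                    self.repro_queue.pop(0)
                else:  # defensive: drop an unproducible head
                    self.repro_queue.pop(0)
        elif action.kind == "totem":
            self.pending_totem = False
        elif action.kind == "observe" and not action.is_reproduction:
            self._schedule_monitor(float(state.clock), len(state.plan.visible))

    def learn_from_snapshot(self, state: GameState, snapshot: InnovationRecord) -> None:
        """Fold newly observed recipes into the reproduction plan (groups)."""
        fresh = [
            e.item
            for e in snapshot.entries
            if e.item not in state.produced
            and e.item not in self.known_from_others
            and e.item not in set(self.repro_queue)
        ]
        if not fresh:
            return
        self.known_from_others.update(fresh)
        pseudo = InnovationRecord(snapshot.owner, snapshot.entries)
        try:
            plan = plan_reproduction(pseudo, state.produced, self.tree)
        except AgentError:
            return
        current = set(self.repro_queue)
        self.repro_queue.extend(i for i in plan if i not in current)
        self.repro_source = snapshot.owner

    # -- exploration ------------------------------------------------------
    def _space_size(self, n: int) -> int:
        return count_multisets(n, 1, MAX_SLOTS)

    def _draw_exploration(self, state: GameState) -> tuple[str, ...] | None:
        rng = self.rng
        if self.policy.insight > 0 and rng.random() < self.policy.insight:
            frontier = self._frontier(state)
            if frontier:
                return frontier[int(rng.integers(len(frontier)))]
        produced = sorted(state.produced)
        n = len(produced)
        if (
            self.policy.exploration == "complexity_biased"
            and self._last_discovered in state.produced
            and rng.random() < self.policy.anchor_bias
        ):
            # anchor on the most recent discovery: small, salient subspace
            # that co-present group members sweep in near-identical fashion
            anchor = self._last_discovered
            sizes = (1, 2, 3)
            for _ in range(8):
                k = int(rng.choice(sizes, p=(0.6, 0.3, 0.1)))
                extras = tuple(rng.choice(produced, size=k, replace=True))
                key = canonical_combination((anchor,) + extras)
                if key not in state.tried:
                    return key
        total = self._space_size(n)
        if total <= _SMALL_SPACE:
            if self._pool_n_produced != n or self._pool is None:
                self._pool = [
                    key
                    for k in range(1, MAX_SLOTS + 1)
                    for key in combinations_with_replacement(produced, k)
                    if key not in state.tried
                ]
                self._pool_n_produced = n
            while self._pool:
                i = int(rng.integers(len(self._pool)))
                self._pool[i], self._pool[-1] = self._pool[-1], self._pool[i]
                key = self._pool.pop()
                if key not in state.tried:
                    return key
            frontier = self._frontier(state)
            if frontier:
                return frontier[int(rng.integers(len(frontier)))]
            return None
        # large space: uniform multiset via the stars-and-bars bijection
        weights = np.array(
            [math.comb(n + k - 1, k) for k in range(1, MAX_SLOTS + 1)], dtype=float
        )
        weights /= weights.sum()
        for _ in range(80):
            k = 1 + int(rng.choice(MAX_SLOTS, p=weights))
            picks = sorted(rng.choice(n + k - 1, size=k, replace=False))
            combo = tuple(produced[c - j] for j, c in enumerate(picks))
            key = canonical_combination(combo)
            if key not in state.tried:
                return key
        return None

    def _frontier(self, state: GameState) -> list[tuple[str, ...]]:
        """Untried, currently satisfiable recipe keys with unproduced products."""
        out = []
        for r in self.tree.recipes.values():
            if r.product in state.produced or r.key in state.tried:
                continue
            if all(i in state.produced for i in r.key):
                out.append(r.key)
        return out

    def _best_totem_logs(self, state: GameState) -> tuple[str, ...] | None:
        vals = self.tree.log_values
        owned = sorted(
            (l for l in state.produced if l in vals), key=lambda l: -vals[l]
        )
        if not owned:
            return None
        v = [vals[l] for l in owned]
        options = [(3 * v[0], (owned[0],) * 3)]
        if len(owned) >= 2:
            options.append((1.15 * (2 * v[0] + v[1]), (owned[0], owned[0], owned[1])))
        if len(owned) >= 3:
            options.append(
                (1.30 * (v[0] + v[1] + v[2]), (owned[0], owned[1], owned[2]))
            )
        best = max(options, key=lambda o: o[0])
        if best[0] <= state.best_totem:
            return None
        return best[1]


def act(
    session: AgentSession, state: GameState
) -> Action:
    """Functional wrapper: next action of a stateful agent session."""
    return session.act(state)
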