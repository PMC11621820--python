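"""Single-session game engine: state, legal actions, and the event log.

The engine executes one participant-session on a tech tree.  It knows
nothing about experimental designs or agent policies; it enforces the game
rules (only produced items can be combined, totems require produced logs,
records are knowledge rather than items) and writes a timestamped event log
from which every behavioral metric can be recomputed.

Time is discrete 1-second ticks.  The clock is advanced by the caller
(the session runner), which charges each action its duration.
"""

from __future__ import annotations

import copy
import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

from .landscape import (
    LandscapeError,
    TechTree,
    TotemScoreParams,
    canonical_combination,
    final_score,
    totem_score,
)

EVENT_TYPES = ("try", "discover", "observe_switch", "totem", "inherit")


class EngineError(RuntimeError):
    """Base class for game-rule violations."""


class IllegalActionError(EngineError):
    """Action referencing items the participant has not produced."""


class VisibilityError(EngineError):
    """Observation target not visible under the session's condition."""


class SessionOverError(EngineError):
    """Action attempted outside the session's time window."""


@dataclass(frozen=True)
class Event:
    t: int
    participant: str
    etype: str
    payload: dict

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "participant": self.participant,
            "type": self.etype,
            "payload": self.payload,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(int(d["t"]), d["participant"], d["type"], dict(d["payload"]))


class EventLog:
    """Ordered, append-only list of session events with text round-trips."""

    def __init__(self, events=None):
        self.events: list[Event] = list(events or [])

    def append(self, event: Event) -> None:
        if self.events and event.t < self.events[-1].t:
            raise EngineError("event times must be nondecreasing")
        if event.etype not in EVENT_TYPES:
            raise EngineError(f"unknown event type {event.etype!r}")
        self.events.append(event)

    def of_type(self, etype: str) -> list[Event]:
        return [e for e in self.events if e.etype == etype]

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other):
        return isinstance(other, EventLog) and self.events == other.events

    # -- serialization ---------------------------------------------------
    def to_jsonl(self) -> str:
        return "".join(json.dumps(e.to_dict(), sort_keys=True) + "\n" for e in self.events)

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        return cls(Event.from_dict(json.loads(line)) for line in text.splitlines() if line.strip())

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["t", "participant", "type", "payload"])
        for e in self.events:
            w.writerow([e.t, e.participant, e.etype, json.dumps(e.payload, sort_keys=True)])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "EventLog":
        rows = list(csv.reader(io.StringIO(text)))
        return cls(
            Event(int(t), p, ty, json.loads(pl)) for t, p, ty, pl in rows[1:]
        )

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".csv":
            path.write_text(self.to_csv())
        else:
            path.write_text(self.to_jsonl())

    @classmethod
    def load(cls, path) -> "EventLog":
        path = Path(path)
        text = path.read_text()
        return cls.from_csv(text) if path.suffix == ".csv" else cls.from_jsonl(text)


@dataclass(frozen=True)
class RecordEntry:
    item: str
    ingredients: tuple[str, ...]
    t: int


class InnovationRecord:
    """Ordered list of discovered recipes; transmitted knowledge, not items."""

    def __init__(self, owner: str, entries=None):
        self.owner = owner
        self.entries: list[RecordEntry] = list(entries or [])

    def items(self) -> list[str]:
        return [e.item for e in self.entries]

    def add(self, item: str, ingredients, t: int) -> None:
        if item in set(self.items()):
            raise EngineError(f"duplicate record entry {item}")
        self.entries.append(RecordEntry(item, canonical_combination(ingredients), t))

    def validate_against(self, tree: TechTree) -> None:
        for e in self.entries:
            if e.item not in tree.items:
                raise EngineError(f"record item {e.item} absent from tree")
            if e.item not in tree.recipes or tree.recipes[e.item].key != e.ingredients:
                raise EngineError(f"record recipe for {e.item} does not match tree")

    def copy(self, owner: str | None = None) -> "InnovationRecord":
        return InnovationRecord(owner or self.owner, list(self.entries))

    def __len__(self):
        return len(self.entries)

    def __eq__(self, other):
        return (
            isinstance(other, InnovationRecord) and self.entries == other.entries
        )

    def to_dict(self) -> dict:
        return {
            "owner": self.owner,
            "entries": [
                {"item": e.item, "ingredients": list(e.ingredients), "t": e.t}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InnovationRecord":
        return cls(
            d["owner"],
            [
                RecordEntry(e["item"], tuple(e["ingredients"]), int(e["t"]))
                for e in d["entries"]
            ],
        )


def empty_record(owner: str) -> InnovationRecord:
    return InnovationRecord(owner)


@dataclass(frozen=True)
class SessionPlan:
    """Who plays, for how long, inheriting from whom, seeing whom."""

    participant: str
    duration_s: int
    design: str = "extended_individual"
    generation: int = 1
    unit: str = "u0"
    inherit_from: str | None = None
    visible: tuple[str, ...] = ()
    global_offset_s: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise EngineError("session duration must be positive")


@dataclass(frozen=True)
class TryResult:
    success: bool
    product: str | None
    new_item: bool  # first production in this session
    new_to_record: bool


class GameState:
    """Mutable state of one participant-session."""

    def __init__(self, plan: SessionPlan, tree: TechTree,
                 inherited: InnovationRecord, params: TotemScoreParams):
        self.plan = plan
        self.tree = tree
        self.params = params
        self.clock: int = 0
        self.bases = frozenset(tree.base_ids)
        self.produced: set[str] = set(self.bases)
        self.record = InnovationRecord(plan.participant)
        self.inherited = inherited
        self.tried: set[tuple[str, ...]] = set()
        self.best_totem: float = 0.0
        self.view: str = plan.participant
        self.events = EventLog()
        self.ended = False

    @property
    def participant(self) -> str:
        return self.plan.participant

    def advance(self, dt: int) -> None:
        if dt < 0:
            raise EngineError("cannot move the clock backwards")
        self.clock += int(dt)

    def _log(self, etype: str, payload: dict) -> None:
        self.events.append(Event(self.clock, self.participant, etype, payload))


def start_session(
    plan: SessionPlan,
    inherited: InnovationRecord | None,
    tree: TechTree,
    params: TotemScoreParams | None = None,
) -> GameState:
    """Open a session: base resources only, inherited recipes as knowledge."""
    inherited = inherited if inherited is not None else empty_record(plan.participant)
    inherited.validate_against(tree)
    state = GameState(plan, tree, inherited, params or TotemScoreParams())
    state._log(
        "inherit",
        {
            "n_items": len(inherited),
            "items": inherited.items(),
            "source": plan.inherit_from,
        },
    )
    return state


def try_combination(state: GameState, items) -> TryResult:
    """Drop 1-4 produced items in the workshop and hit Try."""
    if state.clock >= state.plan.duration_s:
        raise SessionOverError("session time is up")
    key = canonical_combination(items)
    for i in key:
        if i not in state.produced:
            raise IllegalActionError(f"item {i} has not been produced this session")
    state._log("try", {"key": list(key)})
    state.tried.add(key)
    product = state.tree.recipe_index.get(key)
    if product is None:
        return TryResult(False, None, False, False)
    new_item = product not in state.produced
    new_to_record = product not in set(state.record.items())
    if new_item:
        state.produced.add(product)
        if new_to_record:
            state.record.add(product, key, state.clock)
        state._log("discover", {"item": product, "key": list(key)})
        # the UI focuses the player's own record on a fresh discovery
        state.view = state.participant
    return TryResult(True, product, new_item, new_to_record)


def observe_record(state: GameState, target: str, snapshot=None):
    """Switch the record panel to ``target``; log only actual switches.

    Returns the caller-supplied snapshot (the runner is responsible for the
    10-second refresh cadence in groups), the inherited record when the
    target is the demonstrator, or the participant's own record.
    """
    own = state.participant
    if target != own and target not in state.plan.visible:
        raise VisibilityError(
            f"{target} is not visible to {own} in design {state.plan.design!r}"
        )
    if target != state.view:
        state._log("observe_switch", {"target": target, "from": state.view})
        state.view = target
    if snapshot is not None:
        return snapshot
    if target == own:
        return state.record
    if target == state.plan.inherit_from:
        return state.inherited
    return None


def build_totem(state: GameState, logs) -> float:
    """Slot 1-3 produced logs into the totem pole; keep the best score."""
    if state.clock >= state.plan.duration_s:
        raise SessionOverError("session time is up")
    logs = list(logs)
    for l in logs:
        if l not in state.produced:
            raise IllegalActionError(f"log {l} has not been produced this session")
        if l not in state.tree.log_values:
            raise IllegalActionError(f"item {l} is not a log")
    score = totem_score(logs, state.tree.log_values, state.params)
    state._log("totem", {"logs": sorted(logs), "score": score})
    state.best_totem = max(state.best_totem, score)
    return score


@dataclass
class SessionResult:
    plan: SessionPlan
    record: InnovationRecord
    events: EventLog
    best_totem: float
    n_new_items: int
    final_score: float
    inherited_items: tuple[str, ...]
    complete: bool = True


def end_session(state: GameState) -> SessionResult:
    """Close the session and score it.

    The +15 new-item bonus counts every item produced for the first time in
    this session, including reproductions of inherited recipes (they still
    had to be physically made).
    """
    if state.clock < state.plan.duration_s:
        raise EngineError("session has not reached its duration")
    state.ended = True
    n_new = len(state.produced - state.bases)
    return SessionResult(
        plan=state.plan,
        record=state.record,
        events=state.events,
        best_totem=state.best_totem,
        n_new_items=n_new,
        final_score=final_score(state.best_totem, n_new, state.params),
        inherited_items=tuple(state.inherited.items()),
    )


def replay(result: SessionResult, tree: TechTree,
           params: TotemScoreParams | None = None) -> SessionResult:
    """Re-execute a session from its event log's action sequence.

    Deterministic check that the log fully determines the final state: the
    returned result must match the original (record, score, event log).
    """
    inherited = InnovationRecord(result.plan.inherit_from or result.plan.participant)
    inh = result.events.of_type("inherit")
    if inh:
        # rebuild the inherited record from the tree's recipes
        for item in inh[0].payload["items"]:
            inherited.add(item, tree.recipes[item].key, 0)
    state = start_session(result.plan, inherited, tree, params)
    for e in result.events:
        state.clock = e.t
        if e.etype == "try":
            try_combination(state, e.payload["key"])
        elif e.etype == "totem":
            build_totem(state, e.payload["logs"])
        elif e.etype == "observe_switch":
            state._log("observe_switch", dict(e.payload))
            state.view = e.payload["target"]
    state.clock = result.plan.duration_s
    return end_session(state)
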