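"""Combinatorial innovation landscape ("tech tree") for the totem task.

The game world consists of six base resources that can be combined, one to
four at a time and order-free, in a workshop panel.  Certain combinations
are recipes: they yield a new item, which can in turn be used in further
combinations.  Items are either *tools* (intermediate innovations) or *logs*
(high-level innovations that can be slotted into a three-slot totem pole).
Each log carries a point value drawn within a range that increases with the
log's complexity, so deeper logs are always worth more.

The original game's recipe network is unpublished; this module provides a
seeded generator that constructs a landscape with the same published
structure: 6 base resources, 27 tools, 115 logs (142 innovations in total),
at most 4 ingredients per recipe, at least 8 innovations required before any
log becomes producible, 209 combinations available from the bare resources,
and 266,915 distinct totem-pole contents.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement, permutations
from pathlib import Path

import networkx as nx
import numpy as np

BASE_NAMES = ("wood", "stone", "fiber", "clay", "pigment", "shell")

CATEGORY_BASE = "base"
CATEGORY_TOOL = "tool"
CATEGORY_LOG = "log"

MAX_SLOTS = 4
TOTEM_SLOTS = 3


class LandscapeError(ValueError):
    """Invalid landscape input, configuration, or construction failure."""


def count_multisets(n_items: int, size_min: int, size_max: int) -> int:
    """Number of unordered combinations-with-repetition of sizes in a range.

    This counts the distinct fillings of a panel with ``size_min`` to
    ``size_max`` slots from ``n_items`` item types, where slot order is
    irrelevant and repetition is allowed:
    sum over k of C(n_items + k - 1, k).
    """
    if n_items <= 0:
        raise LandscapeError(f"n_items must be positive, got {n_items}")
    if not (1 <= size_min <= size_max):
        raise LandscapeError(
            f"need 1 <= size_min <= size_max, got ({size_min}, {size_max})"
        )
    return sum(math.comb(n_items + k - 1, k) for k in range(size_min, size_max + 1))


def canonical_combination(items) -> tuple[str, ...]:
    """Order-independent key for a workshop combination (1-4 items)."""
    items = tuple(items)
    if not 1 <= len(items) <= MAX_SLOTS:
        raise LandscapeError(
            f"a combination uses 1 to {MAX_SLOTS} items, got {len(items)}"
        )
    return tuple(sorted(str(i) for i in items))


@dataclass(frozen=True)
class Item:
    """A game item.

    depth is the size of the item's minimal production closure including the
    item itself (0 for base resources): the number of distinct innovations
    involved in making it from scratch.
    """

    id: str
    category: str
    depth: int

    def __post_init__(self):
        if self.category not in (CATEGORY_BASE, CATEGORY_TOOL, CATEGORY_LOG):
            raise LandscapeError(f"unknown category {self.category!r}")
        if self.category == CATEGORY_BASE and self.depth != 0:
            raise LandscapeError("base items have depth 0")
        if self.category != CATEGORY_BASE and self.depth < 1:
            raise LandscapeError("non-base items have depth >= 1")


@dataclass(frozen=True)
class Recipe:
    """The unique ingredient multiset that produces a non-base item."""

    product: str
    ingredients: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "ingredients", canonical_combination(self.ingredients)
        )

    @property
    def key(self) -> tuple[str, ...]:
        return self.ingredients


@dataclass
class TechTree:
    """Items, recipes, and log point values of one landscape."""

    items: dict[str, Item]
    recipes: dict[str, Recipe]
    log_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self._recipe_index: dict[tuple[str, ...], str] | None = None
        self._required: dict[str, frozenset[str]] = {}

    # -- basic accessors -------------------------------------------------
    @property
    def base_ids(self) -> tuple[str, ...]:
        return tuple(i for i, it in self.items.items() if it.category == CATEGORY_BASE)

    @property
    def tool_ids(self) -> tuple[str, ...]:
        return tuple(i for i, it in self.items.items() if it.category == CATEGORY_TOOL)

    @property
    def log_ids(self) -> tuple[str, ...]:
        return tuple(i for i, it in self.items.items() if it.category == CATEGORY_LOG)

    @property
    def recipe_index(self) -> dict[tuple[str, ...], str]:
        """Map canonical combination key -> product id."""
        if self._recipe_index is None:
            idx: dict[tuple[str, ...], str] = {}
            for r in self.recipes.values():
                if r.key in idx:
                    raise LandscapeError(f"duplicate recipe key {r.key}")
                idx[r.key] = r.product
            self._recipe_index = idx
        return self._recipe_index

    def required_items(self, item_id: str) -> frozenset[str]:
        """Non-base items that must be produced before ``item_id`` can be.

        With one recipe per product the minimal dependency closure is the
        item's ancestor set in the recipe graph (the item itself excluded).
        """
        if item_id in self._required:
            return self._required[item_id]
        if self.items[item_id].category == CATEGORY_BASE:
            out = frozenset()
        else:
            acc: set[str] = set()
            stack = [item_id]
            seen = {item_id}
            while stack:
                cur = stack.pop()
                for ing in self.recipes[cur].ingredients:
                    if self.items[ing].category == CATEGORY_BASE:
                        continue
                    if ing not in acc:
                        acc.add(ing)
                    if ing not in seen:
                        seen.add(ing)
                        stack.append(ing)
            out = frozenset(acc)
        self._required[item_id] = out
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [
                {"id": it.id, "category": it.category, "depth": it.depth}
                for it in self.items.values()
            ],
            "recipes": [
                {"product": r.product, "ingredients": list(r.ingredients)}
                for r in self.recipes.values()
            ],
            "log_values": {k: v for k, v in sorted(self.log_values.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TechTree":
        items = {e["id"]: Item(e["id"], e["category"], e["depth"]) for e in d["items"]}
        recipes = {
            e["product"]: Recipe(e["product"], tuple(e["ingredients"]))
            for e in d["recipes"]
        }
        return cls(items=items, recipes=recipes, log_values=dict(d["log_values"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "TechTree":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def validate(self) -> None:
        """Check structural invariants; raise LandscapeError on violation."""
        for iid, it in self.items.items():
            if it.category != CATEGORY_BASE and iid not in self.recipes:
                raise LandscapeError(f"non-base item {iid} has no recipe")
        for r in self.recipes.values():
            if self.items[r.product].category == CATEGORY_BASE:
                raise LandscapeError(f"base item {r.product} cannot have a recipe")
            for ing in r.ingredients:
                if ing not in self.items:
                    raise LandscapeError(f"unknown ingredient {ing}")
        g = dependency_graph(self)
        if not nx.is_directed_acyclic_graph(g):
            raise LandscapeError("cyclic recipe dependencies")
        self.recipe_index  # raises on duplicate keys
        census = enumerate_closure(self)
        non_base = [i for i in self.items.values() if i.category != CATEGORY_BASE]
        if census.n_items != len(non_base):
            raise LandscapeError(
                f"only {census.n_items} of {len(non_base)} non-base items reachable"
            )


def dependency_graph(tree: TechTree) -> nx.DiGraph:
    """Directed graph with an edge ingredient -> product for every recipe."""
    g = nx.DiGraph()
    g.add_nodes_from(tree.items)
    for r in tree.recipes.values():
        for ing in set(r.ingredients):
            g.add_edge(ing, r.product)
    return g


@dataclass(frozen=True)
class DiscoveryCensus:
    """Result of exhaustively closing the recipe set from the base resources."""

    n_tools: int
    n_logs: int
    n_items: int
    reachable: frozenset[str]
    productive: dict[tuple[str, ...], str]


def enumerate_closure(tree: TechTree) -> DiscoveryCensus:
    """Breadth-first recipe closure starting from the base resources.

    Repeatedly fires every recipe whose ingredients are all available until a
    fixed point; the census reports reachable tools/logs and the set of
    productive combination keys.
    """
    g = dependency_graph(tree)
    if not nx.is_directed_acyclic_graph(g):
        raise LandscapeError("cyclic recipe dependencies")
    available = set(tree.base_ids)
    pending = dict(tree.recipes)
    productive: dict[tuple[str, ...], str] = {}
    changed = True
    while changed:
        changed = False
        for prod in list(pending):
            r = pending[prod]
            if all(i in available for i in r.ingredients):
                available.add(prod)
                productive[r.key] = prod
                del pending[prod]
                changed = True
    reach = frozenset(available)
    n_tools = sum(1 for i in reach if tree.items[i].category == CATEGORY_TOOL)
    n_logs = sum(1 for i in reach if tree.items[i].category == CATEGORY_LOG)
    return DiscoveryCensus(
        n_tools=n_tools,
        n_logs=n_logs,
        n_items=n_tools + n_logs,
        reachable=reach,
        productive=productive,
    )


def min_innovations_before_log(tree: TechTree) -> int:
    """Minimum, over logs, of the innovations needed before the log itself."""
    logs = tree.log_ids
    if not logs:
        raise LandscapeError("tree has no logs")
    return min(len(tree.required_items(l)) for l in logs)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TotemScoreParams:
    """Coefficients of the totem scoring rule.

    A totem holds 1-3 logs; its score is (1 + bonus_coefficient * alpha)
    times the summed log values, where alpha = number of distinct log types
    minus one.  Each new item produced adds per_item_bonus points to the
    final score.
    """

    bonus_coefficient: float = 0.15
    per_item_bonus: float = 15.0


@dataclass(frozen=True)
class LogValueTable:
    """Point value and complexity class of every log."""

    values: dict[str, float]
    complexity: dict[str, int]

    def __post_init__(self):
        for lid, v in self.values.items():
            if v <= 0:
                raise LandscapeError(f"log value for {lid} must be positive")
            if lid not in self.complexity:
                raise LandscapeError(f"missing complexity for {lid}")
        # strict monotonicity between complexity classes
        by_depth: dict[int, list[float]] = {}
        for lid, v in self.values.items():
            by_depth.setdefault(self.complexity[lid], []).append(v)
        depths = sorted(by_depth)
        for lo, hi in zip(depths, depths[1:]):
            if max(by_depth[lo]) >= min(by_depth[hi]):
                raise LandscapeError(
                    "log values must strictly increase with complexity "
                    f"(classes {lo} and {hi} overlap)"
                )

    def __getitem__(self, lid: str) -> float:
        return self.values[lid]

    def __contains__(self, lid: str) -> bool:
        return lid in self.values


def totem_score(logs, values, params: TotemScoreParams | None = None) -> float:
    """Score of a totem pole holding a multiset of 1-3 logs.

    ScoreTotem = (1 + 0.15 * alpha) * (sum of slotted log values), with alpha
    equal to the number of distinct log types minus one.  Empty slots
    contribute nothing.
    """
    params = params or TotemScoreParams()
    logs = list(logs)
    if not 1 <= len(logs) <= TOTEM_SLOTS:
        raise LandscapeError(f"a totem holds 1 to {TOTEM_SLOTS} logs, got {len(logs)}")
    vals = values.values if isinstance(values, LogValueTable) else values
    for l in logs:
        if l not in vals:
            raise LandscapeError(f"unknown log {l!r}")
    alpha = len(set(logs)) - 1
    return (1.0 + params.bonus_coefficient * alpha) * sum(vals[l] for l in logs)


def final_score(
    best_totem: float, n_new_items: int, params: TotemScoreParams | None = None
) -> float:
    """Best totem score plus the per-item bonus for each new item produced."""
    params = params or TotemScoreParams()
    if best_totem < 0:
        raise LandscapeError("best_totem must be >= 0")
    if n_new_items < 0:
        raise LandscapeError("n_new_items must be >= 0")
    return best_totem + params.per_item_bonus * n_new_items


# ---------------------------------------------------------------------------
# Reference landscape generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeConfig:
    """Structural and scoring constraints for landscape construction.

    Defaults reproduce the published structure of the totem task: 6 base
    resources, 27 tools, 115 logs, 4 workshop slots, 8 innovations before the
    first log, single-log totems worth at least 50 points and a best possible
    totem of 1.3 * 5700 = 7410 points.
    """

    n_base: int = 6
    n_tools: int = 27
    n_logs: int = 115
    min_innovations_before_log: int = 8
    max_ingredients: int = 4
    n_primitive_tools: int = 6  # tools craftable from base resources alone
    n_basic_logs: int = 24  # logs whose recipe holds no other log
    value_floor: float = 50.0
    value_ceiling: float = 1920.0
    top_three_sum: float | None = 5700.0


CANONICAL_SEED = 7  # frozen seed of the reference landscape

_MAX_TRIES = 400


def _check_feasible(cfg: LandscapeConfig) -> None:
    if cfg.n_base < 1 or cfg.n_tools < 0 or cfg.n_logs < 0:
        raise LandscapeError("counts must be non-negative (n_base >= 1)")
    if cfg.max_ingredients < 1 or cfg.max_ingredients > MAX_SLOTS:
        raise LandscapeError("max_ingredients must be in 1..4")
    if cfg.n_logs > 0 and cfg.n_tools < cfg.min_innovations_before_log:
        raise LandscapeError(
            "infeasible config: need at least "
            f"{cfg.min_innovations_before_log} tools to gate the first log"
        )
    if cfg.n_primitive_tools > cfg.n_tools:
        raise LandscapeError("n_primitive_tools exceeds n_tools")
    space = count_multisets(cfg.n_base, 1, cfg.max_ingredients)
    if cfg.n_primitive_tools > space:
        raise LandscapeError("more primitive tools than base combinations")


def generate_reference_landscape(
    config: LandscapeConfig | None = None, seed: int = CANONICAL_SEED
) -> TechTree:
    """Construct a landscape satisfying the published structural counts.

    Layered construction: a "spine" chain of tools whose length equals the
    required innovations-before-first-log, a handful of primitive tools
    craftable directly from base resources, randomly wired deeper tools, then
    logs gated behind the spine, most of which refine earlier logs.  The
    deepest three logs share the maximal complexity class so the best totem
    uses three distinct top-value logs.  Deterministic for a fixed seed.
    """
    cfg = config or LandscapeConfig()
    _check_feasible(cfg)
    rng = np.random.default_rng(seed)

    base = list(BASE_NAMES[: cfg.n_base])
    if cfg.n_base > len(BASE_NAMES):
        base = BASE_NAMES + tuple(f"base-{i}" for i in range(len(BASE_NAMES), cfg.n_base))
        base = list(base)
    items: dict[str, Item] = {b: Item(b, CATEGORY_BASE, 0) for b in base}
    recipes: dict[str, Recipe] = {}
    used_keys: set[tuple[str, ...]] = set()
    required: dict[str, set[str]] = {b: set() for b in base}

    def add(pid: str, category: str, ingredients: tuple[str, ...]) -> None:
        key = canonical_combination(ingredients)
        if key in used_keys:
            raise LandscapeError(f"recipe key collision for {pid}")
        req: set[str] = set()
        for ing in key:
            if ing not in items:
                raise LandscapeError(f"unknown ingredient {ing}")
            if items[ing].category != CATEGORY_BASE:
                req |= required[ing]
                req.add(ing)
        used_keys.add(key)
        required[pid] = req
        items[pid] = Item(pid, category, len(req) + 1)
        recipes[pid] = Recipe(pid, key)

    def fresh_key(pool: list[str], sizes, weights) -> tuple[str, ...]:
        for _ in range(_MAX_TRIES):
            k = int(rng.choice(sizes, p=weights))
            k = min(k, cfg.max_ingredients)
            ings = tuple(rng.choice(pool, size=k, replace=True))
            key = canonical_combination(ings)
            if key not in used_keys:
                return key
        raise LandscapeError("could not find an unused recipe key (space exhausted)")

    tools: list[str] = []
    spine_len = cfg.min_innovations_before_log if cfg.n_logs > 0 else 0

    # spine: a strict chain t1 <- bases, t_i <- {t_{i-1}, base}
    for i in range(spine_len):
        tid = f"tool-{i + 1:02d}"
        if i == 0:
            key = fresh_key(base, [2, 3], [0.6, 0.4])
        else:
            b = str(rng.choice(base))
            key = canonical_combination((tools[-1], b))
            if key in used_keys:  # same (tool, base) pair drawn twice is impossible
                b2 = next(x for x in base if canonical_combination((tools[-1], x)) not in used_keys)
                key = canonical_combination((tools[-1], b2))
        add(tid, CATEGORY_TOOL, key)
        tools.append(tid)

    # primitive tools: craftable from the bare resources (early-game density)
    n_prim = max(0, cfg.n_primitive_tools - (1 if spine_len else 0))
    n_prim = min(n_prim, cfg.n_tools - len(tools))
    for i in range(n_prim):
        tid = f"tool-{len(tools) + 1:02d}"
        add(tid, CATEGORY_TOOL, fresh_key(base, [1, 2, 3], [0.15, 0.5, 0.35]))
        tools.append(tid)

    # deeper tools: wired into whatever exists already
    while len(tools) < cfg.n_tools:
        tid = f"tool-{len(tools) + 1:02d}"
        pool = base + tools
        add(tid, CATEGORY_TOOL, fresh_key(pool, [2, 3, 4], [0.45, 0.35, 0.2]))
        tools.append(tid)

    logs: list[str] = []
    if cfg.n_logs > 0:
        gate = tools[spine_len - 1]  # the spine tip: needs exactly spine_len - 1 priors

        def gate_pool() -> list[str]:
            return [
                t
                for t in tools
                if len(required[t]) + 1 >= cfg.min_innovations_before_log
            ]

        # first log: exactly min_innovations_before_log innovations before it
        lid = "log-001"
        b = next(
            x for x in base if canonical_combination((gate, x)) not in used_keys
        )
        add(lid, CATEGORY_LOG, (gate, b))
        logs.append(lid)

        n_basic = min(cfg.n_basic_logs, cfg.n_logs)
        gates = gate_pool()
        while len(logs) < n_basic:
            lid = f"log-{len(logs) + 1:03d}"
            g = str(rng.choice(gates))
            pool = base + tools
            for _ in range(_MAX_TRIES):
                extra = tuple(
                    rng.choice(pool, size=int(rng.integers(1, cfg.max_ingredients)), replace=True)
                )
                key = canonical_combination((g,) + extra)
                if key not in used_keys:
                    break
            else:
                raise LandscapeError("could not place a basic log recipe")
            add(lid, CATEGORY_LOG, key)
            logs.append(lid)

        # refined logs: each builds on a recent log, so complexity keeps rising
        while len(logs) < cfg.n_logs - 3:
            lid = f"log-{len(logs) + 1:03d}"
            window = logs[-15:]
            prev = str(rng.choice(window))
            pool = base + tools
            for _ in range(_MAX_TRIES):
                extra = tuple(
                    rng.choice(pool, size=int(rng.integers(1, 3)), replace=True)
                )
                key = canonical_combination((prev,) + extra)
                if key not in used_keys:
                    break
            else:
                raise LandscapeError("could not place a refined log recipe")
            add(lid, CATEGORY_LOG, key)
            logs.append(lid)

        # apex trio: three log types sharing the strictly deepest complexity
        if cfg.n_logs >= max(4, n_basic + 1):
            deepest = max(logs, key=lambda l: len(required[l]))
            carver = str(rng.choice(tools))
            fillers = [(), (base[0],), (base[1 % len(base)],), (base[0], base[0])]
            placed = 0
            for extra in fillers:
                if placed == 3 or len(logs) >= cfg.n_logs:
                    break
                lid = f"log-{len(logs) + 1:03d}"
                key = canonical_combination((deepest, carver) + extra)
                if key in used_keys:
                    continue
                add(lid, CATEGORY_LOG, key)
                logs.append(lid)
                placed += 1
            while len(logs) < cfg.n_logs:  # pragma: no cover - tiny configs
                lid = f"log-{len(logs) + 1:03d}"
                prev = logs[-1]
                key = fresh_key(base + tools + [prev], [2, 3], [0.6, 0.4])
                add(lid, CATEGORY_LOG, key)
                logs.append(lid)
        else:
            while len(logs) < cfg.n_logs:
                lid = f"log-{len(logs) + 1:03d}"
                g = str(rng.choice(gates))
                key = fresh_key(base + [g], [2, 3], [0.6, 0.4])
                if g not in key:
                    key = canonical_combination((g,) + key[:-1])
                    if key in used_keys:
                        continue
                add(lid, CATEGORY_LOG, key)
                logs.append(lid)

    tree = TechTree(items=items, recipes=recipes)
    if cfg.n_logs > 0:
        table = assign_log_values(tree, cfg, seed=int(rng.integers(0, 2**31 - 1)))
        tree.log_values = dict(table.values)

    # construction-time checks against the configured census
    census = enumerate_closure(tree)
    if (census.n_tools, census.n_logs) != (cfg.n_tools, cfg.n_logs):
        raise LandscapeError(
            f"construction failed census: got {census.n_tools} tools, "
            f"{census.n_logs} logs; wanted {cfg.n_tools}/{cfg.n_logs}"
        )
    if cfg.n_logs > 0:
        m = min_innovations_before_log(tree)
        if m != cfg.min_innovations_before_log:
            raise LandscapeError(
                f"minimum innovations before a log is {m}, "
                f"wanted {cfg.min_innovations_before_log}"
            )
    return tree


def log_value_ranges(
    tree: TechTree, cfg: LandscapeConfig
) -> dict[int, tuple[float, float]]:
    """Disjoint, strictly increasing value range per log complexity class."""
    logs = tree.log_ids
    depths = sorted({len(tree.required_items(l)) for l in logs})
    if not depths:
        return {}
    m = len(depths)
    top_width = 80.0 if (cfg.top_three_sum is not None and m > 1) else 0.0
    lo, hi = cfg.value_floor, cfg.value_ceiling - top_width
    if hi <= lo:
        raise LandscapeError("value_ceiling too close to value_floor")
    ranges: dict[int, tuple[float, float]] = {}
    body = depths if top_width == 0 else depths[:-1]
    nb = max(len(body), 1)
    span = (hi - lo) / nb
    for i, d in enumerate(body):
        ranges[d] = (lo + i * span, lo + (i + 1) * span - 1.0)
    if top_width:
        ranges[depths[-1]] = (cfg.value_ceiling - top_width, cfg.value_ceiling)
    return ranges


def assign_log_values(
    tree: TechTree,
    config: LandscapeConfig | None = None,
    seed: int = 0,
    ranges: dict[int, tuple[float, float]] | None = None,
) -> LogValueTable:
    """Randomly value each log within its complexity class range.

    Values are unique, strictly increase between complexity classes, the
    global minimum is pinned to the configured floor, and (when the apex
    class holds at least three logs) the top three values are pinned so the
    best three-distinct-log totem reaches the configured calibration total.
    """
    cfg = config or LandscapeConfig()
    logs = tree.log_ids
    complexity = {l: len(tree.required_items(l)) for l in logs}
    if not logs:
        return LogValueTable(values={}, complexity={})
    if ranges is None:
        ranges = log_value_ranges(tree, cfg)
    else:
        ordered = sorted(ranges.items())
        for (d1, (a1, b1)), (d2, (a2, b2)) in zip(ordered, ordered[1:]):
            if b1 >= a2:
                raise LandscapeError(
                    f"value ranges for classes {d1} and {d2} overlap"
                )
    rng = np.random.default_rng(seed)
    by_depth: dict[int, list[str]] = {}
    for l in logs:
        by_depth.setdefault(complexity[l], []).append(l)

    values: dict[str, float] = {}
    depths = sorted(by_depth)
    for d in depths:
        lo, hi = ranges[d]
        grid = np.arange(lo, hi + 1e-9, 0.5)
        members = by_depth[d]
        if len(grid) < len(members):
            raise LandscapeError(
                f"value range {ranges[d]} too narrow for {len(members)} logs"
            )
        draws = rng.choice(grid, size=len(members), replace=False)
        for l, v in zip(members, draws):
            values[l] = float(v)

    # pin the global minimum to the floor
    low_class = by_depth[depths[0]]
    lmin = min(low_class, key=lambda l: values[l])
    values[lmin] = float(cfg.value_floor)

    # pin the apex trio so 1.3 * (v1 + v2 + v3) hits the calibration target
    if cfg.top_three_sum is not None and len(by_depth[depths[-1]]) >= 3:
        third = cfg.top_three_sum / 3.0
        targets = (third - 20.0, third, third + 20.0)
        apex = sorted(by_depth[depths[-1]], key=lambda l: values[l])[-3:]
        lo, hi = ranges[depths[-1]]
        if targets[0] >= lo and targets[-1] <= hi:
            taken = {values[l] for l in by_depth[depths[-1]] if l not in apex}
            if not taken & set(targets):
                for l, v in zip(apex, targets):
                    values[l] = float(v)

    return LogValueTable(values=values, complexity=complexity)


def best_possible_totem(tree: TechTree, params: TotemScoreParams | None = None) -> float:
    """Maximum achievable totem score on this landscape."""
    vals = sorted(tree.log_values.values(), reverse=True)
    if not vals:
        raise LandscapeError("tree has no valued logs")
    params = params or TotemScoreParams()
    v1 = vals[0]
    best = TOTEM_SLOTS * v1
    if len(vals) >= 2:
        best = max(best, (1 + params.bonus_coefficient) * (2 * v1 + vals[1]))
    if len(vals) >= 3:
        best = max(
            best, (1 + 2 * params.bonus_coefficient) * (v1 + vals[1] + vals[2])
        )
    return best


def enumerate_totem_space(tree: TechTree) -> int:
    """Count distinct totem contents by explicit enumeration over producible logs."""
    logs = sorted(enumerate_closure(tree).reachable & set(tree.log_ids))
    n = 0
    for k in range(1, TOTEM_SLOTS + 1):
        for _ in combinations_with_replacement(logs, k):
            n += 1
    return n
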