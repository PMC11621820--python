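import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from totemlab.landscape import (
    Item,
    Recipe,
    TechTree,
    generate_reference_landscape,
)


@pytest.fixture(scope="session")
def reference_tree():
    return generate_reference_landscape()


def make_tree(items, recipes, log_values=None):
    """Build a TechTree from compact (id, category) and (product, ingredients)."""
    item_objs = {}
    tree_recipes = {p: Recipe(p, tuple(ings)) for p, ings in recipes.items()}

    def depth(iid, cat, seen=None):
        if cat == "base":
            return 0
        seen = set()
        stack = [iid]
        while stack:
            cur = stack.pop()
            for ing in tree_recipes[cur].ingredients:
                if dict(items)[ing] != "base" and ing not in seen:
                    seen.add(ing)
                    stack.append(ing)
        return len(seen - {iid}) + 1

    for iid, cat in items:
        item_objs[iid] = Item(iid, cat, depth(iid, cat))
    return TechTree(items=item_objs, recipes=tree_recipes,
                    log_values=dict(log_values or {}))


@pytest.fixture
def toy_tree():
    """Small hand-built tree: 3 bases, 3 tools, 2 logs."""
    return make_tree(
        items=[("a", "base"), ("b", "base"), ("c", "base"),
               ("t1", "tool"), ("t2", "tool"), ("t3", "tool"),
               ("l1", "log"), ("l2", "log")],
        recipes={
            "t1": ("a", "b"),
            "t2": ("t1", "c"),
            "t3": ("t1", "t2"),
            "l1": ("t3", "a"),
            "l2": ("l1", "t2"),
        },
        log_values={"l1": 100.0, "l2": 250.0},
    )


def random_toy_tree(rng: np.random.Generator, n_tools=5, n_logs=2):
    """Random small acyclic tree for oracle-equivalence tests."""
    items = [(f"b{i}", "base") for i in range(3)]
    recipes = {}
    used = set()
    pool = [i for i, _ in items]

    def draw(max_k):
        while True:
            k = int(rng.integers(1, max_k + 1))
            ings = tuple(sorted(rng.choice(pool, size=k, replace=True)))
            if ings not in used:
                used.add(ings)
                return ings

    for i in range(n_tools):
        tid = f"t{i}"
        recipes[tid] = draw(3)
        items.append((tid, "tool"))
        pool.append(tid)
    for i in range(n_logs):
        lid = f"l{i}"
        recipes[lid] = draw(2)
        items.append((lid, "log"))
        pool.append(lid)
    values = {f"l{i}": 50.0 * (i + 1) for i in range(n_logs)}
    tree = make_tree(items, recipes)
    tree.log_values = values
    return tree
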