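"""Tech-tree construction, enumeration, and scoring."""

import json
from itertools import combinations_with_replacement, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from totemlab.landscape import (
    LandscapeConfig,
    LandscapeError,
    LogValueTable,
    TotemScoreParams,
    assign_log_values,
    best_possible_totem,
    canonical_combination,
    count_multisets,
    enumerate_closure,
    enumerate_totem_space,
    final_score,
    generate_reference_landscape,
    min_innovations_before_log,
    totem_score,
)

from conftest import make_tree, random_toy_tree


def brute_force_multisets(n, smin, smax):
    syms = list(range(n))
    return sum(
        1
        for k in range(smin, smax + 1)
        for _ in combinations_with_replacement(syms, k)
    )


class TestCountMultisets:
    @pytest.mark.parametrize(
        "n,smin,smax,expected",
        [(6, 1, 4, 209), (10, 1, 4, 1000), (1, 1, 1, 1), (115, 1, 3, 266915)],
    )
    def test_published_counts(self, n, smin, smax, expected):
        assert count_multisets(n, smin, smax) == expected

    @pytest.mark.parametrize("n", range(1, 9))
    @pytest.mark.parametrize("smax", range(1, 5))
    def test_matches_enumeration_oracle(self, n, smax):
        assert count_multisets(n, 1, smax) == brute_force_multisets(n, 1, smax)

    def test_invalid_inputs(self):
        with pytest.raises(LandscapeError):
            count_multisets(0, 1, 3)
        with pytest.raises(LandscapeError):
            count_multisets(5, 3, 2)
        with pytest.raises(LandscapeError):
            count_multisets(5, 0, 2)


class TestCanonicalCombination:
    def test_permutation_invariance_exhaustive(self):
        keys = {
            canonical_combination(p) for p in permutations(["A", "B", "C", "D"])
        }
        assert len(keys) == 1

    def test_repeats_and_singletons(self):
        assert canonical_combination(["A", "B", "A"]) == canonical_combination(
            ["A", "A", "B"]
        )
        assert canonical_combination(["A"]) == ("A",)

    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=4))
    @settings(deadline=None, max_examples=50)
    def test_sorted_and_stable(self, items):
        key = canonical_combination(items)
        assert key == tuple(sorted(items))
        assert canonical_combination(key) == key

    def test_size_bounds(self):
        with pytest.raises(LandscapeError):
            canonical_combination([])
        with pytest.raises(LandscapeError):
            canonical_combination(list("abcde"))


class TestReferenceLandscape:
    def test_census_and_gates(self, reference_tree):
        census = enumerate_closure(reference_tree)
        assert (census.n_tools, census.n_logs, census.n_items) == (27, 115, 142)
        assert min_innovations_before_log(reference_tree) == 8

    def test_deterministic_for_fixed_seed(self, reference_tree):
        again = generate_reference_landscape()
        assert again.to_dict() == reference_tree.to_dict()

    def test_totem_space_by_enumeration(self, reference_tree):
        assert enumerate_totem_space(reference_tree) == 266915

    def test_base_space_is_209(self, reference_tree):
        assert count_multisets(len(reference_tree.base_ids), 1, 4) == 209

    def test_degenerate_config_without_logs(self):
        cfg = LandscapeConfig(n_tools=5, n_logs=0, n_primitive_tools=3)
        tree = generate_reference_landscape(cfg, seed=1)
        census = enumerate_closure(tree)
        assert census.n_logs == 0 and census.n_tools == 5

    def test_infeasible_config_raises(self):
        with pytest.raises(LandscapeError):
            generate_reference_landscape(
                LandscapeConfig(n_tools=3, min_innovations_before_log=8), seed=1
            )

    def test_value_monotone_in_complexity(self, reference_tree):
        t = reference_tree
        depth = {l: len(t.required_items(l)) for l in t.log_ids}
        vals = t.log_values
        for a in t.log_ids:
            for b in t.log_ids:
                if depth[a] > depth[b]:
                    assert vals[a] > vals[b]

    def test_score_range_calibration(self, reference_tree):
        assert min(reference_tree.log_values.values()) == 50.0
        assert best_possible_totem(reference_tree) == pytest.approx(7410.0)

    def test_json_round_trip(self, reference_tree, tmp_path):
        p = tmp_path / "tree.json"
        reference_tree.save(p)
        loaded = type(reference_tree).load(p)
        assert loaded.to_dict() == reference_tree.to_dict()
        assert json.loads(p.read_text())["log_values"]


def brute_force_closure(tree):
    """Fixed-point oracle: try every 1-4 multiset of available items."""
    available = set(tree.base_ids)
    while True:
        found = set()
        for k in range(1, 5):
            for combo in combinations_with_replacement(sorted(available), k):
                prod = tree.recipe_index.get(combo)
                if prod is not None and prod not in available:
                    found.add(prod)
        if not found:
            return available
        available |= found


class TestClosure:
    def test_matches_fixed_point_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            tree = random_toy_tree(rng, n_tools=6, n_logs=2)
            census = enumerate_closure(tree)
            assert census.reachable == frozenset(brute_force_closure(tree))

    def test_base_only_tree(self):
        tree = make_tree([("a", "base"), ("b", "base")], {})
        census = enumerate_closure(tree)
        assert census.n_items == 0

    def test_cyclic_recipes_raise(self):
        tree = make_tree(
            [("a", "base"), ("x", "tool"), ("y", "tool")],
            {"x": ("y", "a"), "y": ("x", "a")},
        )
        with pytest.raises(LandscapeError):
            enumerate_closure(tree)


class TestMinInnovationsBeforeLog:
    def test_base_only_log_needs_zero(self):
        tree = make_tree(
            [("a", "base"), ("l", "log")], {"l": ("a", "a")}, {"l": 60.0}
        )
        assert min_innovations_before_log(tree) == 0

    def test_no_logs_raises(self):
        tree = make_tree([("a", "base"), ("t", "tool")], {"t": ("a",)})
        with pytest.raises(LandscapeError):
            min_innovations_before_log(tree)

    def test_matches_subset_search_oracle(self, toy_tree):
        # smallest closed set of non-base items making some log satisfiable
        non_base = [
            i for i, it in toy_tree.items.items() if it.category != "base"
        ]
        bases = set(toy_tree.base_ids)
        best = len(non_base) + 1
        for mask in range(2 ** len(non_base)):
            s = {non_base[i] for i in range(len(non_base)) if mask >> i & 1}
            closed = all(
                set(toy_tree.recipes[i].key) <= bases | s for i in s
            )
            if not closed:
                continue
            for log in toy_tree.log_ids:
                if set(toy_tree.recipes[log].key) <= bases | s:
                    best = min(best, len(s))
        assert min_innovations_before_log(toy_tree) == best


def oracle_totem(logs, values, params=None):
    params = params or TotemScoreParams()
    alpha = len(set(logs)) - 1
    return (1 + params.bonus_coefficient * alpha) * sum(values[l] for l in logs)


class TestScoring:
    def test_printed_formula_examples(self):
        vals = {"x": 100.0, "y": 200.0, "z": 300.0, "w": 50.0, "v": 50.0}
        assert totem_score(["x", "x", "x"], vals) == pytest.approx(300.0)
        assert totem_score(["x", "y", "z"], vals) == pytest.approx(780.0)
        assert totem_score(["w", "v", "w"], vals) == pytest.approx(172.5)

    def test_exhaustive_against_brute_force(self):
        vals = {c: 50.0 * (i + 1) for i, c in enumerate("pqrs")}
        for k in range(1, 4):
            for logs in combinations_with_replacement("pqrs", k):
                assert totem_score(logs, vals) == pytest.approx(
                    oracle_totem(logs, vals)
                )

    @given(
        st.lists(st.sampled_from("pqr"), min_size=1, max_size=3),
        st.integers(0, 5),
    )
    @settings(deadline=None, max_examples=60)
    def test_permutation_invariant_and_linear(self, logs, scale):
        vals = {"p": 60.0, "q": 75.0, "r": 90.0}
        scaled = {k: v * (scale + 1) for k, v in vals.items()}
        base = totem_score(logs, vals)
        assert totem_score(list(reversed(logs)), vals) == pytest.approx(base)
        assert totem_score(logs, scaled) == pytest.approx(base * (scale + 1))

    def test_errors(self):
        vals = {"x": 100.0}
        with pytest.raises(LandscapeError):
            totem_score([], vals)
        with pytest.raises(LandscapeError):
            totem_score(["x"] * 4, vals)
        with pytest.raises(LandscapeError):
            totem_score(["nope"], vals)

    @pytest.mark.parametrize(
        "totem,n,expected", [(390, 10, 540), (0, 0, 0), (7410, 142, 9540)]
    )
    def test_final_score(self, totem, n, expected):
        assert final_score(totem, n) == expected

    def test_final_score_rejects_negative(self):
        with pytest.raises(LandscapeError):
            final_score(-1, 0)
        with pytest.raises(LandscapeError):
            final_score(0, -1)


class TestLogValues:
    def test_fixed_seed_reproducible(self, reference_tree):
        t1 = assign_log_values(reference_tree, seed=5)
        t2 = assign_log_values(reference_tree, seed=5)
        assert t1.values == t2.values

    def test_same_depth_values_may_differ(self, reference_tree):
        table = assign_log_values(reference_tree, seed=5)
        by_depth = {}
        for l, v in table.values.items():
            by_depth.setdefault(table.complexity[l], set()).add(v)
        assert any(len(vs) > 1 for vs in by_depth.values())

    def test_overlapping_ranges_rejected(self, toy_tree):
        with pytest.raises(LandscapeError):
            assign_log_values(
                toy_tree, seed=0,
                ranges={3: (50.0, 120.0), 5: (100.0, 200.0)},
            )

    def test_monotonicity_enforced_by_table_type(self):
        with pytest.raises(LandscapeError):
            LogValueTable(
                values={"a": 100.0, "b": 90.0}, complexity={"a": 1, "b": 2}
            )
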