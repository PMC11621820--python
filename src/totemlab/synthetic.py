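"""One-command generation of complete synthetic experiments.

A scenario runs landscape construction, all requested cohort designs, and
metric extraction end to end, writing event logs (JSON Lines), a tidy
metrics table (CSV), the tech tree (JSON), and a manifest with every seed
and a scenario hash.  Two presets ship:

* ``tiny`` — seconds-scale smoke configuration (a couple of short units per
  design) for fast testing;
* ``paper`` — the study's session structure and cohort sizes (41 extended
  individuals, 59 repeated individuals, 53 chains of four, 53 groups of
  two, 38 groups of four) with the paper-calibrated agent policy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AgentPolicy
from .conditions import CohortPlan, ExperimentLog, make_cohort_plan, run_experiment
from .landscape import CANONICAL_SEED, LandscapeConfig, generate_reference_landscape
from .metrics import participant_table


class ScenarioError(ValueError):
    pass


#: the paper-calibrated policy: default timing calibration plus the
#: salience-anchored exploration needed to reproduce group redundancy
PAPER_POLICY = AgentPolicy(exploration="complexity_biased")


@dataclass(frozen=True)
class ScenarioConfig:
    """Fully serializable description of one synthetic experiment."""

    name: str = "tiny"
    master_seed: int = 0
    landscape_seed: int = CANONICAL_SEED
    session_minutes: dict = field(default_factory=dict)  # per-design override
    cohorts: dict = field(default_factory=dict)  # design -> n_units
    policy: AgentPolicy = field(default_factory=AgentPolicy)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def scenario_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def tiny_config(seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        name="tiny",
        master_seed=seed,
        session_minutes={
            "extended_individual": 10,
            "repeated_individual": 5,
            "chain": 5,
            "group2": 5,
            "group4": 5,
        },
        cohorts={
            "extended_individual": 2,
            "repeated_individual": 2,
            "chain": 2,
            "group2": 1,
            "group4": 1,
        },
        policy=AgentPolicy(exploration="complexity_biased"),
    )


def paper_config(seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        name="paper",
        master_seed=seed,
        cohorts={
            "extended_individual": 41,
            "repeated_individual": 59,
            "chain": 53,
            "group2": 53,
            "group4": 38,
        },
        policy=PAPER_POLICY,
    )


PRESETS = {"tiny": tiny_config, "paper": paper_config}


def preset_config(name: str, seed: int = 0, cohorts: dict | None = None) -> ScenarioConfig:
    if name not in PRESETS:
        raise ScenarioError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[name](seed)
    if cohorts:
        merged = dict(cfg.cohorts)
        merged.update(cohorts)
        cfg = dataclasses.replace(cfg, cohorts=merged)
    return cfg


@dataclass
class Scenario:
    """In-memory result of one scenario run."""

    config: ScenarioConfig
    tree: "object"
    experiments: dict[str, ExperimentLog]
    table: pd.DataFrame
    manifest: dict


def _cohort_key_params(key: str) -> tuple[str, dict]:
    if key.startswith("group"):
        return "group", {"group_size": int(key.removeprefix("group"))}
    return key, {}


def run_scenario(config: ScenarioConfig) -> Scenario:
    """Run landscape -> conditions -> agents -> metrics for one scenario."""
    tree = generate_reference_landscape(seed=config.landscape_seed)
    ss = np.random.SeedSequence(config.master_seed)
    keys = sorted(config.cohorts)
    seeds = ss.spawn(len(keys))
    experiments: dict[str, ExperimentLog] = {}
    manifest = {
        "scenario": config.name,
        "scenario_hash": config.scenario_hash(),
        "master_seed": config.master_seed,
        "landscape_seed": config.landscape_seed,
        "cohort_seeds": {},
    }
    tables = []
    for key, key_ss in zip(keys, seeds):
        design, extra = _cohort_key_params(key)
        params = dict(extra)
        params["n_units"] = config.cohorts[key]
        if key in config.session_minutes:
            params["session_minutes"] = config.session_minutes[key]
        seed = int(key_ss.generate_state(1)[0] % (2**31 - 1))
        manifest["cohort_seeds"][key] = seed
        plan = make_cohort_plan(design, params, seed=seed)
        log = run_experiment(plan, config.policy, tree)
        experiments[key] = log
        tab = participant_table(log)
        tab.insert(0, "cohort", key)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    return Scenario(config, tree, experiments, table, manifest)


def generate_scenario(config: ScenarioConfig, out_dir) -> Scenario:
    """Run a scenario and write its artifacts to ``out_dir``.

    Writes tree.json, one ``events-<cohort>.jsonl`` per cohort, metrics.csv,
    and manifest.json.  Identical configs produce byte-identical output.
    """
    scenario = run_scenario(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.tree.save(out / "tree.json")
    for key, log in scenario.experiments.items():
        lines = []
        for result in log.results():
            lines.append(result.events.to_jsonl())
        (out / f"events-{key}.jsonl").write_text("".join(lines))
    scenario.table.to_csv(out / "metrics.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(scenario.manifest, indent=1, sort_keys=True)
    )
    return scenario
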