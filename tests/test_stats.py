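"""Model designs, posterior inference, contrasts, and recovery checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from totemlab.stats import (
    DegenerateDesignError,
    ModelSpec,
    StatsError,
    build_model_spec,
    contrast,
    effort_table,
    fit,
    inheritance_table,
    monitoring_table,
    novelty_table,
    score_table,
)


class TestModelSpecs:
    def test_score_models(self):
        s25 = build_model_spec("score25")
        assert s25.predictors == ("is_repeated", "is_chain")
        assert s25.random_effect is None and s25.likelihood == "gaussian"
        s50 = build_model_spec("score50")
        assert s50.predictors == ("is_repeated", "is_chain", "is_group")
        assert s50.random_effect == "unit"
        assert build_model_spec("score100").predictors == ("is_chain", "is_group")

    def test_inheritance_models_have_interaction(self):
        for aid in ("inherited", "reproduction_time"):
            spec = build_model_spec(aid)
            assert ("generation", "is_repeated") in spec.interactions
            assert spec.random_effect == "unit"

    def test_novelty_models_binomial_with_unit_effect(self):
        nf = build_model_spec("novelty_full")
        assert nf.likelihood == "binomial"
        assert nf.predictors == ("is_group4", "is_chain")
        assert nf.random_effect == "unit" and nf.trials == "total_combinations"
        ns = build_model_spec("novelty_small")
        assert ns.predictors == ("is_chain",)

    def test_monitoring_and_effort_dummies(self):
        assert build_model_spec("monitoring").predictors == (
            "is_chain4", "is_group2", "is_group4",
        )
        eff = build_model_spec("effort")
        assert eff.predictors == ("is_ext50", "is_rep1", "is_rep2")
        assert eff.random_effect == "participant"

    def test_unknown_id_rejected(self):
        with pytest.raises(StatsError):
            build_model_spec("score75")


def gaussian_table(rng, n=120, effect=0.0, sigma=1.0, n_dummies=1):
    d = {"final_score": rng.normal(0, sigma, n)}
    for j in range(n_dummies):
        dummy = rng.integers(0, 2, n)
        d[f"d{j}"] = dummy
        d["final_score"] = d["final_score"] + effect * dummy
    return pd.DataFrame(d)


def spec_for(n_dummies=1, random_effect=None):
    return ModelSpec(
        "adhoc", "final_score", tuple(f"d{j}" for j in range(n_dummies)),
        random_effect=random_effect,
    )


class TestGaussianFit:
    def test_agrees_with_least_squares_on_balanced_data(self):
        rng = np.random.default_rng(1)
        table = gaussian_table(rng, n=400, effect=50.0, sigma=5.0)
        summary = fit(spec_for(), table, seed=2, n_draws=8000)
        X = sm.add_constant(table["d0"].to_numpy(dtype=float))
        ols = sm.OLS(table["final_score"], X).fit()
        assert summary.mean("intercept") == pytest.approx(
            ols.params.iloc[0], abs=0.15
        )
        assert summary.mean("d0") == pytest.approx(ols.params.iloc[1], abs=0.15)

    def test_recovers_known_dummy_effect(self):
        rng = np.random.default_rng(7)
        table = gaussian_table(rng, n=300, effect=100.0, sigma=20.0)
        summary = fit(spec_for(), table, seed=3)
        lo, hi = summary.interval("d0")
        assert lo < 100.0 < hi
        assert summary.mean("d0") == pytest.approx(100.0, abs=5.0)

    def test_zero_effect_interval_coverage(self):
        """Central 95% intervals cover a true null effect 93-97% of the time."""
        rng = np.random.default_rng(11)
        covered = 0
        reps = 500
        for _ in range(reps):
            table = gaussian_table(rng, n=60, effect=0.0)
            summary = fit(
                spec_for(), table,
                seed=int(rng.integers(2**31 - 1)), n_draws=1500,
            )
            lo, hi = summary.interval("d0")
            covered += lo <= 0.0 <= hi
        assert 0.93 <= covered / reps <= 0.97

    def test_mixed_model_recovers_effect_with_unit_noise(self):
        rng = np.random.default_rng(5)
        units = np.repeat(np.arange(40), 6)
        unit_fx = rng.normal(0, 3.0, 40)[units]
        dummy = rng.integers(0, 2, len(units))
        y = 10.0 + 25.0 * dummy + unit_fx + rng.normal(0, 2.0, len(units))
        table = pd.DataFrame({"final_score": y, "d0": dummy, "unit": units})
        summary = fit(spec_for(random_effect="unit"), table, seed=4)
        lo, hi = summary.interval("d0")
        assert lo < 25.0 < hi
        assert summary.diagnostics["engine"] == "mixedlm-normal-approx"

    def test_missing_outcomes_dropped_and_counted(self):
        rng = np.random.default_rng(6)
        table = gaussian_table(rng, n=100)
        table.loc[:9, "final_score"] = np.nan
        summary = fit(spec_for(), table, seed=1)
        assert summary.diagnostics["n_dropped_missing"] == 10
        assert summary.diagnostics["n"] == 90

    def test_degenerate_design_raises(self):
        rng = np.random.default_rng(8)
        table = gaussian_table(rng, n=50)
        table["d1"] = table["d0"]  # perfectly collinear
        with pytest.raises(DegenerateDesignError):
            fit(spec_for(n_dummies=2), table, seed=1)


class TestBinomialFit:
    @staticmethod
    def binomial_table(rng, p_by_arm, n_units=30, trials=200):
        rows = []
        for arm, p in enumerate(p_by_arm):
            for u in range(n_units):
                rows.append(
                    {
                        "novel_combinations": rng.binomial(trials, p),
                        "total_combinations": trials,
                        "is_group4": arm,
                        "unit": f"a{arm}-u{u}",
                    }
                )
        return pd.DataFrame(rows)

    def test_recovers_printed_probabilities(self):
        """Truth 0.45 vs 0.34 at 200 trials; both inside their intervals."""
        rng = np.random.default_rng(10)
        table = self.binomial_table(rng, (0.45, 0.34))
        spec = ModelSpec(
            "adhoc", "novel_combinations", ("is_group4",),
            random_effect="unit", likelihood="binomial",
            trials="total_combinations",
        )
        summary = fit(spec, table, seed=2)

        def invlogit(x):
            return 1 / (1 + np.exp(-x))

        draws0 = invlogit(summary.draws[:, 0])
        draws1 = invlogit(summary.draws[:, 0] + summary.draws[:, 1])
        assert np.quantile(draws0, 0.025) < 0.45 < np.quantile(draws0, 0.975)
        assert np.quantile(draws1, 0.025) < 0.34 < np.quantile(draws1, 0.975)

    def test_invalid_counts_rejected(self):
        table = pd.DataFrame(
            {"novel_combinations": [5], "total_combinations": [3],
             "is_group4": [0], "unit": ["u"]}
        )
        spec = ModelSpec(
            "adhoc", "novel_combinations", ("is_group4",),
            likelihood="binomial", trials="total_combinations",
        )
        with pytest.raises(StatsError):
            fit(spec, table, seed=0)


@pytest.fixture(scope="module")
def summary():
    rng = np.random.default_rng(3)
    table = gaussian_table(rng, n=200, effect=40.0, n_dummies=2)
    return fit(spec_for(n_dummies=2), table, seed=5)


class TestContrast:
    def test_contrast_of_coefficient_with_itself_is_zero(self, summary):
        mean, (lo, hi) = contrast(summary, {"d0": 1.0}, level=0.95)
        diff, (dlo, dhi) = contrast(summary, {"d0": 0.0})
        assert diff == 0.0 and dlo == 0.0 and dhi == 0.0
        assert lo <= mean <= hi

    def test_sign_flip_symmetry(self, summary):
        m1, (lo1, hi1) = contrast(summary, {"d0": 1.0, "d1": -1.0})
        m2, (lo2, hi2) = contrast(summary, {"d0": -1.0, "d1": 1.0})
        assert m1 == pytest.approx(-m2)
        assert lo1 == pytest.approx(-hi2) and hi1 == pytest.approx(-lo2)

    def test_matches_draw_level_subtraction(self, summary):
        mean, (lo, hi) = contrast(summary, {"d0": 1.0, "d1": -1.0})
        diff = summary.draws[:, 1] - summary.draws[:, 2]
        assert mean == pytest.approx(float(diff.mean()))
        assert lo == pytest.approx(float(np.quantile(diff, 0.025)))
        assert hi == pytest.approx(float(np.quantile(diff, 0.975)))

    def test_unknown_coefficient_rejected(self, summary):
        with pytest.raises(StatsError):
            contrast(summary, {"nope": 1.0})


@pytest.fixture(scope="module")
def tiny_table():
    from totemlab.synthetic import preset_config, run_scenario

    return run_scenario(preset_config("tiny", seed=1)).table


class TestAnalysisTables:
    def test_score_tables_pick_the_right_rows(self, tiny_table):
        t25 = score_table(tiny_table, 25)
        assert set(t25.design) <= {
            "extended_individual", "repeated_individual", "chain"
        }
        assert (t25[t25.design != "extended_individual"].generation == 1).all()
        t100 = score_table(tiny_table, 100)
        assert "extended_individual" not in set(t100.design)

    def test_inheritance_table_excludes_first_generation(self, tiny_table):
        t = inheritance_table(tiny_table)
        assert (t.generation >= 2).all()
        assert set(t.is_repeated.unique()) <= {0, 1}

    def test_monitoring_table_dummies_are_exclusive(self, tiny_table):
        t = monitoring_table(tiny_table)
        assert ((t.is_chain4 + t.is_group2 + t.is_group4) <= 1).all()

    def test_novelty_table_small_restricts_generations(self, tiny_table):
        t = novelty_table(tiny_table, full=False)
        assert set(t[t.design == "chain"].generation) <= {1, 2}

    def test_effort_table_block_structure(self, tiny_table):
        t = effort_table(tiny_table)
        ext = t[(t.is_rep1 == 0) & (t.is_rep2 == 0)]
        assert len(ext) % 2 == 0  # two blocks per extended participant
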