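"""Regression models behind the study's seven analysis families.

All analyses are linear or binomial regressions with dummy coding, optional
random effects for chain/group/participant identity, and inference via
central 95% intervals on posterior draws of the coefficients.  Contrasts
are linear combinations evaluated draw-by-draw.

Inference engines (the original analysis package and its priors are
unpublished; ours are documented, not claimed equivalent):

* Gaussian fixed-effects models: exact conjugate Normal-inverse-gamma
  posterior with a weakly informative normal prior scaled to the outcome
  spread, sampled directly.
* Gaussian mixed models: REML fit (statsmodels MixedLM); fixed-effect
  posterior approximated by a normal centered on the estimates with the
  asymptotic covariance.
* Binomial models: GLM fit with, when a unit random effect is specified,
  cluster-robust covariance by unit; posterior approximated by a normal on
  the coefficient scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

ANALYSES = (
    "score25",
    "score50",
    "score100",
    "inherited",
    "reproduction_time",
    "monitoring",
    "novelty_small",
    "novelty_full",
    "effort",
)


class StatsError(ValueError):
    pass


class DegenerateDesignError(StatsError):
    """Rank-deficient design or separated binomial outcome."""


@dataclass(frozen=True)
class ModelSpec:
    """Design of one analysis: outcome, dummies, interactions, random effect."""

    analysis_id: str
    outcome: str
    predictors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random_effect: str | None = None
    likelihood: str = "gaussian"
    trials: str | None = None  # binomial: column holding the trial counts

    def __post_init__(self):
        if self.likelihood not in ("gaussian", "binomial"):
            raise StatsError(f"unknown likelihood {self.likelihood!r}")
        if self.likelihood == "binomial" and self.trials is None:
            raise StatsError("binomial models need a trials column")

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        names = ["intercept", *self.predictors]
        names += [f"{a}:{b}" for a, b in self.interactions]
        return tuple(names)


def build_model_spec(analysis_id: str) -> ModelSpec:
    """The exact design of each analysis family.

    Dummy conventions: ``is_repeated``, ``is_chain``, ``is_group`` mark the
    treatment of each row against the analysis baseline; ``generation`` is
    the session/generation number; unit identity columns are ``unit`` and
    ``participant``.
    """
    if analysis_id == "score25":
        return ModelSpec(analysis_id, "final_score",
                         ("is_repeated", "is_chain"))
    if analysis_id == "score50":
        return ModelSpec(analysis_id, "final_score",
                         ("is_repeated", "is_chain", "is_group"),
                         random_effect="unit")
    if analysis_id == "score100":
        return ModelSpec(analysis_id, "final_score",
                         ("is_chain", "is_group"), random_effect="unit")
    if analysis_id == "inherited":
        return ModelSpec(analysis_id, "items_inherited",
                         ("generation", "is_repeated"),
                         interactions=(("generation", "is_repeated"),),
                         random_effect="unit")
    if analysis_id == "reproduction_time":
        return ModelSpec(analysis_id, "time_to_reproduce_min",
                         ("generation", "is_repeated"),
                         interactions=(("generation", "is_repeated"),),
                         random_effect="unit")
    if analysis_id == "monitoring":
        return ModelSpec(analysis_id, "monitoring",
                         ("is_chain4", "is_group2", "is_group4"))
    if analysis_id == "novelty_small":
        return ModelSpec(analysis_id, "novel_combinations", ("is_chain",),
                         random_effect="unit", likelihood="binomial",
                         trials="total_combinations")
    if analysis_id == "novelty_full":
        return ModelSpec(analysis_id, "novel_combinations",
                         ("is_group4", "is_chain"),
                         random_effect="unit", likelihood="binomial",
                         trials="total_combinations")
    if analysis_id == "effort":
        return ModelSpec(analysis_id, "combinations",
                         ("is_ext50", "is_rep1", "is_rep2"),
                         random_effect="participant")
    raise StatsError(f"unknown analysis_id {analysis_id!r}")


@dataclass
class PosteriorSummary:
    """Per-coefficient posterior mean and central 95% interval, with draws."""

    names: tuple[str, ...]
    draws: np.ndarray  # (n_draws, n_coefficients)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.names):
            raise StatsError("draws shape does not match coefficient names")

    def mean(self, name: str) -> float:
        return float(self.draws[:, self._idx(name)].mean())

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.quantile(
            self.draws[:, self._idx(name)],
            [(1 - level) / 2, 1 - (1 - level) / 2],
        )
        return float(lo), float(hi)

    def _idx(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise StatsError(f"unknown coefficient {name!r}") from None

    def summary(self) -> pd.DataFrame:
        lo, hi = np.quantile(self.draws, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "mean": self.draws.mean(axis=0),
                "ci_lo": lo,
                "ci_hi": hi,
            },
            index=list(self.names),
        )


def _design_matrix(spec: ModelSpec, table: pd.DataFrame):
    cols = {}
    for p in spec.predictors:
        if p not in table:
            raise StatsError(f"table lacks predictor column {p!r}")
        cols[p] = table[p].to_numpy(dtype=float)
    for a, b in spec.interactions:
        cols[f"{a}:{b}"] = table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table))] + list(cols.values()))
    names = spec.coefficient_names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "design matrix is rank deficient (collinear or constant dummies)"
        )
    return X, names


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    seed: int = 0,
    n_draws: int = 4000,
    prior_scale: float = 10.0,
) -> PosteriorSummary:
    """Fit one analysis and return posterior draws of its coefficients.

    Rows with missing outcome values (e.g. incomplete reproducers) are
    dropped with their count recorded in the diagnostics.
    """
    if spec.outcome not in table:
        raise StatsError(f"table lacks outcome column {spec.outcome!r}")
    work = table.copy()
    n0 = len(work)
    needed = [spec.outcome, *spec.predictors]
    if spec.trials:
        needed.append(spec.trials)
    work = work.dropna(subset=needed)
    n_dropped = n0 - len(work)
    if len(work) <= len(spec.coefficient_names) + 1:
        raise StatsError("not enough rows to fit the model")
    X, names = _design_matrix(spec, work)
    rng = np.random.default_rng(seed)
    diagnostics = {
        "engine": None,
        "n": len(work),
        "n_dropped_missing": n_dropped,
        "seed": seed,
    }

    if spec.likelihood == "binomial":
        succ = work[spec.outcome].to_numpy(dtype=float)
        trials = work[spec.trials].to_numpy(dtype=float)
        if np.any(succ > trials) or np.any(trials <= 0):
            raise StatsError("binomial outcome needs 0 <= successes <= trials > 0")
        endog = np.column_stack([succ, trials - succ])
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if spec.random_effect:
                groups = work[spec.random_effect].to_numpy()
                res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
                diagnostics["engine"] = "glm-binomial-cluster"
            else:
                res = model.fit()
                diagnostics["engine"] = "glm-binomial"
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 15):
            raise DegenerateDesignError(
                "binomial fit did not converge (possible separation)"
            )
        draws = rng.multivariate_normal(params, cov, size=n_draws, method="svd")
        return PosteriorSummary(names, draws, diagnostics)

    y = work[spec.outcome].to_numpy(dtype=float)
    if spec.random_effect:
        groups = work[spec.random_effect].to_numpy()
        if len(np.unique(groups)) < 2:
            raise DegenerateDesignError("random effect needs at least 2 groups")
        p = X.shape[1]
        params = cov = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
            params = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:p, :p]
            if np.all(np.isfinite(params)) and np.all(np.isfinite(cov)):
                diagnostics["engine"] = "mixedlm-normal-approx"
                diagnostics["converged"] = bool(res.converged)
            else:
                params = None
        except (np.linalg.LinAlgError, ValueError):
            params = None
        if params is None:
            # boundary/singular mixed fit: cluster-robust OLS keeps the
            # group dependence in the coefficient covariance
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.OLS(y, X).fit(
                    cov_type="cluster", cov_kwds={"groups": groups}
                )
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            diagnostics["engine"] = "ols-cluster-robust"
        draws = rng.multivariate_normal(params, cov, size=n_draws, method="svd")
        return PosteriorSummary(names, draws, diagnostics)

    # conjugate Normal-inverse-gamma posterior, weak prior scaled to sd(y)
    n, p = X.shape
    s_y = float(np.std(y)) or 1.0
    tau2 = (prior_scale * s_y) ** 2
    lam0 = np.eye(p) / tau2
    a0, b0 = 2.0, s_y**2
    xtx = X.T @ X
    lam_n = xtx + lam0
    lam_inv = np.linalg.inv(lam_n)
    mu_n = lam_inv @ (X.T @ y)
    a_n = a0 + n / 2.0
    b_n = b0 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
    sigma2 = b_n / rng.gamma(a_n, 1.0, size=n_draws)
    z = rng.standard_normal((n_draws, p))
    chol = np.linalg.cholesky(lam_inv)
    draws = mu_n + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    diagnostics["engine"] = "conjugate-nig"
    return PosteriorSummary(names, draws, diagnostics)


def contrast(
    summary: PosteriorSummary, weights: dict[str, float], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Posterior mean and central interval of a linear coefficient combination."""
    comb = np.zeros(summary.draws.shape[0])
    for name, w in weights.items():
        comb += w * summary.draws[:, summary._idx(name)]
    lo, hi = np.quantile(comb, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(comb.mean()), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Analysis-table builders: map the tidy metrics table onto each model's rows
# ---------------------------------------------------------------------------


def _one_row_per(table: pd.DataFrame, mask, **dummies) -> pd.DataFrame:
    out = table[mask].copy()
    for k, v in dummies.items():
        out[k] = v
    return out


def score_table(table: pd.DataFrame, accumulated_minutes: int) -> pd.DataFrame:
    """Rows entering the score-at-accumulated-time models (25/50/100 min)."""
    t = table
    parts = []
    if accumulated_minutes == 25:
        ext25 = _one_row_per(
            t, (t.design == "extended_individual") & (t.generation == 1),
            is_repeated=0, is_chain=0,
        )
        if "score_at_25min" in ext25:
            ext25["final_score"] = ext25["score_at_25min"]
        parts = [
            ext25,
            _one_row_per(t, (t.design == "repeated_individual") & (t.generation == 1),
                         is_repeated=1, is_chain=0),
            _one_row_per(t, (t.design == "chain") & (t.generation == 1),
                         is_repeated=0, is_chain=1),
        ]
    elif accumulated_minutes == 50:
        parts = [
            _one_row_per(t, (t.design == "extended_individual"),
                         is_repeated=0, is_chain=0, is_group=0),
            _one_row_per(t, (t.design == "repeated_individual") & (t.generation == 2),
                         is_repeated=1, is_chain=0, is_group=0),
            _one_row_per(t, (t.design == "chain") & (t.generation == 2),
                         is_repeated=0, is_chain=1, is_group=0),
            _one_row_per(t, (t.design == "group") & (t.session_minutes * 2 == 50),
                         is_repeated=0, is_chain=0, is_group=1),
        ]
    elif accumulated_minutes == 100:
        parts = [
            _one_row_per(t, (t.design == "repeated_individual") & (t.generation == 4),
                         is_chain=0, is_group=0),
            _one_row_per(t, (t.design == "chain") & (t.generation == 4),
                         is_chain=1, is_group=0),
            _one_row_per(t, (t.design == "group") & (t.session_minutes * 4 == 100),
                         is_chain=0, is_group=1),
        ]
    else:
        raise StatsError("accumulated_minutes must be 25, 50, or 100")
    return pd.concat(parts, ignore_index=True)


def inheritance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Generations 2+ of repeated individuals and chains."""
    t = table
    mask = t.design.isin(["repeated_individual", "chain"]) & (t.generation >= 2)
    out = t[mask].copy()
    out["is_repeated"] = (out.design == "repeated_individual").astype(int)
    out["time_to_reproduce_min"] = out.time_to_reproduce_s / 60.0
    return out


def monitoring_table(table: pd.DataFrame, group_size_of=None) -> pd.DataFrame:
    """2nd/4th-generation chain members plus group members, dummy coded."""
    t = table
    chains = t[(t.design == "chain") & t.generation.isin([2, 4])].copy()
    chains["is_chain4"] = (chains.generation == 4).astype(int)
    chains["is_group2"] = 0
    chains["is_group4"] = 0
    groups = t[t.design == "group"].copy()
    sizes = groups.unit.str.extract(r"group-(\d+)-")[0].astype(int) \
        if group_size_of is None else groups.unit.map(group_size_of)
    groups["is_chain4"] = 0
    groups["is_group2"] = (sizes == 2).astype(int)
    groups["is_group4"] = (sizes == 4).astype(int)
    return pd.concat([chains, groups], ignore_index=True)


def novelty_table(table: pd.DataFrame, full: bool = True) -> pd.DataFrame:
    """Chain and group rows entering the binomial redundancy models."""
    t = table
    groups = t[t.design == "group"].copy()
    sizes = groups.unit.str.extract(r"group-(\d+)-")[0].astype(int)
    if full:
        chains = t[t.design == "chain"].copy()
        chains["is_group4"] = 0
        chains["is_chain"] = 1
        groups["is_group4"] = (sizes == 4).astype(int)
        groups["is_chain"] = 0
        return pd.concat([chains, groups], ignore_index=True)
    chains = t[(t.design == "chain") & t.generation.isin([1, 2])].copy()
    chains["is_chain"] = 1
    g2 = groups[sizes == 2].copy()
    g2["is_chain"] = 0
    return pd.concat([chains, g2], ignore_index=True)


def effort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Attempt counts per 25-minute block for extended and repeated learners."""
    t = table
    rows = []
    ext = t[t.design == "extended_individual"]
    for _, r in ext.iterrows():
        rows.append(dict(participant=r.participant, combinations=r.combinations_h1,
                         is_ext50=0, is_rep1=0, is_rep2=0))
        rows.append(dict(participant=r.participant, combinations=r.combinations_h2,
                         is_ext50=1, is_rep1=0, is_rep2=0))
    rep = t[(t.design == "repeated_individual") & t.generation.isin([1, 2])]
    for _, r in rep.iterrows():
        rows.append(dict(participant=r.participant, combinations=r.combinations,
                         is_ext50=0, is_rep1=int(r.generation == 1),
                         is_rep2=int(r.generation == 2)))
    return pd.DataFrame(rows)
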