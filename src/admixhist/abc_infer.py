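"""Machine-learning ABC: scenario choice and posterior parameter estimation.

A *reference table* holds, per simulation, the scenario label, the
generating parameters and the 42 summary statistics.  Scenario choice
is a random-forest classification on the statistics (optionally
augmented with linear-discriminant axes): the forest's per-tree votes
select the scenario for the observed statistics, out-of-bag
classification of the table gives the prior error and confusion matrix,
and the posterior probability of the selected scenario is one minus the
prediction of a second regression forest fitted to the out-of-bag
misclassification indicators.

Parameter estimation restricts the table to the winning scenario,
retains the tolerance fraction of simulations nearest to the observed
statistics (Euclidean distance on robustly standardized statistics),
maps parameters to the real line with a bounded logit using their prior
ranges, fits an ensemble of feed-forward neural-network regressions of
the transformed parameters on the statistics, applies the nonlinear
regression adjustment (observed prediction plus retained residuals) and
back-transforms, reporting the median with 50% and 95% credibility
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .scenarios import PARAMETER_COLUMNS, PriorSpec
from .sumstats import SUMMARY_NAMES

__all__ = [
    "ReferenceTable",
    "PriorCheckResult",
    "ScenarioChoiceResult",
    "PosteriorEstimate",
    "prior_check",
    "rf_scenario_choice",
    "rf_cross_validate",
    "nn_estimate",
    "nn_cross_validate",
]


@dataclass
class ReferenceTable:
    """Simulations x (scenario label + parameters + 42 statistics)."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SUMMARY_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"table lacks statistic columns: {missing[:3]}...")
        if "scenario" not in self.data.columns:
            raise ValueError("table lacks a scenario column")
        if self.data[list(SUMMARY_NAMES)].isna().any().any():
            raise ValueError("missing values in summary statistics")

    @property
    def stats(self) -> np.ndarray:
        return self.data[list(SUMMARY_NAMES)].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["scenario"].to_numpy()

    @property
    def scenarios(self) -> list:
        return sorted(self.data["scenario"].unique())

    def restrict(self, scenario: str) -> "ReferenceTable":
        sub = self.data[self.data["scenario"] == scenario].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no rows for scenario {scenario!r}")
        return ReferenceTable(sub)

    def parameter_names(self) -> list:
        """Parameter columns populated (non-NA) in every row of the table."""
        cols = [c for c in PARAMETER_COLUMNS if c != "scenario" and c in self.data]
        return [c for c in cols if self.data[c].notna().all()]

    def parameters(self) -> pd.DataFrame:
        return self.data[self.parameter_names()]


@dataclass
class PriorCheckResult:
    p_value: float
    gof_observed: float
    gof_null: np.ndarray
    statistic_percentiles: pd.Series  # per-statistic percentile of observed
    pca_observed: np.ndarray
    pca_table: np.ndarray


@dataclass
class ScenarioChoiceResult:
    votes: pd.Series  # per-scenario tree votes
    selected: str
    posterior_probability: float
    prior_error: float
    confusion: pd.DataFrame  # out-of-bag, rows = true, cols = predicted
    importances: pd.Series


@dataclass
class PosteriorEstimate:
    samples: pd.DataFrame  # adjusted posterior sample per parameter
    medians: pd.Series
    ci50: pd.DataFrame  # columns lo, hi
    ci95: pd.DataFrame


def _standardize(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-statistic robust scale (MAD, falling back to SD then 1)."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0) * 1.4826
    sd = stats.std(axis=0)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return med, scale


def prior_check(
    observed: np.ndarray,
    table: ReferenceTable,
    n_null: int = 1_000,
    n_nearest: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> PriorCheckResult:
    """Goodness of fit of the observed statistics to the simulated cloud.

    The statistic is the mean distance (statistics z-scored over the
    table) from the observed vector to its n_nearest nearest
    simulations; the null distribution re-computes it for n_null table
    rows treated as pseudo-observed (distances to the other rows); the
    p-value is the fraction of null values at least as large.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_null < 100:
        warnings.warn("n_null < 100 gives a coarse null distribution", stacklevel=2)
    S = table.stats
    mu, sd = S.mean(axis=0), S.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (S - mu) / sd
    z_obs = (np.asarray(observed, dtype=float) - mu) / sd

    def gof(z: np.ndarray, pool: np.ndarray) -> float:
        d = np.sqrt(((pool - z) ** 2).sum(axis=1))
        return float(np.sort(d)[:n_nearest].mean())

    obs_stat = gof(z_obs, Z)
    idx = rng.choice(len(Z), size=min(n_null, len(Z)), replace=False)
    null = np.empty(idx.size)
    for i, row in enumerate(idx):
        pool = np.delete(Z, row, axis=0)
        null[i] = gof(Z[row], pool)
    p = float((null >= obs_stat).mean())

    pct = pd.Series(
        [float((S[:, j] <= observed[j]).mean() * 100) for j in range(S.shape[1])],
        index=list(SUMMARY_NAMES),
    )
    # 2-component PCA projection for visual prior checking
    cov_evecs = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)[2][:2].T
    return PriorCheckResult(
        p_value=p,
        gof_observed=obs_stat,
        gof_null=null,
        statistic_percentiles=pct,
        pca_observed=(z_obs - Z.mean(axis=0)) @ cov_evecs,
        pca_table=(Z - Z.mean(axis=0)) @ cov_evecs,
    )


def _design_matrices(table: ReferenceTable, observed: np.ndarray, add_lda: bool,
                     seed: int):
    X = table.stats
    y = table.labels
    obs = np.asarray(observed, dtype=float)[None, :]
    if add_lda and len(np.unique(y)) >= 2:
        lda = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            axes = lda.fit(X, y).transform(X)
            obs_axes = lda.transform(obs)
        X = np.hstack([X, axes])
        obs = np.hstack([obs, obs_axes])
        names = list(SUMMARY_NAMES) + [f"LD{i+1}" for i in range(axes.shape[1])]
    else:
        names = list(SUMMARY_NAMES)
    return X, y, obs, names


def _oob_predictions(clf: RandomForestClassifier, y: np.ndarray) -> np.ndarray:
    proba = clf.oob_decision_function_
    bad = np.isnan(proba).any(axis=1) | (proba.sum(axis=1) == 0)
    pred = clf.classes_[np.nanargmax(np.where(np.isnan(proba), -1, proba), axis=1)]
    pred[bad] = y[bad]  # rows never out-of-bag: count as correct (rare)
    return pred


class ScenarioForest:
    """A fitted scenario-choice forest, reusable across observed vectors.

    Bundles the classification forest, the out-of-bag error regression
    forest for posterior probabilities, and the (optional) linear
    discriminant augmentation.
    """

    def __init__(self, table: ReferenceTable, rng: Optional[np.random.Generator] = None,
                 n_trees: int = 500, add_lda: bool = True):
        rng = np.random.default_rng() if rng is None else rng
        if len(set(table.labels)) < 2:
            raise ValueError("scenario choice needs >= 2 scenarios in the table")
        seed = int(rng.integers(0, 2**31))
        X = table.stats
        y = table.labels
        self._lda = None
        names = list(SUMMARY_NAMES)
        if add_lda and len(np.unique(y)) >= 2:
            self._lda = LinearDiscriminantAnalysis()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                axes = self._lda.fit(X, y).transform(X)
            X = np.hstack([X, axes])
            names += [f"LD{i+1}" for i in range(axes.shape[1])]
        self.feature_names = names
        self.clf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf.fit(X, y)
        oob_pred = _oob_predictions(self.clf, y)
        self.prior_error = float((oob_pred != y).mean())
        self.confusion = pd.crosstab(
            pd.Series(y, name="true"), pd.Series(oob_pred, name="predicted"),
            dropna=False,
        ).reindex(index=self.clf.classes_, columns=self.clf.classes_, fill_value=0)
        err = (oob_pred != y).astype(float)
        self.err_forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed + 1, n_jobs=1
        )
        self.err_forest.fit(X, err)
        self.importances = pd.Series(
            self.clf.feature_importances_, index=names
        ).sort_values(ascending=False)

    def _obs_row(self, observed: np.ndarray) -> np.ndarray:
        obs = np.asarray(observed, dtype=float)[None, :]
        if self._lda is not None:
            obs = np.hstack([obs, self._lda.transform(obs)])
        return obs

    def choose(self, observed: np.ndarray) -> ScenarioChoiceResult:
        obs = self._obs_row(observed)
        # forest trees predict encoded class indices
        tree_idx = np.array([int(t.predict(obs)[0]) for t in self.clf.estimators_])
        classes = self.clf.classes_
        votes = pd.Series([(tree_idx == i).sum() for i in range(len(classes))],
                          index=classes)
        return ScenarioChoiceResult(
            votes=votes,
            selected=str(votes.idxmax()),
            posterior_probability=float(1.0 - self.err_forest.predict(obs)[0]),
            prior_error=self.prior_error,
            confusion=self.confusion,
            importances=self.importances,
        )


def strong_signal_vectors(forest: "ScenarioForest", table: ReferenceTable,
                          k: int = 3) -> dict:
    """Per scenario: the k table rows the forest classifies with the
    highest out-of-bag confidence for their true scenario.

    These parameter vectors sit deepest inside each scenario's
    recognisable region of the statistic space, making datasets
    regenerated from them the natural strong-signal inputs for
    scenario-recovery experiments.
    """
    from .scenarios import vector_from_record

    proba = forest.clf.oob_decision_function_
    classes = list(forest.clf.classes_)
    labels = table.labels
    out = {}
    for scen in classes:
        ci = classes.index(scen)
        conf = np.where(labels == scen, proba[:, ci], -1.0)
        best = np.argsort(-conf)[:k]
        out[scen] = [vector_from_record(table.data.iloc[b]) for b in best]
    return out


def rf_scenario_choice(
    table: ReferenceTable,
    observed: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    n_trees: int = 500,
    add_lda: bool = True,
) -> ScenarioChoiceResult:
    """Random-forest scenario choice for one observed statistics vector."""
    return ScenarioForest(table, rng=rng, n_trees=n_trees, add_lda=add_lda).choose(
        observed
    )


def rf_cross_validate(
    table: ReferenceTable,
    rng: Optional[np.random.Generator] = None,
    n_trees: int = 500,
    add_lda: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Out-of-bag confusion matrix and prior error over the whole table."""
    rng = np.random.default_rng() if rng is None else rng
    seed = int(rng.integers(0, 2**31))
    X, y, _, _ = _design_matrices(table, table.stats[0], add_lda, seed)
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    oob_pred = _oob_predictions(clf, y)
    prior_error = float((oob_pred != y).mean())
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(oob_pred, name="predicted"),
        dropna=False,
    ).reindex(index=clf.classes_, columns=clf.classes_, fill_value=0)
    return confusion, prior_error


# ---------------------------------------------------------------------------
# neural-network posterior estimation

_EPS = 1e-6


def _to_real(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    u = np.clip((x - lo) / (hi - lo), _EPS, 1 - _EPS)
    return np.log(u / (1 - u))


def _from_real(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    from scipy.special import expit

    return lo + (hi - lo) * expit(z)


def nn_estimate(
    table: ReferenceTable,
    observed: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    tolerance: float = 0.01,
    n_networks: int = 10,
    hidden: int = 8,
    alpha: float = 0.5,
    prior: Optional[PriorSpec] = None,
    param_names: Optional[Sequence[str]] = None,
) -> PosteriorEstimate:
    """Neural-network ABC joint posterior for one scenario's parameters.

    Retains the `tolerance` fraction of simulations nearest to the
    observed statistics, regresses logit-transformed (and per-parameter
    z-scored) parameters on the statistics with an ensemble of
    `n_networks` single-hidden-layer networks, each fitted on a random
    half of the retained rows, and adjusts the retained parameter
    values by the ensemble regression: observed prediction plus each
    row's *out-of-bag* residual.  Out-of-bag residuals keep the
    adjusted spread honest where in-sample residuals of a flexible
    regression would collapse it; `alpha` is the networks' L2 weight
    decay.  Posterior samples are back-transformed to the prior ranges.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not (0 < tolerance <= 1):
        raise ValueError("tolerance must be in (0, 1]")
    prior = PriorSpec() if prior is None else prior
    names = list(param_names) if param_names is not None else table.parameter_names()
    if not names:
        raise ValueError("no parameter columns in table")
    S = table.stats
    n = len(S)
    if n < 5:
        raise ValueError("table too small for rejection sampling")
    n_keep = min(max(int(np.ceil(tolerance * n)), min(10, n)), n)
    med, scale = _standardize(S)
    Z = (S - med) / scale
    z_obs = (np.asarray(observed, dtype=float) - med) / scale
    d = np.sqrt(((Z - z_obs) ** 2).sum(axis=1))
    keep = np.argsort(d)[:n_keep]

    theta = table.data.iloc[keep][names].to_numpy(dtype=float)
    bounds = [prior.bounds_for(p) for p in names]
    T = np.column_stack(
        [_to_real(theta[:, j], lo, hi) for j, (lo, hi) in enumerate(bounds)]
    )
    if np.ptp(T, axis=0).max() == 0:
        raise ValueError("degenerate retained parameter set")
    t_mu = T.mean(axis=0)
    t_sd = np.where(T.std(axis=0) > 0, T.std(axis=0), 1.0)
    Tz = (T - t_mu) / t_sd

    Xk = Z[keep]
    pred_obs = np.zeros((n_networks, len(names)))
    oob_sum = np.zeros_like(Tz)
    oob_cnt = np.zeros(n_keep)
    for m in range(n_networks):
        sub = rng.random(n_keep) < 0.5
        if sub.sum() < min(10, n_keep):
            sub[rng.choice(n_keep, size=min(10, n_keep), replace=False)] = True
        net = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            solver="lbfgs",
            max_iter=500,
            alpha=alpha,
            random_state=int(rng.integers(0, 2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(Xk[sub], Tz[sub])
        pred_obs[m] = np.atleast_2d(net.predict(z_obs[None, :]))[0]
        oob = ~sub
        if oob.any():
            oob_sum[oob] += net.predict(Xk[oob]).reshape(int(oob.sum()), len(names))
            oob_cnt[oob] += 1
    seen = oob_cnt > 0
    oob_pred = oob_sum[seen] / oob_cnt[seen, None]
    adjusted = (pred_obs.mean(axis=0)[None, :] + (Tz[seen] - oob_pred)) * t_sd + t_mu

    cols = {}
    for j, (name, (lo, hi)) in enumerate(zip(names, bounds)):
        cols[name] = _from_real(adjusted[:, j], lo, hi)
    samples = pd.DataFrame(cols)
    medians = samples.median()
    ci50 = pd.DataFrame(
        {"lo": samples.quantile(0.25), "hi": samples.quantile(0.75)}
    )
    ci95 = pd.DataFrame(
        {"lo": samples.quantile(0.025), "hi": samples.quantile(0.975)}
    )
    return PosteriorEstimate(samples=samples, medians=medians, ci50=ci50, ci95=ci95)


def nn_cross_validate(
    table: ReferenceTable,
    rng: Optional[np.random.Generator] = None,
    tolerance: float = 0.01,
    n_folds: int = 20,
    n_networks: int = 5,
    prior: Optional[PriorSpec] = None,
) -> pd.Series:
    """Per-parameter scaled prediction error by leave-out pseudo-observation.

    For n_folds random table rows used in turn as pseudo-observed, the
    squared error of the posterior median is averaged and divided by the
    parameter's variance over the table (prior-level error is ~1).
    """
    rng = np.random.default_rng() if rng is None else rng
    names = table.parameter_names()
    truth_all = table.data[names].to_numpy(dtype=float)
    prior_var = truth_all.var(axis=0)
    prior_var = np.where(prior_var > 0, prior_var, 1.0)
    idx = rng.choice(len(table.data), size=min(n_folds, len(table.data)), replace=False)
    sq = np.zeros((idx.size, len(names)))
    for i, row in enumerate(idx):
        rest = ReferenceTable(table.data.drop(table.data.index[row]).reset_index(drop=True))
        est = nn_estimate(
            rest, table.stats[row], rng=rng, tolerance=tolerance,
            n_networks=n_networks, prior=prior, param_names=names,
        )
        sq[i] = (est.medians[names].to_numpy() - truth_all[row]) ** 2
    return pd.Series(sq.mean(axis=0) / prior_var, index=names)
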