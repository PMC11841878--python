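"""Four-phase covariate selection for the habitat model.

Phase 1 screens covariates within thematic groups by predictive strength
(percent contribution, permutation importance, jackknife gains); Phase 2
combines the survivors while forbidding correlated covariates (pairwise
Pearson R^2 or Cramer's V above 0.65) from sharing a model; Phase 3
enumerates all candidate models of uncorrelated covariates and ranks them
by median AIC over bootstrap resamples; Phase 4 sweeps the regularization
multiplier (1.0 to 5.0 in steps of 0.5) and keeps the RM with the lowest
median AIC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .evaluation import auc
from .maxent import (FeatureExpansion, FeatureSpec, FitConfig, MaxentModel,
                     aic, fit_maxent, gain, n_parameters, unregularized_gain)

DEFAULT_CORR_THRESHOLD = 0.65  # pairs exceeding this are "correlated"


# ---------------------------------------------------------------- phase 0
@dataclass
class CorrelationReport:
    names: list[str]
    matrix: np.ndarray              # R^2 or Cramer's V per pair
    threshold: float
    groups: list[list[str]]         # connected components over > threshold edges

    def correlated(self, a: str, b: str) -> bool:
        i, j = self.names.index(a), self.names.index(b)
        return self.matrix[i, j] > self.threshold


def cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    """Cramer's V from the chi-square statistic of the contingency table."""
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    chi2 = chi2_contingency(table, correction=False).statistic
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def _decile_bins(x: np.ndarray) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, 11)))
    return np.digitize(x, edges[1:-1])


def correlation_screen(
    design: np.ndarray | pd.DataFrame,
    kinds: list[str] | None = None,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> CorrelationReport:
    """Pairwise association matrix and correlated groups.

    Continuous pairs use squared Pearson correlation; categorical pairs
    Cramer's V; mixed pairs Cramer's V after decile-binning the continuous
    member.  Groups are connected components of the graph whose edges are
    pairs *strictly exceeding* the threshold.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"cov{i}" for i in range(X.shape[1])]
    d = X.shape[1]
    if d < 2:
        raise ValueError("need at least 2 covariates")
    kinds = kinds or ["continuous"] * d
    mat = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            xi, xj = X[:, i], X[:, j]
            if kinds[i] == kinds[j] == "continuous":
                if xi.std() == 0 or xj.std() == 0:
                    warnings.warn(f"constant covariate in pair ({names[i]}, "
                                  f"{names[j]}); R^2 set to 0")
                    val = 0.0
                else:
                    val = float(np.corrcoef(xi, xj)[0, 1] ** 2)
            elif kinds[i] == kinds[j] == "categorical":
                val = cramers_v(xi, xj)
            else:  # mixed: V on the decile-binned continuous member
                a = _decile_bins(xi) if kinds[i] == "continuous" else xi
                b = _decile_bins(xj) if kinds[j] == "continuous" else xj
                val = cramers_v(a, b)
            mat[i, j] = mat[j, i] = val
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(d):
        for j in range(i + 1, d):
            if mat[i, j] > threshold:
                graph.add_edge(names[i], names[j])
    groups = [sorted(c, key=names.index) for c in nx.connected_components(graph)]
    groups.sort(key=lambda g: names.index(g[0]))
    return CorrelationReport(names, mat, threshold, groups)


# ---------------------------------------------------------- strength measures
def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Path-dependent attribution: each coordinate update's objective gain
    is credited to the updated feature's parent covariate(s), normalized
    to sum to 100.  Requires the fit trace (kept by fit_maxent)."""
    if model.trace is None:
        raise ValueError("fit trace absent; refit with tracking enabled")
    names = model.covariate_names
    credit = dict.fromkeys(names, 0.0)
    for feat_idx, improvement in model.trace:
        parents = model.expansion.feature_parents[feat_idx]
        for p in parents:
            credit[names[p]] += improvement / len(parents)
    total = sum(credit.values())
    if total <= 0:
        return dict.fromkeys(names, 0.0)
    return {k: 100.0 * v / total for k, v in credit.items()}


def permutation_importance(
    model: MaxentModel,
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    n_permutations: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Normalized training-AUC drop when each covariate is permuted.

    The covariate's values are shuffled jointly across the used+available
    rows; the drop is averaged over ``n_permutations`` shuffles, floored
    at 0, and the vector is scaled to sum to 100.
    """
    rng = np.random.default_rng(seed)
    used_raw = np.atleast_2d(used_raw)
    available_raw = np.atleast_2d(available_raw)
    names = model.covariate_names
    base = auc(model.predict_raw(used_raw), model.predict_raw(available_raw))
    n_u = used_raw.shape[0]
    stacked = np.vstack([used_raw, available_raw])
    drops = {}
    for idx, name in enumerate(names):
        vals = []
        for _ in range(n_permutations):
            perm = stacked.copy()
            perm[:, idx] = rng.permutation(perm[:, idx])
            a = auc(model.predict_raw(perm[:n_u]), model.predict_raw(perm[n_u:]))
            vals.append(base - a)
        drops[name] = max(float(np.mean(vals)), 0.0)
    total = sum(drops.values())
    if total <= 0:
        return dict.fromkeys(names, 0.0)
    return {k: 100.0 * v / total for k, v in drops.items()}


@dataclass
class JackknifeResult:
    only_train_gain: dict[str, float]
    only_test_gain: dict[str, float]
    without_train_gain: dict[str, float]
    without_test_gain: dict[str, float]
    full_train_gain: float


def jackknife_gains(
    names: list[str],
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    config: FitConfig = FitConfig(),
    spec: FeatureSpec = FeatureSpec(),
) -> JackknifeResult:
    """Per-covariate "only" and "without" training/test gains.

    Test gains come from one seeded 80/20 split of the used points; the
    with-only-covariate-j gain near zero marks a covariate carrying no
    signal, and the advancement rule keeps covariates whose only-gain
    meets the threshold (default 2.5 nats, i.e. an exp(2.5) = 12.2-fold
    likelihood improvement over the null model).
    """
    if len(names) < 2:
        raise ValueError("need at least 2 covariates")
    used_raw = np.atleast_2d(used_raw)
    rng = np.random.default_rng(config.seed)
    n_u = used_raw.shape[0]
    order = rng.permutation(n_u)
    n_train = max(int(round(config.train_fraction * n_u)), 2)
    train, test = order[:n_train], order[n_train:]
    if test.size == 0:
        test = order[-1:]

    def _fit(cols: list[int]) -> tuple[float, float]:
        m = fit_maxent(used_raw[train][:, cols], available_raw[:, cols],
                       [names[c] for c in cols], config, spec)
        return (gain(m, used_raw[train][:, cols]),
                unregularized_gain(m, used_raw[test][:, cols]))

    only_tr, only_te, without_tr, without_te = {}, {}, {}, {}
    all_cols = list(range(len(names)))
    full_tr, _ = _fit(all_cols)
    for j, name in enumerate(names):
        g_tr, g_te = _fit([j])
        only_tr[name], only_te[name] = g_tr, g_te
        rest = [c for c in all_cols if c != j]
        g_tr, g_te = _fit(rest)
        without_tr[name], without_te[name] = g_tr, g_te
    return JackknifeResult(only_tr, only_te, without_tr, without_te, full_tr)


def advance_covariates(
    contribution: dict[str, float],
    importance: dict[str, float],
    jack: JackknifeResult,
    influence_threshold: float = 20.0,
    gain_threshold: float = 2.5,
) -> list[str]:
    """Phase-1 style advancement: influence >= 20 on either attribution
    measure AND jackknife only-gain >= 2.5 (both configurable)."""
    out = []
    for name in contribution:
        influential = (contribution[name] >= influence_threshold
                       or importance[name] >= influence_threshold)
        strong = (jack.only_train_gain[name] >= gain_threshold
                  and jack.only_test_gain[name] >= gain_threshold)
        if influential and strong:
            out.append(name)
    return out


# ------------------------------------------------------------- enumeration
def enumerate_uncorrelated_models(
    advanced: list[str], report: CorrelationReport
) -> list[tuple[str, ...]]:
    """All models taking exactly one covariate per correlated group.

    Singleton covariates appear in every model; the result is
    deduplicated and deterministically ordered.
    """
    groups = []
    for g in report.groups:
        members = [c for c in g if c in advanced]
        if members:
            groups.append(members)
    for c in advanced:  # covariates unseen by the report count as singletons
        if not any(c in g for g in report.groups):
            groups.append([c])
    models = set()
    for combo in itertools.product(*groups):
        models.add(tuple(sorted(combo, key=advanced.index)))
    return sorted(models, key=lambda m: [advanced.index(c) for c in m])


# ----------------------------------------------------------- AIC comparison
@dataclass
class CandidateRanking:
    candidates: list[tuple[str, ...]]
    aics: list[np.ndarray]          # per candidate, AIC per bootstrap resample
    order: list[int]                # candidate indices sorted by median AIC

    @property
    def best(self) -> tuple[str, ...]:
        return self.candidates[self.order[0]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, (cand, a) in enumerate(zip(self.candidates, self.aics)):
            q = np.quantile(a, [0.1, 0.25, 0.5, 0.75, 0.9])
            rows.append({"model": "+".join(cand), "median_aic": q[2],
                         "q10": q[0], "q25": q[1], "q75": q[3], "q90": q[4]})
        return pd.DataFrame(rows)


def bootstrap_aic_compare(
    candidates: list[tuple[str, ...]],
    names: list[str],
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    config: FitConfig = FitConfig(),
    spec: FeatureSpec = FeatureSpec(),
) -> CandidateRanking:
    """Rank candidate covariate sets by median AIC over bootstrap resamples.

    Each resample draws n_used points with replacement; every candidate is
    fitted to the *same* resamples (common random numbers).  AIC is
    evaluated on the original used sample, keeping the likelihoods of all
    resample fits comparable and not rewarding within-resample overfit.
    """
    if not candidates:
        raise ValueError("need at least 1 candidate model")
    used_raw = np.atleast_2d(used_raw)
    n_u = used_raw.shape[0]
    rng = np.random.default_rng(config.seed)
    resamples = [rng.integers(0, n_u, size=n_u) for _ in range(config.replicates)]
    aics: list[np.ndarray] = []
    for cand in candidates:
        cols = [names.index(c) for c in cand]
        vals = []
        for idx in resamples:
            m = fit_maxent(used_raw[idx][:, cols], available_raw[:, cols],
                           list(cand), config, spec)
            vals.append(aic(m, used_raw[:, cols]))
        aics.append(np.array(vals))
    order = sorted(range(len(candidates)),
                   key=lambda i: (np.median(aics[i]), candidates[i]))
    return CandidateRanking(list(candidates), aics, order)


DEFAULT_RM_GRID = tuple(np.arange(1.0, 5.01, 0.5))  # 1.0 .. 5.0 by 0.5 (9 values)


@dataclass
class RMSweepResult:
    table: pd.DataFrame             # RM, mean_k, mean_lnl, mean_aic, delta_aic
    best_rm: float
    aics: dict[float, np.ndarray]


def rm_sweep(
    covariates: tuple[str, ...],
    names: list[str],
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    config: FitConfig = FitConfig(),
    spec: FeatureSpec = FeatureSpec(),
    rms: tuple[float, ...] = DEFAULT_RM_GRID,
) -> RMSweepResult:
    """Regularization-multiplier sweep on one covariate set.

    For each RM, bootstrap-refit and collect the replicate-average
    parameter count, log-likelihood and AIC; the winner has the lowest
    median AIC.  The mean-AIC column satisfies
    mean_aic = 2 * mean_k - 2 * mean_lnl exactly (linearity of the mean).
    """
    if not rms:
        raise ValueError("rms grid must be nonempty")
    used_raw = np.atleast_2d(used_raw)
    cols = [names.index(c) for c in covariates]
    u_all = used_raw[:, cols]
    a_all = available_raw[:, cols]
    n_u = u_all.shape[0]
    rng = np.random.default_rng(config.seed)
    resamples = [rng.integers(0, n_u, size=n_u) for _ in range(config.replicates)]
    rows = []
    aics: dict[float, np.ndarray] = {}
    for rm in rms:
        cfg = FitConfig(rm=rm, max_iterations=config.max_iterations,
                        tolerance=config.tolerance, replicates=config.replicates,
                        train_fraction=config.train_fraction, tau=config.tau,
                        seed=config.seed)
        ks, lnls, vals = [], [], []
        for idx in resamples:
            m = fit_maxent(u_all[idx], a_all, list(covariates), cfg, spec)
            k = n_parameters(m)
            lnl = float(np.log(m.predict_raw(u_all)).sum())
            ks.append(k)
            lnls.append(lnl)
            vals.append(2 * k - 2 * lnl)
        aics[rm] = np.array(vals)
        rows.append({"rm": rm, "mean_k": float(np.mean(ks)),
                     "mean_lnl": float(np.mean(lnls)),
                     "mean_aic": float(np.mean(vals)),
                     "median_aic": float(np.median(vals))})
    table = pd.DataFrame(rows)
    best_rm = float(table.loc[table["median_aic"].idxmin(), "rm"])
    table["delta_aic"] = table["mean_aic"] - table["mean_aic"].min()
    table = table.sort_values("median_aic").reset_index(drop=True)
    return RMSweepResult(table, best_rm, aics)
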