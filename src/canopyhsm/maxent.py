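"""Two-sample presence-background maximum-entropy habitat model.

The model compares covariates at "used" locations against the "available"
background.  With feature expansion f(x) (linear / quadratic / product /
hinge classes) and coefficients beta, the penalized objective maximized is
the presence-background log-likelihood per presence::

    (1/n_u) sum_used beta'f(x)  -  log sum_avail exp(beta'f(x))
        -  sum_j lambda_j |beta_j|

Per-feature L1 penalties follow the published default tables, scaled by a
global regularization multiplier (RM) and by each feature's spread over
the used sample.  Raw output is the normalized exponential model over the
background (sums to 1); the scaled logistic output (the HSI in [0, 1]) is
``r * exp(H) / (1 + r * exp(H))`` with H the entropy of the background
raw distribution, so the null model scores 0.5 everywhere.

Fitting is cyclic coordinate descent with soft-thresholding and a
monotone backtracking line search on the convex objective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# default per-class L1 base constants, interpolated by presence-sample size
_LQP_TABLE = ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05])
_HINGE_TABLE = ([0], [0.5])


def _base_penalty(feature_class: str, n_used: int) -> float:
    if feature_class == "hinge":
        return _HINGE_TABLE[1][0]
    ns, betas = _LQP_TABLE
    return float(np.interp(n_used, ns, betas))


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand, and the hinge knot count per direction."""

    classes: tuple[str, ...] = FEATURE_CLASSES
    hinge_knots: int = 50

    def __post_init__(self) -> None:
        for c in self.classes:
            if c not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {c!r}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise ValueError("hinge knot count must be >= 2")


@dataclass(frozen=True)
class FitConfig:
    rm: float = 2.0                  # regularization multiplier
    max_iterations: int = 5000       # coordinate-descent cycles cap
    tolerance: float = 1e-5          # relative objective change per cycle
    replicates: int = 10             # bootstrap replicates
    train_fraction: float = 0.8
    tau: float = 0.5                 # logistic scaling constant
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train fraction must be in (0, 1)")
        if self.rm <= 0:
            raise ValueError("RM must be > 0")


class FeatureExpansion:
    """Maps raw covariate rows to the expanded feature matrix.

    Covariates are clamped to the background (available) range and
    standardized with background mean/SD; linear features are the
    standardized values, quadratic their squares, products all distinct
    pairs.  Hinge features work on the raw scale
    with knots at equally spaced quantiles of the available distribution:
    forward max(0, x - k)/(max - k) and reverse max(0, k - x)/(k - min),
    both scaled to [0, 1].
    """

    def __init__(self, available: np.ndarray, names: list[str], spec: FeatureSpec):
        available = np.asarray(available, dtype=float)
        self.spec = spec
        self.mean_ = available.mean(axis=0)
        self.sd_ = available.std(axis=0)
        keep = self.sd_ > 0
        if not keep.all():
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"zero-variance covariates dropped: {dropped}")
        self.names = [n for n, k in zip(names, keep) if k]
        self.keep_ = keep
        self.mean_ = self.mean_[keep]
        self.sd_ = self.sd_[keep]
        av = available[:, keep]
        self.min_ = av.min(axis=0)
        self.max_ = av.max(axis=0)
        d = len(self.names)

        feature_names: list[str] = []
        parents: list[tuple[int, ...]] = []
        classes: list[str] = []
        if "linear" in spec.classes:
            for i in range(d):
                feature_names.append(f"lin({self.names[i]})")
                parents.append((i,))
                classes.append("linear")
        if "quadratic" in spec.classes:
            for i in range(d):
                feature_names.append(f"quad({self.names[i]})")
                parents.append((i,))
                classes.append("quadratic")
        if "product" in spec.classes:
            for i in range(d):
                for j in range(i + 1, d):
                    feature_names.append(f"prod({self.names[i]},{self.names[j]})")
                    parents.append((i, j))
                    classes.append("product")
        self.hinge_knots_: list[np.ndarray] = []
        if "hinge" in spec.classes:
            qs = np.linspace(0, 1, spec.hinge_knots + 2)[1:-1]
            for i in range(d):
                knots = np.unique(np.quantile(av[:, i], qs))
                knots = knots[(knots > self.min_[i]) & (knots < self.max_[i])]
                self.hinge_knots_.append(knots)
                for k in knots:
                    feature_names.append(f"hingef({self.names[i]},{k:.6g})")
                    parents.append((i,))
                    classes.append("hinge")
                for k in knots:
                    feature_names.append(f"hinger({self.names[i]},{k:.6g})")
                    parents.append((i,))
                    classes.append("hinge")
        self.feature_names = feature_names
        self.feature_parents = parents
        self.feature_classes = classes

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))[:, self.keep_]
        # clamp to the background range: points outside the available
        # support behave like the boundary, keeping the objective bounded
        raw = np.clip(raw, self.min_, self.max_)
        z = (raw - self.mean_) / self.sd_
        blocks: list[np.ndarray] = []
        d = len(self.names)
        if "linear" in self.spec.classes:
            blocks.append(z)
        if "quadratic" in self.spec.classes:
            blocks.append(z**2)
        if "product" in self.spec.classes:
            prods = [z[:, i] * z[:, j] for i in range(d) for j in range(i + 1, d)]
            if prods:
                blocks.append(np.column_stack(prods))
        if "hinge" in self.spec.classes:
            for i in range(d):
                knots = self.hinge_knots_[i]
                if knots.size == 0:
                    continue
                x = raw[:, i][:, None]
                fwd = np.clip(x - knots[None, :], 0, None) / (self.max_[i] - knots)
                rev = np.clip(knots[None, :] - x, 0, None) / (knots - self.min_[i])
                blocks.append(np.clip(fwd, 0, 1))
                blocks.append(np.clip(rev, 0, 1))
        return np.concatenate(blocks, axis=1) if blocks else np.empty((raw.shape[0], 0))

    def penalties(self, used_features: np.ndarray, rm: float) -> np.ndarray:
        """Per-feature lambda: RM x class base(n_used) x sd over used / sqrt(n_used).

        The used-sample SD is floored at 0.05 (features live on a
        standardized or [0, 1] scale) so that features inactive on the
        used sample keep a small positive penalty, keeping the problem
        bounded.
        """
        n_used = used_features.shape[0]
        sd_used = used_features.std(axis=0)
        lam = np.empty(self.n_features)
        for j, cls in enumerate(self.feature_classes):
            lam[j] = rm * _base_penalty(cls, n_used) / np.sqrt(n_used)
        floor = 0.05
        sd = np.maximum(sd_used, floor)
        return lam * sd


@dataclass
class MaxentModel:
    expansion: FeatureExpansion
    beta: np.ndarray
    log_z: float
    entropy: float
    rm: float
    tau: float = 0.5
    n_available: int = 0
    iterations: int = 0
    objective: float = 0.0
    penalties: np.ndarray | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)
    objective_path: list[float] = field(default_factory=list)

    @property
    def covariate_names(self) -> list[str]:
        return self.expansion.names

    def linear_predictor(self, raw: np.ndarray) -> np.ndarray:
        return self.expansion.transform(raw) @ self.beta

    def predict_raw(self, raw: np.ndarray) -> np.ndarray:
        """exp(beta'f(x) - logZ); sums to 1 over the fitting background."""
        return np.exp(self.linear_predictor(raw) - self.log_z)

    def predict_logistic(self, raw: np.ndarray) -> np.ndarray:
        """Scaled logistic output (HSI in [0, 1]), increasing in raw output."""
        r = self.predict_raw(raw)
        scale = np.exp(self.entropy) * self.tau / (1.0 - self.tau)
        return scale * r / (1.0 + scale * r)

    def to_json(self, path: str | Path) -> None:
        exp = self.expansion
        payload = {
            "covariates": exp.names,
            "classes": list(exp.spec.classes),
            "hinge_knots": [k.tolist() for k in exp.hinge_knots_],
            "standardization": {"mean": exp.mean_.tolist(), "sd": exp.sd_.tolist(),
                                "min": exp.min_.tolist(), "max": exp.max_.tolist()},
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "rm": self.rm,
            "tau": self.tau,
            "n_available": self.n_available,
            "iterations": self.iterations,
            "objective": self.objective,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def penalized_objective(
    beta: np.ndarray, f_used: np.ndarray, f_avail: np.ndarray, lam: np.ndarray
) -> float:
    """The fitted objective at beta; shared by solver and oracles."""
    eta_u = f_used @ beta
    eta_a = f_avail @ beta
    return float(eta_u.mean() - logsumexp(eta_a) - np.abs(beta) @ lam)


def fit_maxent(
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    names: list[str],
    config: FitConfig = FitConfig(),
    spec: FeatureSpec = FeatureSpec(),
    expansion: FeatureExpansion | None = None,
) -> MaxentModel:
    """Fit the presence-background model by cyclic coordinate descent.

    Each coordinate takes a soft-thresholded Newton step, backtracking by
    halves until the penalized objective does not decrease, so the
    objective path is monotone non-decreasing.  Converged when a full
    cycle improves the objective by less than ``tolerance`` relative.
    """
    used_raw = np.atleast_2d(np.asarray(used_raw, dtype=float))
    available_raw = np.atleast_2d(np.asarray(available_raw, dtype=float))
    if used_raw.shape[0] < 2:
        raise ValueError("need at least 2 used points")
    if available_raw.shape[0] < used_raw.shape[0]:
        raise ValueError("available sample must be at least as large as used")
    if expansion is None:
        expansion = FeatureExpansion(available_raw, names, spec)
    f_u = expansion.transform(used_raw)
    f_a = expansion.transform(available_raw)
    lam = expansion.penalties(f_u, config.rm)
    p = f_u.shape[1]
    n_a = f_a.shape[0]

    beta = np.zeros(p)
    eta_a = np.zeros(n_a)
    mean_fu = f_u.mean(axis=0)
    mean_eta_u = 0.0
    pen = 0.0
    obj = penalized_objective(beta, f_u, f_a, lam)
    path = [obj]
    trace: list[tuple[int, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        cycle_start = obj
        shift = eta_a.max()
        w = np.exp(eta_a - shift)
        w_sum = w.sum()
        for j in range(p):
            fj = f_a[:, j]
            wf = w @ fj
            e_fj = wf / w_sum
            g = mean_fu[j] - e_fj
            var = (w @ (fj * fj)) / w_sum - e_fj * e_fj
            h = max(var, 1e-8)
            z = beta[j] + g / h
            new = _soft_threshold(z, lam[j] / h)
            delta = new - beta[j]
            if delta == 0.0:
                continue
            # line search: the coordinate restriction is concave, so scan
            # the halving sequence and take its peak (approximate 1-D max)
            best_obj, best_delta = obj, 0.0
            step = delta
            for _ in range(40):
                cand = beta[j] + step
                pen_try = pen - lam[j] * abs(beta[j]) + lam[j] * abs(cand)
                obj_try = float(
                    mean_eta_u + step * mean_fu[j]
                    - logsumexp(eta_a + step * fj) - pen_try)
                if obj_try > best_obj:
                    best_obj, best_delta = obj_try, step
                elif best_delta != 0.0:
                    break  # past the peak
                step *= 0.5
            if best_delta == 0.0:
                continue
            trace.append((j, best_obj - obj))
            mean_eta_u += best_delta * mean_fu[j]
            cand = beta[j] + best_delta
            pen = pen - lam[j] * abs(beta[j]) + lam[j] * abs(cand)
            beta[j] = cand
            eta_a = eta_a + best_delta * fj
            obj = best_obj
            shift = eta_a.max()
            w = np.exp(eta_a - shift)
            w_sum = w.sum()
        path.append(obj)
        if abs(obj - cycle_start) <= config.tolerance * (abs(cycle_start) + 1e-9):
            converged = True
            break
    if not converged and it == config.max_iterations:
        raise RuntimeError(
            f"maxent fit did not converge in {config.max_iterations} cycles; "
            f"final objective {obj:.6g}, last change "
            f"{abs(path[-1] - path[-2]):.3g}")

    log_z = float(logsumexp(eta_a))
    raw = np.exp(eta_a - log_z)
    entropy = float(-(raw * np.log(np.clip(raw, 1e-300, None))).sum())
    return MaxentModel(
        expansion=expansion, beta=beta, log_z=log_z, entropy=entropy,
        rm=config.rm, tau=config.tau, n_available=n_a, iterations=it,
        objective=obj, penalties=lam, trace=trace, objective_path=path,
    )


def gain(model: MaxentModel, used_raw: np.ndarray) -> float:
    """Regularized training gain (nats): 0 for the null model.

    mean over used of log raw output, plus log n_available (so the
    uniform model scores 0), minus the L1 penalty term.
    """
    mean_log_raw = float(np.log(model.predict_raw(used_raw)).mean())
    penalty = float(np.abs(model.beta) @ model.penalties)
    return mean_log_raw + np.log(model.n_available) - penalty


def unregularized_gain(model: MaxentModel, used_raw: np.ndarray) -> float:
    """Gain without the penalty term; used for held-out (test) gain."""
    return float(np.log(model.predict_raw(used_raw)).mean()) + np.log(model.n_available)


def aic_from_parts(k: float, log_likelihood: float) -> float:
    """AIC = 2k - 2 lnL; k may be a replicate average (fractional)."""
    return 2.0 * k - 2.0 * log_likelihood


def aic(model: MaxentModel, used_raw: np.ndarray) -> float:
    """AIC with k = nonzero coefficients, lnL = sum of used log raw output."""
    k = int(np.count_nonzero(model.beta))
    lnl = float(np.log(model.predict_raw(used_raw)).sum())
    return aic_from_parts(k, lnl)


def n_parameters(model: MaxentModel) -> int:
    return int(np.count_nonzero(model.beta))


@dataclass
class BootstrapResult:
    models: list[MaxentModel]
    test_auc: np.ndarray
    test_gain: np.ndarray
    train_gain: np.ndarray
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]

    @property
    def median_test_auc(self) -> float:
        return float(np.median(self.test_auc))

    @property
    def median_test_gain(self) -> float:
        return float(np.median(self.test_gain))


def bootstrap_fit(
    used_raw: np.ndarray,
    available_raw: np.ndarray,
    names: list[str],
    config: FitConfig = FitConfig(),
    spec: FeatureSpec = FeatureSpec(),
) -> BootstrapResult:
    """Bootstrap replicate fits: train on an 80% resample of used points.

    Each replicate draws round(train_fraction * n_used) used points *with
    replacement*; the held-out set is the points never drawn.  Test gain
    and AUC are computed on the held-out points against the full
    available sample.
    """
    from .evaluation import auc as auc_stat

    if config.replicates < 1:
        raise ValueError("need at least 1 replicate")
    used_raw = np.atleast_2d(np.asarray(used_raw, dtype=float))
    n_u = used_raw.shape[0]
    if n_u < 5:
        raise ValueError("too few used points to split")
    rng = np.random.default_rng(config.seed)
    models, t_auc, t_gain, tr_gain = [], [], [], []
    train_idx_all, test_idx_all = [], []
    expansion = FeatureExpansion(available_raw, names, spec)
    for _ in range(config.replicates):
        m = int(round(config.train_fraction * n_u))
        draw = rng.integers(0, n_u, size=m)
        held = np.setdiff1d(np.arange(n_u), draw)
        if held.size == 0:  # pathological tiny-n case
            held = np.array([int(rng.integers(0, n_u))])
        model = fit_maxent(used_raw[draw], available_raw, names, config, spec,
                           expansion=expansion)
        models.append(model)
        train_idx_all.append(draw)
        test_idx_all.append(held)
        tr_gain.append(gain(model, used_raw[draw]))
        t_gain.append(unregularized_gain(model, used_raw[held]))
        t_auc.append(auc_stat(model.predict_raw(used_raw[held]),
                              model.predict_raw(available_raw)))
    return BootstrapResult(models, np.array(t_auc), np.array(t_gain),
                           np.array(tr_gain), train_idx_all, test_idx_all)
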