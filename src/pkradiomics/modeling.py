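"""Feature reduction and bootstrap logistic model building.

The scheme operates on a lesions-by-features table with a binary outcome
per classification task:

1. *Reduction*: stepwise forward selection of 25 features maximizing a gain
   that rewards outcome association (|Spearman|, averaged over
   imbalance-adjusted bootstrap samples) and penalizes redundancy (mean MIC
   against the already-selected features):
       gain = delta * |rho| - (1 - delta) * mean MIC,  delta = 0.5.
2. *Model building*: for orders 1..10, stepwise forward selection inside
   the reduced set maximizing the 0.632+ bootstrap AUC of a logistic
   regression; the final order maximizes the AUC curve.
3. *Final fit*: coefficients averaged over imbalance-adjusted bootstrap
   in-bag fits, with AUC/sensitivity/specificity/accuracy +/- bootstrap SE.

Imbalance-adjusted bootstrap resampling (IABR) draws each of the n indices
by first picking a class with probability 1/2, then a member uniformly
within the class, so resamples are balanced in expectation regardless of
the native class ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mic import mic

__all__ = ["spearman_corr", "gain", "reduce_features", "iabr_sample", "auc",
           "bootstrap_632plus_auc", "build_models", "select_final_model",
           "mann_whitney_u", "bonferroni_flags",
           "ReducedSet", "LogisticModel", "PerformanceEstimate"]


# ---------------------------------------------------------------- statistics

def spearman_corr(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties); 0 at zero rank
    variance by convention."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1D inputs with n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative;
    ties count 1/2 (the normalized Mann-Whitney U statistic)."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    r = sps.rankdata(s)
    u1 = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


def mann_whitney_u(group0, group1) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when n0*n1 <= 64 and there are no ties, else the
    normal approximation with tie and continuity corrections.  Returns
    {"U": U of group0, "p": two-sided p}.
    """
    g0 = np.asarray(group0, dtype=np.float64)
    g1 = np.asarray(group1, dtype=np.float64)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([g0, g1])).size < g0.size + g1.size
    method = "exact" if (g0.size * g1.size <= 64 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(g0, g1, alternative="two-sided", method=method,
                           use_continuity=True)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def bonferroni_flags(pvals, alpha: float = 0.05) -> np.ndarray:
    """flag_i = (p_i < alpha / m), m the number of comparisons."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    return p < alpha / p.size


def iabr_sample(labels, rng) -> np.ndarray:
    """One imbalance-adjusted bootstrap resample of indices 0..n-1.

    Each of n draws picks class 0 or 1 with probability 1/2, then a member
    uniformly within that class; expected class balance is 1:1.
    """
    y = np.asarray(labels)
    idx0 = np.nonzero(y == 0)[0]
    idx1 = np.nonzero(y == 1)[0]
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be present")
    n = y.size
    pick1 = rng.random(n) < 0.5
    out = np.where(pick1,
                   idx1[rng.integers(0, idx1.size, n)],
                   idx0[rng.integers(0, idx0.size, n)])
    return out


# ---------------------------------------------------------- logistic fitting

def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                  max_iter: int = 50, tol: float = 1e-8):
    """Newton-Raphson maximum-likelihood logistic regression.

    Returns (beta, intercept, converged).  ``ridge`` adds an L2 penalty on
    the slope coefficients (used as a 1e-6 fallback under separation).
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Z.T @ (y - mu)
        H = (Z * w[:, None]).T @ Z
        if ridge > 0:
            pen = np.full(p + 1, ridge)
            pen[0] = 0.0
            grad = grad - pen * beta
            H = H + np.diag(pen)
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError:
            return beta[1:], beta[0], False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta[1:], beta[0], True
    return beta[1:], beta[0], False


def _fit_logistic_safe(X: np.ndarray, y: np.ndarray):
    """Unpenalized fit with a tiny-ridge (1e-6) fallback on separation or
    non-convergence."""
    beta, b0, ok = _fit_logistic(X, y)
    if not ok or np.max(np.abs(beta), initial=0.0) > 30.0:
        beta, b0, _ = _fit_logistic(X, y, ridge=1e-6, max_iter=200)
        return beta, b0, True
    return beta, b0, False


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


# ------------------------------------------------------------- domain types

@dataclass(frozen=True)
class ReducedSet:
    """Ordered reduced feature set for one outcome."""

    outcome: str
    features: tuple[str, ...]
    gains: tuple[float, ...]

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("reduced features must be unique")

    def to_json(self) -> str:
        return json.dumps({"outcome": self.outcome,
                           "features": list(self.features),
                           "gains": list(self.gains)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReducedSet":
        d = json.loads(text)
        return cls(d["outcome"], tuple(d["features"]), tuple(d["gains"]))


@dataclass(frozen=True)
class PerformanceEstimate:
    """Bootstrap performance: point estimates with standard errors."""

    auc: float
    auc_se: float
    sensitivity: float
    sensitivity_se: float
    specificity: float
    specificity_se: float
    accuracy: float
    accuracy_se: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class LogisticModel:
    """A fitted multivariable logistic model g(x) = sum beta_i x_i + b0.

    ``transform`` holds per-feature (mean, sd) applied before the linear
    predictor when the model was trained on standardized features; models
    built from externally printed coefficients use transform=None and apply
    the coefficients to raw feature values.
    """

    outcome: str
    features: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    transform: tuple[tuple[float, float], ...] | None = None
    used_ridge: bool = False

    def __post_init__(self):
        if len(self.features) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")

    @property
    def order(self) -> int:
        return len(self.features)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.features)].to_numpy(dtype=np.float64)
        if self.transform is not None:
            t = np.asarray(self.transform)
            X = (X - t[:, 0]) / t[:, 1]
        return X @ np.asarray(self.coefficients) + self.intercept

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        g = np.clip(self.linear_predictor(table), -500, 500)
        return 1.0 / (1.0 + np.exp(-g))

    def to_json(self) -> str:
        return json.dumps({
            "outcome": self.outcome, "order": self.order,
            "features": list(self.features),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "transform": None if self.transform is None
            else [list(t) for t in self.transform],
            "used_ridge": self.used_ridge}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        tr = d.get("transform")
        return cls(d["outcome"], tuple(d["features"]),
                   tuple(d["coefficients"]), d["intercept"],
                   None if tr is None else tuple(tuple(t) for t in tr),
                   d.get("used_ridge", False))


# -------------------------------------------------------- feature reduction

def gain(candidate, outcome, selected, delta: float = 0.5,
         mic_kwargs: dict | None = None) -> float:
    """Gain of adding one candidate feature.

    gain = delta * |spearman(candidate, outcome)|
           - (1 - delta) * mean_i MIC(candidate, selected_i),
    reducing to |spearman| for an empty selected set.
    """
    rho = abs(spearman_corr(candidate, outcome))
    if not selected:
        return rho
    kw = mic_kwargs or {}
    redundancy = float(np.mean([mic(candidate, s, **kw) for s in selected]))
    return delta * rho - (1.0 - delta) * redundancy


def _iabr_spearman(X: np.ndarray, y: np.ndarray, n_boot: int,
                   rng) -> np.ndarray:
    """|Spearman| of every feature with the outcome, averaged over IABR
    resamples (vectorized across features)."""
    n, p = X.shape
    acc = np.zeros(p)
    for _ in range(n_boot):
        idx = iabr_sample(y, rng)
        Xb = X[idx]
        yb = y[idx]
        ry = sps.rankdata(yb)
        ry_c = ry - ry.mean()
        denom_y = np.sqrt((ry_c ** 2).sum())
        rX = np.apply_along_axis(sps.rankdata, 0, Xb)
        rX_c = rX - rX.mean(axis=0)
        denom_x = np.sqrt((rX_c ** 2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (rX_c * ry_c[:, None]).sum(axis=0) / (denom_x * denom_y)
        acc += np.abs(np.nan_to_num(rho))
    return acc / n_boot


def reduce_features(table: pd.DataFrame, outcome, k: int = 25,
                    n_boot: int = 1000, seed: int = 0, delta: float = 0.5,
                    use_iabr_spearman: bool = True,
                    mic_kwargs: dict | None = None) -> ReducedSet:
    """Stepwise forward reduction of the feature table to k features.

    ``table`` holds one row per lesion and only feature columns; ``outcome``
    is the binary label vector.  The first feature maximizes |Spearman| with
    the outcome (averaged over n_boot IABR resamples when
    ``use_iabr_spearman``); subsequent features maximize the gain equation.
    Ties break toward the earlier column.  Deterministic under ``seed``.
    """
    y = np.asarray(outcome)
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    names = list(table.columns)
    X = table.to_numpy(dtype=np.float64)
    if X.shape[0] != y.size:
        raise ValueError("table rows must match outcome length")
    k = min(k, len(names))
    rng = np.random.default_rng(seed)

    if use_iabr_spearman:
        rho = _iabr_spearman(X, y, n_boot, rng)
    else:
        rho = np.abs([spearman_corr(X[:, j], y) for j in range(X.shape[1])])

    kw = mic_kwargs or {}
    selected: list[int] = []
    gains: list[float] = []
    mic_cache: dict[tuple[int, int], float] = {}

    def pair_mic(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mic_cache:
            mic_cache[key] = mic(X[:, a], X[:, b], **kw)
        return mic_cache[key]

    remaining = list(range(len(names)))
    while len(selected) < k:
        best_j, best_g = None, -np.inf
        for j in remaining:
            if not selected:
                g = rho[j]
            else:
                red = np.mean([pair_mic(j, s) for s in selected])
                g = delta * rho[j] - (1.0 - delta) * red
            if g > best_g + 1e-15:
                best_j, best_g = j, g
        selected.append(best_j)
        remaining.remove(best_j)
        gains.append(float(best_g))
    return ReducedSet(outcome=str(getattr(outcome, "name", "outcome")),
                      features=tuple(names[j] for j in selected),
                      gains=tuple(gains))


# ------------------------------------------------- 0.632+ bootstrap modeling

def _scores_metrics(prob: np.ndarray, y: np.ndarray):
    pred = prob >= 0.5
    pos = y == 1
    neg = ~pos
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    acc = float((pred == pos).mean())
    return sens, spec, acc


def _fit_and_score(Xtr, ytr, Xte):
    Xs, mu, sd = _standardize(Xtr)
    beta, b0, _ = _fit_logistic_safe(Xs, ytr)
    eta = np.clip(((Xte - mu) / sd) @ beta + b0, -500, 500)
    return 1.0 / (1.0 + np.exp(-eta))


def bootstrap_632plus_auc(feature_subset, table: pd.DataFrame, outcome,
                          n_boot: int = 1000, seed: int = 0,
                          max_redraws: int = 50) -> PerformanceEstimate:
    """0.632+ bootstrap performance of a logistic model on a feature subset.

    Per IABR resample the model is fitted in-bag and scored on the
    out-of-bag lesions.  The AUC estimate combines the apparent AUC (fit
    and scored on the full table) with the mean out-of-bag AUC through the
    0.632+ rule with no-information AUC 0.5 and relative overfitting rate
    R = (apparent - oob) / (apparent - 0.5) clamped to [0, 1]:

        w = 0.632 / (1 - 0.368 R),  estimate = (1 - w) apparent + w oob.

    Sensitivity/specificity/accuracy are evaluated at probability 0.5 and
    combined by the same rule.  SEs are standard deviations of the
    per-resample out-of-bag values.  Resamples whose out-of-bag set is
    single-class are redrawn (bounded), then skipped.
    """
    feats = list(feature_subset)
    if not feats:
        raise ValueError("feature subset must be non-empty")
    y = np.asarray(outcome)
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    X = table[feats].to_numpy(dtype=np.float64)
    n = y.size
    rng = np.random.default_rng(seed)

    prob_app = _fit_and_score(X, y, X)
    app_auc = auc(prob_app, y)
    app_sens, app_spec, app_acc = _scores_metrics(prob_app, y)

    oob_vals = {"auc": [], "sens": [], "spec": [], "acc": []}
    for _ in range(n_boot):
        idx = None
        for _try in range(max_redraws):
            cand = iabr_sample(y, rng)
            oob = np.setdiff1d(np.arange(n), cand)
            if oob.size and np.unique(y[oob]).size == 2:
                idx = cand
                break
        if idx is None:
            continue
        prob = _fit_and_score(X[idx], y[idx], X[oob])
        oob_vals["auc"].append(auc(prob, y[oob]))
        s, p, a = _scores_metrics(prob, y[oob])
        oob_vals["sens"].append(s)
        oob_vals["spec"].append(p)
        oob_vals["acc"].append(a)
    if not oob_vals["auc"]:
        raise ValueError("no usable bootstrap resample")

    def combine(app: float, oob_mean: float, gamma: float) -> float:
        oob_c = max(oob_mean, gamma) if app > gamma else oob_mean
        denom = app - gamma
        r = 0.0 if denom <= 0 else (app - oob_c) / denom
        r = float(np.clip(r, 0.0, 1.0))
        w = 0.632 / (1.0 - 0.368 * r)
        return (1.0 - w) * app + w * oob_c

    oob_auc = float(np.mean(oob_vals["auc"]))
    est_auc = combine(app_auc, oob_auc, 0.5)
    sens = combine(app_sens, float(np.nanmean(oob_vals["sens"])), 0.5)
    spec = combine(app_spec, float(np.nanmean(oob_vals["spec"])), 0.5)
    acc = combine(app_acc, float(np.nanmean(oob_vals["acc"])), 0.5)
    return PerformanceEstimate(
        auc=est_auc, auc_se=float(np.std(oob_vals["auc"])),
        sensitivity=sens, sensitivity_se=float(np.nanstd(oob_vals["sens"])),
        specificity=spec, specificity_se=float(np.nanstd(oob_vals["spec"])),
        accuracy=acc, accuracy_se=float(np.std(oob_vals["acc"])))


def build_models(reduced: ReducedSet, table: pd.DataFrame, outcome,
                 max_order: int = 10, n_boot: int = 1000, seed: int = 0):
    """Stepwise forward 0.632+ model building over the reduced set.

    Order 1 is the single best feature by 0.632+ AUC; order i adds the
    feature maximizing the order-i model's 0.632+ AUC.  Returns
    (per-order feature lists, AUC-vs-order curve) with ties broken by
    earlier reduced-set rank.  The curve is the model-order analogue of the
    order-performance plot.
    """
    if not reduced.features:
        raise ValueError("reduced set is empty")
    max_order = min(max_order, len(reduced.features))
    chosen: list[str] = []
    per_order: list[tuple[str, ...]] = []
    curve: list[float] = []
    ss = np.random.SeedSequence(seed)
    for order in range(1, max_order + 1):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        best_feat, best_auc = None, -np.inf
        for feat in reduced.features:                 # reduced-set rank order
            if feat in chosen:
                continue
            perf = bootstrap_632plus_auc(chosen + [feat], table, outcome,
                                         n_boot=n_boot, seed=sub_seed)
            if perf.auc > best_auc + 1e-12:
                best_feat, best_auc = feat, perf.auc
        chosen.append(best_feat)
        per_order.append(tuple(chosen))
        curve.append(float(best_auc))
    return per_order, np.asarray(curve)


def select_final_model(per_order, curve, table: pd.DataFrame, outcome,
                       n_boot: int = 1000, seed: int = 0,
                       outcome_name: str = "outcome"):
    """Pick the AUC-maximizing order (ties -> smaller) and fit the final
    model: coefficients averaged over IABR in-bag fits on standardized
    features, performance re-estimated by the 0.632+ bootstrap."""
    curve = np.asarray(curve, dtype=np.float64)
    if curve.size == 0:
        raise ValueError("empty AUC curve")
    order_idx = int(np.argmax(curve))             # first max -> smaller order
    feats = list(per_order[order_idx])
    y = np.asarray(outcome)
    X = table[feats].to_numpy(dtype=np.float64)
    Xs, mu, sd = _standardize(X)

    rng = np.random.default_rng(seed)
    betas, b0s = [], []
    used_ridge = False
    for _ in range(n_boot):
        for _try in range(50):
            idx = iabr_sample(y, rng)
            if np.unique(y[idx]).size == 2:
                break
        beta, b0, ridged = _fit_logistic_safe(Xs[idx], y[idx])
        used_ridge = used_ridge or ridged
        betas.append(beta)
        b0s.append(b0)
    beta = np.mean(betas, axis=0)
    b0 = float(np.mean(b0s))
    model = LogisticModel(outcome=outcome_name, features=tuple(feats),
                          coefficients=tuple(float(b) for b in beta),
                          intercept=b0,
                          transform=tuple((float(m), float(s))
                                          for m, s in zip(mu, sd)),
                          used_ridge=used_ridge)
    perf = bootstrap_632plus_auc(feats, table, outcome, n_boot=n_boot,
                                 seed=seed)
    return model, perf
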