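"""Elastic-net reference models.

Survival: penalized Cox (scikit-survival Coxnet) on top of univariate-filter
feature selection or principal components.  Drugs: per-drug elastic-net
regression (scikit-learn).  Hyper-parameters (penalty, L1 ratio, and k or
component count) are chosen by grid search in nested cross-validation; all
reducers are fitted inside training folds only.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .data import SurvivalRecordSet, stratified_survival_folds
from .evaluation import harrell_cindex

__all__ = ["BaselineSpec", "FittedBaseline", "univariate_topk", "fit_baseline"]

DEFAULT_PENALTIES = tuple(np.logspace(-3, -1, 5))
DEFAULT_L1_RATIOS = (0.1, 0.3, 0.5, 0.77, 0.99)
DEFAULT_KS = (100, 250, 500, 1000)
DEFAULT_PCS = (10, 100)


@dataclasses.dataclass(frozen=True)
class BaselineSpec:
    task: str  # "survival" | "drug"
    reducer: str = "univariate"  # "univariate" | "pca"
    k_grid: tuple = DEFAULT_KS
    n_components_grid: tuple = DEFAULT_PCS
    penalty_grid: tuple = DEFAULT_PENALTIES
    l1_ratio_grid: tuple = DEFAULT_L1_RATIOS
    inner_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("survival", "drug"):
            raise ValueError("task must be 'survival' or 'drug'")
        if self.reducer not in ("univariate", "pca"):
            raise ValueError("reducer must be 'univariate' or 'pca'")
        if not self.penalty_grid or not self.l1_ratio_grid:
            raise ValueError("hyper-parameter grids must be non-empty")
        if self.reducer == "univariate" and any(
            not (100 <= k <= 1000) for k in self.k_grid
        ):
            raise ValueError("top-k values must lie in [100, 1000]")


def _cox_score_statistics(X, time, event):
    """Per-feature Cox score-test statistic at beta = 0 (vectorized).

    Ranks features by U^2 / V where U is the score and V the information,
    both accumulated over events with Breslow-style risk sets.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")  # decreasing: cumsum = risk sets
    Xs = X[order]
    cs1 = np.cumsum(Xs, axis=0)
    cs2 = np.cumsum(Xs**2, axis=0)
    counts = np.arange(1, len(time) + 1)[:, None]
    mean = cs1 / counts
    var = cs2 / counts - mean**2
    ev_sorted = event[order] == 1
    U = (Xs[ev_sorted] - mean[ev_sorted]).sum(axis=0)
    V = var[ev_sorted].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(V > 0, U**2 / V, 0.0)
    return stat


def univariate_topk(features, target, k: int):
    """Indices of the k features with the strongest univariate association.

    ``target`` is either a 1-D continuous vector (per-feature linear
    regression, ranked by |t| which is monotone in |r|) or a (time, event)
    pair / SurvivalRecordSet (per-feature Cox score test).
    """
    X = np.asarray(features, dtype=float)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the number of features ({X.shape[1]})")
    if isinstance(target, SurvivalRecordSet):
        stat = _cox_score_statistics(X, target.time, target.event)
    elif isinstance(target, tuple) and len(target) == 2:
        stat = _cox_score_statistics(X, target[0], target[1])
    else:
        y = np.asarray(target, dtype=float)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, Xc.T @ yc / denom, 0.0)
        stat = np.abs(r)
    ranked = np.argsort(-stat, kind="stable")
    return np.sort(ranked[:k])


@dataclasses.dataclass
class FittedBaseline:
    spec: BaselineSpec
    reducer_state: dict
    model: object  # Coxnet for survival, list of per-drug models for drugs
    chosen: dict

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.reducer_state["kind"] == "identity":
            return X  # drug task: each per-drug model owns its reducer
        return _apply_reducer(self.reducer_state, X)

    def predict_risk(self, X):
        return np.asarray(self.model.predict(self.transform(X))).ravel()

    def predict_drugs(self, X):
        Z = self.transform(X)
        out = np.full((Z.shape[0], len(self.model)), np.nan)
        for j, mdl in enumerate(self.model):
            if mdl is not None:
                out[:, j] = mdl.predict(Z)
        return out


def _fit_reducer(spec, X, target, size_param):
    from sklearn.decomposition import PCA

    if spec.reducer == "univariate":
        idx = univariate_topk(X, target, size_param)
        return {"kind": "univariate", "indices": idx}
    n_comp = min(size_param, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, random_state=spec.seed).fit(X)
    return {"kind": "pca", "pca": pca}


def _apply_reducer(state, X):
    if state["kind"] == "univariate":
        return np.asarray(X)[:, state["indices"]]
    return state["pca"].transform(np.asarray(X))


def _fit_cox_en(Z, time, event, penalty, l1_ratio):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(
        alphas=[penalty], l1_ratio=l1_ratio, fit_baseline_model=False
    )
    model.fit(Z, y)
    return model


def fit_baseline(spec: BaselineSpec, X, target, folds=None) -> FittedBaseline:
    """Grid-search (penalty x l1_ratio x reducer size) in inner CV, then refit.

    ``target`` is a SurvivalRecordSet for the survival task or a
    (values, observed_mask) pair for the drug task (drug models are fitted
    independently per drug).
    """
    X = np.asarray(X, dtype=float)
    size_grid = spec.k_grid if spec.reducer == "univariate" else spec.n_components_grid
    size_grid = tuple(s for s in size_grid if s <= X.shape[1]) or (min(X.shape[1], 10),)
    grid = list(itertools.product(size_grid, spec.penalty_grid, spec.l1_ratio_grid))

    if spec.task == "survival":
        return _fit_baseline_survival(spec, X, target, grid)
    return _fit_baseline_drug(spec, X, target, grid)


def _fit_baseline_survival(spec, X, surv: SurvivalRecordSet, grid):
    inner = stratified_survival_folds(
        surv, k_folds=spec.inner_folds, n_quantiles=min(10, max(2, surv.n // 10)),
        seed=spec.seed,
    )
    best, best_score = None, -np.inf
    if len(grid) > 1:
        for size, pen, l1 in grid:
            scores = []
            for f in range(1, spec.inner_folds + 1):
                tr, te = inner.split(f)
                if surv.event[te].sum() == 0 or surv.event[tr].sum() == 0:
                    continue
                red = _fit_reducer(spec, X[tr], surv.subset(tr), size)
                try:
                    model = _fit_cox_en(
                        _apply_reducer(red, X[tr]), surv.time[tr], surv.event[tr], pen, l1
                    )
                    pred = np.asarray(model.predict(_apply_reducer(red, X[te]))).ravel()
                    scores.append(harrell_cindex(pred, surv.time[te], surv.event[te]))
                except (ArithmeticError, ValueError):
                    continue
            if scores and np.mean(scores) > best_score:
                best_score, best = float(np.mean(scores)), (size, pen, l1)
    if best is None:
        best = grid[0]
    size, pen, l1 = best
    red = _fit_reducer(spec, X, surv, size)
    model = _fit_cox_en(_apply_reducer(red, X), surv.time, surv.event, pen, l1)
    return FittedBaseline(
        spec, red, model, {"size": size, "penalty": pen, "l1_ratio": l1, "inner_score": best_score}
    )


def _fit_baseline_drug(spec, X, target, grid):
    from sklearn.linear_model import ElasticNet
    from sklearn.model_selection import KFold

    values, mask = target
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    m = values.shape[1]
    models, chosen = [], []
    for j in range(m):
        obs = np.where(mask[:, j])[0]
        if obs.size < max(spec.inner_folds, 3):
            models.append(None)
            chosen.append(None)
            continue
        Xo, yo = X[obs], values[obs, j]
        best, best_score = None, -np.inf
        if len(grid) > 1:
            cv = KFold(n_splits=spec.inner_folds, shuffle=True, random_state=spec.seed)
            for size, pen, l1 in grid:
                scores = []
                for tr, te in cv.split(Xo):
                    red = _fit_reducer(spec, Xo[tr], yo[tr], size)
                    mdl = ElasticNet(alpha=pen, l1_ratio=l1, max_iter=5000)
                    mdl.fit(_apply_reducer(red, Xo[tr]), yo[tr])
                    pred = mdl.predict(_apply_reducer(red, Xo[te]))
                    ss_tot = ((yo[te] - yo[te].mean()) ** 2).sum()
                    if ss_tot == 0:
                        continue
                    scores.append(1.0 - ((yo[te] - pred) ** 2).sum() / ss_tot)
                if scores and np.mean(scores) > best_score:
                    best_score, best = float(np.mean(scores)), (size, pen, l1)
        if best is None:
            best = grid[0]
        size, pen, l1 = best
        red = _fit_reducer(spec, Xo, yo, size)
        mdl = ElasticNet(alpha=pen, l1_ratio=l1, max_iter=5000)
        mdl.fit(_apply_reducer(red, Xo), yo)
        models.append(_DrugModel(red, mdl))
        chosen.append({"size": size, "penalty": pen, "l1_ratio": l1})
    return FittedBaseline(spec, {"kind": "identity"}, models, {"per_drug": chosen})


class _DrugModel:
    """Reducer + elastic net fitted for a single drug."""

    def __init__(self, reducer_state, model):
        self.reducer_state = reducer_state
        self.model = model

    def predict(self, X):
        return self.model.predict(_apply_reducer(self.reducer_state, X))
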