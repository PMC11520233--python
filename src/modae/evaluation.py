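"""Evaluation metrics and downstream procedures.

Harrell's C-index, per-drug R² with 90th-percentile summary, linear-SVM
domain AUROC of the shared embeddings, Pareto fronts over metric tuples,
risk-tertile stratification transferred from a discovery cohort, and the
drug-target dysregulation screen.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EvaluationReport",
    "RiskStratification",
    "harrell_cindex",
    "per_drug_r2",
    "r2_quantile90",
    "domain_auroc",
    "pareto_front",
    "stratify_risk",
    "dysregulation_test",
]


@dataclasses.dataclass
class EvaluationReport:
    cindex: float
    per_drug_r2: np.ndarray
    r2_q90: float
    domain_auroc: float

    @property
    def composite(self) -> float:
        return self.cindex + self.r2_q90 - self.domain_auroc

    def to_dict(self) -> dict:
        return {
            "cindex": self.cindex,
            "per_drug_r2": [None if np.isnan(v) else float(v) for v in np.atleast_1d(self.per_drug_r2)],
            "r2_q90": self.r2_q90,
            "domain_auroc": self.domain_auroc,
            "composite": self.composite,
        }


def harrell_cindex(risk, time, event) -> float:
    """Concordant / comparable pairs; risk ties count 0.5.

    A pair is comparable iff the member with the earlier time had an event;
    ties in time with both events are not comparable (standard Harrell
    convention).
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(risk)
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        mask = (time > time[i]) | ((time == time[i]) & (event == 0))
        comparable += int(mask.sum())
        ri = risk[i]
        rj = risk[mask]
        concordant += float((ri > rj).sum()) + 0.5 * float((ri == rj).sum())
    if comparable == 0:
        raise ValueError("no comparable pairs: cannot compute C-index")
    return concordant / comparable


def per_drug_r2(r_hat, r, mask, test_idx=None) -> np.ndarray:
    """Per-drug 1 - SS_res/SS_tot over observed (test) entries.

    Drugs with fewer than two observed values or zero target variance yield
    NaN and are excluded from downstream quantiles.  Values may be negative;
    no truncation is applied.
    """
    r_hat = np.asarray(r_hat, dtype=float)
    r = np.asarray(r, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if test_idx is not None:
        sel = np.asarray(test_idx)
        r_hat, r, mask = r_hat[sel], r[sel], mask[sel]
    m = r.shape[1]
    out = np.full(m, np.nan)
    for j in range(m):
        obs = mask[:, j]
        if obs.sum() < 2:
            continue
        y, yhat = r[obs, j], r_hat[obs, j]
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        ss_res = float(((y - yhat) ** 2).sum())
        out[j] = 1.0 - ss_res / ss_tot
    return out


def r2_quantile90(per_drug: np.ndarray) -> float:
    """90th percentile (linear interpolation) of the valid per-drug R² values."""
    vals = np.asarray(per_drug, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no valid per-drug R² values")
    return float(np.percentile(vals, 90, method="linear"))


def domain_auroc(z_patients, z_celllines, seed: int = 0, n_folds: int = 5) -> float:
    """Cross-validated AUROC of a linear soft-margin SVM separating domains.

    Features are standardized within each training fold; decision values are
    used as scores.  0.5 means perfectly deconfounded.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    zp = np.asarray(z_patients, dtype=float)
    zc = np.asarray(z_celllines, dtype=float)
    if len(zp) < 10 or len(zc) < 10:
        raise ValueError("need at least 10 samples per domain")
    if min(len(zp), len(zc)) < n_folds:
        raise ValueError("each class needs at least one sample per fold")
    X = np.concatenate([zp, zc], axis=0)
    y = np.concatenate([np.zeros(len(zp)), np.ones(len(zc))])
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for train, test in cv.split(X, y):
        clf = make_pipeline(StandardScaler(), LinearSVC(C=1.0))
        clf.fit(X[train], y[train])
        scores[test] = clf.decision_function(X[test])
    return float(roc_auc_score(y, scores))


def pareto_front(points, directions=None) -> list:
    """Indices of points not strictly dominated.

    ``directions`` is a sequence of "max"/"min" per coordinate (default all
    "max").  A point dominates another if it is at least as good everywhere
    and strictly better somewhere; duplicates of a front point all stay.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a list of equal-arity tuples")
    k = pts.shape[1]
    if directions is None:
        directions = ["max"] * k
    sign = np.array([1.0 if d == "max" else -1.0 for d in directions])
    vals = pts * sign
    front = []
    for i in range(len(vals)):
        dominated = False
        for j in range(len(vals)):
            if j == i:
                continue
            if np.all(vals[j] >= vals[i]) and np.any(vals[j] > vals[i]):
                dominated = True
                break
        if not dominated:
            front.append(i)
    return front


@dataclasses.dataclass
class RiskStratification:
    lower_cut: float
    upper_cut: float
    labels: np.ndarray  # "low" / "mid" / "high"


def stratify_risk(discovery_risk, new_risk) -> RiskStratification:
    """Tertile boundaries from discovery scores, applied to new scores.

    score <= lower cut -> low; <= upper cut -> mid; else high.
    """
    disc = np.asarray(discovery_risk, dtype=float)
    if disc.size == 0:
        raise ValueError("discovery risk scores must be non-empty")
    lower = float(np.percentile(disc, 100 / 3, method="linear"))
    upper = float(np.percentile(disc, 200 / 3, method="linear"))
    new = np.asarray(new_risk, dtype=float)
    labels = np.where(new <= lower, "low", np.where(new <= upper, "mid", "high"))
    return RiskStratification(lower, upper, labels)


def dysregulation_test(
    expression,
    predicted_sensitivity,
    drug_targets: dict,
    drug_ids=None,
    z_low: float = -1.0,
    z_high: float = 1.0,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Compare drug-target gene expression between predicted sensitivity groups.

    Per drug, patients are z-scored on predicted sensitivity; resistant
    (z < z_low) and sensitive (z > z_high) groups are compared per target
    gene with a two-sided t-test and a log2 fold-change.  Returns a table
    with one row per (drug, gene) plus untestable / missing-gene flags.
    """
    pred = np.asarray(predicted_sensitivity, dtype=float)
    if drug_ids is None:
        drug_ids = [f"drug{j}" for j in range(pred.shape[1])]
    gene_index = {g: i for i, g in enumerate(expression.gene_ids)}
    rows = []
    for j, drug in enumerate(drug_ids):
        targets = drug_targets.get(drug)
        if not targets:
            continue
        scores = pred[:, j]
        sd = scores.std()
        if sd == 0 or not np.isfinite(sd):
            for gene in targets:
                rows.append(_dys_row(drug, gene, np.nan, np.nan, False, False, "untestable"))
            continue
        z = (scores - scores.mean()) / sd
        res, sen = z < z_low, z > z_high
        if res.sum() == 0 or sen.sum() == 0:
            for gene in targets:
                rows.append(_dys_row(drug, gene, np.nan, np.nan, False, False, "untestable"))
            continue
        for gene in targets:
            gi = gene_index.get(gene)
            if gi is None:
                rows.append(_dys_row(drug, gene, np.nan, np.nan, False, False, "gene_absent"))
                continue
            xs, xr = expression.values[sen, gi], expression.values[res, gi]
            logfc = float(xs.mean() - xr.mean())  # expression already on log2 scale
            t, p = sps.ttest_ind(xs, xr, equal_var=False)
            rows.append(
                _dys_row(
                    drug,
                    gene,
                    logfc,
                    float(p),
                    bool(p < alpha),
                    bool(abs(logfc) > np.log2(fc_threshold)),
                    "ok",
                )
            )
    return pd.DataFrame(rows, columns=["drug", "gene", "logFC", "p", "significant", "substantial", "status"])


def _dys_row(drug, gene, logfc, p, sig, sub, status):
    return {
        "drug": drug,
        "gene": gene,
        "logFC": logfc,
        "p": p,
        "significant": sig,
        "substantial": sub,
        "status": status,
    }
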