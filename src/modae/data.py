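"""Data containers, table I/O, and preprocessing.

Implements the preprocessing protocol used throughout: gene filtering on
mean log-expression, per-dataset standardization, follow-up capping, and
survival-stratified fold assignment (time quantiles crossed with event
status).

Expression inputs are expected on the log2(TPM+1) scale; upstream
normalization (e.g. upper-quartile TPM) is out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalRecordSet",
    "DrugResponseMatrix",
    "FoldAssignment",
    "StandardizationStats",
    "load_expression",
    "load_survival",
    "load_drug_response",
    "filter_genes",
    "standardize",
    "inverse_standardize",
    "cap_followup",
    "stratified_survival_folds",
]

PATIENT, CELLLINE = 0, 1


class ParseError(ValueError):
    pass


@dataclasses.dataclass
class OmicsMatrix:
    """Samples x genes expression matrix with a per-sample domain indicator."""

    values: np.ndarray
    sample_ids: list
    gene_ids: list
    domain: np.ndarray  # 0 = patient, 1 = cell-line

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.domain = np.asarray(self.domain, dtype=int)
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match matrix columns")
        if self.domain.shape != (n,):
            raise ValueError("domain must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "OmicsMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return OmicsMatrix(
            self.values[:, idx], list(self.sample_ids), list(gene_ids), self.domain
        )

    def to_table(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclasses.dataclass
class SurvivalRecordSet:
    """Follow-up time (days), event indicator, optional covariates."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time and event must align 1:1 with sample_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != n:
                raise ValueError("covariates must have one row per sample")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def subset(self, idx) -> "SurvivalRecordSet":
        idx = np.asarray(idx)
        return SurvivalRecordSet(
            [self.sample_ids[i] for i in idx],
            self.time[idx],
            self.event[idx],
            None if self.covariates is None else self.covariates[idx],
            self.covariate_names,
        )

    def to_table(self, path) -> None:
        cols = {"time_days": self.time, "event": self.event}
        if self.covariates is not None:
            names = self.covariate_names or [
                f"cov{i}" for i in range(self.covariates.shape[1])
            ]
            for j, name in enumerate(names):
                cols[name] = self.covariates[:, j]
        df = pd.DataFrame(cols, index=self.sample_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclasses.dataclass
class DrugResponseMatrix:
    """Cell-lines x drugs AAC matrix with an explicit observed mask."""

    values: np.ndarray
    observed_mask: np.ndarray
    sample_ids: list
    drug_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.drug_ids) != m:
            raise ValueError("ID lists do not match matrix shape")
        obs = self.values[self.observed_mask]
        if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
            raise ValueError("observed AAC values must lie in [0, 1]")
        if m and not np.all(self.observed_mask.any(axis=0)):
            bad = [d for j, d in enumerate(self.drug_ids) if not self.observed_mask[:, j].any()]
            raise ValueError(f"drugs with no observed entries: {bad}")

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    def to_table(self, path) -> None:
        vals = self.values.astype(object).copy()
        vals[~self.observed_mask] = ""
        df = pd.DataFrame(vals, index=self.sample_ids, columns=self.drug_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclasses.dataclass
class FoldAssignment:
    sample_ids: list
    fold_id: np.ndarray  # 1..k
    stratum_id: np.ndarray

    def __post_init__(self):
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        self.stratum_id = np.asarray(self.stratum_id, dtype=int)

    @property
    def n_folds(self) -> int:
        return int(self.fold_id.max())

    def split(self, fold: int):
        test = np.where(self.fold_id == fold)[0]
        train = np.where(self.fold_id != fold)[0]
        return train, test

    def to_table(self, path) -> None:
        df = pd.DataFrame(
            {"fold": self.fold_id, "stratum": self.stratum_id}, index=self.sample_ids
        )
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


@dataclasses.dataclass
class StandardizationStats:
    gene_ids: list
    location: np.ndarray
    scale: np.ndarray


# -- loading -------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ParseError(f"duplicated column IDs in {path}: {dups}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas error wrapping
        raise ParseError(f"could not parse {path}: {e}") from e
    return df


def load_expression(path, domain: int) -> OmicsMatrix:
    """Read an expression table (rows = samples, header = gene IDs)."""
    df = _read_table(path)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicated sample IDs in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"duplicated gene IDs in {path}: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        for rid, row in df.iterrows():
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ParseError(f"non-numeric value in row '{rid}' of {path}") from e
        raise ParseError(f"non-numeric values in {path}") from e
    if np.isnan(values).any():
        rid = df.index[np.isnan(values).any(axis=1)][0]
        raise ParseError(f"missing value in row '{rid}' of {path}")
    n = len(df)
    return OmicsMatrix(
        values,
        df.index.tolist(),
        df.columns.tolist(),
        np.full(n, int(domain), dtype=int),
    )


def load_survival(path) -> SurvivalRecordSet:
    df = _read_table(path)
    required = {"time_days", "event"}
    if not required.issubset(df.columns):
        raise ParseError(f"survival table must have columns {sorted(required)}")
    cov_cols = [c for c in df.columns if c not in required]
    cov = df[cov_cols].to_numpy(dtype=float) if cov_cols else None
    return SurvivalRecordSet(
        df.index.tolist(),
        df["time_days"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=int),
        cov,
        cov_cols or None,
    )


def load_drug_response(path) -> DrugResponseMatrix:
    df = _read_table(path)
    values = df.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    values = np.where(mask, values, 0.0)
    return DrugResponseMatrix(values, mask, df.index.tolist(), df.columns.tolist())


# -- preprocessing -------------------------------------------------------


def filter_genes(
    patient: OmicsMatrix, cellline: OmicsMatrix, min_mean: float = 1.0
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Keep genes whose mean log-expression is >= ``min_mean`` in both datasets.

    Operates on the intersection of the gene universes; genes with mean
    strictly below the threshold in either dataset are excluded.
    """
    common = [g for g in patient.gene_ids if g in set(cellline.gene_ids)]
    if not common:
        raise ValueError("patient and cell-line matrices share no genes")
    p = patient.subset_genes(common)
    c = cellline.subset_genes(common)
    keep = (p.values.mean(axis=0) >= min_mean) & (c.values.mean(axis=0) >= min_mean)
    kept = [g for g, k in zip(common, keep) if k]
    if not kept:
        raise ValueError("no genes pass the mean-expression filter")
    return p.subset_genes(kept), c.subset_genes(kept)


def standardize(m: OmicsMatrix, stats: StandardizationStats | None = None):
    """Center and scale each gene to mean 0, sd 1 (population convention).

    When ``stats`` is given, applies those statistics instead of fitting new
    ones (used to transform validation data with discovery statistics).
    """
    if stats is None:
        loc = m.values.mean(axis=0)
        scale = m.values.std(axis=0)  # population sd: divide by n
        zero = np.where(scale == 0)[0]
        if zero.size:
            genes = [m.gene_ids[i] for i in zero]
            raise ValueError(f"zero-variance genes cannot be standardized: {genes}")
        stats = StandardizationStats(list(m.gene_ids), loc, scale)
    else:
        if stats.gene_ids != m.gene_ids:
            raise ValueError("standardization statistics were fitted on different genes")
    out = OmicsMatrix(
        (m.values - stats.location) / stats.scale,
        list(m.sample_ids),
        list(m.gene_ids),
        m.domain,
    )
    return out, stats


def inverse_standardize(m: OmicsMatrix, stats: StandardizationStats) -> OmicsMatrix:
    return OmicsMatrix(
        m.values * stats.scale + stats.location,
        list(m.sample_ids),
        list(m.gene_ids),
        m.domain,
    )


def cap_followup(s: SurvivalRecordSet, max_days: float = 3000.0) -> SurvivalRecordSet:
    """Censor records with follow-up strictly beyond ``max_days``."""
    over = s.time > max_days
    time = np.where(over, max_days, s.time)
    event = np.where(over, 0, s.event)
    return SurvivalRecordSet(
        list(s.sample_ids), time, event, s.covariates, s.covariate_names
    )


def stratified_survival_folds(
    s: SurvivalRecordSet,
    k_folds: int = 5,
    n_quantiles: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign folds stratified by (time-quantile x event-status) strata.

    Times are ranked (ties broken by stable sample order) and cut into
    ``n_quantiles`` equally sized bins; each bin crossed with event status
    forms a stratum whose members are dealt round-robin into shuffled folds.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = s.n
    order = np.argsort(s.time, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    quant = np.minimum((rank * n_quantiles) // n, n_quantiles - 1)
    stratum = quant * 2 + s.event

    rng = np.random.default_rng(seed)
    fold = np.zeros(n, dtype=int)
    start = 0  # rotate fold offsets so small strata spread across folds
    for st in np.unique(stratum):
        members = np.where(stratum == st)[0]
        rng.shuffle(members)
        for i, idx in enumerate(members):
            fold[idx] = (start + i) % k_folds + 1
        start = (start + len(members)) % k_folds
    return FoldAssignment(list(s.sample_ids), fold, stratum)
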