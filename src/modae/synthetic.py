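"""Synthetic paired patient / cell-line cohorts.

Generates two expression domains that share latent factors but are separated
by a constant per-gene domain shift, survival times whose hazard depends on
the shared factors, and a partially observed drug-sensitivity matrix driven
by the same factors.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data import DrugResponseMatrix, OmicsMatrix, SurvivalRecordSet

__all__ = ["SyntheticConfig", "SyntheticCohorts", "generate_cohorts", "write_cohorts"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 300
    n_celllines: int = 300
    n_genes: int = 50
    n_shared_factors: int = 5
    n_private_factors: int = 2
    domain_shift_scale: float = 3.0
    hazard_coefficients: tuple = (1.0, -1.0, 0.5, 0.0, 0.0)
    baseline_hazard: float = 1e-3
    censoring_rate: float = 2e-4
    max_followup: float = 3000.0
    n_drugs: int = 10
    drug_signal_fraction: float = 0.5
    missing_fraction: float = 0.2
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_patients": self.n_patients,
            "n_celllines": self.n_celllines,
            "n_genes": self.n_genes,
            "n_shared_factors": self.n_shared_factors,
            "n_drugs": self.n_drugs,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_private_factors < 0:
            raise ValueError("n_private_factors must be >= 0")
        for name in ("drug_signal_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("domain_shift_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("baseline_hazard", "censoring_rate", "max_followup"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        hc = np.asarray(self.hazard_coefficients, dtype=float)
        if hc.shape != (self.n_shared_factors,):
            raise ValueError(
                "hazard_coefficients must have length n_shared_factors "
                f"({self.n_shared_factors}), got shape {hc.shape}"
            )
        scalars = [
            self.domain_shift_scale,
            self.baseline_hazard,
            self.censoring_rate,
            self.max_followup,
            self.drug_signal_fraction,
            self.missing_fraction,
            self.noise_sd,
        ]
        if not np.all(np.isfinite(scalars)) or not np.all(np.isfinite(hc)):
            raise ValueError("configuration values must be finite")


@dataclasses.dataclass
class SyntheticCohorts:
    """Generated data plus the ground truth used to generate it."""

    patients: OmicsMatrix
    celllines: OmicsMatrix
    survival: SurvivalRecordSet
    drugs: DrugResponseMatrix
    factors_patients: np.ndarray  # shared factors, patients x k
    factors_celllines: np.ndarray
    loadings_shared: np.ndarray  # k x genes
    loadings_private_patient: np.ndarray
    loadings_private_cellline: np.ndarray
    drug_weights: np.ndarray  # k x drugs, zero column for noise drugs
    signal_drugs: np.ndarray  # boolean per drug
    config: SyntheticConfig


def generate_cohorts(config: SyntheticConfig) -> SyntheticCohorts:
    """Simulate patient and cell-line cohorts with shared latent structure."""
    rng = np.random.default_rng(config.seed)
    k, kp, d = config.n_shared_factors, config.n_private_factors, config.n_genes
    n_p, n_c = config.n_patients, config.n_celllines

    loadings_shared = rng.standard_normal((k, d))
    loadings_priv_p = rng.standard_normal((kp, d)) if kp else np.zeros((0, d))
    loadings_priv_c = rng.standard_normal((kp, d)) if kp else np.zeros((0, d))

    z_p = rng.standard_normal((n_p, k))
    z_c = rng.standard_normal((n_c, k))
    zp_priv = rng.standard_normal((n_p, kp)) if kp else np.zeros((n_p, 0))
    zc_priv = rng.standard_normal((n_c, kp)) if kp else np.zeros((n_c, 0))

    x_p = z_p @ loadings_shared + zp_priv @ loadings_priv_p
    x_p = x_p + config.noise_sd * rng.standard_normal((n_p, d))
    shift = config.domain_shift_scale * rng.standard_normal(d) if config.domain_shift_scale > 0 else np.zeros(d)
    x_c = z_c @ loadings_shared + zc_priv @ loadings_priv_c + shift
    x_c = x_c + config.noise_sd * rng.standard_normal((n_c, d))

    patient_ids = [f"P{i:05d}" for i in range(n_p)]
    cellline_ids = [f"C{i:05d}" for i in range(n_c)]
    gene_ids = [f"G{j:05d}" for j in range(d)]
    patients = OmicsMatrix(x_p, patient_ids, gene_ids, domain=np.zeros(n_p, dtype=int))
    celllines = OmicsMatrix(x_c, cellline_ids, gene_ids, domain=np.ones(n_c, dtype=int))

    # survival: exponential event times with log-linear hazard in shared factors
    beta = np.asarray(config.hazard_coefficients, dtype=float)
    rate = config.baseline_hazard * np.exp(z_p @ beta)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / config.censoring_rate, size=n_p)
    observed = np.minimum(np.minimum(event_time, censor_time), config.max_followup)
    event = (event_time <= censor_time) & (event_time <= config.max_followup)
    observed = np.maximum(observed, np.finfo(float).tiny)  # strictly positive
    survival = SurvivalRecordSet(
        sample_ids=list(patient_ids),
        time=observed,
        event=event.astype(int),
    )

    # drugs: logistic squash of a linear map of shared factors, or pure noise
    m = config.n_drugs
    n_signal = int(round(config.drug_signal_fraction * m))
    signal = np.zeros(m, dtype=bool)
    signal[:n_signal] = True
    drug_w = np.zeros((k, m))
    if n_signal:
        # unit-variance linear predictor keeps the logistic out of saturation
        drug_w[:, signal] = rng.standard_normal((k, n_signal)) / np.sqrt(k)
    lin = z_c @ drug_w
    lin[:, ~signal] = 0.0
    aac = 1.0 / (1.0 + np.exp(-lin))
    aac = aac + 0.05 * rng.standard_normal((n_c, m))
    aac[:, ~signal] = rng.uniform(0.0, 1.0, size=(n_c, (~signal).sum()))
    aac = np.clip(aac, 0.0, 1.0)

    # exact-count missingness: |O(R)| is deterministic given the seed
    n_missing = int(round(config.missing_fraction * n_c * m))
    mask = np.ones(n_c * m, dtype=bool)
    if n_missing:
        hidden = rng.choice(n_c * m, size=n_missing, replace=False)
        mask[hidden] = False
    mask = mask.reshape(n_c, m)
    drug_ids = [f"D{j:03d}" for j in range(m)]
    drugs = DrugResponseMatrix(aac, mask, list(cellline_ids), drug_ids)

    return SyntheticCohorts(
        patients=patients,
        celllines=celllines,
        survival=survival,
        drugs=drugs,
        factors_patients=z_p,
        factors_celllines=z_c,
        loadings_shared=loadings_shared,
        loadings_private_patient=loadings_priv_p,
        loadings_private_cellline=loadings_priv_c,
        drug_weights=drug_w,
        signal_drugs=signal,
        config=config,
    )


def write_cohorts(cohorts: SyntheticCohorts, outdir) -> Path:
    """Write the four tables as TSV plus a JSON sidecar with the ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts.patients.to_table(out / "patients_expression.tsv")
    cohorts.celllines.to_table(out / "celllines_expression.tsv")
    cohorts.survival.to_table(out / "survival.tsv")
    cohorts.drugs.to_table(out / "drug_response.tsv")
    sidecar = {
        "config": dataclasses.asdict(cohorts.config),
        "signal_drugs": cohorts.signal_drugs.tolist(),
        "hazard_coefficients": list(cohorts.config.hazard_coefficients),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return out
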