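"""Synthetic ground-truth cohorts and geometry tables for testing.

Real coronary-disease cohorts of the kind this package models (a few
hundred patients, a mix of continuous risk markers and binary risk
factors) are not freely redistributable, so every pipeline stage is
exercised against synthetic data with *known* statistical structure: a
log-space multivariate normal with a specified mean and covariance,
categorical covariates cut at specified latent quantiles, missingness
injected completely at random, and a geometry table with monotone
per-patient stenosis progression.

The ``smartool_like`` preset emulates a 186-patient coronary CT cohort:
10 positive continuous covariates (age, BMI, lipid panel, glucose, blood
pressure, creatinine, CRP) and 10 binary risk factors at realistic
prevalences (e.g. 57% male, 16% diabetes), with a plausible correlation
structure (lipids inter-correlated, obesity tracking BMI, hypertension
tracking systolic pressure, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Cohort, VariableSchema
from .errors import ConfigError

__all__ = [
    "GroundTruth",
    "smartool_like",
    "make_cohort",
    "inject_missing",
    "make_geometry_table",
]

VESSELS = ("LAD", "LCX", "RCA")


@dataclass
class GroundTruth:
    """Known log-space moments plus categorical cut proportions.

    ``sigma_true`` is the log-space covariance over all p variables
    (categorical variables act through a latent Gaussian column).
    ``category_cut_probs[name]`` gives the cumulative proportions of the
    categories, strictly increasing and ending at 1: a latent value below
    the q-th implied quantile falls in category q.
    """

    mu_true: np.ndarray
    sigma_true: np.ndarray
    schemas: list[VariableSchema]
    category_cut_probs: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_true = np.asarray(self.mu_true, dtype=float)
        self.sigma_true = np.asarray(self.sigma_true, dtype=float)
        p = self.mu_true.shape[0]
        if self.sigma_true.shape != (p, p) or len(self.schemas) != p:
            raise ConfigError("inconsistent ground-truth dimensions")
        if not np.allclose(self.sigma_true, self.sigma_true.T, atol=1e-10):
            raise ConfigError("sigma_true must be symmetric")
        lam = np.linalg.eigvalsh((self.sigma_true + self.sigma_true.T) / 2)
        if lam.min() < -1e-10:
            raise ConfigError("sigma_true must be positive semidefinite")
        for s in self.schemas:
            if s.is_categorical:
                cum = self.category_cut_probs.get(s.name)
                if cum is None:
                    raise ConfigError(f"no cut proportions for {s.name!r}")
                if len(cum) != s.n_categories:
                    raise ConfigError(f"{s.name!r}: need one cumulative value per category")
                if not all(b > a for a, b in zip(cum, cum[1:])):
                    raise ConfigError(f"{s.name!r}: cumulative proportions must increase")
                if abs(cum[-1] - 1.0) > 1e-12:
                    raise ConfigError(f"{s.name!r}: cumulative proportions must end at 1")

    @property
    def p(self) -> int:
        return self.mu_true.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu_true": self.mu_true.tolist(),
            "sigma_true": self.sigma_true.tolist(),
            "schemas": [s.to_dict() for s in self.schemas],
            "category_cut_probs": self.category_cut_probs,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


# (name, typical value on the original scale, log-space SD)
_CONTINUOUS = [
    ("age_years", 60.0, 0.15),
    ("bmi", 27.0, 0.15),
    ("ldl_mg_dl", 130.0, 0.30),
    ("hdl_mg_dl", 48.0, 0.25),
    ("total_chol_mg_dl", 200.0, 0.20),
    ("triglycerides_mg_dl", 140.0, 0.45),
    ("glucose_mg_dl", 100.0, 0.18),
    ("systolic_bp_mmhg", 135.0, 0.12),
    ("creatinine_mg_dl", 0.9, 0.20),
    ("crp_mg_l", 2.0, 0.80),
]

# (name, categories, probability of the second ("yes") category)
_BINARY = [
    ("gender", ["female", "male"], 0.5699),
    ("family_history", ["no", "yes"], 0.4946),
    ("current_smoking", ["no", "yes"], 0.2097),
    ("past_smoking", ["no", "yes"], 0.4570),
    ("diabetes", ["no", "yes"], 0.1613),
    ("dyslipidemia", ["no", "yes"], 0.6935),
    ("hypertension", ["no", "yes"], 0.6398),
    ("metabolic_syndrome", ["no", "yes"], 0.0054),
    ("obesity", ["no", "yes"], 0.1774),
    ("statins", ["no", "yes"], 0.4677),
]

# off-diagonal correlations of the latent log-space Gaussian
_CORRELATIONS = [
    ("ldl_mg_dl", "total_chol_mg_dl", 0.85),
    ("triglycerides_mg_dl", "total_chol_mg_dl", 0.35),
    ("hdl_mg_dl", "triglycerides_mg_dl", -0.45),
    ("bmi", "triglycerides_mg_dl", 0.40),
    ("bmi", "glucose_mg_dl", 0.35),
    ("age_years", "systolic_bp_mmhg", 0.35),
    ("glucose_mg_dl", "triglycerides_mg_dl", 0.30),
    ("bmi", "obesity", 0.80),
    ("glucose_mg_dl", "diabetes", 0.60),
    ("systolic_bp_mmhg", "hypertension", 0.60),
    ("ldl_mg_dl", "dyslipidemia", 0.50),
    ("ldl_mg_dl", "statins", -0.30),
    ("hdl_mg_dl", "gender", -0.30),
    ("current_smoking", "past_smoking", -0.30),
    ("bmi", "metabolic_syndrome", 0.40),
    ("glucose_mg_dl", "metabolic_syndrome", 0.40),
]


def _nearest_correlation(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone and renormalise to unit
    diagonal (one clip-and-rescale pass is enough for mild indefiniteness)."""
    lam, u = np.linalg.eigh((corr + corr.T) / 2)
    lam = np.clip(lam, 1e-6, None)
    fixed = (u * lam[np.newaxis, :]) @ u.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2


def smartool_like() -> GroundTruth:
    """Default ground truth: 10 continuous + 10 binary covariates, n≈186 scale."""
    schemas: list[VariableSchema] = []
    mu, sd = [], []
    for name, typical, log_sd in _CONTINUOUS:
        schemas.append(VariableSchema(name=name, kind="continuous"))
        mu.append(np.log(typical))
        sd.append(log_sd)
    cut_probs: dict[str, list[float]] = {}
    for name, cats, p_yes in _BINARY:
        schemas.append(VariableSchema(name=name, kind="categorical", categories=cats))
        mu.append(0.0)
        sd.append(1.0)  # latent scale is arbitrary; cuts are quantile-based
        cut_probs[name] = [1.0 - p_yes, 1.0]
    names = [s.name for s in schemas]
    p = len(names)
    corr = np.eye(p)
    for a, b, r in _CORRELATIONS:
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r
    corr = _nearest_correlation(corr)
    sd = np.asarray(sd)
    sigma = corr * np.outer(sd, sd)
    return GroundTruth(
        mu_true=np.asarray(mu), sigma_true=sigma,
        schemas=schemas, category_cut_probs=cut_probs,
    )


def make_cohort(truth: GroundTruth, n: int, seed: int) -> Cohort:
    """Draw n patients: MVN(mu_true, sigma_true) in log space, exponentiated;
    categorical columns cut at the latent quantiles of their cumulative
    proportions. Reproducible by seed; no missing cells."""
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    lam, u = np.linalg.eigh((truth.sigma_true + truth.sigma_true.T) / 2)
    lam = np.clip(lam, 0.0, None)
    k = u * np.sqrt(lam)[np.newaxis, :]
    z = rng.standard_normal((n, truth.p))
    latent = truth.mu_true[np.newaxis, :] + z @ k.T
    values = np.empty_like(latent)
    for j, s in enumerate(truth.schemas):
        if s.is_categorical:
            cum = np.asarray(truth.category_cut_probs[s.name][:-1])
            sd_j = np.sqrt(truth.sigma_true[j, j])
            cuts = truth.mu_true[j] + sd_j * stats.norm.ppf(cum)
            values[:, j] = s.code_offset + np.searchsorted(
                cuts, latent[:, j], side="right"
            )
        else:
            values[:, j] = np.exp(latent[:, j]) - s.positivity_offset
    return Cohort(
        schemas=[VariableSchema.from_dict(s.to_dict()) for s in truth.schemas],
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        ids=[f"R{i + 1:04d}" for i in range(n)],
    )


def inject_missing(
    cohort: Cohort, rate: float, seed: int
) -> tuple[Cohort, dict[tuple[int, int], float]]:
    """Mask each cell independently with probability *rate* (MCAR).

    Rows that would end up fully masked are redrawn so at least one cell
    per row stays observed.  Returns the masked cohort and a map of
    ``(row, column) -> hidden true value`` for scoring imputation.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = cohort.copy()
    if rate == 0:
        return out, {}
    rng = np.random.default_rng(seed)
    new_mask = rng.random(out.mask.shape) < rate
    for i in range(out.n):
        while new_mask[i].all():
            new_mask[i] = rng.random(out.p) < rate
    hidden = {
        (int(i), int(j)): float(cohort.values[i, j])
        for i, j in np.argwhere(new_mask & ~cohort.mask)
    }
    out.mask |= new_mask
    out.values[out.mask] = np.nan
    return out, hidden


def make_geometry_table(
    patient_ids: list[str],
    time_points: list[float],
    seed: int,
    min_final_stenosis: float = 50.0,
) -> pd.DataFrame:
    """One geometry row per (patient, time point) with monotone stenosis.

    Stenosis grows from a random baseline to a final value strictly above
    ``min_final_stenosis`` (the >50% population filter used for stent-trial
    populations) through strictly positive random increments, so within a
    patient stenosis_pct never decreases over time.  Columns: patient_id,
    geometry_id, time_point_years, stenosis_pct, vessel_label,
    plaque_burden_pct.
    """
    if not patient_ids:
        raise ValueError("patient_ids must be non-empty")
    if not time_points:
        raise ValueError("time_points must be non-empty")
    times = sorted(float(t) for t in time_points)
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for pid in patient_ids:
        vessel = VESSELS[rng.integers(len(VESSELS))]
        baseline = rng.uniform(20.0, 45.0)
        final = rng.uniform(min_final_stenosis + 5.0, 90.0)
        parts = rng.dirichlet(np.ones(len(times)) * 2.0)
        stenosis = baseline + np.cumsum(parts) * (final - baseline)
        for t, s in zip(times, stenosis):
            gid += 1
            burden = min(95.0, max(5.0, 0.8 * s + rng.normal(0, 3)))
            rows.append({
                "patient_id": pid,
                "geometry_id": f"G{gid:05d}",
                "time_point_years": t,
                "stenosis_pct": float(s),
                "vessel_label": vessel,
                "plaque_burden_pct": float(burden),
            })
    return pd.DataFrame(rows)
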