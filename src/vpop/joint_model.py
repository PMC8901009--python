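"""Joint multivariate log-normal model of a clinical cohort.

The cohort is encoded (categorical codes, positivity-shifted continuous
values), log-transformed elementwise, and summarised by its mean vector μ
and covariance matrix Σ.  Sampling uses the eigendecomposition Σ = U Λ Uᵀ:
the sampling matrix K = U Λ^(1/2) maps i.i.d. standard-normal latent
vectors Z to correlated log-space deviations, x' = μ + K Z.  Because the
model lives in log space, exponentiating samples yields strictly positive,
log-normally distributed covariates — no rejection of negative draws is
ever needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import Cohort, VariableSchema, encode
from .errors import InsufficientDataError, PositivityError, SchemaError, VpopError

#: relative threshold under which eigenvalues are clipped to zero
EIG_CLIP_REL = 1e-12

__all__ = ["FittedJointModel", "log_transform", "fit", "fit_pairwise", "decompose"]


def log_transform(matrix: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Elementwise natural log of the unmasked entries.

    Raises :class:`PositivityError` naming the first offending cell if an
    unmasked entry is not strictly positive.  Masked entries stay NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    if mask is None:
        mask = np.isnan(matrix)
    bad = (~mask) & ~(matrix > 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise PositivityError(
            f"non-positive entry {matrix[i, j]!r} at row {i}, column {j}; "
            "set a positivity_offset on this variable"
        )
    out = np.full_like(matrix, np.nan)
    out[~mask] = np.log(matrix[~mask])
    return out


def decompose(sigma: np.ndarray, atol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition Σ = U Λ Uᵀ with positive-semidefinite repair.

    Eigenvalues below ``EIG_CLIP_REL * max(Λ)`` (including small negatives
    from rounding on collinear covariates) are clipped to zero.  Returns
    ``(U, Lambda)`` with eigenvalues in descending order.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise SchemaError(f"covariance must be square, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=atol):
        raise SchemaError("covariance matrix is not symmetric within tolerance")
    lam, u = np.linalg.eigh((sigma + sigma.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]
    top = max(lam.max(initial=0.0), 0.0)
    lam[lam < EIG_CLIP_REL * top] = 0.0
    lam[lam < 0.0] = 0.0
    return u, lam


@dataclass
class FittedJointModel:
    """Log-space moments and sampling matrix of a fitted cohort model.

    Attributes
    ----------
    mu : (p,) log-space mean vector
    sigma : (p, p) log-space covariance Σ
    U, Lambda : eigenpairs of Σ after PSD repair
    K : sampling matrix U Λ^(1/2) (or the Cholesky factor L of Σ when the
        ``cholesky`` backend was used) satisfying K Kᵀ = Σ
    schemas : the variable schemas the model was fitted on
    n_source : number of source patients
    backend : ``"eigen"`` or ``"cholesky"``
    """

    mu: np.ndarray
    sigma: np.ndarray
    U: np.ndarray
    Lambda: np.ndarray
    K: np.ndarray
    schemas: list[VariableSchema]
    n_source: int
    backend: str = "eigen"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        p = self.mu.shape[0]
        if self.sigma.shape != (p, p) or self.K.shape != (p, p):
            raise SchemaError("inconsistent model dimensions")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise SchemaError("sigma must be symmetric")
        if (self.Lambda < 0).any():
            raise SchemaError("negative eigenvalue after repair")
        if not np.allclose(self.K @ self.K.T, self.sigma, atol=1e-8):
            raise VpopError("K Kᵀ does not reconstruct sigma")

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schemas]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "U": self.U.tolist(),
            "Lambda": self.Lambda.tolist(),
            "K": self.K.tolist(),
            "schemas": [s.to_dict() for s in self.schemas],
            "n_source": self.n_source,
            "backend": self.backend,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedJointModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            U=np.array(d["U"]),
            Lambda=np.array(d["Lambda"]),
            K=np.array(d["K"]),
            schemas=[VariableSchema.from_dict(s) for s in d["schemas"]],
            n_source=int(d["n_source"]),
            backend=d.get("backend", "eigen"),
        )


def _build_model(
    log_matrix: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    schemas: list[VariableSchema],
    backend: str,
) -> FittedJointModel:
    if backend == "eigen":
        u, lam = decompose(sigma)
        k = u * np.sqrt(lam)[np.newaxis, :]
    elif backend == "cholesky":
        u, lam = decompose(sigma)
        # Cholesky needs PD; add the smallest jitter that makes it succeed
        # on semidefinite repairs, so K Kᵀ = Σ still holds within tolerance.
        sym = (sigma + sigma.T) / 2.0
        jitter = 0.0
        top = max(float(lam.max(initial=0.0)), 1.0)
        for _ in range(10):
            try:
                k = np.linalg.cholesky(sym + jitter * np.eye(sym.shape[0]))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10, EIG_CLIP_REL * top)
        else:
            raise VpopError("Cholesky factorization failed")
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return FittedJointModel(
        mu=mu, sigma=sigma, U=u, Lambda=lam, K=k,
        schemas=schemas, n_source=log_matrix.shape[0], backend=backend,
    )


def fit(
    cohort: Cohort,
    backend: str = "eigen",
    legacy_mean: bool = False,
) -> FittedJointModel:
    """Fit the joint multivariate log-normal model to a complete cohort.

    The encoded matrix is log-transformed; μ is the sample mean (1/n) and Σ
    the sample covariance with 1/(n−1) normalisation.  ``legacy_mean``
    switches the mean to a 1/(n−1) normalisation, reproducing a variant of
    the estimator seen in some published pipelines (not recommended: it
    biases μ upward by n/(n−1)).

    The cohort must have no missing cells — impute first
    (:func:`vpop.imputer.impute`).
    """
    if cohort.n_missing:
        raise SchemaError(
            f"cohort has {cohort.n_missing} missing cell(s); run imputation first"
        )
    if cohort.n < 2:
        raise InsufficientDataError(f"need n >= 2 patients, got {cohort.n}")
    matrix, mask = encode(cohort)
    logm = log_transform(matrix, mask)
    denom = cohort.n - 1 if legacy_mean else cohort.n
    mu = logm.sum(axis=0) / denom
    centred = logm - logm.mean(axis=0)
    sigma = centred.T @ centred / (cohort.n - 1)
    sigma = (sigma + sigma.T) / 2.0
    return _build_model(logm, mu, sigma, [s for s in cohort.schemas], backend)


def fit_pairwise(cohort: Cohort, backend: str = "eigen") -> FittedJointModel:
    """Fit μ, Σ from pairwise-complete observations of an incomplete cohort.

    Each mean uses the rows where that covariate is observed; each covariance
    uses the rows where both covariates of the pair are observed (1/(m−1)
    normalisation).  The resulting matrix can be indefinite, so it is
    repaired by eigenvalue clipping before the sampling matrix is formed.
    This is the model used to impute the source cohort itself.
    """
    if cohort.n < 2:
        raise InsufficientDataError(f"need n >= 2 patients, got {cohort.n}")
    matrix, mask = encode(cohort)
    logm = log_transform(matrix, mask)
    df = pd.DataFrame(logm)
    counts = (~mask).sum(axis=0)
    if (counts < 2).any():
        j = int(np.argmin(counts))
        raise InsufficientDataError(
            f"variable {cohort.schemas[j].name!r} has {counts[j]} observed value(s)"
        )
    mu = df.mean().to_numpy()
    sigma = df.cov(min_periods=2).to_numpy()
    if np.isnan(sigma).any():
        raise InsufficientDataError(
            "some covariate pair has < 2 jointly observed rows"
        )
    sigma = (sigma + sigma.T) / 2.0
    u, lam = decompose(sigma)
    sigma = (u * lam[np.newaxis, :]) @ u.T  # PSD projection
    sigma = (sigma + sigma.T) / 2.0
    return _build_model(logm, mu, sigma, [s for s in cohort.schemas], backend)
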