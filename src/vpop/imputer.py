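"""Missing-value imputation by inverting the sampling equation.

A patient row with missing entries gives an underdetermined linear system
in the latent vector Z: only the known components of x' = μ + K Z are
constraints.  Among the infinitely many solutions, the one of least
Euclidean norm ‖Z‖ is chosen — the latent vector closest to the centre of
the standard-normal latent distribution that still reproduces every known
entry exactly.  It is computed with the Moore–Penrose pseudoinverse of the
known-row submatrix of K; missing log-space entries are then read off
μ + K Z, exponentiated, and (for categoricals) discretized.

Because K Kᵀ = Σ, the least-norm reconstruction of the missing block
equals the Gaussian conditional mean E[x_miss | x_known] under the fitted
model, which is why the procedure tracks strongly correlated covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import Cohort, encode
from .errors import InsufficientDataError, SchemaError
from .generator import DiscretizationRule, default_rules, discretize
from .joint_model import FittedJointModel, fit, fit_pairwise, log_transform

__all__ = ["ImputationResult", "vector_norm", "solve_latent", "impute"]


def vector_norm(z: np.ndarray) -> float:
    """Euclidean norm √(Σ Z_j²) — the length of the latent vector."""
    return float(np.linalg.norm(np.asarray(z, dtype=float)))


def solve_latent(
    x_log: np.ndarray,
    known: np.ndarray,
    model: FittedJointModel,
) -> tuple[np.ndarray, float]:
    """Least-norm latent vector for a partially known log-space row.

    Returns ``(Z, residual)`` where Z minimises ‖Z‖ subject to
    ``(μ + K Z)_j = x_log_j`` for every known index j, and *residual* is the
    max absolute violation of those constraints.  For a consistent system
    (K of full row rank on the known indices) the residual is ~0; a
    rank-deficient subsystem (possible after eigenvalue repair) is solved in
    the least-squares-then-least-norm sense and flagged by its residual.
    """
    x_log = np.asarray(x_log, dtype=float)
    known = np.asarray(known, dtype=bool)
    if x_log.shape != (model.p,) or known.shape != (model.p,):
        raise SchemaError(
            f"row of length {x_log.shape} does not match model dimension {model.p}"
        )
    if not known.any():
        raise InsufficientDataError("row has no known entries")
    k_sub = model.K[known, :]
    rhs = x_log[known] - model.mu[known]
    z = np.linalg.pinv(k_sub) @ rhs
    residual = float(np.max(np.abs(k_sub @ z - rhs)))
    return z, residual


@dataclass
class ImputationResult:
    """Completed cohort plus per-row diagnostics of the latent solve."""

    cohort: Cohort
    #: row index -> recovered latent vector (rows that had missing cells)
    latents: dict[int, np.ndarray] = field(default_factory=dict)
    #: row index -> max |(μ + K Z)_j − x'_j| over that row's known entries
    residuals: dict[int, float] = field(default_factory=dict)
    #: row index -> ‖Z‖
    norms: dict[int, float] = field(default_factory=dict)
    #: (row, column) pairs that were filled
    imputed_cells: list[tuple[int, int]] = field(default_factory=list)
    rounds: int = 1

    def report(self) -> dict:
        return {
            "n_imputed_cells": len(self.imputed_cells),
            "imputed_cells": [[i, j] for i, j in self.imputed_cells],
            "norms": {str(i): v for i, v in self.norms.items()},
            "residuals": {str(i): v for i, v in self.residuals.items()},
            "rounds": self.rounds,
        }


def _impute_once(
    cohort: Cohort,
    model: FittedJointModel,
    rules: dict[str, DiscretizationRule],
) -> ImputationResult:
    if [s.name for s in model.schemas] != cohort.names:
        raise SchemaError("cohort and model schemas do not match")
    matrix, mask = encode(cohort)
    logm = log_transform(matrix, mask)
    values = cohort.values.copy()
    out = ImputationResult(cohort=cohort)  # placeholder, replaced below
    latents, residuals, norms = {}, {}, {}
    cells: list[tuple[int, int]] = []
    for i in range(cohort.n):
        miss = mask[i]
        if not miss.any():
            continue
        z, res = solve_latent(logm[i], ~miss, model)
        recon = model.mu + model.K @ z
        for j in np.flatnonzero(miss):
            s = cohort.schemas[j]
            raw = float(np.exp(recon[j]))
            if s.is_categorical:
                values[i, j] = discretize(raw, rules[s.name])
            else:
                values[i, j] = raw - s.positivity_offset
            cells.append((i, int(j)))
        latents[i], residuals[i], norms[i] = z, res, vector_norm(z)
    completed = Cohort(
        schemas=[s for s in cohort.schemas],
        values=values,
        mask=np.zeros_like(mask),
        ids=list(cohort.ids),
    )
    out = ImputationResult(
        cohort=completed, latents=latents, residuals=residuals,
        norms=norms, imputed_cells=cells,
    )
    return out


def impute(
    cohort: Cohort,
    model: FittedJointModel | None = None,
    rules: dict[str, DiscretizationRule] | None = None,
    iterate: bool = False,
    max_rounds: int = 10,
    tol: float = 1e-6,
) -> ImputationResult:
    """Fill every missing cell of *cohort* by least-norm latent inversion.

    If no model is supplied, μ and Σ are estimated from pairwise-complete
    observations (:func:`vpop.joint_model.fit_pairwise`) and imputation runs
    once.  With ``iterate=True`` the model is refitted on the completed
    cohort and imputation repeated until the largest cell change is below
    *tol* (at most *max_rounds* rounds).

    Rows without missing cells are returned untouched; a cohort with no
    missing cells is returned as-is.
    """
    if rules is None:
        rules = default_rules(cohort)
    if cohort.n_missing == 0:
        return ImputationResult(cohort=cohort.copy())
    if model is None:
        model = fit_pairwise(cohort)
    result = _impute_once(cohort, model, rules)
    result.rounds = 1
    if iterate:
        for round_no in range(2, max_rounds + 1):
            refit = fit(result.cohort, backend=model.backend)
            nxt = _impute_once(cohort, refit, rules)
            delta = float(np.max(np.abs(nxt.cohort.values - result.cohort.values)))
            nxt.rounds = round_no
            result = nxt
            if delta < tol:
                break
    return result
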