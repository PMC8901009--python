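"""Virtual patient sampling and categorical discretization.

Sampling: draw i.i.d. standard-normal latent vectors Z, map them to
correlated log-space rows x' = μ + K Z, exponentiate, and undo positivity
offsets.  Simulated categorical covariates come out continuous; they are
mapped back to integer codes by critical values (CrV): either the midpoint
of two sequential integer codes (default) or log-normal quantiles
CrV(μ, σ, P) = exp(μ + σ Φ⁻¹(P)) matched to the empirical category
proportions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import Cohort, VariableSchema
from .errors import SchemaError, VpopError
from .joint_model import FittedJointModel

__all__ = [
    "DiscretizationRule",
    "sample_latent",
    "crv",
    "build_rule",
    "default_rules",
    "discretize",
    "generate",
]


@dataclass
class DiscretizationRule:
    """Maps a continuous simulated value to an integer category code.

    ``boundaries`` are the k−1 strictly increasing critical values
    separating codes ``code_offset .. code_offset+k−1``.  A value exactly
    equal to a boundary goes to the upper code (half-open intervals
    ``[lo, hi)``); the result is clamped at the extreme codes, so
    discretization is a total function.
    """

    variable: str
    method: str
    boundaries: np.ndarray
    code_offset: int = 1
    proportions: np.ndarray | None = None
    mu_sigma: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size and not np.all(np.diff(self.boundaries) > 0):
            raise VpopError(
                f"rule for {self.variable!r}: boundaries must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return self.boundaries.size + 1


def sample_latent(p: int, k: int, seed: int) -> np.ndarray:
    """k i.i.d. standard-normal latent vectors of dimension p, as a (k, p)
    array; reproducible for a given seed."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((k, p))


def crv(mu: float, sigma: float, p: float) -> float:
    """Critical value CrV(μ, σ, P) = exp(μ + σ Φ⁻¹(P)) of a log-normal with
    log-mean μ and log-SD σ at cumulative proportion P."""
    return float(np.exp(mu + sigma * stats.norm.ppf(p)))


def build_rule(
    variable: str, method: str, cohort: Cohort
) -> DiscretizationRule:
    """Build the discretization rule for one categorical variable.

    ``midpoint``: boundary between consecutive codes j, j+1 is (j + j+1)/2.
    ``lognormal_quantile``: boundaries are CrV(μ, σ, P) = exp(μ + σ Φ⁻¹(P))
    with μ, σ the mean and SD of the log codes and P the cumulative
    empirical proportions of the categories.
    """
    j = cohort.column_index(variable)
    schema = cohort.schemas[j]
    if not schema.is_categorical:
        raise SchemaError(f"variable {variable!r} is continuous")
    codes = np.asarray(schema.codes, dtype=float)
    if method == "midpoint":
        boundaries = (codes[:-1] + codes[1:]) / 2.0
        return DiscretizationRule(
            variable=variable, method=method,
            boundaries=boundaries, code_offset=schema.code_offset,
        )
    if method == "lognormal_quantile":
        observed = cohort.column(variable)
        counts = np.array([(observed == c).sum() for c in codes], dtype=float)
        if (counts == 0).any():
            empty = [schema.categories[i] for i in np.flatnonzero(counts == 0)]
            raise VpopError(
                f"variable {variable!r}: zero observations for {empty}; "
                "the quantile rule is degenerate"
            )
        props = counts / counts.sum()
        logs = np.log(observed)
        mu, sd = float(logs.mean()), float(logs.std(ddof=1))
        cum = np.cumsum(props)[:-1]
        boundaries = np.array([crv(mu, sd, c) for c in cum])
        return DiscretizationRule(
            variable=variable, method=method, boundaries=boundaries,
            code_offset=schema.code_offset, proportions=props,
            mu_sigma=(mu, sd),
        )
    raise ValueError(f"unknown discretization method {method!r}")


def default_rules(cohort_or_schemas) -> dict[str, DiscretizationRule]:
    """Midpoint rules for every categorical variable."""
    schemas = (
        cohort_or_schemas.schemas
        if isinstance(cohort_or_schemas, Cohort)
        else cohort_or_schemas
    )
    rules = {}
    for s in schemas:
        if s.is_categorical:
            codes = np.asarray(s.codes, dtype=float)
            rules[s.name] = DiscretizationRule(
                variable=s.name, method="midpoint",
                boundaries=(codes[:-1] + codes[1:]) / 2.0,
                code_offset=s.code_offset,
            )
    return rules


def discretize(value, rule: DiscretizationRule):
    """Integer code for a continuous simulated value (vectorised).

    Code j is returned when boundary_{j−1} <= value < boundary_j, with
    boundary_0 = −∞ and boundary_k = +∞ — i.e. ties go to the upper code
    and the extremes are clamped.
    """
    idx = np.searchsorted(rule.boundaries, value, side="right")
    code = rule.code_offset + idx
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(code)
    return code.astype(float)


def generate(
    model: FittedJointModel,
    k: int,
    seed: int,
    rules: dict[str, DiscretizationRule] | None = None,
    id_prefix: str = "V",
) -> Cohort:
    """Sample k virtual patients from a fitted model.

    Each log-space row is μ + K Z with Z ~ N(0, I); rows are exponentiated
    (hence strictly positive), positivity offsets are removed, and
    categorical columns are discretized (midpoint rules by default).
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if rules is None:
        rules = default_rules(model.schemas)
    z = sample_latent(model.p, k, seed) if k else np.empty((0, model.p))
    log_rows = model.mu[np.newaxis, :] + z @ model.K.T
    x = np.exp(log_rows)
    values = np.empty_like(x)
    for j, s in enumerate(model.schemas):
        if s.is_categorical:
            rule = rules.get(s.name)
            if rule is None:
                raise SchemaError(f"no discretization rule for {s.name!r}")
            values[:, j] = discretize(x[:, j], rule)
        else:
            values[:, j] = x[:, j] - s.positivity_offset
    return Cohort(
        schemas=[s for s in model.schemas],
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        ids=[f"{id_prefix}{i + 1:05d}" for i in range(k)],
    )


def provenance(model: FittedJointModel, k: int, seed: int,
               rule_method: str = "midpoint") -> dict:
    """Provenance record written next to a generated cohort."""
    digest = hashlib.sha256(
        json.dumps({"mu": model.mu.tolist(), "sigma": model.sigma.tolist()},
                   sort_keys=True).encode()
    ).hexdigest()[:16]
    return {"seed": seed, "n_generated": k, "model_hash": digest,
            "rule_method": rule_method, "backend": model.backend}
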