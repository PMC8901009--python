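"""Probabilistic record linkage of clinical and geometry records.

Three tables take part: A (virtual clinical records), B (arterial geometry
records) and C, the bridge cohort carrying both kinds of features.  Each
(A, C) and (B, C) record pair receives a scalar matching weight — a
Fellegi–Sunter-style sum of per-field agreement/disagreement weights.  For
every bridge record c_k, the candidate sets V_AC^k and V_BC^k collect the
A and B records whose weight strictly exceeds the thresholds Ŵ_AC and
Ŵ_BC.  The assembled virtual population is C itself (re-keyed, provenance
"bridge") plus, for each c_k, the Cartesian product V_AC^k × V_BC^k of
clinical-with-geometry records (provenance "linked"), so its size is
|C| + Σ_k |V_AC^k|·|V_BC^k|.  Lowering the thresholds is the intended way
to widen variety; no noise is injected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "FieldComparison",
    "LinkageConfig",
    "CandidateSets",
    "VirtualPopulation",
    "matching_weight",
    "build_candidate_sets",
    "assemble",
    "weights_from_mu_probabilities",
]


@dataclass
class FieldComparison:
    """One compared field: comparator plus agreement/disagreement weights.

    ``comparator`` is ``"exact"`` (equality, used for categorical fields) or
    ``"numeric"`` (|a − c| <= tolerance).  A record pair where either side
    is missing the field contributes 0 to the total weight.
    """

    field: str
    comparator: str = "exact"
    agreement_weight: float = 1.0
    disagreement_weight: float = -1.0
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.comparator not in ("exact", "numeric"):
            raise ConfigError(f"unknown comparator {self.comparator!r}")
        if not self.agreement_weight > self.disagreement_weight:
            raise ConfigError(
                f"field {self.field!r}: agreement weight must exceed "
                "disagreement weight"
            )
        if self.tolerance < 0:
            raise ConfigError(f"field {self.field!r}: negative tolerance")

    def to_dict(self) -> dict:
        return {
            "field": self.field, "comparator": self.comparator,
            "agreement_weight": self.agreement_weight,
            "disagreement_weight": self.disagreement_weight,
            "tolerance": self.tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldComparison":
        return cls(
            field=d["field"], comparator=d.get("comparator", "exact"),
            agreement_weight=float(d.get("agreement_weight", 1.0)),
            disagreement_weight=float(d.get("disagreement_weight", -1.0)),
            tolerance=float(d.get("tolerance", 0.0)),
        )


@dataclass
class LinkageConfig:
    """Thresholds Ŵ_AC, Ŵ_BC and the compared-field lists for each pairing."""

    threshold_ac: float
    threshold_bc: float
    fields_ac: list[FieldComparison]
    fields_bc: list[FieldComparison]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold_AC": self.threshold_ac,
            "threshold_BC": self.threshold_bc,
            "compared_fields_AC": [f.to_dict() for f in self.fields_ac],
            "compared_fields_BC": [f.to_dict() for f in self.fields_bc],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinkageConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            threshold_ac=float(d["threshold_AC"]),
            threshold_bc=float(d["threshold_BC"]),
            fields_ac=[FieldComparison.from_dict(f) for f in d["compared_fields_AC"]],
            fields_bc=[FieldComparison.from_dict(f) for f in d["compared_fields_BC"]],
        )


def weights_from_mu_probabilities(m: float, u: float) -> tuple[float, float]:
    """Fellegi–Sunter log2 weights from a field's m- and u-probabilities.

    m = P(field agrees | records truly match), u = P(agrees | non-match).
    Returns (agreement_weight, disagreement_weight) =
    (log2(m/u), log2((1−m)/(1−u))).
    """
    if not (0 < m < 1 and 0 < u < 1):
        raise ConfigError("m and u probabilities must lie strictly in (0, 1)")
    if m <= u:
        raise ConfigError("m must exceed u for the field to be informative")
    return math.log2(m / u), math.log2((1 - m) / (1 - u))


def _missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def matching_weight(
    record_a: Mapping, record_c: Mapping, fields: Sequence[FieldComparison]
) -> float:
    """Additive matching weight between two records over the compared fields."""
    total = 0.0
    for f in fields:
        a, c = record_a.get(f.field), record_c.get(f.field)
        if _missing(a) or _missing(c):
            continue
        if f.comparator == "numeric":
            agree = abs(float(a) - float(c)) <= f.tolerance
        else:
            agree = a == c
        total += f.agreement_weight if agree else f.disagreement_weight
    return total


@dataclass
class CandidateSets:
    """Per-bridge-record candidate sets and the full weight matrices."""

    w_ac: np.ndarray  # (|A|, |C|)
    w_bc: np.ndarray  # (|B|, |C|)
    v_ac: list[list[int]] = field(default_factory=list)  # A row indices per c_k
    v_bc: list[list[int]] = field(default_factory=list)  # B row indices per c_k

    @property
    def linked_count(self) -> int:
        return sum(len(a) * len(b) for a, b in zip(self.v_ac, self.v_bc))


def _check_fields(df: pd.DataFrame, fields: Sequence[FieldComparison],
                  table: str) -> None:
    for f in fields:
        if f.field not in df.columns:
            raise ConfigError(f"compared field {f.field!r} absent from table {table}")


def build_candidate_sets(
    a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame, config: LinkageConfig
) -> CandidateSets:
    """Weight every (A, C) and (B, C) pair and threshold strictly.

    A record enters V_AC^k only if its weight is strictly above Ŵ_AC
    (ties excluded); likewise for V_BC^k.
    """
    _check_fields(a, config.fields_ac, "A")
    _check_fields(c, config.fields_ac, "C")
    _check_fields(b, config.fields_bc, "B")
    _check_fields(c, config.fields_bc, "C")
    a_recs = a.to_dict("records")
    b_recs = b.to_dict("records")
    c_recs = c.to_dict("records")
    w_ac = np.array(
        [[matching_weight(ra, rc, config.fields_ac) for rc in c_recs]
         for ra in a_recs]
    ).reshape(len(a_recs), len(c_recs))
    w_bc = np.array(
        [[matching_weight(rb, rc, config.fields_bc) for rc in c_recs]
         for rb in b_recs]
    ).reshape(len(b_recs), len(c_recs))
    v_ac = [list(np.flatnonzero(w_ac[:, k] > config.threshold_ac))
            for k in range(len(c_recs))]
    v_bc = [list(np.flatnonzero(w_bc[:, k] > config.threshold_bc))
            for k in range(len(c_recs))]
    return CandidateSets(w_ac=w_ac, w_bc=w_bc, v_ac=v_ac, v_bc=v_bc)


@dataclass
class VirtualPopulation:
    """Assembled population: bridge records plus linked clinical×geometry pairs."""

    records: pd.DataFrame
    counts: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.records)


def assemble(
    a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame, config: LinkageConfig
) -> VirtualPopulation:
    """Assemble the virtual population.

    The output holds one record per de-identified bridge row (provenance
    ``"bridge"``) and one per element of V_AC^k × V_BC^k for each bridge row
    (provenance ``"linked"``), with clinical fields taken unchanged from A
    and geometry fields unchanged from B.  Clashing column names get a
    ``_geom`` suffix on the geometry side.
    """
    sets = build_candidate_sets(a, b, c, config)
    geom_cols = [col for col in b.columns]
    clin_cols = [col for col in a.columns]
    rename_geom = {
        col: f"{col}_geom" for col in geom_cols if col in clin_cols
    }
    rows: list[dict] = []
    for k, rec in enumerate(c.to_dict("records")):
        row = dict(rec)
        row["record_id"] = f"C{k + 1:05d}"
        row["provenance"] = "bridge"
        rows.append(row)
    n_linked = 0
    for k in range(len(c)):
        for ia in sets.v_ac[k]:
            clin = a.iloc[ia].to_dict()
            for ib in sets.v_bc[k]:
                geom = b.iloc[ib].to_dict()
                row = dict(clin)
                for col, val in geom.items():
                    row[rename_geom.get(col, col)] = val
                n_linked += 1
                row["record_id"] = f"L{n_linked:06d}"
                row["provenance"] = "linked"
                row["bridge_index"] = k
                rows.append(row)
    records = pd.DataFrame(rows)
    pop = VirtualPopulation(
        records=records,
        counts={"bridge": len(c), "linked": n_linked},
    )
    assert pop.size == len(c) + sets.linked_count
    return pop
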