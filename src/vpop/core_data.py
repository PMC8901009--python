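"""Cohort container, variable schemas, categorical encoding and CSV/JSON I/O.

A cohort is a patient-by-covariate table.  Continuous covariates are stored
as floats; categorical covariates are stored as their integer codes
(consecutive, starting at ``code_offset``, default 1 — codes must stay
strictly positive because the modelling pipeline takes logarithms of them).
Missing cells are tracked by an explicit boolean mask, never by sentinel
numbers.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

ID_COLUMN = "patient_id"

__all__ = [
    "VariableSchema",
    "Cohort",
    "read_schema",
    "write_schema",
    "read_cohort",
    "write_cohort",
    "encode",
]


@dataclass
class VariableSchema:
    """Describes one covariate: its kind, categories and transforms.

    Parameters
    ----------
    name
        Column name as it appears in the CSV header.
    kind
        ``"continuous"`` or ``"categorical"``.
    categories
        Ordered category labels (categorical only).  Label ``categories[i]``
        is encoded as integer code ``code_offset + i``.
    code_offset
        Integer code of the first category.  Defaults to 1 so codes are
        strictly positive and can be log-transformed.
    positivity_offset
        Non-negative shift added to a continuous covariate before the
        log-transform, and removed again on output, so that every observed
        value is strictly positive.
    """

    name: str
    kind: str
    categories: list[str] | None = None
    code_offset: int = 1
    positivity_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories or len(self.categories) < 2:
                raise SchemaError(
                    f"categorical variable {self.name!r} needs >= 2 categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"variable {self.name!r}: duplicate category labels")
        if self.positivity_offset < 0:
            raise SchemaError(f"variable {self.name!r}: negative positivity_offset")

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"

    @property
    def n_categories(self) -> int:
        return len(self.categories) if self.categories else 0

    @property
    def codes(self) -> list[int]:
        """Integer codes, consecutive from ``code_offset``."""
        return [self.code_offset + i for i in range(self.n_categories)]

    def code_of(self, label: str) -> int:
        try:
            return self.code_offset + self.categories.index(label)
        except (ValueError, AttributeError):
            raise SchemaError(
                f"variable {self.name!r}: unknown category label {label!r}"
            ) from None

    def label_of(self, code: int) -> str:
        i = int(round(code)) - self.code_offset
        if self.categories is None or not 0 <= i < len(self.categories):
            raise SchemaError(f"variable {self.name!r}: invalid code {code!r}")
        return self.categories[i]

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "kind": self.kind}
        if self.is_categorical:
            d["categories"] = list(self.categories)
            if self.code_offset != 1:
                d["code_offset"] = self.code_offset
        else:
            if self.positivity_offset:
                d["positivity_offset"] = self.positivity_offset
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        return cls(
            name=d["name"],
            kind=d["kind"],
            categories=list(d["categories"]) if d.get("categories") else None,
            code_offset=int(d.get("code_offset", 1)),
            positivity_offset=float(d.get("positivity_offset", 0.0)),
        )


@dataclass
class Cohort:
    """A patient-by-covariate table with an explicit missing-cell mask.

    ``values`` is an (n, p) float array.  Categorical cells hold integer
    codes; continuous cells hold raw (unshifted) values.  ``mask`` is an
    (n, p) boolean array, True where the cell is missing; masked cells of
    ``values`` are NaN.
    """

    schemas: list[VariableSchema]
    values: np.ndarray
    mask: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise SchemaError("values and mask must be 2-D arrays of equal shape")
        if self.values.shape[1] != len(self.schemas):
            raise SchemaError(
                f"{self.values.shape[1]} columns but {len(self.schemas)} schemas"
            )
        if not self.ids:
            self.ids = [f"P{i + 1:04d}" for i in range(self.values.shape[0])]
        if len(self.ids) != self.values.shape[0]:
            raise SchemaError("one id required per row")
        self.values = self.values.copy()
        self.values[self.mask] = np.nan
        # non-missing categorical cells must decode to a valid label
        for j, s in enumerate(self.schemas):
            if s.is_categorical:
                col = self.values[~self.mask[:, j], j]
                valid = set(s.codes)
                bad = [v for v in col if int(round(v)) not in valid]
                if bad:
                    raise SchemaError(
                        f"variable {s.name!r}: invalid code(s) {sorted(set(bad))}"
                    )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.schemas]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def column_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"no variable named {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        """Non-missing values of one variable."""
        j = self.column_index(name)
        return self.values[~self.mask[:, j], j]

    def copy(self) -> "Cohort":
        return Cohort(
            schemas=[replace(s) for s in self.schemas],
            values=self.values.copy(),
            mask=self.mask.copy(),
            ids=list(self.ids),
        )

    def to_dataframe(self, decode: bool = True) -> pd.DataFrame:
        """Render as a DataFrame; categorical codes become labels if *decode*."""
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, ID_COLUMN, self.ids)
        if decode:
            for s in self.schemas:
                if s.is_categorical:
                    df[s.name] = [
                        s.label_of(v) if not math.isnan(v) else None
                        for v in df[s.name]
                    ]
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.names == other.names
            and self.ids == other.ids
            and np.array_equal(self.mask, other.mask)
            and np.allclose(
                np.nan_to_num(self.values), np.nan_to_num(other.values)
            )
        )


def read_schema(path: str | Path) -> list[VariableSchema]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise FormatError("schema file must contain a JSON list")
    return [VariableSchema.from_dict(d) for d in raw]


def write_schema(schemas: Sequence[VariableSchema], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([s.to_dict() for s in schemas], fh, indent=2)
        fh.write("\n")


_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def _is_missing(token: str) -> bool:
    return token.strip().lower() in _MISSING_TOKENS


def read_cohort(path: str | Path, schema_path: str | Path) -> Cohort:
    """Read a cohort CSV against its JSON schema.

    The CSV is comma-separated UTF-8 with a header row; the first column is
    the patient id.  Categorical labels are encoded to integer codes; empty
    or NA cells become missing.  A continuous column whose observed minimum
    is <= 0 (after its declared offset) gets an automatic
    ``positivity_offset = 1 - min`` recorded in the returned schema.
    """
    schemas = read_schema(schema_path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        rows = list(reader)

    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"{path}: duplicate column(s) {dupes}")
    if header[0] != ID_COLUMN:
        raise FormatError(f"{path}: first column must be {ID_COLUMN!r}")
    expected = [ID_COLUMN] + [s.name for s in schemas]
    if header != expected:
        raise SchemaError(
            f"{path}: header {header} does not match schema columns {expected}"
        )

    n, p = len(rows), len(schemas)
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    ids = []
    for i, row in enumerate(rows):
        if len(row) != p + 1:
            raise FormatError(f"{path}: row {i + 2} has {len(row)} cells, expected {p + 1}")
        ids.append(row[0])
        for j, s in enumerate(schemas):
            token = row[j + 1]
            if _is_missing(token):
                mask[i, j] = True
            elif s.is_categorical:
                try:
                    values[i, j] = s.code_of(token.strip())
                except SchemaError:
                    raise SchemaError(
                        f"{path}: row {i + 2}, column {s.name!r}: "
                        f"unknown category label {token!r}"
                    ) from None
            else:
                try:
                    values[i, j] = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: row {i + 2}, column {s.name!r}: "
                        f"not a number: {token!r}"
                    ) from None

    # auto positivity offset for continuous columns touching zero or below
    for j, s in enumerate(schemas):
        if not s.is_categorical:
            col = values[~mask[:, j], j]
            if col.size and col.min() + s.positivity_offset <= 0:
                s.positivity_offset = 1.0 - float(col.min())
    return Cohort(schemas=schemas, values=values, mask=mask, ids=ids)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV (labels for categoricals, empty string for missing)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([ID_COLUMN] + cohort.names)
        for i in range(cohort.n):
            row: list[str] = [cohort.ids[i]]
            for j, s in enumerate(cohort.schemas):
                if cohort.mask[i, j]:
                    row.append("")
                elif s.is_categorical:
                    row.append(s.label_of(cohort.values[i, j]))
                else:
                    row.append(repr(float(cohort.values[i, j])))
            writer.writerow(row)


def encode(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Numeric (n, p) matrix plus missing mask, ready for the log-transform.

    Categorical cells keep their integer codes; continuous cells are shifted
    by their ``positivity_offset`` so every unmasked entry is strictly
    positive.  The mask is returned alongside (True = missing).
    """
    matrix = cohort.values.copy()
    for j, s in enumerate(cohort.schemas):
        if not s.is_categorical and s.positivity_offset:
            matrix[:, j] = matrix[:, j] + s.positivity_offset
    return matrix, cohort.mask.copy()


def decode_matrix(
    matrix: np.ndarray,
    schemas: Sequence[VariableSchema],
    ids: Iterable[str] | None = None,
) -> Cohort:
    """Inverse of :func:`encode` for complete matrices: undo the positivity
    offsets and wrap as a Cohort (categorical cells must already be codes)."""
    values = np.asarray(matrix, dtype=float).copy()
    for j, s in enumerate(schemas):
        if not s.is_categorical and s.positivity_offset:
            values[:, j] = values[:, j] - s.positivity_offset
    mask = np.isnan(values)
    return Cohort(
        schemas=list(schemas),
        values=values,
        mask=mask,
        ids=list(ids) if ids is not None else [],
    )
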