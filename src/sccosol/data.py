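"""Solubility measurement containers and delimited-text I/O.

A measurement couples an operating point (temperature in K, pressure in
MPa, pure-CO2 density in kg/m3) with the observed solute mole fraction
``y2``.  Datasets are one drug's ordered collection of measurements.

On disk a dataset file is comma-separated UTF-8 text with '#' comment
lines and the exact header

    drug_id,T_K,P_MPa,rho_kg_m3,y2

holding one or more drugs; readers group rows by drug preserving order,
and writers print numbers with 12 significant digits so a write/read
round trip is lossless at the precision that matters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "OperatingPoint",
    "SolubilityRecord",
    "SolubilityDataset",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
]

COLUMNS = ("drug_id", "T_K", "P_MPa", "rho_kg_m3", "y2")


class SchemaError(ValueError):
    """The file header does not match the expected column names."""


class ValidationError(ValueError):
    """One or more rows violate the dataset invariants."""


@dataclass(frozen=True)
class OperatingPoint:
    """One (T, P, rho) state: kelvin, MPa, kg/m3; all strictly positive."""

    T: float
    P: float
    rho: float

    def __post_init__(self):
        for name in ("T", "P", "rho"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


class SolubilityRecord(NamedTuple):
    drug_id: str
    T: float
    P: float
    rho: float
    y2: float


@dataclass
class SolubilityDataset:
    """One drug's solubility measurements as aligned arrays.

    Invariants: equal-length positive arrays; y2 strictly positive (the
    AARD objective divides by it).
    """

    drug_id: str
    T: np.ndarray
    P: np.ndarray
    rho: np.ndarray
    y2: np.ndarray
    source: str = field(default="")

    def __post_init__(self):
        self.T = np.atleast_1d(np.asarray(self.T, dtype=float))
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.y2 = np.atleast_1d(np.asarray(self.y2, dtype=float))
        n = len(self.T)
        if not (len(self.P) == len(self.rho) == len(self.y2) == n) or n == 0:
            raise ValueError("T, P, rho, y2 must be equal-length and nonempty")
        for name in ("T", "P", "rho", "y2"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                bad = np.flatnonzero(~(np.isfinite(arr) & (arr > 0)))
                raise ValidationError(
                    f"{name} must be finite and positive; offending record "
                    f"indices: {bad.tolist()}"
                )

    @property
    def nobs(self) -> int:
        return len(self.y2)

    def __len__(self) -> int:
        return self.nobs

    def records(self) -> Iterator[SolubilityRecord]:
        for i in range(self.nobs):
            yield SolubilityRecord(
                self.drug_id, self.T[i], self.P[i], self.rho[i], self.y2[i]
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, drug_id: str | None = None,
                       source: str = "") -> "SolubilityDataset":
        """Build a dataset from a DataFrame with the standard columns."""
        missing = [c for c in COLUMNS[1:] if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if drug_id is None:
            if "drug_id" not in df.columns:
                raise SchemaError("drug_id column absent and no drug_id given")
            ids = df["drug_id"].unique()
            if len(ids) != 1:
                raise ValueError(
                    f"dataframe holds {len(ids)} drugs; pass drug_id or use "
                    "read_dataset-style grouping"
                )
            drug_id = str(ids[0])
        return cls(
            drug_id=drug_id,
            T=df["T_K"].to_numpy(),
            P=df["P_MPa"].to_numpy(),
            rho=df["rho_kg_m3"].to_numpy(),
            y2=df["y2"].to_numpy(),
            source=source,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": self.drug_id,
                "T_K": self.T,
                "P_MPa": self.P,
                "rho_kg_m3": self.rho,
                "y2": self.y2,
            }
        )


def read_dataset(path) -> dict[str, SolubilityDataset]:
    """Read a dataset file, grouping records by drug_id (order preserved).

    Malformed or invalid rows are reported with their 1-based line numbers.
    """
    groups: dict[str, dict[str, list]] = {}
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = None
        for row in reader:
            if not row or row[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = tuple(c.strip() for c in row)
                if header != COLUMNS:
                    raise SchemaError(
                        f"expected header {','.join(COLUMNS)!r}, "
                        f"got {','.join(header)!r} (line {reader.line_num})"
                    )
                continue
            if len(row) != len(COLUMNS):
                problems.append(
                    f"line {reader.line_num}: expected {len(COLUMNS)} fields, "
                    f"got {len(row)}"
                )
                continue
            drug = row[0].strip()
            try:
                vals = [float(x) for x in row[1:]]
            except ValueError:
                problems.append(f"line {reader.line_num}: non-numeric field")
                continue
            if not all(np.isfinite(v) and v > 0 for v in vals):
                problems.append(
                    f"line {reader.line_num}: all of T_K, P_MPa, rho_kg_m3, y2 "
                    "must be finite and positive"
                )
                continue
            g = groups.setdefault(
                drug, {"T": [], "P": [], "rho": [], "y2": []}
            )
            for key, v in zip(("T", "P", "rho", "y2"), vals):
                g[key].append(v)
    if header is None:
        raise SchemaError(f"{path}: no header row found")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    if not groups:
        raise ValidationError(f"{path}: no data rows")
    return {
        drug: SolubilityDataset(drug_id=drug, source=str(path), **arrays)
        for drug, arrays in groups.items()
    }


def write_dataset(datasets, path, comment: str | None = None) -> None:
    """Write one dataset or an iterable/mapping of datasets to CSV."""
    if isinstance(datasets, SolubilityDataset):
        datasets = [datasets]
    elif isinstance(datasets, dict):
        datasets = list(datasets.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(",".join(COLUMNS) + "\n")
        for ds in datasets:
            for rec in ds.records():
                fh.write(
                    f"{rec.drug_id},{rec.T:.12g},{rec.P:.12g},"
                    f"{rec.rho:.12g},{rec.y2:.12g}\n"
                )
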