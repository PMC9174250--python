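"""Model comparison, ranking analysis and operating-condition optimisation.

A comparison table collects per-(drug, correlation) AARD% values plus a
pooled "overall" row; the ranking analysis converts each drug's row into
competition ranks (rank 1 = most accurate, ties share the minimum rank)
and tallies how often each correlation takes each rank.  The maximiser
scans a dense (T, P) grid of a correlation's predictions — with the CO2
density supplied by a user callable — to locate the operating condition
of highest solubility inside an envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import metrics
from .correlations import evaluate_y2
from .fixtures import dataset_summary, reference_aard
from .model import FitFailure

__all__ = [
    "ComparisonTable",
    "RankTable",
    "build_comparison",
    "reference_comparison",
    "rank_models",
    "MaximizeResult",
    "maximize_solubility",
]


@dataclass(frozen=True)
class ComparisonTable:
    """AARD% cells (drugs x correlations) with per-drug record counts.

    Failed cells hold NaN; the pooled ``overall`` row is the count-weighted
    mean of each column's finite cells (failures excluded with their
    counts).
    """

    cells: pd.DataFrame
    counts: pd.Series

    def __post_init__(self):
        if not self.cells.index.equals(self.counts.index):
            raise ValueError("cells and counts must share the drug index")

    @property
    def overall(self) -> pd.Series:
        """Pooled AARD% per correlation (count-weighted over finite cells)."""
        out = {}
        n = self.counts.to_numpy(dtype=float)
        for col in self.cells.columns:
            a = self.cells[col].to_numpy(dtype=float)
            if np.isfinite(a).any():
                out[col] = metrics.aggregate_overall(a, n)
            else:
                out[col] = np.nan  # every cell failed
        return pd.Series(out, name="overall")

    def with_overall(self) -> pd.DataFrame:
        """Cells with the pooled row appended (the printed-table layout)."""
        return pd.concat([self.cells, self.overall.to_frame().T])

    def to_csv(self, path) -> None:
        df = self.with_overall().copy()
        df.insert(0, "n_data", list(self.counts) + [int(self.counts.sum())])
        df.to_csv(path, index_label="drug_id", float_format="%.10g")


def build_comparison(fit_matrix: dict, counts=None) -> ComparisonTable:
    """Assemble a ComparisonTable from a fit_all result matrix.

    ``fit_matrix`` maps (drug_id, model_id) to SolubilityResults or
    FitFailure; failures become NaN cells.  Counts default to each drug's
    dataset size.
    """
    if not fit_matrix:
        raise ValueError("empty fit matrix")
    drugs = list(dict.fromkeys(d for d, _ in fit_matrix))
    models = list(dict.fromkeys(m for _, m in fit_matrix))
    cells = pd.DataFrame(np.nan, index=drugs, columns=models)
    inferred_counts = {}
    for (drug, mid), res in fit_matrix.items():
        if isinstance(res, FitFailure):
            continue
        cells.loc[drug, mid] = res.aard
        inferred_counts[drug] = res.nobs
    if counts is None:
        counts = inferred_counts
    counts = pd.Series({d: counts[d] for d in drugs}, dtype=float)
    return ComparisonTable(cells=cells, counts=counts)


def reference_comparison() -> ComparisonTable:
    """The packaged published AARD% matrix as a ComparisonTable."""
    cells = reference_aard()
    counts = dataset_summary()["n_data"].astype(float)
    return ComparisonTable(cells=cells, counts=counts.loc[cells.index])


@dataclass(frozen=True)
class RankTable:
    """Per-drug competition ranks and the per-correlation rank histogram."""

    ranks: pd.DataFrame

    @property
    def rank_counts(self) -> pd.DataFrame:
        """Histogram: rows = correlations, columns = rank, values = #drugs."""
        n_models = self.ranks.shape[1]
        out = pd.DataFrame(
            0, index=self.ranks.columns, columns=range(1, n_models + 1)
        )
        for mid in self.ranks.columns:
            vc = self.ranks[mid].value_counts()
            for rank, cnt in vc.items():
                out.loc[mid, int(rank)] = int(cnt)
        return out

    def first_place_count(self, model_id: str) -> int:
        return int((self.ranks[model_id] == 1).sum())


def rank_models(table: ComparisonTable) -> RankTable:
    """Competition-rank each drug's correlations by ascending AARD%.

    Ties share the minimum rank ("1,1,3"); failed (NaN) cells rank last.
    """
    cells = table.cells
    if cells.shape[0] < 1 or cells.shape[1] < 2:
        raise ValueError("ranking needs at least one drug and two models")
    filled = cells.fillna(np.inf)
    ranks = filled.rank(axis=1, method="min", ascending=True).astype(int)
    return RankTable(ranks=ranks)


class MaximizeResult(NamedTuple):
    T: float
    P: float
    y2: float


def maximize_solubility(model_id, coeffs, T_bounds, P_bounds, rho_fn,
                        n_grid: int = 201, mw_drug=None) -> MaximizeResult:
    """Grid-search the (T, P) box for the condition of maximum solubility.

    Evaluates the correlation on a dense ``n_grid`` x ``n_grid`` lattice
    with rho = rho_fn(T, P) and returns the maximising point and value.
    """
    if hasattr(coeffs, "a"):
        coeffs = coeffs.a
    T_lo, T_hi = map(float, T_bounds)
    P_lo, P_hi = map(float, P_bounds)
    if not (T_lo < T_hi and P_lo < P_hi):
        raise ValueError("bounds must satisfy lo < hi")
    T = np.linspace(T_lo, T_hi, n_grid)
    P = np.linspace(P_lo, P_hi, n_grid)
    TT, PP = np.meshgrid(T, P, indexing="ij")
    rho = np.asarray(rho_fn(TT, PP), dtype=float)
    y = np.asarray(
        evaluate_y2(model_id, coeffs, TT, PP, rho, mw_drug=mw_drug), dtype=float
    )
    y = np.where(np.isfinite(y), y, -np.inf)
    if not np.isfinite(y).any():
        raise RuntimeError(
            "correlation is non-finite over the whole grid; check the "
            "coefficients and the density surface"
        )
    i, j = np.unravel_index(np.argmax(y), y.shape)
    return MaximizeResult(T=float(TT[i, j]), P=float(PP[i, j]),
                          y2=float(y[i, j]))
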