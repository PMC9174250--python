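"""Outlier diagnostics (Williams plot/leverage method) and relevancy analysis.

The leverage method cross-plots standardized residuals SR against hat
(leverage) values.  Residual errors RE_i = y_exp_i - y_cal_i are
standardized by their population standard deviation,

    SR_i = RE_i / sqrt((1/N) * sum_j (RE_j - mean(RE))^2),

and leverage is the diagonal of the projection (hat) matrix of a design
matrix X, H = X (X'X)^-1 X'.  A record is flagged suspect when |SR| > 3
or its leverage exceeds the warning value H* = 3(k+1)/N — the standard
Williams-plot applicability-domain convention.  Because the correlations
are nonlinear in their coefficients, the design matrix defaults to the
input variables with an intercept, [1, T, P, rho].

Relevancy analysis reports the Pearson (linear) and Spearman (monotone,
average-rank ties) correlation of the solubility with each of T, P and
rho, each a factor in [-1, 1]; a larger |Spearman| than |Pearson| for a
variable indicates a predominantly non-linear dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import SolubilityDataset

__all__ = [
    "LeverageReport",
    "standardized_residuals",
    "hat_values",
    "williams_classify",
    "leverage_design",
    "relevancy",
]


def standardized_residuals(y_exp, y_cal):
    """Residuals centered and scaled by their population (1/N) SD.

    SR_i = (RE_i - mean(RE)) / SD with RE = y_exp - y_cal; the returned
    vector has mean 0 and population SD 1 by construction.  Raises if all
    residuals are equal (zero SD).
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape or y_exp.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 records")
    re = y_exp - y_cal
    centered = re - re.mean()
    sd = float(np.sqrt(np.mean(centered**2)))
    if sd == 0.0:
        raise ValueError("all residuals identical: standard deviation is zero")
    return centered / sd


def hat_values(design):
    """Diagonal of the hat matrix H = X (X'X)^-1 X' of a full-rank design.

    Computed from the thin QR factorisation (h_i = ||Q_i||^2), which is
    numerically safer than forming the normal equations.  Values lie in
    [0, 1] and sum to the number of columns k.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    n, k = X.shape
    if k > n:
        raise ValueError(f"more columns ({k}) than rows ({n})")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; drop collinear columns"
        )
    Q, _ = np.linalg.qr(X, mode="reduced")
    return np.einsum("ij,ij->i", Q, Q)


def leverage_design(dataset: SolubilityDataset):
    """Default leverage design matrix: columns [1, T, P, rho]."""
    return np.column_stack(
        [np.ones(dataset.nobs), dataset.T, dataset.P, dataset.rho]
    )


@dataclass(frozen=True)
class LeverageReport:
    """Williams-plot classification of a dataset's records."""

    hat: np.ndarray
    sr: np.ndarray
    hat_limit: float
    sr_limit: float
    flags: np.ndarray  # "valid" / "outlier" per record

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.flags == "outlier"))

    @property
    def valid_fraction(self) -> float:
        """Percentage of records classified valid."""
        return 100.0 * float(np.mean(self.flags == "valid"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hat": self.hat, "sr": self.sr, "flag": self.flags})


def williams_classify(sr, hat, k, sr_limit=3.0):
    """Classify records as valid/outlier from SR and leverage.

    A record is an outlier when |SR| > sr_limit (default 3) or when its
    hat value exceeds the warning leverage H* = 3(k+1)/N, with k the
    number of explanatory variables (design columns excluding the
    intercept; k = 3 for the default [1, T, P, rho] design).
    """
    sr = np.asarray(sr, dtype=float)
    hat = np.asarray(hat, dtype=float)
    if sr.shape != hat.shape:
        raise ValueError("sr and hat must have equal length")
    n = sr.size
    hat_limit = 3.0 * (k + 1) / n
    outlier = (np.abs(sr) > sr_limit) | (hat > hat_limit)
    flags = np.where(outlier, "outlier", "valid")
    return LeverageReport(
        hat=hat, sr=sr, hat_limit=hat_limit, sr_limit=sr_limit, flags=flags
    )


def relevancy(datasets, method: str = "both") -> pd.DataFrame:
    """Pearson/Spearman relevancy of y2 with T, P and rho.

    Parameters
    ----------
    datasets : SolubilityDataset or iterable of SolubilityDataset
        Pooled before computing factors (the default analysis pools every
        drug's records into one collection).
    method : {"both", "pearson", "spearman"}

    Returns
    -------
    DataFrame indexed by feature (T, P, rho) with one column per method.
    """
    if isinstance(datasets, SolubilityDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets given")
    T = np.concatenate([d.T for d in datasets])
    P = np.concatenate([d.P for d in datasets])
    rho = np.concatenate([d.rho for d in datasets])
    y2 = np.concatenate([d.y2 for d in datasets])
    if y2.size < 3:
        raise ValueError("relevancy needs at least 3 records")
    features = {"T": T, "P": P, "rho": rho}
    methods = ("pearson", "spearman") if method == "both" else (method,)
    out = {}
    for m in methods:
        fn = stats.pearsonr if m == "pearson" else stats.spearmanr
        vals = []
        for name, x in features.items():
            if np.ptp(x) == 0:
                raise ValueError(f"feature {name} has zero variance")
            vals.append(float(fn(x, y2)[0] if m == "pearson" else fn(x, y2).statistic))
        out[m] = vals
    return pd.DataFrame(out, index=list(features))
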