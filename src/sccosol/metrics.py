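"""Goodness-of-fit metrics for solubility correlations.

The central quantity is the absolute average relative deviation

    AARD% = (100/N) * sum_i |y_exp_i - y_cal_i| / y_exp_i,

which serves both as the fitting objective and as the comparison metric
between correlations.  Relative (not absolute) deviations are essential
here: solubilities span four orders of magnitude, so a squared-error
criterion would let the most soluble drug dominate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "aard",
    "r2",
    "relative_deviations",
    "std_error",
    "aggregate_overall",
    "improvement_pct",
]


def _as_pair(y_exp, y_cal):
    y_exp = np.asarray(y_exp, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    if y_exp.shape != y_cal.shape:
        raise ValueError("y_exp and y_cal must have the same shape")
    if np.any(y_exp <= 0):
        raise ValueError("experimental values must be positive")
    return y_exp, y_cal


def relative_deviations(y_exp, y_cal):
    """Per-record relative deviation RD_i = (y_exp_i - y_cal_i)/y_exp_i."""
    y_exp, y_cal = _as_pair(y_exp, y_cal)
    return (y_exp - y_cal) / y_exp


def aard(y_exp, y_cal):
    """Absolute average relative deviation in percent (>= 0)."""
    return 100.0 * float(np.mean(np.abs(relative_deviations(y_exp, y_cal))))


def r2(y_exp, y_cal):
    """Coefficient of determination 1 - SS_res/SS_tot (== 1 iff exact)."""
    y_exp, y_cal = _as_pair(y_exp, y_cal)
    if y_exp.size < 2:
        raise ValueError("r2 needs at least two records")
    ss_tot = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_exp has zero variance")
    ss_res = float(np.sum((y_exp - y_cal) ** 2))
    return 1.0 - ss_res / ss_tot


def std_error(y_exp, y_cal):
    """Root-mean-square residual sqrt(sum (y_exp-y_cal)^2 / n), y2 units."""
    y_exp, y_cal = _as_pair(y_exp, y_cal)
    if y_exp.size < 2:
        raise ValueError("std_error needs at least two records")
    return float(np.sqrt(np.mean((y_exp - y_cal) ** 2)))


def aggregate_overall(per_group_aard, per_group_n):
    """Pool per-group AARD% values into one overall AARD%.

    The pooled value is the count-weighted mean sum(aard_i*n_i)/sum(n_i),
    i.e. exactly the AARD that would result from concatenating the groups'
    records.  Groups with a missing (NaN) AARD are excluded together with
    their counts.
    """
    a = np.asarray(per_group_aard, dtype=float)
    n = np.asarray(per_group_n, dtype=float)
    if a.shape != n.shape or a.size == 0:
        raise ValueError("need equal-length, nonempty AARD and count vectors")
    if np.any(n <= 0):
        raise ValueError("counts must be positive")
    keep = np.isfinite(a)
    if not keep.any():
        raise ValueError("no finite group AARD values to pool")
    return float(np.sum(a[keep] * n[keep]) / np.sum(n[keep]))


def improvement_pct(aard_ref, aard_new):
    """Relative accuracy improvement 100*(aard_ref - aard_new)/aard_new."""
    if aard_new <= 0:
        raise ValueError("aard_new must be positive")
    return 100.0 * (aard_ref - aard_new) / aard_new
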