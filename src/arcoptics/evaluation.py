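"""Algorithm-evaluation statistics for retrieved-versus-measured pairs.

RMSE is computed in log10 space; MAE and bias in linear space as defined
(a documented log-space option exists because published evaluation tables
in this field are sometimes log10-space); r^2, slope and intercept come from
an OLS regression of log10(retrieved) on log10(measured).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PairedRetrievals:
    """Matched retrieved (Y) and in-situ measured (X) values.

    Pairs where either side is missing or non-positive are excluded on
    construction and counted in ``n_dropped``; ``n`` reflects the surviving
    pairs.
    """

    retrieved: np.ndarray
    measured: np.ndarray
    label: str = ""
    n_dropped: int = 0

    @classmethod
    def from_arrays(cls, retrieved, measured, label: str = "") -> "PairedRetrievals":
        y = np.asarray(retrieved, dtype=float)
        x = np.asarray(measured, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("retrieved and measured must be 1-D and equal length")
        ok = np.isfinite(y) & np.isfinite(x) & (y > 0) & (x > 0)
        return cls(y[ok], x[ok], label=label, n_dropped=int(np.sum(~ok)))

    @property
    def n(self) -> int:
        return int(self.retrieved.size)


@dataclass
class EvaluationStats:
    """The evaluation row for one algorithm: regression + error metrics."""

    label: str
    n: int
    r2: float
    slope: float
    intercept: float
    rmse: float
    mae: float
    bias: float


def _check_positive(pairs: PairedRetrievals) -> None:
    for name, arr in (("retrieved", pairs.retrieved), ("measured", pairs.measured)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(f"non-positive {name} value at index {bad[0]}")


def rmse_log10(pairs: PairedRetrievals) -> float:
    """Root mean square error of log10(Y) - log10(X)."""
    if pairs.n == 0:
        raise ValueError("no pairs")
    _check_positive(pairs)
    d = np.log10(pairs.retrieved) - np.log10(pairs.measured)
    return float(np.sqrt(np.mean(d**2)))


def mae(pairs: PairedRetrievals, log_space: bool = False) -> float:
    """Mean absolute error of Y - X (linear space by default).

    ``log_space=True`` computes mean |log10 Y - log10 X| instead.
    """
    if pairs.n == 0:
        raise ValueError("no pairs")
    if log_space:
        _check_positive(pairs)
        return float(np.mean(np.abs(np.log10(pairs.retrieved) - np.log10(pairs.measured))))
    return float(np.mean(np.abs(pairs.retrieved - pairs.measured)))


def bias(pairs: PairedRetrievals, log_space: bool = False) -> float:
    """Signed mean of Y - X (linear space by default; log10 option)."""
    if pairs.n == 0:
        raise ValueError("no pairs")
    if log_space:
        _check_positive(pairs)
        return float(np.mean(np.log10(pairs.retrieved) - np.log10(pairs.measured)))
    return float(np.mean(pairs.retrieved - pairs.measured))


def loglog_regression(pairs: PairedRetrievals) -> tuple[float, float, float]:
    """OLS of log10(Y) on log10(X): returns (r2, slope, intercept)."""
    if pairs.n < 2:
        raise ValueError("regression needs at least 2 pairs")
    _check_positive(pairs)
    lx = np.log10(pairs.measured)
    if np.allclose(lx, lx[0]):
        raise ValueError("degenerate X: zero variance in log10(measured)")
    res = stats.linregress(lx, np.log10(pairs.retrieved))
    return float(res.rvalue**2), float(res.slope), float(res.intercept)


def evaluate(pairs: PairedRetrievals, log_space_mae: bool = False) -> EvaluationStats:
    """All evaluation statistics for one retrieved-vs-measured pairing."""
    r2, slope, intercept = loglog_regression(pairs)
    return EvaluationStats(
        label=pairs.label,
        n=pairs.n,
        r2=r2,
        slope=slope,
        intercept=intercept,
        rmse=rmse_log10(pairs),
        mae=mae(pairs, log_space=log_space_mae),
        bias=bias(pairs, log_space=log_space_mae),
    )
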