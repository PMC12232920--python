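"""Correlation-aware preprocessing of scalar simulation time series.

Molecular-simulation observables are serially correlated, so the number of
statistically independent samples is n/g, where g >= 1 is the statistical
inefficiency.  This module estimates g from the empirical autocorrelation
function, locates the equilibrated region of a series by maximizing the
effective sample count of the retained tail, and produces decorrelated
subsample indices for downstream reweighting estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fenet.exceptions import DataError, InsufficientDataError

__all__ = [
    "Series",
    "EquilReport",
    "statistical_inefficiency",
    "detect_equilibration",
    "subsample_indices",
]

#: Relative variance below which a series is treated as numerically constant.
_CONST_RTOL = 1e-14


@dataclass(frozen=True)
class Series:
    """A scalar observable sampled at strictly increasing times.

    Parameters
    ----------
    t : array-like
        Sample times in ps, strictly increasing.
    y : array-like
        Observable value per sample (kcal/mol or unitless).
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or y.ndim != 1:
            raise DataError("Series.t and Series.y must be one-dimensional")
        if t.size != y.size:
            raise DataError(
                f"length mismatch: {t.size} times vs {y.size} values"
            )
        if t.size < 2:
            raise DataError("a Series needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise DataError("Series.t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.y.size


@dataclass(frozen=True)
class EquilReport:
    """Result of automated equilibration detection.

    Attributes
    ----------
    t0_index : int
        Index of the first sample retained as equilibrated.
    g : float
        Statistical inefficiency (in samples) of the retained region, >= 1.
    n_eff : float
        Effective number of independent samples in the retained region.
    constant : bool
        True when the retained region has (numerically) zero variance.
    """

    t0_index: int
    g: float
    n_eff: float
    constant: bool = field(default=False)


def _as_values(s) -> np.ndarray:
    if isinstance(s, Series):
        return s.y
    y = np.asarray(s, dtype=float)
    if y.ndim != 1:
        raise DataError("expected a 1-D array of observations")
    return y


def _is_constant(y: np.ndarray) -> bool:
    v = np.var(y)
    scale = max(np.mean(np.abs(y)) ** 2, 1.0)
    return v <= _CONST_RTOL * scale


def statistical_inefficiency(s) -> float:
    """Statistical inefficiency g = 1 + 2*sum_tau (1 - tau/n) * rho(tau).

    The autocorrelation rho is estimated with the biased (1/n) normalization
    and the sum stops at the first non-positive estimate, which curbs the
    noise that accumulates at long lags.  A numerically constant series is
    legal input and has g = 1 by convention (harmonic-bias energy series can
    be flat in stiff umbrella windows).

    Parameters
    ----------
    s : Series or 1-D array
        At least 4 samples.

    Returns
    -------
    float
        g >= 1, in units of sampling intervals.
    """
    y = _as_values(s)
    n = y.size
    if n < 4:
        raise InsufficientDataError(
            f"statistical_inefficiency requires n >= 4, got n = {n}"
        )
    if _is_constant(y):
        return 1.0
    dy = y - y.mean()
    c0 = float(np.dot(dy, dy)) / n
    g = 1.0
    for tau in range(1, n):
        c = float(np.dot(dy[:-tau], dy[tau:])) / n
        rho = c / c0
        if rho <= 0.0:
            break
        g += 2.0 * (1.0 - tau / n) * rho
    return max(g, 1.0)


def is_constant(s) -> bool:
    """Whether the series has numerically zero variance (the 'constant' flag)."""
    return _is_constant(_as_values(s))


def detect_equilibration(s) -> EquilReport:
    """Locate the equilibrated region of a series.

    Candidate truncation points are scanned at every 2% of the series
    (50 candidates regardless of length).  For each candidate t0 the
    statistical inefficiency g of the retained tail y[t0:] is estimated and
    the effective sample count n_eff = (n - t0)/g computed; the t0 that
    maximizes n_eff wins, ties going to the smallest t0.  An unequilibrated
    head inflates g of any tail that includes it, so n_eff peaks once the
    head is discarded.

    Parameters
    ----------
    s : Series or 1-D array with n >= 20.

    Returns
    -------
    EquilReport
    """
    y = _as_values(s)
    n = y.size
    if n < 20:
        raise InsufficientDataError(
            f"detect_equilibration requires n >= 20, got n = {n}"
        )
    candidates = sorted({(i * n) // 50 for i in range(50)})
    best = None
    any_nonconstant = False
    for t0 in candidates:
        tail = y[t0:]
        if tail.size < 4:
            continue
        if _is_constant(tail):
            continue
        any_nonconstant = True
        g = statistical_inefficiency(tail)
        n_eff = (n - t0) / g
        if best is None or n_eff > best.n_eff:
            best = EquilReport(t0_index=t0, g=g, n_eff=n_eff)
    if not any_nonconstant:
        # every candidate tail constant: series is flat, keep everything
        return EquilReport(t0_index=0, g=1.0, n_eff=float(n), constant=True)
    return best


def subsample_indices(s, g: float, t0: int = 0) -> np.ndarray:
    """Indices of approximately decorrelated samples.

    Returns t0, t0+ceil(g), t0+2*ceil(g), ... up to the series length.

    Parameters
    ----------
    s : Series, 1-D array, or int
        The series to subsample (an int is taken as its length).
    g : float
        Statistical inefficiency, >= 1.
    t0 : int
        First retained index (from :func:`detect_equilibration`).

    Raises
    ------
    InsufficientDataError
        If fewer than 2 decorrelated samples remain.
    """
    if g < 1.0:
        raise DataError(f"statistical inefficiency must be >= 1, got {g}")
    n = int(s) if isinstance(s, (int, np.integer)) else _as_values(s).size
    if not 0 <= t0 < n:
        raise DataError(f"t0 = {t0} outside series of length {n}")
    stride = int(math.ceil(g))
    idx = np.arange(t0, n, stride)
    if idx.size < 2:
        raise InsufficientDataError(
            "insufficient equilibrated data: fewer than 2 decorrelated "
            f"samples (n = {n}, t0 = {t0}, stride = {stride})"
        )
    return idx
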