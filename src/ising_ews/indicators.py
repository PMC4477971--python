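"""Metric-based early-warning indicators of a univariate time series.

Near a critical threshold a system recovers slowly from perturbations
(critical slowing down); its fluctuation time series then shows rising
variance, possible asymmetry (skewness), heavier or lighter tails (kurtosis)
and rising short-lag autocorrelation. This module computes those statistics
for one series; ensembles are aggregated by :mod:`ising_ews.experiment`.

Conventions (declared once, used everywhere):

* central moments are population moments (divide by n, no bias correction);
* skewness = m3 / m2**1.5, reported both signed and as absolute value;
* kurtosis = m4 / m2**2, i.e. non-excess, normal reference value 3;
* autocorrelation uses the biased estimator
  C(tau) = sum_{t<=n-tau}(x_t - xbar)(x_{t+tau} - xbar) / sum_t (x_t - xbar)^2,
  which satisfies |C(tau)| <= 1 for any input;
* undefined statistics (zero-variance series) are NaN, never zero.

The functions accept any numeric sequence, so the suite applies to
magnetization traces and to external data alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["IndicatorSet", "moments", "autocorrelation", "compute_indicators"]


@dataclass(frozen=True)
class IndicatorSet:
    """Early-warning summary of one series; NaN marks undefined statistics."""

    mean: float
    variance: float
    skewness: float
    abs_skewness: float
    kurtosis: float
    autocorr_lag1: float
    n_samples: int

    @property
    def is_degenerate(self) -> bool:
        """True when the series had zero variance (higher moments undefined)."""
        return self.variance == 0.0


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    return x


def _degenerate(x: np.ndarray, m2: float) -> bool:
    """Variance indistinguishable from mean-subtraction rounding noise.

    A constant series can acquire a spurious m2 ~ (eps*|x|)^2 because its
    floating-point mean differs from the common value by an ulp; moments of
    such a series are undefined, not tiny.
    """
    scale = float(np.max(np.abs(x), initial=0.0))
    # also degenerate when m2**2 would underflow (kurtosis unrepresentable)
    return m2 <= (8 * np.finfo(float).eps * scale) ** 2 or m2 < np.sqrt(
        np.finfo(float).tiny
    )


def moments(series) -> IndicatorSet:
    """First four population moments of a series (autocorrelation left NaN).

    Requires at least 4 samples. For a constant series the variance is
    reported as 0 and skewness/kurtosis are NaN.
    """
    x = _as_series(series)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    if _degenerate(x, m2):
        m2 = 0.0
        skew = kurt = float("nan")
    else:
        skew = np.mean(d**3) / m2**1.5
        kurt = np.mean(d**4) / m2**2
    return IndicatorSet(
        mean=float(mean),
        variance=float(m2),
        skewness=float(skew),
        abs_skewness=abs(float(skew)),
        kurtosis=float(kurt),
        autocorr_lag1=float("nan"),
        n_samples=n,
    )


def autocorrelation(series, lag: int) -> float:
    """Biased autocorrelation estimate C(lag); NaN for a zero-variance series.

    C(0) = 1 by construction; |C(lag)| <= 1 for every input by
    Cauchy-Schwarz. ``lag`` must satisfy 0 <= lag < n.
    """
    x = _as_series(series)
    n = len(x)
    if not 0 <= lag < n:
        raise ValueError(f"lag must satisfy 0 <= lag < {n}, got {lag}")
    d = x - x.mean()
    denom = np.sum(d**2)
    if _degenerate(x, denom / n):
        return float("nan")
    if lag == 0:
        return 1.0
    return float(np.sum(d[:-lag] * d[lag:]) / denom)


def compute_indicators(series, lag: int = 1) -> IndicatorSet:
    """Moments plus lag-``lag`` autocorrelation in one :class:`IndicatorSet`."""
    base = moments(series)
    return IndicatorSet(
        mean=base.mean,
        variance=base.variance,
        skewness=base.skewness,
        abs_skewness=base.abs_skewness,
        kurtosis=base.kurtosis,
        autocorr_lag1=autocorrelation(series, lag),
        n_samples=base.n_samples,
    )
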