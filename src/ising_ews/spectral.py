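"""Power spectral density of fluctuations and the crossover-frequency fit.

At criticality the magnetization series is temporally scale invariant and its
PSD follows a power law over all frequencies. Away from the critical point
the low-frequency end flattens to a white-noise plateau while the
high-frequency end keeps the power law; the frequency separating the two
regimes (the crossover frequency C_f) shrinks toward zero as the system
approaches criticality and is the early-warning statistic this module fits.

The fit works on the log10-log10 spectrum: a constant ``c`` for f < C_f and a
line ``a*u + b`` (u = log10 f) for f >= C_f, with no continuity constraint at
the joint; C_f is the grid frequency minimizing the total squared error, ties
broken toward the smallest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PSDEstimate",
    "CrossoverFit",
    "periodogram",
    "ensemble_psd",
    "fit_crossover",
    "fit_single_power_law",
]


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided periodogram (possibly ensemble averaged).

    ``frequencies`` is the Fourier grid j/n for j = 1 .. n//2 in cycles per
    sweep (zero frequency excluded — the mean is removed; Nyquist = 0.5 for
    even n). ``power[j]`` stores |DFT(x - xbar)_j|^2 / n without one-sided
    doubling, so Parseval reads: sum of power over the full two-sided grid,
    divided by n, equals the population variance of the series.
    """

    frequencies: np.ndarray
    power: np.ndarray
    n_series: int
    n_samples: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be 1-D of equal length")
        if not (np.diff(f) > 0).all() or f[0] <= 0 or f[-1] > 0.5:
            raise ValueError("frequencies must be strictly increasing in (0, 0.5]")
        if (p < 0).any():
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class CrossoverFit:
    """Dual-model fit of a log-log PSD.

    ``crossover_frequency`` is on the PSD frequency grid; the flat segment
    covers f < C_f at level ``flat_level`` (log10 power) and the power-law
    segment covers f >= C_f with slope ``slope`` and intercept ``intercept``
    in log10-log10 axes. ``sse`` is the summed squared error of both
    segments.
    """

    crossover_frequency: float
    flat_level: float
    slope: float
    intercept: float
    sse: float
    n_low: int
    n_high: int


def periodogram(series) -> PSDEstimate:
    """Raw periodogram of a mean-removed series on the Fourier grid.

    No tapering or segment averaging: variance reduction comes from
    ensemble averaging over independent runs (:func:`ensemble_psd`).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = len(x)
    if n < 16:
        raise ValueError(f"series too short for a periodogram: n={n} < 16")
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec[1 : n // 2 + 1]) ** 2 / n
    freqs = np.arange(1, n // 2 + 1) / n
    return PSDEstimate(frequencies=freqs, power=power, n_series=1, n_samples=n)


def ensemble_psd(psds: Sequence[PSDEstimate]) -> PSDEstimate:
    """Pointwise mean of periodograms sharing one frequency grid."""
    if not psds:
        raise ValueError("need at least one PSD")
    ref = psds[0]
    for p in psds[1:]:
        if p.n_samples != ref.n_samples or not np.array_equal(
            p.frequencies, ref.frequencies
        ):
            raise ValueError("all PSDs must share the same frequency grid")
    mean_power = np.mean([p.power for p in psds], axis=0)
    return PSDEstimate(
        frequencies=ref.frequencies.copy(),
        power=mean_power,
        n_series=sum(p.n_series for p in psds),
        n_samples=ref.n_samples,
    )


def _log_axes(psd: PSDEstimate) -> tuple[np.ndarray, np.ndarray]:
    if (psd.power <= 0).any():
        bad = int(np.argmax(psd.power <= 0))
        raise ValueError(
            f"power must be strictly positive to fit in log axes "
            f"(first offender at frequency {psd.frequencies[bad]:g})"
        )
    return np.log10(psd.frequencies), np.log10(psd.power)


def _line_sse(u: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line v = a*u + b; returns (a, b, sse)."""
    a, b = np.polyfit(u, v, 1)
    resid = v - (a * u + b)
    return float(a), float(b), float(resid @ resid)


def fit_single_power_law(psd: PSDEstimate) -> CrossoverFit:
    """One power law over the whole grid (the critical-point reference model).

    Returned as a :class:`CrossoverFit` with an empty flat segment and
    ``crossover_frequency`` at the lowest grid frequency, so its ``sse`` is
    directly comparable with the dual model's.
    """
    u, v = _log_axes(psd)
    a, b, sse = _line_sse(u, v)
    return CrossoverFit(
        crossover_frequency=float(psd.frequencies[0]),
        flat_level=float("nan"),
        slope=a,
        intercept=b,
        sse=sse,
        n_low=0,
        n_high=len(u),
    )


def fit_crossover(psd: PSDEstimate, m_min: int = 3) -> CrossoverFit:
    """Locate the crossover frequency by exhaustive scan of grid breakpoints.

    For every admissible breakpoint C_f on the frequency grid, the flat
    segment (f < C_f) is fitted by its mean log-power and the high-frequency
    segment (f >= C_f) by a least-squares line in log10-log10 axes; the
    breakpoint minimizing the summed squared error wins. Each segment must
    hold at least ``m_min`` points (``m_min >= 2`` so the line fit is
    determined). A spectrum that is a pure power law ends up with C_f at the
    smallest admissible frequency.
    """
    if m_min < 2:
        raise ValueError("m_min must be >= 2")
    u, v = _log_axes(psd)
    n = len(u)
    if n < 2 * m_min:
        raise ValueError(f"need at least {2 * m_min} grid points, got {n}")

    best: CrossoverFit | None = None
    for k in range(m_min, n - m_min + 1):  # segment 1 = [0, k), segment 2 = [k, n)
        c = float(np.mean(v[:k]))
        sse_flat = float(np.sum((v[:k] - c) ** 2))
        a, b, sse_line = _line_sse(u[k:], v[k:])
        sse = sse_flat + sse_line
        # ties (within round-off) break toward the smallest frequency
        if best is None or sse < best.sse - (1e-9 * best.sse + 1e-20):
            best = CrossoverFit(
                crossover_frequency=float(psd.frequencies[k]),
                flat_level=c,
                slope=a,
                intercept=b,
                sse=sse,
                n_low=k,
                n_high=n - k,
            )
    assert best is not None
    return best
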