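"""Mean-field companion: pitchfork bifurcation and Landau free energy.

Neglecting fluctuations, the average magnetization obeys the rate equation
``dM/dt = -M + tanh(beta*M)`` (beta in mean-field units, critical value
beta_c = 1, the slope of tanh at the origin). Expanding to cubic order gives
the normal form of a supercritical pitchfork,
``dM/dt = (beta - beta_c) M - (1/3) beta^3 M^3``, and the associated Landau
free energy is the quartic
``F(M) = C + (1/2)(beta_c - beta) M^2 + (1/12) beta^3 M^4``:
one stable state at M = 0 for beta <= beta_c splits into two symmetric
magnetized states for beta > beta_c. This is the qualitative skeleton the
lattice indicators are interpreted against; no quantitative mapping between
mean-field beta and the lattice temperature is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MeanFieldParams",
    "FixedPoint",
    "mf_rate",
    "mf_fixed_points",
    "landau_free_energy",
    "landau_stationary_points",
    "mf_consistency",
]


@dataclass(frozen=True)
class MeanFieldParams:
    """beta: inverse temperature (dimensionless); beta_c: critical value;
    free_energy_offset: the additive constant C in the Landau expansion."""

    beta: float
    beta_c: float = 1.0
    free_energy_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")


@dataclass(frozen=True)
class FixedPoint:
    value: float
    stability: str  # "stable" | "unstable" | "marginal"


def mf_rate(M, params: MeanFieldParams):
    """Rate of change of magnetization, ``-M + tanh(beta*M)`` (odd in M)."""
    M = np.asarray(M, dtype=float)
    out = -M + np.tanh(params.beta * M)
    return float(out) if out.ndim == 0 else out


def _rate_derivative(M: float, beta: float) -> float:
    return -1.0 + beta / np.cosh(beta * M) ** 2


def mf_fixed_points(params: MeanFieldParams, tol: float = 1e-12) -> list[FixedPoint]:
    """Solve M = tanh(beta*M); label stability from the rate derivative.

    beta <= 1: only M = 0 (stable; marginal exactly at beta = 1).
    beta > 1: M = 0 turns unstable and a symmetric pair of stable fixed
    points +/- m(beta) appears — the pitchfork. The positive branch is found
    by bisection on (0, 1], where ``tanh(beta*M) - M`` is monotone through
    its single sign change.
    """
    beta = params.beta
    if beta < 1.0:
        return [FixedPoint(0.0, "stable")]
    if beta == 1.0:
        return [FixedPoint(0.0, "marginal")]
    lo, hi = tol, 1.0
    # g(M) = tanh(beta M) - M: g(lo) > 0 (slope beta > 1), g(1) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.tanh(beta * mid) - mid > 0:
            lo = mid
        else:
            hi = mid
    m = 0.5 * (lo + hi)
    branch_stability = "stable" if _rate_derivative(m, beta) < 0 else "unstable"
    return [
        FixedPoint(0.0, "unstable"),
        FixedPoint(-m, branch_stability),
        FixedPoint(m, branch_stability),
    ]


def landau_free_energy(M, params: MeanFieldParams):
    """Quartic Landau expansion ``C + (1/2)(beta_c-beta)M^2 + (1/12)beta^3 M^4``."""
    M = np.asarray(M, dtype=float)
    out = (
        params.free_energy_offset
        + 0.5 * (params.beta_c - params.beta) * M**2
        + params.beta**3 * M**4 / 12.0
    )
    return float(out) if out.ndim == 0 else out


def landau_stationary_points(params: MeanFieldParams) -> dict:
    """Minima and maxima of the quartic free energy.

    dF/dM = (beta_c - beta) M + (1/3) beta^3 M^3 vanishes at M = 0 and, when
    beta > beta_c, at M = +/- sqrt(3 (beta - beta_c) / beta^3). Below the
    critical point F has a single minimum at 0; above it, two symmetric
    minima flank a maximum at 0.
    """
    beta, beta_c = params.beta, params.beta_c
    if beta <= beta_c:
        return {"minima": [0.0], "maxima": []}
    m = float(np.sqrt(3.0 * (beta - beta_c) / beta**3))
    return {"minima": [-m, m], "maxima": [0.0]}


def mf_consistency(
    params: MeanFieldParams, grid: Sequence[float] | None = None
) -> dict:
    """Check that -dF/dM equals the cubic truncation of the rate equation.

    Both should equal ``(beta - beta_c) M - (1/3) beta^3 M^3``; the report
    gives the maximum absolute deviation over the M grid (default 201 points
    in [-1, 1]) together with the truncation error of the cubic against the
    full tanh rate, which is *not* expected to vanish.
    """
    M = np.linspace(-1, 1, 201) if grid is None else np.asarray(grid, float)
    beta, beta_c = params.beta, params.beta_c
    minus_dF = -((beta_c - beta) * M + beta**3 * M**3 / 3.0)
    cubic_rate = (beta - beta_c) * M - (beta * M) ** 3 / 3.0
    full_rate = mf_rate(M, params)
    return {
        "max_abs_deviation": float(np.max(np.abs(minus_dF - cubic_rate))),
        "max_truncation_error": float(np.max(np.abs(full_rate - cubic_rate))),
        "n_grid": len(M),
    }
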