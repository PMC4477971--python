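"""Temperature-sweep experiment: ensembles of runs, indicators, summaries.

The reference numerical experiment holds the temperature fixed within each
run (the system is *not* driven through the transition) and samples a grid of
temperatures across the critical region: for each T it runs an ensemble of
independent Metropolis simulations, discards the initial transient of each
magnetization trace, computes the early-warning indicators per run, and
aggregates ensemble means with standard errors. The ensemble-averaged PSD per
temperature is fitted for its crossover frequency. Reference-scale defaults:
100 x 100 lattice, T from 1.42 to 3.12 in steps of 0.05, 1000 runs of 5000
sweeps with the first 1000 discarded; below the critical temperature runs
start fully magnetized, at and above it from random spins.

Everything is a pure function of the :class:`SweepConfig` (including its
``base_seed``), so summary tables are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .indicators import IndicatorSet, compute_indicators
from .lattice import MagnetizationSeries, ModelParams, simulate
from .spectral import (
    CrossoverFit,
    PSDEstimate,
    ensemble_psd,
    fit_crossover,
    fit_single_power_law,
    periodogram,
)

__all__ = [
    "SweepConfig",
    "EnsembleSummary",
    "GridSizeStudy",
    "make_temperature_grid",
    "choose_initial_condition",
    "standard_error",
    "summarize_run",
    "positive_branch_mean",
    "derive_seed",
    "run_sweep",
    "grid_size_experiment",
    "SUMMARY_COLUMNS",
    "INDICATOR_FIELDS",
]

logger = logging.getLogger("ising_ews")

INDICATOR_FIELDS = ("mean", "variance", "abs_skewness", "kurtosis", "autocorr_lag1")

SUMMARY_COLUMNS = [
    "T",
    "n_runs",
    "mean",
    "mean_se",
    "pos_branch_mean",
    "variance",
    "variance_se",
    "abs_skewness",
    "abs_skewness_se",
    "kurtosis",
    "kurtosis_se",
    "ac1",
    "ac1_se",
    "crossover_freq",
    "psd_slope",
    "psd_sse",
]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a temperature-sweep experiment (reference defaults)."""

    t_min: float = 1.42
    t_max: float = 3.12
    delta_t: float = 0.05
    L: int = 100
    n_runs: int = 1000
    n_sweeps: int = 5000
    burn_in: int = 1000
    base_seed: int = 0
    init_threshold: float = 2.27
    grid_sizes: tuple[int, ...] = (60, 80, 120, 140)
    coupling: float = 1.0
    boltzmann_k: float = 1.0
    psd_m_min: int = 3

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError("t_min must be <= t_max")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_sweeps")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.L < 2:
            raise ValueError("L must be >= 2")

    def temperatures(self) -> np.ndarray:
        return make_temperature_grid(self.t_min, self.t_max, self.delta_t)

    def scaled(self, factor: float) -> "SweepConfig":
        """Shrink the ensemble and run length by ``factor`` (burn-in with them)."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        n_sweeps = max(16, int(round(self.n_sweeps * factor)))
        return replace(
            self,
            n_runs=max(2, int(round(self.n_runs * factor))),
            n_sweeps=n_sweeps,
            burn_in=min(int(round(self.burn_in * factor)), n_sweeps - 16),
        )

    @classmethod
    def desk_scale(cls, base_seed: int = 0) -> "SweepConfig":
        """The package's reduced study conditions for laptop-scale runs.

        50 x 50 lattice, 100 runs of 2000 sweeps (burn-in 500) on the grid
        T = 1.8 .. 2.9 step 0.1; the grid-size companion uses L in {30, 50}.
        """
        return cls(
            t_min=1.8,
            t_max=2.9,
            delta_t=0.1,
            L=50,
            n_runs=100,
            n_sweeps=2000,
            burn_in=500,
            base_seed=base_seed,
            grid_sizes=(30, 50),
        )


def make_temperature_grid(t_min: float, t_max: float, delta_t: float) -> np.ndarray:
    """Arithmetic grid from t_min toward t_max (inclusive when it lands on it)."""
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    if t_min > t_max:
        raise ValueError("t_min must be <= t_max")
    n_steps = int(np.floor((t_max - t_min) / delta_t + 1e-9))
    grid = t_min + delta_t * np.arange(n_steps + 1)
    if len(grid) == 0:
        raise ValueError("empty temperature grid")
    return grid


def choose_initial_condition(T: float, init_threshold: float) -> str:
    """'all_up' strictly below the threshold temperature, 'random' at or above.

    Starting fully magnetized below the critical point avoids the metastable
    two-cluster states that trap |M| below its equilibrium value.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    return "all_up" if T < init_threshold else "random"


def standard_error(values) -> float:
    """Ensemble standard error: sample standard deviation (n-1) over sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("standard error needs at least 2 values")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def summarize_run(series: MagnetizationSeries, burn_in: int) -> IndicatorSet:
    """Indicators of one run over its post-transient values."""
    if burn_in >= series.n_total:
        raise ValueError(
            f"burn_in {burn_in} >= series length {series.n_total}"
        )
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    return compute_indicators(series.values[burn_in:])


def positive_branch_mean(run_means) -> float:
    """Ensemble mean of |per-run mean magnetization|.

    Below the critical temperature the magnetization converges to +1 or -1
    with equal probability; folding the sign recovers the magnitude of the
    spontaneous magnetization (the upper pitchfork branch).
    """
    x = np.asarray(run_means, dtype=float)
    if len(x) == 0:
        return float("nan")
    return float(np.abs(x).mean())


def derive_seed(base_seed: int, L: int, t_index: int, run: int) -> int:
    """Deterministic, collision-resistant per-run seed below 2**31."""
    ss = np.random.SeedSequence((int(base_seed), int(L), int(t_index), int(run)))
    return int(ss.generate_state(1)[0]) % 2**31


@dataclass
class EnsembleSummary:
    """Per-temperature ensemble summary of a sweep (the data behind the
    indicator-versus-temperature figures)."""

    table: pd.DataFrame
    psds: dict[float, PSDEstimate]
    crossover_fits: dict[float, CrossoverFit]
    single_fits: dict[float, CrossoverFit]
    excluded_runs: dict[float, int]
    config: SweepConfig


def _ensemble_stats(values: np.ndarray) -> tuple[float, float, int]:
    """(mean, SE, n_excluded) over finite entries; NaNs are undefined runs."""
    finite = values[np.isfinite(values)]
    n_excluded = len(values) - len(finite)
    if len(finite) == 0:
        return float("nan"), float("nan"), n_excluded
    se = standard_error(finite) if len(finite) >= 2 else float("nan")
    return float(finite.mean()), se, n_excluded


def run_temperature(
    config: SweepConfig, T: float, t_index: int
) -> tuple[dict, PSDEstimate, CrossoverFit, CrossoverFit, int]:
    """One grid cell: the full ensemble at temperature T."""
    params = ModelParams(
        temperature=float(T),
        coupling=config.coupling,
        boltzmann_k=config.boltzmann_k,
    )
    init_mode = choose_initial_condition(T, config.init_threshold)
    indicator_rows = {name: np.empty(config.n_runs) for name in INDICATOR_FIELDS}
    psds = []
    for run in range(config.n_runs):
        seed = derive_seed(config.base_seed, config.L, t_index, run)
        series = simulate(params, config.L, config.n_sweeps, init_mode, seed)
        ind = summarize_run(series, config.burn_in)
        for name in INDICATOR_FIELDS:
            indicator_rows[name][run] = getattr(ind, name)
        psds.append(periodogram(series.values[config.burn_in :]))

    psd = ensemble_psd(psds)
    nan = float("nan")
    try:
        fit = fit_crossover(psd, m_min=config.psd_m_min)
        single = fit_single_power_law(psd)
    except ValueError as exc:  # frozen ensemble: zero power, log fit undefined
        logger.warning("T=%.4f: crossover fit undefined (%s)", T, exc)
        fit = CrossoverFit(nan, nan, nan, nan, nan, 0, 0)
        single = CrossoverFit(nan, nan, nan, nan, nan, 0, 0)

    row: dict = {"T": float(T), "n_runs": config.n_runs}
    n_excluded = 0
    for name, col in (
        ("mean", "mean"),
        ("variance", "variance"),
        ("abs_skewness", "abs_skewness"),
        ("kurtosis", "kurtosis"),
        ("autocorr_lag1", "ac1"),
    ):
        m, se, nx = _ensemble_stats(indicator_rows[name])
        row[col] = m
        row[f"{col}_se"] = se
        n_excluded = max(n_excluded, nx)
    row["pos_branch_mean"] = positive_branch_mean(indicator_rows["mean"])
    row["crossover_freq"] = fit.crossover_frequency
    row["psd_slope"] = fit.slope
    row["psd_sse"] = fit.sse
    return row, psd, fit, single, n_excluded


def run_sweep(
    config: SweepConfig,
    skip_temperatures: Iterable[float] = (),
    on_row: Optional[Callable[[dict], None]] = None,
) -> EnsembleSummary:
    """Run the full temperature sweep described by ``config``.

    ``skip_temperatures`` supports resumable execution (already-summarized
    grid points are left out of the returned table); ``on_row`` is invoked
    with each completed row, enabling incremental writing.
    """
    temps = config.temperatures()
    skip = {round(float(t), 9) for t in skip_temperatures}
    rows = []
    psds: dict[float, PSDEstimate] = {}
    fits: dict[float, CrossoverFit] = {}
    singles: dict[float, CrossoverFit] = {}
    excluded: dict[float, int] = {}
    for t_index, T in enumerate(temps):
        key = round(float(T), 9)
        if key in skip:
            logger.info("T=%.4f already done, skipping", T)
            continue
        logger.info(
            "T=%.4f (%d/%d): %d runs x %d sweeps, L=%d",
            T, t_index + 1, len(temps), config.n_runs, config.n_sweeps, config.L,
        )
        row, psd, fit, single, n_excluded = run_temperature(config, T, t_index)
        if n_excluded:
            logger.warning(
                "T=%.4f: %d run(s) with undefined indicators excluded", T, n_excluded
            )
        rows.append(row)
        psds[key] = psd
        fits[key] = fit
        singles[key] = single
        excluded[key] = n_excluded
        if on_row is not None:
            on_row(row)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return EnsembleSummary(
        table=table,
        psds=psds,
        crossover_fits=fits,
        single_fits=singles,
        excluded_runs=excluded,
        config=config,
    )


@dataclass
class GridSizeStudy:
    """Sweeps repeated at several lattice sizes, plus their differences."""

    sizes: tuple[int, ...]
    summaries: dict[int, EnsembleSummary]

    _COMPARED = ("mean", "variance", "abs_skewness", "kurtosis", "ac1", "crossover_freq")

    def difference_table(self) -> pd.DataFrame:
        """Pairwise per-temperature absolute differences of each indicator."""
        records = []
        for i, La in enumerate(self.sizes):
            for Lb in self.sizes[i + 1 :]:
                ta = self.summaries[La].table.set_index("T")
                tb = self.summaries[Lb].table.set_index("T")
                common = ta.index.intersection(tb.index)
                for T in common:
                    rec = {"L_a": La, "L_b": Lb, "T": float(T)}
                    for col in self._COMPARED:
                        rec[f"abs_diff_{col}"] = abs(
                            ta.loc[T, col] - tb.loc[T, col]
                        )
                    records.append(rec)
        return pd.DataFrame(records)

    def max_differences(self) -> pd.DataFrame:
        """Maximum over temperatures of each pairwise indicator difference."""
        diffs = self.difference_table()
        return (
            diffs.drop(columns="T")
            .groupby(["L_a", "L_b"], as_index=False)
            .max(numeric_only=True)
        )


def grid_size_experiment(
    config: SweepConfig, grid_sizes: Optional[Sequence[int]] = None
) -> GridSizeStudy:
    """Repeat the sweep at each lattice size (robustness-to-resolution study)."""
    sizes = tuple(int(L) for L in (grid_sizes if grid_sizes is not None else config.grid_sizes))
    if len(sizes) < 2:
        raise ValueError("grid-size study needs at least 2 sizes")
    summaries = {}
    for L in dict.fromkeys(sizes):  # unique sizes, run once each
        logger.info("grid-size study: L=%d", L)
        summaries[L] = run_sweep(replace(config, L=L))
    return GridSizeStudy(sizes=sizes, summaries=summaries)
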