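"""Serialization: CSV/JSON artifacts, sweep configs, run manifests.

All floats are written with 17 significant digits so that write-then-read
round-trips reproduce every value exactly. CSV dialect: comma-separated,
header row, LF line endings, '.' decimal separator.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .experiment import SUMMARY_COLUMNS, SweepConfig
from .lattice import MagnetizationSeries
from .spectral import CrossoverFit, PSDEstimate

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_summary_csv",
    "read_summary_csv",
    "write_psd_csv",
    "read_psd_csv",
    "write_crossover_csv",
    "load_sweep_config",
    "write_manifest",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FORMAT % x


def write_series_csv(series: MagnetizationSeries, path: Union[str, Path]) -> Path:
    """Write ``sweep,magnetization`` rows plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write("sweep,magnetization\n")
        for t, m in enumerate(series.values, start=1):
            fh.write(f"{t},{_fmt(m)}\n")
    sidecar = path.with_suffix(".meta.json")
    meta = {
        "T": series.temperature,
        "L": series.side_length,
        "J": 1.0,
        "k": 1.0,
        "seed": series.seed,
        "n_sweeps": series.n_total,
        "burn_in": series.burn_in,
        "init_mode": series.init_mode,
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_series_csv(path: Union[str, Path]) -> tuple[np.ndarray, Optional[dict]]:
    """Read a univariate series from CSV.

    Accepts either a single numeric column or ``sweep,magnetization``
    two-column files, with or without a header row. Non-numeric data rows
    raise with their line number. Returns (values, metadata) where metadata
    comes from a ``.meta.json`` sidecar if present.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(",")
            try:
                values.append(float(fields[-1]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {fields[-1]!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no numeric data rows")
    sidecar = path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return np.asarray(values), meta


def write_summary_csv(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_summary_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def append_summary_row(row: dict, path: Union[str, Path]) -> None:
    """Incremental write: header on first row, then one line per temperature."""
    path = Path(path)
    new_file = not path.exists()
    with open(path, "a", newline="\n") as fh:
        if new_file:
            fh.write(",".join(SUMMARY_COLUMNS) + "\n")
        fh.write(
            ",".join(
                str(row[c]) if c == "n_runs" else _fmt(row[c])
                for c in SUMMARY_COLUMNS
            )
            + "\n"
        )


def write_psd_csv(psd: PSDEstimate, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write("frequency,power\n")
        for f, p in zip(psd.frequencies, psd.power):
            fh.write(f"{_fmt(f)},{_fmt(p)}\n")
    return path


def read_psd_csv(path: Union[str, Path]) -> PSDEstimate:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"frequency", "power"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns frequency,power")
    return PSDEstimate(
        frequencies=df["frequency"].to_numpy(),
        power=df["power"].to_numpy(),
        n_series=1,
        n_samples=2 * len(df),
    )


def write_crossover_csv(
    fits: dict[float, CrossoverFit], path: Union[str, Path]
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write("T,crossover_frequency,flat_level,slope,intercept,sse\n")
        for T in sorted(fits):
            f = fits[T]
            fh.write(
                ",".join(
                    _fmt(x)
                    for x in (
                        T,
                        f.crossover_frequency,
                        f.flat_level,
                        f.slope,
                        f.intercept,
                        f.sse,
                    )
                )
                + "\n"
            )
    return path


def load_sweep_config(source: Union[str, Path, dict]) -> SweepConfig:
    """Build a :class:`SweepConfig` from a JSON file or dict.

    Missing keys take the reference-scale defaults; unknown keys are
    rejected so typos do not silently fall back to defaults.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = dict(source)
    known = {f.name for f in dataclasses.fields(SweepConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid_sizes" in data:
        data["grid_sizes"] = tuple(int(x) for x in data["grid_sizes"])
    return SweepConfig(**data)


def write_manifest(
    config: SweepConfig,
    out_dir: Union[str, Path],
    outputs: list[str],
    timings: dict[str, float],
    warnings: list[str],
) -> Path:
    """Run manifest: config echo, seed, outputs, timings — enough to re-run."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "created_unix_time": time.time(),
        "config": dataclasses.asdict(config),
        "base_seed": config.base_seed,
        "seed_derivation": "SeedSequence((base_seed, L, T_index, run)) % 2**31",
        "outputs": outputs,
        "timings_seconds": timings,
        "warnings": warnings,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
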