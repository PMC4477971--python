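"""Optional figures: indicator-versus-temperature panels and log-log PSDs."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiment import EnsembleSummary  # noqa: E402

__all__ = ["plot_summary", "plot_psds"]

_PANELS = [
    ("pos_branch_mean", None, "positive-branch mean M"),
    ("variance", "variance_se", "variance"),
    ("abs_skewness", "abs_skewness_se", "|skewness|"),
    ("kurtosis", "kurtosis_se", "kurtosis"),
    ("ac1", "ac1_se", "C(1)"),
    ("crossover_freq", None, "crossover frequency"),
]


def plot_summary(summary: EnsembleSummary, path: Union[str, Path]) -> Path:
    """Six-panel overview of every early-warning indicator against T."""
    table = summary.table
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True)
    for ax, (col, se_col, label) in zip(axes.ravel(), _PANELS):
        if se_col is not None:
            ax.errorbar(table["T"], table[col], yerr=table[se_col], fmt="o-", ms=3)
        else:
            ax.plot(table["T"], table[col], "o-", ms=3)
        ax.set_ylabel(label)
        ax.axvline(summary.config.init_threshold, color="0.7", ls="--", lw=0.8)
    for ax in axes[-1]:
        ax.set_xlabel("temperature T")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_psds(summary: EnsembleSummary, path: Union[str, Path]) -> Path:
    """Ensemble PSDs in log-log axes with their fitted crossover frequencies."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for key in sorted(summary.psds):
        psd = summary.psds[key]
        fit = summary.crossover_fits[key]
        (line,) = ax.loglog(psd.frequencies, psd.power, lw=0.8, label=f"T={key:g}")
        idx = int((psd.frequencies >= fit.crossover_frequency).argmax())
        ax.plot(
            [fit.crossover_frequency],
            [psd.power[idx]],
            "o",
            color=line.get_color(),
            ms=5,
        )
    ax.set_xlabel("frequency (cycles/sweep)")
    ax.set_ylabel("power")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
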