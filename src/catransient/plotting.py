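"""Fit-overlay plots: data, predicted curve(s), and the tau marker."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")  # file output only; no interactive backend assumed
import matplotlib.pyplot as plt

from .core import FitResult, Trace

__all__ = ["plot_fit_overlay"]

_COLORS = {"single": "tab:red", "double": "tab:blue"}


def plot_fit_overlay(
    trace: Trace,
    results: Sequence[FitResult],
    path: Union[str, Path],
    tau_ms: Optional[float] = None,
) -> None:
    """Save a figure overlaying the trace, its fit(s) and the tau position.

    Each result is drawn over its own fit region (dashed); when a tau
    estimate is given, its position relative to the first result's window
    start is marked with a vertical line.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.times, trace.values, color="0.6", lw=0.8, label=trace.label or "data")
    for result in results:
        if result.region is not None:
            mask = result.region.mask(trace)
            t = trace.times[mask]
        else:
            t = trace.times
        ax.plot(
            t,
            result.predict(t - t[0]),
            "--",
            color=_COLORS.get(result.model, "k"),
            lw=1.5,
            label=f"{result.model} fit (adj R²="
            f"{result.adjusted_r_squared:.4f})",
        )
    if tau_ms is not None and results and results[0].region is not None:
        ax.axvline(
            results[0].region.t_start + tau_ms,
            color="k",
            lw=0.8,
            ls=":",
            label=f"tau = {tau_ms:g} ms",
        )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"signal ({trace.signal_kind})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
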