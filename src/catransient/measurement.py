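"""Absolute Ca levels: diastolic, peak systolic and transient amplitude.

On calibrated data these are absolute concentrations; on ratio or F/F0 data
they are relative signal changes that reflect changes of Ca.  Two entry
points mirror the two ways a user places the level cursors:

* :func:`measure_levels_manual` — the levels themselves are given (a
  faithful emulation of reading the two Y-axis cursors);
* :func:`measure_levels_auto` — levels are derived from two time regions:
  the diastolic level is the mean over a flat baseline window, the systolic
  level the maximum over a window containing the peak.
"""

from __future__ import annotations

from .core import LevelMeasurement, Region, Trace

__all__ = ["measure_levels_manual", "measure_levels_auto"]


def measure_levels_manual(
    trace: Trace,
    diastolic_level: float,
    systolic_level: float,
    label: str | None = None,
) -> LevelMeasurement:
    """Record cursor-placed diastolic and systolic levels verbatim.

    ``amplitude = systolic - diastolic``; inverted cursor levels are
    rejected.
    """
    if systolic_level < diastolic_level:
        raise ValueError(
            f"systolic level ({systolic_level:g}) must be >= diastolic "
            f"level ({diastolic_level:g})"
        )
    return LevelMeasurement.from_levels(
        diastolic_level,
        systolic_level,
        label=label if label is not None else trace.label,
    )


def measure_levels_auto(
    trace: Trace,
    baseline_region: Region,
    peak_region: Region,
    label: str | None = None,
) -> LevelMeasurement:
    """Measure levels from a baseline window and a peak window.

    Diastole uses the mean (a cursor aligned with a flat resting segment),
    the peak uses the max (a cursor aligned with the transient's crest).
    If the peak window maximum falls below the baseline mean — a mis-chosen
    window on a noisy signal — the measurement is returned with its
    ``warning`` flag set rather than failing.
    """
    base_mask = baseline_region.mask(trace)
    peak_mask = peak_region.mask(trace)
    for mask, name, region in (
        (base_mask, "baseline", baseline_region),
        (peak_mask, "peak", peak_region),
    ):
        if not mask.any():
            raise ValueError(
                f"{name} region [{region.t_start}, {region.t_end}] ms "
                f"contains no samples"
            )
    diastolic = float(trace.values[base_mask].mean())
    systolic = float(trace.values[peak_mask].max())
    return LevelMeasurement.from_levels(
        diastolic,
        systolic,
        label=label if label is not None else trace.label,
        warning=systolic < diastolic,
    )
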