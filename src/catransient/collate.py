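"""Collated results: one row per treatment, and the whole-pipeline driver.

Every measurement and fit for a treatment lands in one row of a collated
CSV — the programmatic counterpart of a results sheet that accumulates as
treatments are analyzed.  Re-sending results for an already-present label
overwrites that label's row (re-analysis replaces, never duplicates).

:func:`run_pipeline` drives the full workflow from a YAML config:
import -> prepare -> measure -> fit -> collate, one treatment at a time,
reporting per-treatment stage failures without aborting the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .core import (
    CalibrationConstants,
    FitResult,
    LevelMeasurement,
    Region,
    Trace,
    read_trace,
)
from .measurement import measure_levels_auto, measure_levels_manual
from .preparation import (
    calibrate_ca,
    define_f0,
    normalize_f0,
    ratio,
    subtract_background,
)
from .regression import (
    DEFAULT_DIVISORS,
    extract_fit_window,
    fit_double,
    fit_simultaneous,
    fit_single,
    indicate_best_fit,
    initial_guess_single,
)

__all__ = ["CollatedRecord", "collate", "run_pipeline", "PipelineError", "COLUMNS"]

logger = logging.getLogger("catransient")

_FIT_FIELDS = (
    "y0",
    "a1",
    "k1",
    "a2",
    "k2",
    "ss_reg",
    "ss_total",
    "r_squared",
    "adjusted_r_squared",
    "n_points",
    "converged",
)

#: Stable collated column order.
COLUMNS = (
    ["label", "preparation", "diastolic", "systolic", "amplitude", "level_warning"]
    + [f"single_{f}" for f in _FIT_FIELDS if f not in ("a2", "k2")]
    + [f"double_{f}" for f in _FIT_FIELDS]
    + ["best_model"]
)


@dataclass(frozen=True)
class CollatedRecord:
    """All results for one treatment, destined for one collated row.

    ``best_model`` may only be present when both fits exist — it is the
    adjusted-R² comparison of the simultaneous fit, meaningless otherwise.
    """

    label: str
    preparation: str = "none"
    levels: Optional[LevelMeasurement] = None
    single: Optional[FitResult] = None
    double: Optional[FitResult] = None
    best_model: Optional[str] = None

    def __post_init__(self) -> None:
        if self.best_model is not None and (self.single is None or self.double is None):
            raise ValueError(
                "best_model is only defined when both fits exist for the label"
            )

    def to_row(self) -> dict:
        row: dict = {c: None for c in COLUMNS}
        row["label"] = self.label
        row["preparation"] = self.preparation
        if self.levels is not None:
            row["diastolic"] = self.levels.diastolic
            row["systolic"] = self.levels.systolic
            row["amplitude"] = self.levels.amplitude
            row["level_warning"] = self.levels.warning
        for prefix, result in (("single", self.single), ("double", self.double)):
            if result is None:
                continue
            for f in _FIT_FIELDS:
                col = f"{prefix}_{f}"
                if col in row:
                    row[col] = getattr(result, f)
        row["best_model"] = self.best_model
        return row


def collate(
    records: Sequence[CollatedRecord],
    path: Union[str, Path, None] = None,
) -> pd.DataFrame:
    """Assemble (and optionally persist) the collated results table.

    One row per treatment label, stable column order.  If ``path`` names an
    existing collated CSV, its rows are loaded first and rows with the same
    label are overwritten; within ``records`` a later record for the same
    label likewise replaces the earlier one.
    """
    frames = []
    if path is not None and Path(path).exists():
        frames.append(pd.read_csv(path))
    if records:
        frames.append(pd.DataFrame([r.to_row() for r in records]))
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.drop_duplicates(subset="label", keep="last").reset_index(drop=True)
        df = df.reindex(columns=COLUMNS)
    else:
        df = pd.DataFrame(columns=COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Whole-pipeline driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineError:
    """A per-treatment stage failure; the batch continues past it."""

    label: str
    stage: str
    message: str


def _as_region(bounds) -> Region:
    t0, t1 = float(bounds[0]), float(bounds[1])
    return Region(t0, t1)


def _load_config(config: Union[str, Path, dict]) -> tuple[dict, Path]:
    if isinstance(config, (str, Path)):
        path = Path(config)
        cfg = yaml.safe_load(path.read_text())
        base = path.parent
    else:
        cfg = dict(config)
        base = Path(".")
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg, base


def _prepare(
    trace: Trace,
    preparation: str,
    constants: CalibrationConstants,
    denominator: Optional[Trace],
    f0_override: Optional[float],
    f0_region: Optional[Region],
) -> Trace:
    """Apply the configured preparation; background is subtracted once."""
    if preparation == "none":
        return trace
    if preparation == "ratio":
        if denominator is None:
            raise ValueError("ratio preparation requires a denominator trace")
        return ratio(
            trace,
            denominator,
            bg_nom=constants.f_background,
            bg_denom=constants.f_background,
        )
    sub = subtract_background(trace, constants.f_background)
    if preparation == "background":
        return sub
    if preparation == "calcium":
        kd, f_max = constants.require_ca()
        return calibrate_ca(sub, kd=kd, f_max=f_max)
    if preparation == "f_over_f0":
        if f0_override is not None:
            f0 = f0_override
        elif f0_region is not None:
            f0 = define_f0(sub, f0_region)
        else:
            f0 = constants.require_f0()
        return normalize_f0(sub, f0)
    raise ValueError(
        f"unknown preparation {preparation!r} (expected none, background, "
        f"ratio, calcium or f_over_f0)"
    )


def run_pipeline(
    config: Union[str, Path, dict],
    output: Union[str, Path, None] = None,
) -> tuple[pd.DataFrame, list[PipelineError]]:
    """Run import -> prepare -> measure -> fit -> collate from a config.

    The config (YAML file path or mapping) lists global calibration
    constants, the preparation kind, fit options, and per-treatment trace
    files with their measurement and fit regions; see the package docs for
    the schema.  Each treatment is processed independently: a stage failure
    is logged and reported with its stage name and label, and the remaining
    treatments still run.

    Returns the collated DataFrame and the list of per-treatment errors.
    """
    cfg, base = _load_config(config)
    cal_cfg = cfg.get("calibration") or {}
    constants = CalibrationConstants(
        f_background=float(cal_cfg.get("background", 0.0)),
        f_max=cal_cfg.get("fmax"),
        kd=cal_cfg.get("kd"),
        f0=cal_cfg.get("f0"),
    )
    preparation = cfg.get("preparation", "none")
    time_units = cfg.get("time_units", "ms")
    fit_cfg = cfg.get("fit") or {}
    model = fit_cfg.get("model", "both")
    zero = bool(fit_cfg.get("zero_fit_range", False))
    smart_rc = bool(fit_cfg.get("smart_rc", True))
    divisors = tuple(fit_cfg.get("divisors", DEFAULT_DIVISORS))
    out_path = output if output is not None else cfg.get("output")
    if out_path is not None and not Path(out_path).is_absolute():
        out_path = base / out_path

    records: list[CollatedRecord] = []
    errors: list[PipelineError] = []
    for entry in cfg.get("treatments", []) or []:
        label = str(entry.get("label", entry.get("trace", "?")))
        stage = "import"
        try:
            trace = read_trace(base / entry["trace"], time_units=time_units)
            denominator = None
            if "denominator" in entry:
                denominator = read_trace(
                    base / entry["denominator"], time_units=time_units
                )
            logger.info("%s: imported %d samples", label, trace.n_samples)

            stage = "prepare"
            f0_region = (
                _as_region(entry["f0_region"]) if "f0_region" in entry else None
            )
            prepared = _prepare(
                trace,
                entry.get("preparation", preparation),
                constants,
                denominator,
                entry.get("f0"),
                f0_region,
            )
            logger.info("%s: prepared as %s", label, prepared.signal_kind)

            stage = "measure"
            levels = None
            if "diastolic_level" in entry and "systolic_level" in entry:
                levels = measure_levels_manual(
                    prepared,
                    float(entry["diastolic_level"]),
                    float(entry["systolic_level"]),
                    label=label,
                )
            elif "baseline_region" in entry and "peak_region" in entry:
                levels = measure_levels_auto(
                    prepared,
                    _as_region(entry["baseline_region"]),
                    _as_region(entry["peak_region"]),
                    label=label,
                )
            if levels is not None:
                logger.info("%s: amplitude %.6g", label, levels.amplitude)

            stage = "fit"
            single = double = best = None
            if "fit_region" in entry:
                region = _as_region(entry["fit_region"])
                baseline = entry.get("baseline_level")
                peak = entry.get("peak_level")
                if baseline is None and levels is not None:
                    baseline = levels.diastolic
                if peak is None and levels is not None:
                    peak = levels.systolic
                window = extract_fit_window(
                    prepared,
                    region,
                    zero=zero,
                    y0_cursor=0.0 if baseline is None else float(baseline),
                )
                init = None
                if baseline is not None and peak is not None:
                    init = initial_guess_single(
                        window.t_rel,
                        window.y,
                        float(baseline) - window.y_offset,
                        float(peak) - window.y_offset,
                        smart_rc=smart_rc,
                    )
                fit_kwargs = dict(
                    y_offset=window.y_offset,
                    zeroed=window.zeroed,
                    region=region,
                    label=label,
                )
                entry_model = entry.get("model", model)
                if entry_model == "both":
                    single, double = fit_simultaneous(
                        window.t_rel, window.y, init, divisors=divisors, **fit_kwargs
                    )
                    best = indicate_best_fit(single, double)
                elif entry_model == "single":
                    single = fit_single(window.t_rel, window.y, init, **fit_kwargs)
                elif entry_model == "double":
                    double = fit_double(
                        window.t_rel, window.y, init, divisors=divisors, **fit_kwargs
                    )
                else:
                    raise ValueError(f"unknown fit model {entry_model!r}")
                logger.info(
                    "%s: %s fit k1=%.6g (best=%s)",
                    label,
                    entry_model,
                    (double or single).k1,
                    best,
                )

            stage = "collate"
            records.append(
                CollatedRecord(
                    label=label,
                    preparation=entry.get("preparation", preparation),
                    levels=levels,
                    single=single,
                    double=double,
                    best_model=best,
                )
            )
        except Exception as exc:  # per-treatment isolation, batch continues
            logger.warning("%s: %s stage failed: %s", label, stage, exc)
            errors.append(PipelineError(label=label, stage=stage, message=str(exc)))

    df = collate(records, out_path)
    return df, errors
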