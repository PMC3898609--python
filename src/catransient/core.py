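"""Domain types shared by every analysis stage, plus delimited-text I/O.

The central container is :class:`Trace` — a uniformly sampled fluorescence
time series tagged with the kind of signal it carries.  Signal kinds form a
small preparation graph: a ``raw`` recording is first background-subtracted,
after which it may become a ratiometric ``ratio``, a pseudo-ratio
``f_over_f0``, or a calibrated ``calcium_nM`` concentration.  Transitions
outside this graph are rejected so that, for example, a trace can never be
background-subtracted twice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "SIGNAL_KINDS",
    "Trace",
    "CalibrationConstants",
    "Region",
    "LevelMeasurement",
    "FitResult",
    "TraceFormatError",
    "read_trace",
    "write_trace",
]

#: Allowed signal kinds and the preparation transitions between them.
SIGNAL_KINDS = ("raw", "background_subtracted", "ratio", "f_over_f0", "calcium_nM")

_ALLOWED_TRANSITIONS = {
    "raw": {"background_subtracted", "ratio"},
    "background_subtracted": {"ratio", "f_over_f0", "calcium_nM"},
}

#: Relative jitter tolerance for the uniform-sampling requirement.
UNIFORM_SAMPLING_RTOL = 1e-4


class TraceFormatError(ValueError):
    """Raised when a delimited-text trace file cannot be parsed."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled fluorescence (or derived) time series.

    Parameters
    ----------
    times : array-like of float
        Sample times in milliseconds, strictly increasing, uniformly spaced
        within one part in 10^4 relative jitter.
    values : array-like of float
        Signal values, same length as ``times``.  Units depend on
        ``signal_kind``: arbitrary fluorescence units for ``raw`` and
        ``background_subtracted``, dimensionless for ``ratio`` and
        ``f_over_f0``, nM for ``calcium_nM``.
    signal_kind : str
        One of :data:`SIGNAL_KINDS`.
    label : str
        Free-text treatment name.
    """

    times: np.ndarray
    values: np.ndarray
    signal_kind: str = "raw"
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.shape != values.shape:
            raise ValueError(
                f"times and values must have equal length "
                f"({times.size} != {values.size})"
            )
        if times.size < 2:
            raise ValueError("a Trace needs at least 2 samples")
        dt = np.diff(times)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValueError(
                f"times must be strictly increasing (violation at row {i + 1}: "
                f"{times[i]} -> {times[i + 1]})"
            )
        mean_dt = dt.mean()
        if np.max(np.abs(dt - mean_dt)) > UNIFORM_SAMPLING_RTOL * mean_dt:
            raise ValueError(
                "sampling must be uniform within 1e-4 relative jitter; "
                "irregular traces are rejected, not resampled"
            )
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(
                f"signal_kind {self.signal_kind!r} not in {SIGNAL_KINDS}"
            )

    # -- convenience -------------------------------------------------------

    @property
    def dt(self) -> float:
        """Mean sample interval in ms."""
        return float(np.diff(self.times).mean())

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in ms."""
        return float(self.times[0]), float(self.times[-1])

    def with_values(self, values: np.ndarray, signal_kind: str) -> "Trace":
        """Return a new trace with ``values`` and a kind-graph-checked kind."""
        allowed = _ALLOWED_TRANSITIONS.get(self.signal_kind, set())
        if signal_kind != self.signal_kind and signal_kind not in allowed:
            raise ValueError(
                f"signal kind transition {self.signal_kind!r} -> "
                f"{signal_kind!r} is not on the preparation graph"
            )
        return dataclasses.replace(self, values=values, signal_kind=signal_kind)


@dataclass(frozen=True)
class CalibrationConstants:
    """Scalar calibration constants for raw-signal preparation.

    ``f_max`` and ``kd`` must both be present to calibrate to [Ca];
    ``f0`` must be present for F/F0 conversion.
    """

    f_background: float = 0.0
    f_max: Optional[float] = None
    kd: Optional[float] = None
    f0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.f_background < 0:
            raise ValueError("f_background must be >= 0")
        if self.f_max is not None and self.f_max <= 0:
            raise ValueError("f_max must be > 0")
        if self.kd is not None and self.kd <= 0:
            raise ValueError("kd must be > 0 (nM)")
        if self.f0 is not None and self.f0 <= 0:
            raise ValueError("f0 must be > 0")

    def require_ca(self) -> tuple[float, float]:
        """Return (kd, f_max), raising if either is missing."""
        missing = [n for n, v in (("kd", self.kd), ("fmax", self.f_max)) if v is None]
        if missing:
            raise ValueError(
                f"[Ca] calibration requires constants: {', '.join(missing)}"
            )
        return float(self.kd), float(self.f_max)

    def require_f0(self) -> float:
        if self.f0 is None:
            raise ValueError("F/F0 conversion requires the f0 constant")
        return float(self.f0)


@dataclass(frozen=True)
class Region:
    """A contiguous time window [t_start, t_end] in ms on a trace.

    The programmatic surrogate for the on-screen X-axis cursors: every place
    the original workflow flanks a region with cursors, this package takes a
    Region.
    """

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"region requires t_start < t_end (got {self.t_start}, {self.t_end})"
            )

    def mask(self, trace: Trace) -> np.ndarray:
        """Boolean mask of samples whose times fall in [t_start, t_end]."""
        lo, hi = trace.span
        if self.t_start < lo or self.t_end > hi:
            raise ValueError(
                f"region [{self.t_start}, {self.t_end}] ms falls outside the "
                f"trace span [{lo}, {hi}] ms"
            )
        return (trace.times >= self.t_start) & (trace.times <= self.t_end)


@dataclass(frozen=True)
class LevelMeasurement:
    """Diastolic, systolic and amplitude levels for one treatment.

    ``amplitude`` is always ``systolic - diastolic``; the identity is
    asserted at construction.  ``warning`` flags physiologically suspect
    measurements (e.g. an automated peak window below the baseline).
    """

    diastolic: float
    systolic: float
    amplitude: float
    label: str = ""
    warning: bool = False

    def __post_init__(self) -> None:
        if self.amplitude != self.systolic - self.diastolic:
            raise ValueError("amplitude must equal systolic - diastolic exactly")

    @classmethod
    def from_levels(
        cls, diastolic: float, systolic: float, label: str = "", warning: bool = False
    ) -> "LevelMeasurement":
        return cls(
            diastolic=float(diastolic),
            systolic=float(systolic),
            amplitude=float(systolic) - float(diastolic),
            label=label,
            warning=warning,
        )


@dataclass(frozen=True)
class FitResult:
    """Result of a single- or double-exponential decay fit.

    For the single model ``y = Y0 + A1 exp(-k1 t)`` only ``y0``, ``a1`` and
    ``k1`` are populated (``a2``/``k2`` are None); for the double model
    ``y = Y0 + A1 exp(-k1 t) + A2 exp(-k2 t)`` components are ordered fast
    first (k1 >= k2).  Rate constants are per ms.  ``r_squared`` and
    ``adjusted_r_squared`` are NaN when the window variance is zero
    (flagged undefined).
    """

    model: str
    y0: float
    a1: float
    k1: float
    a2: Optional[float]
    k2: Optional[float]
    ss_reg: float
    ss_total: float
    r_squared: float
    adjusted_r_squared: float
    n_points: int
    n_params: int
    initial_guess: dict
    converged: bool
    region: Optional[Region] = None
    zeroed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.model not in ("single", "double"):
            raise ValueError("model must be 'single' or 'double'")
        expected = 3 if self.model == "single" else 5
        if self.n_params != expected:
            raise ValueError(
                f"{self.model} model has {expected} parameters, got {self.n_params}"
            )
        if self.ss_reg < 0 or self.ss_total < 0:
            raise ValueError("sums of squares must be non-negative")

    @property
    def tau1(self) -> float:
        """Time constant 1/k1 in ms."""
        return 1.0 / self.k1

    @property
    def parameters(self) -> dict:
        out = {"y0": self.y0, "a1": self.a1, "k1": self.k1}
        if self.model == "double":
            out.update(a2=self.a2, k2=self.k2)
        return out

    def predict(self, t_rel: np.ndarray) -> np.ndarray:
        """Evaluate the fitted model on window-relative times (ms)."""
        t_rel = np.asarray(t_rel, dtype=float)
        y = self.y0 + self.a1 * np.exp(-self.k1 * t_rel)
        if self.model == "double":
            y = y + self.a2 * np.exp(-self.k2 * t_rel)
        return y


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_trace(
    path: Union[str, Path],
    *,
    delimiter: Optional[str] = None,
    time_column: int = 0,
    value_column: int = 1,
    time_units: str = "ms",
    signal_kind: Optional[str] = None,
    label: Optional[str] = None,
) -> Trace:
    """Read a trace from a delimited text file.

    Column mapping is explicit (never sniffed): ``time_column`` and
    ``value_column`` are zero-based indices.  ``delimiter=None`` accepts
    comma, tab or whitespace.  ``time_units`` may be ``"ms"`` (default) or
    ``"s"``, in which case times are converted to ms on input.  A leading
    line whose first token is non-numeric is treated as a header and
    skipped; optional ``# label: NAME`` and ``# signal_kind: KIND`` comment
    lines (as written by :func:`write_trace`) set the label and signal kind
    unless overridden by the keyword arguments.  When neither the file nor
    the caller states a kind, the trace is read as ``raw``.

    Raises
    ------
    TraceFormatError
        For an unreadable file, non-numeric cells, ragged rows or a
        non-monotonic time column; the message names the offending row.
    """
    path = Path(path)
    if time_units not in ("ms", "s"):
        raise ValueError("time_units must be 'ms' or 's'")
    try:
        text = path.read_text()
    except OSError as exc:
        raise TraceFormatError(f"cannot read {path}: {exc}") from exc

    file_label: Optional[str] = None
    file_kind: Optional[str] = None
    times: list[float] = []
    values: list[float] = []
    ncols: Optional[int] = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("label:"):
                file_label = body[6:].strip()
            elif body.lower().startswith("signal_kind:"):
                file_kind = body[12:].strip()
            continue
        fields = line.split(delimiter) if delimiter else line.replace(",", " ").split()
        fields = [f.strip() for f in fields if f.strip() != ""]
        if not fields:
            continue
        if not _is_number(fields[0]):
            if not times:  # single non-numeric header row
                continue
            raise TraceFormatError(f"{path}: non-numeric row {lineno}: {line!r}")
        if ncols is None:
            ncols = len(fields)
        elif len(fields) != ncols:
            raise TraceFormatError(
                f"{path}: ragged row {lineno}: expected {ncols} columns, "
                f"got {len(fields)}"
            )
        needed = max(time_column, value_column)
        if needed >= len(fields):
            raise TraceFormatError(
                f"{path}: row {lineno} has no column {needed} (found {len(fields)})"
            )
        try:
            t = float(fields[time_column])
            v = float(fields[value_column])
        except ValueError as exc:
            raise TraceFormatError(
                f"{path}: non-numeric cell in row {lineno}: {line!r}"
            ) from exc
        times.append(t)
        values.append(v)

    if len(times) < 2:
        raise TraceFormatError(f"{path}: need at least 2 data rows, found {len(times)}")
    t_arr = np.asarray(times)
    if time_units == "s":
        t_arr = t_arr * 1000.0
    try:
        return Trace(
            times=t_arr,
            values=np.asarray(values),
            signal_kind=signal_kind or file_kind or "raw",
            label=label if label is not None else (file_label or path.stem),
        )
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


def write_trace(
    trace: Trace, path: Union[str, Path], *, delimiter: str = ","
) -> None:
    """Write a trace as delimited text re-readable by :func:`read_trace`.

    Layout: an optional ``# label:`` comment (omitted when the label is
    empty), a ``# signal_kind:`` comment, a header row, then one
    ``time<delim>value`` row per sample at full float precision.
    """
    path = Path(path)
    lines = []
    if trace.label:
        lines.append(f"# label: {trace.label}")
    lines.append(f"# signal_kind: {trace.signal_kind}")
    lines.append(f"time_ms{delimiter}value")
    for t, v in zip(trace.times, trace.values):
        lines.append(f"{float(t)!r}{delimiter}{float(v)!r}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise TraceFormatError(f"cannot write {path}: {exc}") from exc
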