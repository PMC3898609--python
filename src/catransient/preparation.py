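"""Raw-signal preparation: background subtraction, ratio, [Ca] calibration, F/F0.

Each preparation is exposed twice, with identical numerics:

* a scikit-learn transformer over plain value arrays
  (:class:`BackgroundSubtractor`, :class:`RatiometricRatio`,
  :class:`CalciumCalibrator`, :class:`F0Normalizer`), composable in
  ``sklearn.pipeline.Pipeline``;
* a thin Trace-level function (:func:`subtract_background`, :func:`ratio`,
  :func:`calibrate_ca`, :func:`normalize_f0`) that additionally enforces the
  signal-kind preparation graph.

Background subtraction is folded into every preparation exactly once: the
ratio, calibration and normalization entry points all start from a
background-subtracted signal (the Trace functions require the
``background_subtracted`` kind; :func:`ratio` subtracts per-channel
backgrounds internally).

All fluorescence below is denoted F *after* background subtraction.  The
three conversions are

.. math::

    \\mathrm{Ratio} = F_{nom}/F_{denom}, \\qquad
    [\\mathrm{Ca}] = \\frac{F \\, K_d}{F_{max} - F}, \\qquad
    F/F_0 = F / F_0 .
"""

from __future__ import annotations

import warnings
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import Region, Trace

__all__ = [
    "BackgroundSubtractor",
    "RatiometricRatio",
    "CalciumCalibrator",
    "F0Normalizer",
    "subtract_background",
    "ratio",
    "calibrate_ca",
    "define_f0",
    "normalize_f0",
    "reduce_background",
]


def reduce_background(background: Union[float, np.ndarray, Trace]) -> float:
    """Reduce a background measurement to a scalar.

    A steady background recording carries one level; if a trace or array is
    supplied it is reduced to its mean before subtraction, so every
    preparation subtracts a single scalar per channel.
    """
    if isinstance(background, Trace):
        return float(background.values.mean())
    arr = np.asarray(background, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    return float(arr.mean())


def _check_background(f_background: float) -> float:
    f_background = float(f_background)
    if f_background < 0:
        raise ValueError("background fluorescence must be >= 0")
    return f_background


class BackgroundSubtractor(TransformerMixin, BaseEstimator):
    """Subtract a scalar background fluorescence from every sample.

    Parameters
    ----------
    f_background : float, default 0.0
        Field-of-view fluorescence with the cell absent, in the same
        arbitrary units as the signal.  Must be non-negative.
    """

    def __init__(self, f_background: float = 0.0):
        self.f_background = f_background

    def fit(self, X, y=None):
        _check_background(self.f_background)
        X = check_array(X, ensure_2d=False)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False)
        return X - self.f_background

    def inverse_transform(self, X):
        check_is_fitted(self)
        return check_array(X, ensure_2d=False) + self.f_background


class RatiometricRatio(TransformerMixin, BaseEstimator):
    """Form the ratiometric signal F_nom / F_denom from a two-column array.

    Per-channel backgrounds are subtracted first.  Transform input is an
    ``(n, 2)`` array whose first column is the nominator channel and second
    the denominator; output is ``(n,)``.

    Raises at transform time if any background-subtracted denominator
    sample is <= 0, identifying the sample index (the ratio would be
    meaningless or divergent there).
    """

    def __init__(self, bg_nom: float = 0.0, bg_denom: float = 0.0):
        self.bg_nom = bg_nom
        self.bg_denom = bg_denom

    def fit(self, X, y=None):
        _check_background(self.bg_nom)
        _check_background(self.bg_denom)
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("expected two columns: nominator, denominator")
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("expected two columns: nominator, denominator")
        nom = X[:, 0] - self.bg_nom
        denom = X[:, 1] - self.bg_denom
        bad = np.flatnonzero(denom <= 0)
        if bad.size:
            raise ValueError(
                f"background-subtracted denominator <= 0 at sample index "
                f"{int(bad[0])} (value {denom[bad[0]]:g})"
            )
        return nom / denom


class CalciumCalibrator(TransformerMixin, BaseEstimator):
    """Calibrate background-subtracted fluorescence to [Ca] in nM.

    Implements ``[Ca] = F * Kd / (Fmax - F)`` for a non-ratiometric
    indicator (e.g. fluo-3), where ``kd`` is the indicator's dissociation
    constant (nM) and ``f_max`` its fluorescence at saturating calcium.

    Samples at or above ``f_max`` abort the calibration (the formula
    diverges — the indicator is saturated).  Samples <= 0 are clamped to
    0 nM with a warning; the physically meaningful domain is (0, f_max).
    """

    def __init__(self, kd: float = 400.0, f_max: float = 1.0):
        self.kd = kd
        self.f_max = f_max

    def fit(self, X, y=None):
        if self.kd is None or self.kd <= 0:
            raise ValueError("kd must be > 0 (nM)")
        if self.f_max is None or self.f_max <= 0:
            raise ValueError("f_max must be > 0")
        X = check_array(X, ensure_2d=False)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        F = check_array(X, ensure_2d=False)
        bad = np.flatnonzero(F >= self.f_max)
        if bad.size:
            raise ValueError(
                f"saturated sample at index {int(bad[0])}: F = "
                f"{F[bad[0]]:g} >= f_max = {self.f_max:g}; calibration aborted"
            )
        nonpos = F <= 0
        if np.any(nonpos):
            warnings.warn(
                f"{int(nonpos.sum())} sample(s) with F <= 0 clamped to 0 nM",
                UserWarning,
                stacklevel=2,
            )
            F = np.where(nonpos, 0.0, F)
        return F * self.kd / (self.f_max - F)

    def inverse_transform(self, X):
        check_is_fitted(self)
        ca = check_array(X, ensure_2d=False)
        return ca * self.f_max / (self.kd + ca)


class F0Normalizer(TransformerMixin, BaseEstimator):
    """Convert background-subtracted fluorescence to the pseudo-ratio F/F0.

    ``f0`` is the diastolic (resting) fluorescence.  It may be supplied
    directly, or estimated by ``fit`` as the mean over a baseline slice of
    the training signal (``baseline_slice``), mirroring the cursor-flanked
    averaging workflow.
    """

    def __init__(self, f0: Optional[float] = None, baseline_slice: Optional[slice] = None):
        self.f0 = f0
        self.baseline_slice = baseline_slice

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False)
        if self.f0 is not None:
            f0 = float(self.f0)
        elif self.baseline_slice is not None:
            seg = np.ravel(X)[self.baseline_slice]
            if seg.size == 0:
                raise ValueError("baseline_slice selects no samples")
            f0 = float(seg.mean())
        else:
            raise ValueError("provide f0 or baseline_slice")
        if f0 <= 0:
            raise ValueError(f"f0 must be > 0 (got {f0:g})")
        self.f0_ = f0
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return check_array(X, ensure_2d=False) / self.f0_

    def inverse_transform(self, X):
        check_is_fitted(self)
        return check_array(X, ensure_2d=False) * self.f0_


# ---------------------------------------------------------------------------
# Trace-level preparation functions (enforce the signal-kind graph)
# ---------------------------------------------------------------------------

def subtract_background(trace: Trace, f_background: float) -> Trace:
    """Subtract scalar background fluorescence from a raw trace."""
    if trace.signal_kind != "raw":
        raise ValueError(
            f"background subtraction applies to raw traces, got "
            f"{trace.signal_kind!r} (it is performed exactly once)"
        )
    sub = BackgroundSubtractor(_check_background(f_background)).fit(trace.values)
    return trace.with_values(sub.transform(trace.values), "background_subtracted")


def ratio(
    nominator: Trace,
    denominator: Trace,
    bg_nom: float = 0.0,
    bg_denom: float = 0.0,
) -> Trace:
    """Ratio two raw channel traces, subtracting per-channel backgrounds first.

    The traces must share their time base sample for sample.
    """
    for tr, name in ((nominator, "nominator"), (denominator, "denominator")):
        if tr.signal_kind not in ("raw", "background_subtracted"):
            raise ValueError(f"{name} must be a raw or background-subtracted trace")
    if nominator.n_samples != denominator.n_samples or not np.allclose(
        nominator.times, denominator.times, rtol=0, atol=1e-9 * nominator.dt
    ):
        raise ValueError("nominator and denominator must share the same time base")
    X = np.column_stack([nominator.values, denominator.values])
    rat = RatiometricRatio(bg_nom=bg_nom, bg_denom=bg_denom).fit(X)
    values = rat.transform(X)
    return Trace(
        times=nominator.times,
        values=values,
        signal_kind="ratio",
        label=nominator.label,
    )


def calibrate_ca(trace: Trace, kd: float, f_max: float) -> Trace:
    """Calibrate a background-subtracted trace to [Ca] in nM."""
    if trace.signal_kind != "background_subtracted":
        raise ValueError(
            "[Ca] calibration requires a background-subtracted trace "
            f"(got {trace.signal_kind!r})"
        )
    cal = CalciumCalibrator(kd=kd, f_max=f_max).fit(trace.values)
    return trace.with_values(cal.transform(trace.values), "calcium_nM")


def define_f0(trace: Trace, region: Region) -> float:
    """Define F0 as the arithmetic mean over a cursor-flanked region."""
    mask = region.mask(trace)
    if not mask.any():
        raise ValueError(
            f"region [{region.t_start}, {region.t_end}] ms contains no samples"
        )
    return float(trace.values[mask].mean())


def normalize_f0(trace: Trace, f0: float) -> Trace:
    """Convert a background-subtracted trace to the pseudo-ratio F/F0.

    The same shared ``f0`` may be applied to every treatment, or re-defined
    per treatment via :func:`define_f0`; both paths simply pass a scalar
    here.
    """
    if trace.signal_kind != "background_subtracted":
        raise ValueError(
            "F/F0 conversion requires a background-subtracted trace "
            f"(got {trace.signal_kind!r})"
        )
    norm = F0Normalizer(f0=f0).fit(trace.values)
    return trace.with_values(norm.transform(trace.values), "f_over_f0")
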