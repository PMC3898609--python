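"""Exponential decay kinetics of the Ca transient by nonlinear least squares.

The decay phase of a transient is modelled as a single exponential

.. math::  y(t) = Y_0 + A_1 e^{-k_1 t}

or a double exponential

.. math::  y(t) = Y_0 + A_1 e^{-k_1 t} + A_2 e^{-k_2 t}

with rate constants k in 1/ms and t the time elapsed since the start of the
fit window.  Fits are bounded-iteration least squares (a trust-region
reflective routine) started from cursor-derived initial guesses:

* Y0 and A come from baseline/peak cursor levels; the initial A is the
  cursor amplitude (peak minus baseline);
* the initial k is 1/tau, with tau read off the experimental curve as the
  time to first fall below the 1/e level between the cursors ("smart" rate
  constant prediction); with smart prediction off, tau defaults to a fifth
  of the window duration;
* the double model splits the single-model guess through four user
  constants: A1 = A/a, A2 = A/b, k1 = k/c, k2 = k/d (defaults 2, 2, 0.5, 2
  — amplitudes split evenly, one component twice as fast and one half as
  fast as the single-model rate).

Goodness of fit is reported as R² = 1 − SSreg/SStotal and as adjusted
R² = 1 − (SSreg/(n−p))/(SStotal/(n−1)); the parameter-count penalty makes
the 3-parameter single and 5-parameter double fits of the same window
directly comparable, which is what :func:`indicate_best_fit` compares.

:class:`ExponentialDecayRegressor` packages the whole procedure as a
scikit-learn estimator; the module-level functions are the individual
steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .core import FitResult, Region, Trace

__all__ = [
    "InitialGuess",
    "FitWindow",
    "GoodnessOfFit",
    "TauFallbackWarning",
    "DEFAULT_DIVISORS",
    "single_exponential",
    "double_exponential",
    "extract_fit_window",
    "estimate_tau",
    "initial_guess_single",
    "initial_guess_double",
    "fit_single",
    "fit_double",
    "fit_simultaneous",
    "goodness_of_fit",
    "indicate_best_fit",
    "ExponentialDecayRegressor",
]

#: Default user constants (a, b, c, d) splitting a single-model guess into
#: double-model starting values.
DEFAULT_DIVISORS = (2.0, 2.0, 0.5, 2.0)

_K_FLOOR = 1e-12  # lower bound keeping rate constants strictly positive


class TauFallbackWarning(UserWarning):
    """The 1/e level was never crossed; tau fell back to half the window."""


def single_exponential(t: np.ndarray, y0: float, a: float, k: float) -> np.ndarray:
    """Monoexponential decay ``y0 + a*exp(-k*t)``."""
    return y0 + a * np.exp(-k * np.asarray(t, dtype=float))


def double_exponential(
    t: np.ndarray, y0: float, a1: float, k1: float, a2: float, k2: float
) -> np.ndarray:
    """Biexponential decay ``y0 + a1*exp(-k1*t) + a2*exp(-k2*t)``."""
    t = np.asarray(t, dtype=float)
    return y0 + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


@dataclass(frozen=True)
class InitialGuess:
    """Starting parameters for the least-squares loop.

    ``y0``/``a``/``k`` are the single-model start (cursor baseline, cursor
    amplitude, 1/tau).  When the guess has been split for the double model,
    ``a1``/``a2``/``k1``/``k2`` hold the component starts and
    ``a_div``..``d_div`` record the user constants that produced them.
    ``tau_fallback`` marks a tau that came from the half-window fallback
    rather than a 1/e crossing.
    """

    y0: float
    a: float
    k: float
    tau: float
    a1: Optional[float] = None
    a2: Optional[float] = None
    k1: Optional[float] = None
    k2: Optional[float] = None
    a_div: Optional[float] = None
    b_div: Optional[float] = None
    c_div: Optional[float] = None
    d_div: Optional[float] = None
    tau_fallback: bool = False

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not np.isclose(self.k, 1.0 / self.tau, rtol=1e-12):
            raise ValueError("k must equal 1/tau")
        if self.a_div is not None and self.a1 is not None:
            if not np.isclose(self.a1, self.a / self.a_div, rtol=1e-12):
                raise ValueError("a1 must equal a / a_div")
        if self.b_div is not None and self.a2 is not None:
            if not np.isclose(self.a2, self.a / self.b_div, rtol=1e-12):
                raise ValueError("a2 must equal a / b_div")

    def as_dict(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if v is not None and v is not False
        }


@dataclass(frozen=True)
class FitWindow:
    """A cursor-flanked fit window in window-relative time.

    ``t_rel`` starts at 0 at the first in-window sample.  If the window was
    zeroed, ``y_offset`` is the baseline-cursor level subtracted from ``y``
    (so reported Y0 values must be re-offset by it).
    """

    t_rel: np.ndarray
    y: np.ndarray
    y_offset: float = 0.0
    zeroed: bool = False
    region: Optional[Region] = None


class GoodnessOfFit(NamedTuple):
    """(SSreg, SStotal, R², adjusted R²); R² fields are NaN when SStotal=0."""

    ss_reg: float
    ss_total: float
    r_squared: float
    adjusted_r_squared: float


def extract_fit_window(
    trace: Trace,
    region: Region,
    zero: bool = False,
    y0_cursor: float = 0.0,
) -> FitWindow:
    """Extract a fit window from a trace, optionally zeroing the baseline.

    Zeroing subtracts the baseline-cursor level ``y0_cursor`` from the
    window so the fitted baseline starts near 0 — an optimizer-conditioning
    aid that reduces the iterations required; the offset is recorded so the
    reported Y0 is re-offset back to original units.  The window must hold
    at least 6 samples (it must exceed the 5-parameter double model).
    """
    mask = region.mask(trace)
    n = int(mask.sum())
    if n < 6:
        raise ValueError(
            f"fit window holds {n} samples; at least 6 are required to "
            f"exceed the 5-parameter double model"
        )
    t = trace.times[mask]
    y = trace.values[mask].copy()
    offset = float(y0_cursor) if zero else 0.0
    return FitWindow(
        t_rel=t - t[0], y=y - offset, y_offset=offset, zeroed=zero, region=region
    )


def estimate_tau(
    t_rel: np.ndarray,
    y: np.ndarray,
    y0_cursor: float,
    peak_cursor: float,
) -> float:
    """Estimate the decay time constant tau (ms) from the curve itself.

    Returns the elapsed time from the window start until y first falls
    below ``y0 + (peak - y0)/e`` — for a clean monoexponential this is the
    time constant by definition.  If the level is never crossed, falls back
    to half the window duration and emits :class:`TauFallbackWarning`.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    y = np.asarray(y, dtype=float)
    if not peak_cursor > y0_cursor:
        raise ValueError(
            f"peak cursor ({peak_cursor:g}) must exceed baseline cursor "
            f"({y0_cursor:g})"
        )
    threshold = y0_cursor + (peak_cursor - y0_cursor) / np.e
    below = np.flatnonzero(y < threshold)
    below = below[below > 0]  # a crossing needs some elapsed time
    if below.size:
        return float(t_rel[below[0]] - t_rel[0])
    duration = float(t_rel[-1] - t_rel[0])
    warnings.warn(
        "decay never crossed the 1/e level inside the window; "
        "tau fell back to half the window duration",
        TauFallbackWarning,
        stacklevel=2,
    )
    return duration / 2.0


def initial_guess_single(
    t_rel: np.ndarray,
    y: np.ndarray,
    y0_cursor: float,
    peak_cursor: float,
    smart_rc: bool = True,
) -> InitialGuess:
    """Cursor-derived starting parameters for the single-exponential fit.

    Y0 starts at the baseline cursor; A at the cursor amplitude (peak minus
    baseline); k at 1/tau with tau estimated from the curve
    (:func:`estimate_tau`) when ``smart_rc`` is on, or a fifth of the
    window duration when it is off.
    """
    if not peak_cursor > y0_cursor:
        raise ValueError(
            f"peak cursor ({peak_cursor:g}) must exceed baseline cursor "
            f"({y0_cursor:g})"
        )
    t_rel = np.asarray(t_rel, dtype=float)
    fallback = False
    if smart_rc:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", TauFallbackWarning)
            tau = estimate_tau(t_rel, y, y0_cursor, peak_cursor)
            fallback = any(
                issubclass(w.category, TauFallbackWarning) for w in caught
            )
    else:
        tau = float(t_rel[-1] - t_rel[0]) / 5.0
    return InitialGuess(
        y0=float(y0_cursor),
        a=float(peak_cursor) - float(y0_cursor),
        k=1.0 / tau,
        tau=tau,
        tau_fallback=fallback,
    )


def initial_guess_double(
    single: InitialGuess,
    a_div: float = DEFAULT_DIVISORS[0],
    b_div: float = DEFAULT_DIVISORS[1],
    c_div: float = DEFAULT_DIVISORS[2],
    d_div: float = DEFAULT_DIVISORS[3],
) -> InitialGuess:
    """Split a single-model guess into double-model starting values.

    ``A1 = A/a``, ``A2 = A/b``, ``k1 = k/c``, ``k2 = k/d`` with the four
    user constants all positive.  The defaults (2, 2, 0.5, 2) split the
    amplitude evenly and start one component twice as fast and one half as
    fast as the single-model rate.
    """
    for name, val in (("a", a_div), ("b", b_div), ("c", c_div), ("d", d_div)):
        if not val > 0:
            raise ValueError(f"user constant {name} must be > 0 (got {val!r})")
    return InitialGuess(
        y0=single.y0,
        a=single.a,
        k=single.k,
        tau=single.tau,
        a1=single.a / a_div,
        a2=single.a / b_div,
        k1=single.k / c_div,
        k2=single.k / d_div,
        a_div=a_div,
        b_div=b_div,
        c_div=c_div,
        d_div=d_div,
        tau_fallback=single.tau_fallback,
    )


def goodness_of_fit(
    y: np.ndarray, y_pred: np.ndarray, p: int
) -> GoodnessOfFit:
    """Sum-of-squares goodness of fit with a parameter-count adjustment.

    R² = 1 − SSreg/SStotal; adjusted R² = 1 − (SSreg/(n−p))/(SStotal/(n−1))
    where n is the number of points and p the number of fitted parameters.
    Requires n > p.  A zero-variance window (SStotal = 0) yields NaN for
    both R² fields — the fit quality is undefined, not perfect.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    n = y.size
    if not n > p >= 1:
        raise ValueError(f"need n > p >= 1 (n={n}, p={p})")
    ss_reg = float(np.sum((y - y_pred) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        return GoodnessOfFit(ss_reg, ss_total, float("nan"), float("nan"))
    r2 = 1.0 - ss_reg / ss_total
    adj = 1.0 - (ss_reg / (n - p)) / (ss_total / (n - 1))
    return GoodnessOfFit(ss_reg, ss_total, r2, adj)


def _default_cursors(y: np.ndarray) -> tuple[float, float]:
    """Derive baseline/peak cursor levels from a decay window itself.

    The window is a decay: its start sits near the peak, its tail near the
    baseline.  The baseline cursor is the mean of the last tenth of the
    window, the peak cursor the maximum of the first tenth.
    """
    n = y.size
    m = max(3, n // 10)
    y0 = float(np.mean(y[-m:]))
    peak = float(np.max(y[:m]))
    if peak <= y0:  # inverted or flat window: fall back to global extremes
        y0, peak = float(np.min(y)), float(np.max(y))
        if peak <= y0:
            peak = y0 + 1.0  # constant window; any positive amplitude start
    return y0, peak


def _build_result(
    model: str,
    params: Sequence[float],
    t_rel: np.ndarray,
    y: np.ndarray,
    init: InitialGuess,
    converged: bool,
    y_offset: float,
    zeroed: bool,
    region: Optional[Region],
    label: str,
) -> FitResult:
    if model == "single":
        y0, a1, k1 = params
        a2 = k2 = None
        y_pred = single_exponential(t_rel, y0, a1, k1)
        p = 3
    else:
        y0, a1, k1, a2, k2 = params
        if k1 < k2:  # normalize: fast component first
            a1, k1, a2, k2 = a2, k2, a1, k1
        y_pred = double_exponential(t_rel, y0, a1, k1, a2, k2)
        p = 5
    gof = goodness_of_fit(y, y_pred, p)
    return FitResult(
        model=model,
        y0=float(y0) + y_offset,
        a1=float(a1),
        k1=float(k1),
        a2=None if a2 is None else float(a2),
        k2=None if k2 is None else float(k2),
        ss_reg=gof.ss_reg,
        ss_total=gof.ss_total,
        r_squared=gof.r_squared,
        adjusted_r_squared=gof.adjusted_r_squared,
        n_points=int(y.size),
        n_params=p,
        initial_guess=init.as_dict(),
        converged=converged,
        region=region,
        zeroed=zeroed,
        label=label,
    )


def _least_squares_fit(
    model: str,
    t_rel: np.ndarray,
    y: np.ndarray,
    x0: np.ndarray,
    max_iterations: int,
    tolerance: float,
) -> tuple[np.ndarray, bool]:
    """Bounded-iteration trust-region least squares; never raises."""
    if model == "single":
        def residual(p):
            return single_exponential(t_rel, *p) - y
        lower = [-np.inf, -np.inf, _K_FLOOR]
        upper = [np.inf, np.inf, np.inf]
    else:
        def residual(p):
            return double_exponential(t_rel, *p) - y
        lower = [-np.inf, -np.inf, _K_FLOOR, -np.inf, _K_FLOOR]
        upper = [np.inf] * 5
    x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
    try:
        sol = least_squares(
            residual,
            x0,
            bounds=(lower, upper),
            method="trf",
            max_nfev=max_iterations,
            xtol=tolerance,
            ftol=tolerance,
            gtol=tolerance,
        )
    except Exception:
        return x0, False
    if not np.all(np.isfinite(sol.x)):
        return x0, False
    return sol.x, bool(sol.success)


def fit_single(
    t_rel: np.ndarray,
    y: np.ndarray,
    init: Optional[InitialGuess] = None,
    *,
    max_iterations: int = 1000,
    tolerance: float = 1e-10,
    y_offset: float = 0.0,
    zeroed: bool = False,
    region: Optional[Region] = None,
    label: str = "",
) -> FitResult:
    """Least-squares single-exponential fit of a decay window.

    Minimizes sum((y − (Y0 + A·exp(−k·t)))²) over (Y0, A, k) from ``init``
    (cursor-derived defaults when omitted).  On optimizer failure the
    initial guess is echoed back with ``converged=False`` — never a crash.
    ``y_offset``/``zeroed`` re-offset the reported Y0 for zeroed windows.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("single-exponential fit needs at least 4 samples")
    if init is None:
        y0c, peakc = _default_cursors(y)
        init = initial_guess_single(t_rel, y, y0c, peakc)
    x0 = np.array([init.y0, init.a, init.k])
    if not np.all(np.isfinite(x0)):
        raise ValueError(f"initial guess must be finite, got {x0}")
    params, converged = _least_squares_fit(
        "single", t_rel, y, x0, max_iterations, tolerance
    )
    return _build_result(
        "single", params, t_rel, y, init, converged, y_offset, zeroed, region, label
    )


def fit_double(
    t_rel: np.ndarray,
    y: np.ndarray,
    init: Optional[InitialGuess] = None,
    *,
    divisors: Sequence[float] = DEFAULT_DIVISORS,
    max_iterations: int = 1000,
    tolerance: float = 1e-10,
    y_offset: float = 0.0,
    zeroed: bool = False,
    region: Optional[Region] = None,
    label: str = "",
) -> FitResult:
    """Least-squares double-exponential fit of a decay window.

    Minimizes over the 5 parameters (Y0, A1, k1, A2, k2); output components
    are ordered fast first (k1 >= k2).  ``init`` may be a split double
    guess or a single guess, which is split through ``divisors``.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 6:
        raise ValueError("double-exponential fit needs at least 6 samples")
    if init is None:
        y0c, peakc = _default_cursors(y)
        init = initial_guess_single(t_rel, y, y0c, peakc)
    if init.a1 is None:
        init = initial_guess_double(init, *divisors)
    x0 = np.array([init.y0, init.a1, init.k1, init.a2, init.k2])
    if not np.all(np.isfinite(x0)):
        raise ValueError(f"initial guess must be finite, got {x0}")
    params, converged = _least_squares_fit(
        "double", t_rel, y, x0, max_iterations, tolerance
    )
    return _build_result(
        "double", params, t_rel, y, init, converged, y_offset, zeroed, region, label
    )


def fit_simultaneous(
    t_rel: np.ndarray,
    y: np.ndarray,
    init: Optional[InitialGuess] = None,
    *,
    divisors: Sequence[float] = DEFAULT_DIVISORS,
    max_iterations: int = 1000,
    tolerance: float = 1e-10,
    y_offset: float = 0.0,
    zeroed: bool = False,
    region: Optional[Region] = None,
    label: str = "",
) -> tuple[FitResult, FitResult]:
    """Fit the identical window with both models.

    Because the fit region is the same, the two results' goodness-of-fit
    statistics are directly comparable (see :func:`indicate_best_fit`).
    """
    kwargs = dict(
        max_iterations=max_iterations,
        tolerance=tolerance,
        y_offset=y_offset,
        zeroed=zeroed,
        region=region,
        label=label,
    )
    single = fit_single(t_rel, y, init, **kwargs)
    double = fit_double(t_rel, y, init, divisors=divisors, **kwargs)
    return single, double


def indicate_best_fit(single: FitResult, double: FitResult) -> str:
    """Indicate which model describes the window more reliably.

    Compares adjusted R² (the parameter-count penalty makes the nested
    models directly comparable on the same window).  Ties within 1e-12 go
    to the single model (parsimony).  Both fits must share the window.
    """
    if single.model != "single" or double.model != "double":
        raise ValueError("expected a single-model and a double-model result")
    if single.n_points != double.n_points:
        raise ValueError(
            f"fits cover different windows (n={single.n_points} vs "
            f"{double.n_points}); they are not comparable"
        )
    a_s, a_d = single.adjusted_r_squared, double.adjusted_r_squared
    if np.isnan(a_d) or np.isnan(a_s):
        if np.isnan(a_d) and not np.isnan(a_s):
            return "single"
        if np.isnan(a_s) and not np.isnan(a_d):
            return "double"
        return "single"
    if a_d - a_s > 1e-12:
        return "double"
    return "single"


class ExponentialDecayRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for Ca-transient decay kinetics.

    Fits ``y = Y0 + A1 exp(-k1 t) [+ A2 exp(-k2 t)]`` to a decay window by
    bounded-iteration least squares, reproducing the full cursor workflow:
    baseline/peak cursor levels seed the initial guess, the initial rate
    constant comes from a 1/e crossing of the curve (smart prediction), and
    with ``model="both"`` the window is fitted with both models
    simultaneously and the one with the larger adjusted R² is selected.

    Parameters
    ----------
    model : {"single", "double", "both"}, default "single"
        Which decay model(s) to fit.  With "both", ``predict`` uses the
        model chosen by adjusted R².
    baseline, peak : float or None
        Y-axis cursor levels seeding Y0 and A.  When None they are derived
        from the window itself (tail mean / head maximum).
    smart_rc : bool, default True
        Estimate the initial rate constant from the curve's 1/e crossing;
        when off, tau starts at a fifth of the window duration.
    zero_fit_range : bool, default False
        Subtract the baseline cursor from the window before fitting (an
        optimizer-conditioning aid); the reported ``y0_`` is re-offset.
    a_div, b_div, c_div, d_div : float
        User constants splitting the single guess into the double start.
    max_iterations : int, default 1000
        Cap on optimizer function evaluations.
    tolerance : float, default 1e-10
        Parameter/cost tolerance of the least-squares routine.

    Attributes
    ----------
    result_ : FitResult
        The selected fit (single, double, or the adjusted-R² winner).
    single_result_, double_result_ : FitResult or None
        Per-model results, populated according to ``model``.
    best_model_ : str
        "single" or "double".
    y0_, a1_, k1_, a2_, k2_ : float
        Fitted parameters of the selected model (a2_/k2_ None for single).

    Examples
    --------
    >>> import numpy as np
    >>> t = np.arange(0.0, 600.0)
    >>> y = 1.0 + 0.5 * np.exp(-0.005 * t)
    >>> reg = ExponentialDecayRegressor().fit(t, y)
    >>> round(reg.k1_, 6)
    0.005
    """

    def __init__(
        self,
        model: str = "single",
        baseline: Optional[float] = None,
        peak: Optional[float] = None,
        smart_rc: bool = True,
        zero_fit_range: bool = False,
        a_div: float = DEFAULT_DIVISORS[0],
        b_div: float = DEFAULT_DIVISORS[1],
        c_div: float = DEFAULT_DIVISORS[2],
        d_div: float = DEFAULT_DIVISORS[3],
        max_iterations: int = 1000,
        tolerance: float = 1e-10,
    ):
        self.model = model
        self.baseline = baseline
        self.peak = peak
        self.smart_rc = smart_rc
        self.zero_fit_range = zero_fit_range
        self.a_div = a_div
        self.b_div = b_div
        self.c_div = c_div
        self.d_div = d_div
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    # sklearn API ----------------------------------------------------------

    def _validate_times(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single time column, shape (n, 1)")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D times or shape (n, 1)")
        return X

    def fit(self, X, y):
        """Fit the decay model(s) to times ``X`` (ms) and signal ``y``."""
        if self.model not in ("single", "double", "both"):
            raise ValueError("model must be 'single', 'double' or 'both'")
        t = self._validate_times(X)
        y = np.asarray(y, dtype=float)
        check_X_y(t.reshape(-1, 1), y)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        min_n = 4 if self.model == "single" else 6
        if t.size < min_n:
            raise ValueError(f"model {self.model!r} needs >= {min_n} samples")

        self.t_start_ = float(t[0])
        t_rel = t - t[0]
        if self.baseline is not None and self.peak is not None:
            y0c, peakc = float(self.baseline), float(self.peak)
        else:
            y0c, peakc = _default_cursors(y)
        offset = y0c if self.zero_fit_range else 0.0
        y_fit = y - offset
        init = initial_guess_single(
            t_rel, y_fit, y0c - offset, peakc - offset, smart_rc=self.smart_rc
        )
        divisors = (self.a_div, self.b_div, self.c_div, self.d_div)
        common = dict(
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            y_offset=offset,
            zeroed=self.zero_fit_range,
        )
        self.single_result_ = None
        self.double_result_ = None
        if self.model in ("single", "both"):
            self.single_result_ = fit_single(t_rel, y_fit, init, **common)
        if self.model in ("double", "both"):
            self.double_result_ = fit_double(
                t_rel, y_fit, init, divisors=divisors, **common
            )
        if self.model == "both":
            self.best_model_ = indicate_best_fit(
                self.single_result_, self.double_result_
            )
        else:
            self.best_model_ = self.model
        self.result_ = (
            self.single_result_
            if self.best_model_ == "single"
            else self.double_result_
        )
        self.y0_ = self.result_.y0
        self.a1_ = self.result_.a1
        self.k1_ = self.result_.k1
        self.a2_ = self.result_.a2
        self.k2_ = self.result_.k2
        self.initial_guess_ = init
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the selected fitted model at times ``X`` (ms)."""
        check_is_fitted(self, "result_")
        t = self._validate_times(X)
        return self.result_.predict(t - self.t_start_)
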