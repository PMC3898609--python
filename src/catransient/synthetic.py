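"""Seedable synthetic Ca-transient generator.

Emulates a single cardiac-myocyte Ca transient as recorded by fluorescence
photometry: a flat diastolic baseline is absent here — the trace begins at
the upstroke — followed by a saturating-exponential rise to the peak and a
mono- or biexponential decay back toward baseline, with optional additive
white Gaussian noise and a constant background offset.  Every stage of the
analysis (preparation, level measurement, decay fitting) can therefore be
exercised against known ground truth with no external recordings.

Default parameter scales follow typical myocyte transients reported by
single-wavelength indicators: rate constants of a few 1e-3 per ms
(hundreds of ms time constants), millisecond sampling, second-scale sweeps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .core import Trace

__all__ = ["TransientSpec", "make_transient", "make_ratiometric_pair"]

#: The peak is placed at this many upstroke time constants after sweep
#: start, where the rise has reached >= 99% of its amplitude, so the decay
#: region is cleanly flankable.
PEAK_TAU_MULTIPLE = 5.0


@dataclass(frozen=True)
class TransientSpec:
    """Ground-truth parameters of one synthetic transient.

    Parameters
    ----------
    baseline : float
        Diastolic signal level (signal units).
    amplitude : float
        Transient amplitude above baseline; must be > 0.
    upstroke_tau : float
        Rise time constant in ms.
    decay : {"mono", "bi"}
        Decay model.
    k : float
        Mono decay rate constant (1/ms); ignored for ``bi``.
    a1_frac : float
        Fast-component amplitude fraction for ``bi`` (0 < a1_frac < 1).
    k1, k2 : float
        Bi decay rate constants (1/ms), fast first (k1 > k2).
    duration : float
        Sweep length in ms (>= 10 sample intervals).
    dt : float
        Sample interval in ms.
    noise_sd : float
        Standard deviation of additive white Gaussian noise (signal units).
    background : float
        Constant background fluorescence added to every sample.
    seed : int
        Seed of the noise generator; the same seed reproduces the trace
        bit for bit.
    """

    baseline: float = 1.0
    amplitude: float = 0.5
    upstroke_tau: float = 20.0
    decay: str = "mono"
    k: float = 0.0033
    a1_frac: float = 0.5
    k1: float = 0.017
    k2: float = 0.0012
    duration: float = 2000.0
    dt: float = 1.0
    noise_sd: float = 0.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be >= 10*dt")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.upstroke_tau > 0:
            raise ValueError("upstroke_tau must be > 0")
        if self.decay not in ("mono", "bi"):
            raise ValueError("decay must be 'mono' or 'bi'")
        if self.decay == "mono":
            if not self.k > 0:
                raise ValueError("k must be > 0")
        else:
            if not (self.k1 > 0 and self.k2 > 0):
                raise ValueError("k1 and k2 must be > 0")
            if not self.k1 > self.k2:
                raise ValueError("k1 must exceed k2 (fast component first)")
            if not 0 < self.a1_frac < 1:
                raise ValueError("a1_frac must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time of the peak: 5 upstroke time constants into the sweep."""
        return PEAK_TAU_MULTIPLE * self.upstroke_tau

    @property
    def peak_amplitude(self) -> float:
        """Amplitude actually reached at the peak (>= 99% of nominal)."""
        return self.amplitude * (1.0 - np.exp(-PEAK_TAU_MULTIPLE))

    def decay_region(self) -> tuple[float, float]:
        """(t_start, t_end) ms of the decay phase, peak to sweep end."""
        return self.t_peak, self.duration

    def to_json(self, path: Union[str, Path]) -> None:
        """Write the generating spec as a JSON sidecar (the ground truth)."""
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "TransientSpec":
        return cls(**json.loads(Path(path).read_text()))


def _waveform(spec: TransientSpec, t: np.ndarray) -> np.ndarray:
    """Noiseless, background-free transient waveform."""
    t_peak = spec.t_peak
    rise = spec.baseline + spec.amplitude * (1.0 - np.exp(-t / spec.upstroke_tau))
    a_peak = spec.peak_amplitude
    td = t - t_peak
    if spec.decay == "mono":
        fall = spec.baseline + a_peak * np.exp(-spec.k * td)
    else:
        fall = spec.baseline + a_peak * (
            spec.a1_frac * np.exp(-spec.k1 * td)
            + (1.0 - spec.a1_frac) * np.exp(-spec.k2 * td)
        )
    return np.where(t < t_peak, rise, fall)


def make_transient(spec: TransientSpec, label: str = "synthetic") -> Trace:
    """Generate one raw synthetic transient trace.

    The decay segment satisfies the fitted decay model exactly when
    ``noise_sd`` is 0 (Y0 = background + baseline, amplitude =
    ``spec.peak_amplitude``, rates as specified).  The same seed always
    yields a bitwise-identical trace.
    """
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    values = _waveform(spec, t) + spec.background
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=t.size)
    return Trace(times=t, values=values, signal_kind="raw", label=label)


def make_ratiometric_pair(
    spec: TransientSpec,
    denom_level: float = 1.0,
    bg_nom: float = 0.0,
    bg_denom: float = 0.0,
    label: str = "synthetic",
) -> tuple[Trace, Trace]:
    """Generate a nominator/denominator channel pair for ratio preparation.

    The nominator carries the transient waveform scaled by a flat
    denominator level; ratioing the noiseless pair (after per-channel
    background subtraction) reproduces the generating waveform exactly.
    Noise of ``spec.noise_sd`` is added independently to each channel.
    """
    if not denom_level > 0:
        raise ValueError("denom_level must be > 0")
    for name, bg in (("bg_nom", bg_nom), ("bg_denom", bg_denom)):
        if bg < 0:
            raise ValueError(f"{name} must be >= 0")
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    waveform = _waveform(spec, t)
    nom = waveform * denom_level + bg_nom
    denom = np.full_like(t, denom_level) + bg_denom
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        nom = nom + rng.normal(0.0, spec.noise_sd, size=t.size)
        denom = denom + rng.normal(0.0, spec.noise_sd, size=t.size)
    return (
        Trace(times=t, values=nom, signal_kind="raw", label=f"{label}_nom"),
        Trace(times=t, values=denom, signal_kind="raw", label=f"{label}_denom"),
    )
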