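"""Shared fixtures: synthetic transients at realistic myocyte scales."""

from __future__ import annotations

import numpy as np
import pytest

from catransient import Region, TransientSpec, extract_fit_window, make_transient

# Parameter scales typical of myocyte transients reported by
# single-wavelength indicators: hundreds-of-ms decay time constants
# (mono k ~ 3e-3 /ms) and, for the biexponential case, a fast component
# roughly an order of magnitude quicker than the slow one.
MONO_PARAMS = dict(y0=2.217389, a=0.688976, k=0.003334)
BI_PARAMS = dict(y0=57.96, a1=64.19, k1=0.017, a2=59.76, k2=0.0012)


@pytest.fixture
def mono_spec() -> TransientSpec:
    return TransientSpec(
        baseline=MONO_PARAMS["y0"],
        amplitude=MONO_PARAMS["a"],
        k=MONO_PARAMS["k"],
        decay="mono",
        duration=2000.0,
    )


@pytest.fixture
def bi_spec() -> TransientSpec:
    a1, a2 = BI_PARAMS["a1"], BI_PARAMS["a2"]
    return TransientSpec(
        baseline=BI_PARAMS["y0"],
        amplitude=a1 + a2,
        a1_frac=a1 / (a1 + a2),
        k1=BI_PARAMS["k1"],
        k2=BI_PARAMS["k2"],
        decay="bi",
        duration=4000.0,
    )


@pytest.fixture
def mono_trace(mono_spec):
    return make_transient(mono_spec)


@pytest.fixture
def bi_trace(bi_spec):
    return make_transient(bi_spec)


def decay_window(spec: TransientSpec, trace=None, zero: bool = False):
    """Extract the decay-phase fit window of a (possibly noisy) transient."""
    if trace is None:
        trace = make_transient(spec)
    return extract_fit_window(
        trace, Region(*spec.decay_region()), zero=zero, y0_cursor=spec.baseline
    )


def mono_decay(t, y0, a, k):
    """Independent evaluation of the single decay model for oracles."""
    return y0 + a * np.exp(-k * np.asarray(t, float))


def grid_search_sse(t, y, center, half_width=0.5, n_axis=21):
    """Brute-force oracle: minimal SSE over a 3-D grid around ``center``.

    Spans +/- ``half_width`` (fractional) around the (y0, a, k) center at
    ``n_axis`` points per axis, evaluating the single decay model
    exhaustively.  Independent of the least-squares path it checks.
    """
    y = np.asarray(y, float)
    axes = [np.linspace(c * (1 - half_width), c * (1 + half_width), n_axis)
            for c in center]
    best = np.inf
    for y0 in axes[0]:
        for a in axes[1]:
            for k in axes[2]:
                sse = float(np.sum((y - mono_decay(t, y0, a, k)) ** 2))
                if sse < best:
                    best = sse
    return best
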