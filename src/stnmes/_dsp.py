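"""Shared DSP helpers: zero-phase FIR filtering and analytic signals.

All behavioral and spectral filters in this package are linear-phase FIR
designs applied with zero net phase, so that band-limited components stay
aligned in time with the epoch grid shared by behavior and neural data.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def odd(n: int) -> int:
    """Round up to the nearest odd integer (symmetric FIR needs odd length)."""
    n = int(n)
    return n if n % 2 == 1 else n + 1


def fir_taps(fs: float, cutoff, pass_zero, numtaps: int) -> np.ndarray:
    """Design a linear-phase FIR (Hamming-windowed sinc) filter."""
    return signal.firwin(odd(numtaps), cutoff, pass_zero=pass_zero, fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with zero phase by centered overlap-add convolution.

    A linear-phase FIR convolved in ``same`` mode, with the group delay
    removed by centering, leaves every passband component unshifted in time.
    """
    if len(taps) > x.shape[-1]:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is shorter than the "
            f"{len(taps)}-tap filter; the transient would cover the trace"
        )
    taps = np.broadcast_to(taps, x.shape[:-1] + taps.shape) if x.ndim > 1 else taps
    return signal.oaconvolve(x, taps, mode="same", axes=-1)


def envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude of a narrow-band signal via the analytic signal."""
    return np.abs(signal.hilbert(x, axis=-1))


def check_uniform(t: np.ndarray, rtol: float = 1e-9) -> float:
    """Validate a strictly increasing, uniform time grid; return its step."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > rtol * max(1.0, abs(step)) + 1e-12):
        raise ValueError("time grid is not uniformly sampled")
    return step
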