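"""Zero-phase Butterworth filtering helpers shared across the pipeline.

Every filter is applied forward-backward (:func:`scipy.signal.sosfiltfilt`),
so the magnitude response is squared (the effective order doubles) and the
group delay is exactly zero.  Zero phase matters here: any lag between the
alpha-band envelope and the low-frequency signal would corrupt their
percentile-bin pairing downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _check_edge(f: float, fs: float, name: str) -> None:
    if not 0.0 < f < fs / 2.0:
        raise ValueError(f"{name} edge {f} Hz outside (0, fs/2) for fs={fs} Hz")


def _filtfilt(sos: np.ndarray, x: np.ndarray, fs: float, f_char: float, axis: int) -> np.ndarray:
    # Narrow-band filters ring for ~1/f_char seconds; scipy's default pad
    # length (a few samples) is far too short for that, so pad with three
    # characteristic times (capped by the signal length).
    n = x.shape[axis]
    padlen = int(min(n - 1, max(15, round(3.0 * fs / f_char))))
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def bandpass(
    x: np.ndarray, lo: float, hi: float, fs: float, order: int = 2, axis: int = -1
) -> np.ndarray:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    _check_edge(lo, fs, "band-pass low")
    _check_edge(hi, fs, "band-pass high")
    if lo >= hi:
        raise ValueError(f"band-pass edges out of order: [{lo}, {hi}] Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _filtfilt(sos, x, fs, hi - lo, axis)


def lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth low-pass at ``cutoff`` Hz."""
    _check_edge(cutoff, fs, "low-pass")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return _filtfilt(sos, x, fs, cutoff, axis)


def highpass(x: np.ndarray, cutoff: float, fs: float, order: int = 2, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth high-pass at ``cutoff`` Hz."""
    _check_edge(cutoff, fs, "high-pass")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return _filtfilt(sos, x, fs, cutoff, axis)


def bandstop(
    x: np.ndarray, lo: float, hi: float, fs: float, order: int = 2, axis: int = -1
) -> np.ndarray:
    """Zero-phase Butterworth band-stop (notch) between ``lo`` and ``hi`` Hz."""
    _check_edge(lo, fs, "band-stop low")
    _check_edge(hi, fs, "band-stop high")
    if lo >= hi:
        raise ValueError(f"band-stop edges out of order: [{lo}, {hi}] Hz")
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return _filtfilt(sos, x, fs, hi - lo, axis)
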