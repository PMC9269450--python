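"""Welch spectra, individual alpha-peak detection and power-ratio covariates.

The two ratios quantify signal-to-noise around the individual alpha peak
(``Ra``, band mean at peak +- 1 Hz over the flanking-band mean) and the
relative weight of slow activity (``Rlf``, band mean over 0.1-3 Hz divided
by the band mean over 0.1-7 Hz).  Both are ratios of band *means*, so they
are invariant to global amplitude scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "SpectralSummary",
    "welch_psd",
    "find_alpha_peak",
    "band_mean",
    "alpha_flank_bands",
    "power_ratio_alpha",
    "power_ratio_lowfreq",
    "summarize",
]


@dataclass
class SpectralSummary:
    """Per-recording spectral summary (channel-average peak and ratios)."""

    freqs: np.ndarray
    psd: np.ndarray
    peak_freq: float
    ratio_alpha: float
    ratio_lowfreq: float
    peak_found: bool


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 10.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density with ``window_s``-second Hann windows.

    Frequency resolution is ``1 / window_s`` Hz (0.1 Hz for the default
    10-s window).  Accepts 1-D traces or channels x samples matrices.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples shorter than one {window_s}-s window"
        )
    return signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        axis=-1,
    )


def _channel_average(psd: np.ndarray) -> np.ndarray:
    psd = np.asarray(psd, dtype=np.float64)
    return psd if psd.ndim == 1 else psd.mean(axis=tuple(range(psd.ndim - 1)))


def find_alpha_peak(
    freqs: np.ndarray,
    psd: np.ndarray,
    f_range: tuple[float, float] = (8.0, 13.0),
    prominence: float = 0.1,
    smooth_hz: float = 1.0,
) -> tuple[float, bool]:
    """Frequency of the psd maximum inside the closed alpha range.

    Multichannel input is averaged across channels first.  The returned
    frequency is the raw argmax on the restricted grid.  To distinguish a
    genuine alpha peak from a featureless (flat, monotone or noisy 1/f)
    spectrum, the spectrum is boxcar-smoothed over ``smooth_hz`` and the
    smoothed maximum must exceed both range endpoints by the relative
    ``prominence`` margin; otherwise ``peak_found=False`` with a warning
    (flat and monotone spectra always fail this test).
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    lo, hi = f_range
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"frequency grid does not cover [{lo}, {hi}] Hz")
    sub = _channel_average(psd)[mask]
    sub_f = freqs[mask]
    peak = float(sub_f[int(np.argmax(sub))])
    if len(sub) > 2:
        df = float(np.median(np.diff(sub_f))) if len(sub_f) > 1 else smooth_hz
        width = max(1, int(round(smooth_hz / df)))
        kernel = np.ones(width)
        smoothed = np.convolve(sub, kernel, mode="same") / np.convolve(
            np.ones_like(sub), kernel, mode="same"
        )
        found = bool(smoothed.max() > (1.0 + prominence) * max(smoothed[0], smoothed[-1]))
    else:
        found = False
    if not found:
        warnings.warn(
            f"no alpha peak: spectrum shows no prominent maximum over [{lo}, {hi}] Hz "
            f"(argmax at {peak:.1f} Hz)",
            stacklevel=2,
        )
    return peak, found


def band_mean(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Mean psd over bins whose center frequency lies in the closed band."""
    freqs = np.asarray(freqs, dtype=np.float64)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{lo}, {hi}] Hz")
    return np.asarray(psd, dtype=np.float64)[..., mask].mean(axis=-1)


def alpha_flank_bands(
    peak_freq: float, convention: str = "edges"
) -> tuple[tuple[float, float], tuple[float, float]]:
    """The two flanking bands around the alpha signal band (peak +- 1 Hz).

    ``"edges"`` (default): offsets of 2-3 Hz measured from the signal-band
    edges (the "corners" at peak +- 1 Hz), giving [peak-4, peak-3] and
    [peak+3, peak+4].  ``"peak"``: offsets measured from the peak itself,
    giving [peak-3, peak-2] and [peak+2, peak+3].
    """
    if convention == "edges":
        return (peak_freq - 4.0, peak_freq - 3.0), (peak_freq + 3.0, peak_freq + 4.0)
    if convention == "peak":
        return (peak_freq - 3.0, peak_freq - 2.0), (peak_freq + 2.0, peak_freq + 3.0)
    raise ValueError(f"unknown flank convention {convention!r}")


def power_ratio_alpha(
    freqs: np.ndarray,
    psd: np.ndarray,
    peak_freq: float,
    convention: str = "edges",
) -> float:
    """Ra: mean power at peak +- 1 Hz over the mean power of the flanks."""
    pa = band_mean(freqs, psd, peak_freq - 1.0, peak_freq + 1.0)
    (l1, h1), (l2, h2) = alpha_flank_bands(peak_freq, convention)
    pn = (band_mean(freqs, psd, l1, h1) + band_mean(freqs, psd, l2, h2)) / 2.0
    if np.any(pn == 0):
        raise ValueError("zero flank power: Ra undefined")
    return pa / pn


def power_ratio_lowfreq(freqs: np.ndarray, psd: np.ndarray) -> float:
    """Rlf: mean power over 0.1-3 Hz divided by mean power over 0.1-7 Hz."""
    plf = band_mean(freqs, psd, 0.1, 3.0)
    pn = band_mean(freqs, psd, 0.1, 7.0)
    if np.any(pn == 0):
        raise ValueError("zero reference power: Rlf undefined")
    return plf / pn


def summarize(
    x: np.ndarray,
    fs: float,
    window_s: float = 10.0,
    f_range: tuple[float, float] = (8.0, 13.0),
    convention: str = "edges",
) -> SpectralSummary:
    """Welch spectrum, channel-average alpha peak and both power ratios."""
    freqs, psd = welch_psd(x, fs, window_s=window_s)
    peak, found = find_alpha_peak(freqs, psd, f_range)
    avg = _channel_average(psd)
    ra = float(power_ratio_alpha(freqs, avg, peak, convention)) if found else float("nan")
    rlf = float(power_ratio_lowfreq(freqs, avg))
    return SpectralSummary(
        freqs=freqs, psd=psd, peak_freq=peak, ratio_alpha=ra, ratio_lowfreq=rlf, peak_found=found
    )
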