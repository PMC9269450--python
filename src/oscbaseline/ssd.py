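"""Spatio-spectral decomposition (SSD).

SSD finds spatial filters ``w`` maximizing narrow-band power at the alpha
peak against power in two flanking bands by solving the generalized
eigenvalue problem ``C_s w = lambda C_n w``, where ``C_s`` is the channel
covariance of the signal-band-filtered data and ``C_n`` the average
covariance of the two flank-band-filtered data sets.  Components (filter
projections of the broadband data) are ordered by the eigenvalue, i.e. by
their band-power ratio; by convention only the leading few (default five)
are analysed further.

Narrow-band covariances estimated from finite data are close to singular,
so the flank covariance is shrunk toward the scaled identity just enough to
keep its condition number below a threshold before the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .filters import bandpass
from .recording import Recording
from .spectral import alpha_flank_bands

__all__ = ["SSDBandDesign", "SSDModel", "design_ssd_bands", "fit_ssd", "apply_ssd"]


@dataclass(frozen=True)
class SSDBandDesign:
    """Signal band (peak +- 1 Hz) and its two flanking bands."""

    signal_band: tuple[float, float]
    flank_bands: tuple[tuple[float, float], tuple[float, float]]
    peak_freq: float


@dataclass
class SSDModel:
    """Fitted spatial filters, patterns and eigenvalues.

    ``filters`` (channels x components) project data onto components;
    ``patterns`` (channels x components) are the corresponding forward
    models ``P = C_s W (W' C_s W)^-1``.  Eigenvalues are sorted descending
    and each filter column is sign-flipped so its maximal-absolute weight is
    positive.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigenvalues: np.ndarray
    band_design: SSDBandDesign
    n_kept: int
    fs: float
    cov_signal: np.ndarray
    cov_noise: np.ndarray
    shrinkage: float = 0.0
    channel_labels: list[str] | None = None


def design_ssd_bands(
    peak_freq: float, convention: str = "edges", fs: float | None = None
) -> SSDBandDesign:
    """Band design around an individual alpha peak in [8, 13] Hz."""
    if not 8.0 <= peak_freq <= 13.0:
        raise ValueError(f"alpha peak {peak_freq} Hz outside [8, 13] Hz")
    signal_band = (peak_freq - 1.0, peak_freq + 1.0)
    flanks = alpha_flank_bands(peak_freq, convention)
    edges = [*signal_band, *flanks[0], *flanks[1]]
    if min(edges) <= 0:
        raise ValueError(f"band design for peak {peak_freq} Hz reaches below 0 Hz")
    if fs is not None and max(edges) >= fs / 2.0:
        raise ValueError(f"band design for peak {peak_freq} Hz exceeds Nyquist ({fs / 2} Hz)")
    return SSDBandDesign(signal_band=signal_band, flank_bands=flanks, peak_freq=peak_freq)


def _coerce(recording) -> tuple[np.ndarray, float, list[str] | None]:
    if isinstance(recording, Recording):
        return recording.data, recording.fs, recording.channel_labels
    raise TypeError("fit_ssd/apply_ssd expect a Recording (use Recording(data, fs))")


def _shrink_to_condition(cov: np.ndarray, cond_max: float) -> tuple[np.ndarray, float]:
    """Smallest grid shrinkage toward the scaled identity meeting cond_max."""
    target = np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    for gamma in (0.0, 1e-6, 1e-4, 1e-3, 1e-2, 1e-1, 0.5):
        shrunk = (1.0 - gamma) * cov + gamma * target
        if np.linalg.cond(shrunk) <= cond_max:
            return shrunk, gamma
    raise np.linalg.LinAlgError(
        "flank-band covariance is rank-deficient beyond shrinkage repair"
    )


def _fix_signs(w: np.ndarray) -> np.ndarray:
    # Per filter column, flip so the maximal-absolute-value weight is positive.
    idx = np.argmax(np.abs(w), axis=0)
    signs = np.sign(w[idx, np.arange(w.shape[1])])
    signs[signs == 0] = 1.0
    return w * signs


def fit_ssd(
    recording: Recording,
    bands: SSDBandDesign | None = None,
    peak_freq: float | None = None,
    n_components: int = 5,
    order: int = 2,
    trim_s: float = 1.0,
    cond_max: float = 1e6,
) -> SSDModel:
    """Fit SSD filters on a multichannel recording.

    ``bands`` may be given directly or built from ``peak_freq``.  Data are
    zero-phase band-pass filtered (order-2 Butterworth) per band; ``trim_s``
    seconds are dropped from both ends before covariance estimation to
    suppress filter transients.
    """
    data, fs, labels = _coerce(recording)
    if bands is None:
        if peak_freq is None:
            raise ValueError("provide either bands or peak_freq")
        bands = design_ssd_bands(peak_freq, fs=fs)
    if data.shape[0] < 2:
        raise ValueError("SSD needs at least 2 channels")
    if data.shape[1] / fs < 10.0:
        raise ValueError("SSD needs at least 10 s of data for stable narrow-band covariances")

    trim = int(round(trim_s * fs))
    sl = slice(trim, data.shape[1] - trim) if data.shape[1] > 4 * trim else slice(None)

    xs = bandpass(data, *bands.signal_band, fs, order=order)[:, sl]
    cov_s = np.cov(xs)
    covs_flank = []
    for lo, hi in bands.flank_bands:
        xf = bandpass(data, lo, hi, fs, order=order)[:, sl]
        covs_flank.append(np.cov(xf))
    cov_n_raw = (covs_flank[0] + covs_flank[1]) / 2.0
    cov_n, gamma = _shrink_to_condition(cov_n_raw, cond_max)

    evals, evecs = linalg.eigh(cov_s, cov_n)
    order_desc = np.argsort(evals)[::-1]
    evals = evals[order_desc]
    w = _fix_signs(evecs[:, order_desc])
    patterns = cov_s @ w @ np.linalg.inv(w.T @ cov_s @ w)
    return SSDModel(
        filters=w,
        patterns=patterns,
        eigenvalues=evals,
        band_design=bands,
        n_kept=min(n_components, data.shape[0]),
        fs=fs,
        cov_signal=cov_s,
        cov_noise=cov_n,
        shrinkage=gamma,
        channel_labels=list(labels) if labels is not None else None,
    )


def apply_ssd(
    recording: Recording, model: SSDModel, n_components: int | None = None
) -> np.ndarray:
    """Project broadband data onto the leading SSD components (k x samples)."""
    data, _fs, labels = _coerce(recording)
    if data.shape[0] != model.filters.shape[0]:
        raise ValueError(
            f"recording has {data.shape[0]} channels, model was fitted on "
            f"{model.filters.shape[0]}"
        )
    if (
        labels is not None
        and model.channel_labels is not None
        and list(labels) != list(model.channel_labels)
    ):
        raise ValueError("channel labels differ between recording and fitted model")
    k = model.n_kept if n_components is None else min(n_components, model.filters.shape[1])
    return model.filters[:, :k].T @ data
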