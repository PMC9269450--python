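"""The multichannel recording container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np


@dataclass
class Recording:
    """A channels x samples signal matrix with sampling rate and labels.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in volts or arbitrary units.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names; auto-generated (``ch01`` ...) when omitted.
    meta
        Provenance map (seeds, source configuration, reference scheme ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 2:
            raise ValueError("Recording data must be a 2-D channels x samples matrix")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n_ch = self.data.shape[0]
        if self.channel_labels is None:
            width = max(2, len(str(n_ch)))
            self.channel_labels = [f"ch{i + 1:0{width}d}" for i in range(n_ch)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [self.channel_labels[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-finite samples in channel(s): {', '.join(names)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, **meta_updates: Any) -> "Recording":
        """Copy of the recording with new samples and updated provenance."""
        meta = {**self.meta, **meta_updates}
        return replace(self, data=np.asarray(data, dtype=np.float64), meta=meta)
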