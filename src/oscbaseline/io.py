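"""Formats, pipeline configuration and the end-to-end analysis chain.

The pipeline mirrors the standard resting-state analysis: broadband filter
(0.1-100 Hz) and notch, resample to 1000 Hz, common-average reference,
Welch spectrum and individual alpha-peak detection, SSD spatial filtering
(first five components), then per-component alpha-peak re-detection and
BSI with a segment-shuffle permutation test.

Recordings are exchanged as TSV (header row of channel labels, one sample
per row) or as raw little-endian float64 channel-major binary next to a
JSON sidecar carrying the sampling rate, shape, labels and provenance.
BrainVision / EDF files are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bsi import BSIResult, compute_bsi_significance
from .filters import bandpass, bandstop
from .recording import Recording
from .spectral import (
    SpectralSummary,
    find_alpha_peak,
    power_ratio_alpha,
    power_ratio_lowfreq,
    summarize,
    welch_psd,
)
from .ssd import SSDModel, apply_ssd, design_ssd_bands, fit_ssd
from .synthetic import derive_seed

logger = logging.getLogger("oscbaseline")

__all__ = [
    "FormatError",
    "PipelineConfig",
    "PipelineResult",
    "read_recording",
    "write_recording",
    "common_average_reference",
    "reject_high_amplitude",
    "preprocess",
    "run_pipeline",
    "load_config_file",
]


class FormatError(ValueError):
    """Malformed recording file or sidecar."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their conventional defaults."""

    broadband: tuple[float, float] | None = (0.1, 100.0)
    broadband_order: int = 2
    notch: tuple[float, float] | None = (48.0, 52.0)
    notch_order: int = 2
    resample_to: float | None = 1000.0
    car: bool = True
    reject_threshold: float | None = None
    welch_window_s: float = 10.0
    alpha_peak_range: tuple[float, float] = (8.0, 13.0)
    flank_convention: str = "edges"
    alpha_half_width: float = 2.0
    alpha_order: int = 2
    lowfreq_cutoff: float = 3.0
    lowfreq_order: int = 4
    lowfreq_highpass: float | None = 0.1
    n_ssd_components: int = 5
    per_component_peak: bool = True
    n_bins: int = 20
    n_perm: int = 500
    max_segment_s: float = 90.0
    alternative: str = "two-sided"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        coerced = dict(d)
        for key in ("broadband", "notch", "alpha_peak_range"):
            if coerced.get(key) is not None:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Outputs of the full chain with provenance."""

    spectral: SpectralSummary
    ssd_model: SSDModel | None
    components: np.ndarray | None
    bsi_table: pd.DataFrame
    bsi_results: list[BSIResult] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def peak_found(self) -> bool:
        return self.spectral.peak_found


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Read a TOML or YAML configuration file into a dictionary."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    raise FormatError(f"unsupported config format: {path.suffix!r} (use .toml or .yaml)")


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def write_recording(rec: Recording, path: str | Path, fmt: str | None = None) -> Path:
    """Write a recording as TSV or raw binary + JSON sidecar.

    Binary format: little-endian float64, channel-major (C order), with a
    sidecar ``<stem>.json``.  TSV: header row of channel labels, one sample
    per row, ``%.17g`` formatting so the round-trip is bit-exact.
    """
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix.lower() == ".tsv" else "bin")
    if fmt == "tsv":
        path = path.with_suffix(".tsv")
        header = "\t".join(rec.channel_labels)
        np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="", fmt="%.17g")
        sidecar = path.with_suffix(".json")
    elif fmt == "bin":
        path = path.with_suffix(".bin")
        rec.data.astype("<f8").tofile(path)
        sidecar = path.with_suffix(".json")
    else:
        raise FormatError(f"unknown recording format {fmt!r}")
    sidecar.write_text(
        json.dumps(
            {
                "fs": rec.fs,
                "shape": list(rec.data.shape),
                "dtype": "<f8",
                "order": "channel-major",
                "channel_labels": rec.channel_labels,
                "meta": _json_safe(rec.meta),
            },
            indent=1,
        )
    )
    return path


def _read_tsv(path: Path) -> tuple[np.ndarray, list[str] | None, float | None, dict]:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    try:
        [float(h) for h in header]
        labels, skip = None, 0  # headerless numeric TSV
    except ValueError:
        labels, skip = header, 1
    data = np.loadtxt(path, delimiter="\t", skiprows=skip, ndmin=2).T
    fs = None
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        fs = side.get("fs")
        meta = side.get("meta", {})
        labels = side.get("channel_labels", labels)
    return data, labels, fs, meta


def _read_bin(path: Path) -> tuple[np.ndarray, list[str] | None, float, dict]:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar} for raw binary recording")
    try:
        side = json.loads(sidecar.read_text())
        fs = float(side["fs"])
        shape = tuple(side["shape"])
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    data = np.fromfile(path, dtype="<f8")
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"binary file holds {data.size} values, sidecar shape {shape} expects "
            f"{int(np.prod(shape))}"
        )
    return data.reshape(shape), side.get("channel_labels"), fs, side.get("meta", {})


def read_recording(
    path: str | Path,
    fs: float | None = None,
    fmt: str | None = None,
    rereference: bool = False,
) -> Recording:
    """Load a recording from TSV, raw binary + sidecar, BrainVision or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix == "tsv":
        data, labels, fs_side, meta = _read_tsv(path)
        fs = fs if fs is not None else fs_side
    elif suffix == "bin":
        data, labels, fs_side, meta = _read_bin(path)
        fs = fs if fs is not None else fs_side
    elif suffix in ("vhdr", "edf"):
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise FormatError("reading BrainVision/EDF requires the optional mne extra") from exc
        reader = mne.io.read_raw_brainvision if suffix == "vhdr" else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        data, labels, fs, meta = raw.get_data(), list(raw.ch_names), raw.info["sfreq"], {}
    else:
        raise FormatError(f"unsupported recording format {suffix!r}")
    if fs is None:
        raise FormatError(f"sampling rate missing for {path} (no sidecar; pass fs=)")
    rec = Recording(data, float(fs), labels, meta={**meta, "source_path": str(path)})
    if rereference:
        rec = common_average_reference(rec)
    return rec


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True), reference="CAR")


def reject_high_amplitude(
    rec: Recording, threshold: float, window_s: float = 1.0
) -> Recording:
    """Drop whole windows where any channel exceeds ``threshold`` (absolute).

    Automatic stand-in for manual artifact inspection; windows are excised
    and the remainder concatenated, with the removed fraction recorded in
    the provenance.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    win = max(1, int(round(window_s * rec.fs)))
    n_win = rec.n_samples // win
    keep_mask = np.ones(rec.n_samples, dtype=bool)
    for w in range(n_win):
        sl = slice(w * win, (w + 1) * win)
        if np.abs(rec.data[:, sl]).max() > threshold:
            keep_mask[sl] = False
    removed = 1.0 - keep_mask.mean()
    if removed > 0:
        logger.info("amplitude rejection removed %.1f%% of samples", 100 * removed)
    return rec.with_data(rec.data[:, keep_mask], rejected_fraction=float(removed))


def preprocess(rec: Recording, cfg: PipelineConfig | None = None) -> Recording:
    """Broadband filter, notch, resample, common-average reference.

    Every stage is individually toggleable (set ``broadband``/``notch``/
    ``resample_to`` to None, ``car`` to False); with all stages off the
    recording is returned unchanged.
    """
    cfg = cfg or PipelineConfig()
    data = rec.data
    fs = rec.fs
    if cfg.broadband is not None:
        if fs <= 2.0 * cfg.broadband[1]:
            raise ValueError(
                f"fs={fs} Hz too low for broadband filtering up to {cfg.broadband[1]} Hz"
            )
        data = bandpass(data, *cfg.broadband, fs, order=cfg.broadband_order)
        logger.info("broadband band-pass %s Hz", cfg.broadband)
    if cfg.notch is not None:
        data = bandstop(data, *cfg.notch, fs, order=cfg.notch_order)
        logger.info("notch %s Hz", cfg.notch)
    if cfg.resample_to is not None and cfg.resample_to != fs:
        if fs < cfg.resample_to:
            raise ValueError(f"cannot upsample from {fs} Hz to {cfg.resample_to} Hz")
        from fractions import Fraction

        frac = Fraction(cfg.resample_to / fs).limit_denominator(10000)
        from scipy.signal import resample_poly

        data = resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        fs = cfg.resample_to
        logger.info("resampled to %s Hz", fs)
    out = Recording(data, fs, rec.channel_labels, meta=dict(rec.meta))
    if cfg.reject_threshold is not None:
        out = reject_high_amplitude(out, cfg.reject_threshold)
    if cfg.car:
        out = common_average_reference(out)
        logger.info("applied common-average reference")
    return out


def run_pipeline(recording: Recording, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Preprocess -> spectrum/peak -> SSD -> per-component BSI + permutation.

    Returns a table with one row per SSD component (peak frequency, power
    ratios, Pearson and slope BSI, permutation p-value and a significance
    flag at 0.05).  When no alpha peak is found the result carries the
    spectral summary only, with ``peak_found=False`` and an empty table.
    """
    cfg = cfg or PipelineConfig()
    rec = preprocess(recording, cfg)
    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "input_meta": _json_safe(rec.meta),
    }
    spec = summarize(
        rec.data,
        rec.fs,
        window_s=cfg.welch_window_s,
        f_range=cfg.alpha_peak_range,
        convention=cfg.flank_convention,
    )
    columns = [
        "component",
        "peak_freq",
        "ratio_alpha",
        "ratio_lowfreq",
        "bsi_pearson",
        "bsi_slope",
        "p_value",
        "significant",
    ]
    if not spec.peak_found:
        logger.warning("no alpha peak in %s Hz: skipping SSD and BSI", cfg.alpha_peak_range)
        return PipelineResult(
            spectral=spec,
            ssd_model=None,
            components=None,
            bsi_table=pd.DataFrame(columns=columns),
            provenance=provenance,
        )
    logger.info("alpha peak at %.1f Hz", spec.peak_freq)
    bands = design_ssd_bands(spec.peak_freq, convention=cfg.flank_convention, fs=rec.fs)
    model = fit_ssd(rec, bands=bands, n_components=cfg.n_ssd_components)
    components = apply_ssd(rec, model)
    logger.info("SSD kept %d components (lambda1=%.2f)", model.n_kept, model.eigenvalues[0])

    rows = []
    results: list[BSIResult] = []
    for i, comp in enumerate(components):
        freqs, psd = welch_psd(comp, rec.fs, window_s=cfg.welch_window_s)
        comp_peak, comp_found = spec.peak_freq, True
        if cfg.per_component_peak:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                comp_peak, comp_found = find_alpha_peak(freqs, psd, cfg.alpha_peak_range)
            if not comp_found:
                comp_peak = spec.peak_freq
        ra = float(power_ratio_alpha(freqs, psd, comp_peak, cfg.flank_convention))
        rlf = float(power_ratio_lowfreq(freqs, psd))
        res = compute_bsi_significance(
            comp,
            comp_peak,
            rec.fs,
            n_perm=cfg.n_perm,
            seed=derive_seed(cfg.seed, 17, i),
            n_bins=cfg.n_bins,
            max_segment_s=cfg.max_segment_s,
            alternative=cfg.alternative,
            band_half_width=cfg.alpha_half_width,
            band_order=cfg.alpha_order,
            lowfreq_cutoff=cfg.lowfreq_cutoff,
            lowfreq_order=cfg.lowfreq_order,
            hp_cutoff=cfg.lowfreq_highpass,
        )
        results.append(res)
        rows.append(
            {
                "component": i + 1,
                "peak_freq": comp_peak,
                "ratio_alpha": ra,
                "ratio_lowfreq": rlf,
                "bsi_pearson": res.bsi_pearson,
                "bsi_slope": res.bsi_slope,
                "p_value": res.p_value,
                "significant": res.p_value < 0.05,
            }
        )
        logger.info(
            "component %d: peak %.1f Hz, BSI %.3f, p=%.3f", i + 1, comp_peak,
            res.bsi_pearson, res.p_value,
        )
    return PipelineResult(
        spectral=spec,
        ssd_model=model,
        components=components,
        bsi_table=pd.DataFrame(rows, columns=columns),
        bsi_results=results,
        provenance=provenance,
    )
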