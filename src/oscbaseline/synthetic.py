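"""Generative model of oscillator populations with a non-zero oscillatory mean.

Each unit in the population is a sinusoidal alpha oscillator with a
phase-locked beta harmonic and a constant offset ``r`` (the oscillatory
mean), all scaled by a shared amplitude-modulation profile ``A(t)``::

    mu(t) = A(t) * [ A_alpha sin(2 pi f_alpha t + th_a)
                     + A_beta sin(2 pi f_beta t + th_b) + r ]

Starting phases across the population are drawn from a von Mises
distribution whose concentration ``kappa`` controls spatial synchrony: large
``kappa`` yields a coherent (synchronous) population whose macroscopic alpha
amplitude grows like N, while ``kappa -> 0`` yields uniform phases and a
random-phasor sum growing like sqrt(N).  Crucially, the offset term
``A(t) * N * r`` is immune to phase dispersion, which is what makes the
baseline-shift mechanism observable even in asynchronous populations.

A compound epoch is the population sum plus pink (1/f) background noise and
white sensor noise.  Epoch sets redraw phases every epoch, mimicking a
stimulus-locked experiment; mixtures project source traces onto sensor
channels through arbitrary weight vectors for spatial-filter recovery
studies.

The population sum of equal-frequency sinusoids is computed exactly through
the complex resultant (sum of unit phasors), so simulation cost is
O(N + T) rather than O(N * T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .filters import lowpass
from .recording import Recording

__all__ = [
    "OscillatorParams",
    "PhaseConfig",
    "ModulationProfile",
    "PopulationConfig",
    "MixtureSource",
    "MixtureConfig",
    "derive_rng",
    "sample_phases",
    "pink_noise",
    "render_modulation",
    "oscillator_signal",
    "simulate_epoch",
    "simulate_epochs",
    "epoch_seeds",
    "simulate_mixture",
    "smooth_envelope",
    "single_source_mixture",
    "two_source_mixture",
    "replace_kappa",
]

# Sub-stream identifiers of the deterministic seeding scheme.  Every random
# draw uses numpy's SeedSequence([seed, stream, ...]) so that any component
# (phases of epoch k, pink noise of epoch k, sensor noise ...) can be
# regenerated in isolation.
PHASE_STREAM = 0
PINK_STREAM = 1
WHITE_STREAM = 2
EPOCH_STREAM = 3
SENSOR_STREAM = 4
SOURCE_STREAM = 5


def derive_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic child generator for ``(seed, stream...)``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def derive_seed(seed: int, *stream: int) -> int:
    """Deterministic 32-bit child seed for ``(seed, stream...)``."""
    return int(np.random.SeedSequence([int(seed), *map(int, stream)]).generate_state(1)[0])


def time_grid(fs: float, duration: float) -> np.ndarray:
    """Left-closed, right-open uniform grid ``t = 0, 1/fs, ..., duration - 1/fs``.

    The right-open convention makes time-means over integer numbers of
    cycles vanish exactly, so the mean of an oscillator trace is exactly
    ``A * r`` for constant modulation.
    """
    n = int(round(fs * duration))
    if n < 1:
        raise ValueError(f"empty grid for fs={fs}, duration={duration}")
    return np.arange(n) / fs


@dataclass(frozen=True)
class OscillatorParams:
    """Amplitudes, frequencies and oscillatory mean of a single oscillator.

    Defaults: unit alpha amplitude at 10 Hz, a quarter-amplitude beta
    harmonic at 20 Hz, oscillatory mean ``r = -0.4`` and a ``pi/4`` beta
    phase offset, which together produce the comb-like, negative-mean
    waveform the population model is built around.
    """

    a_alpha: float = 1.0
    a_beta: float = 0.25
    f_alpha: float = 10.0
    f_beta: float = 20.0
    r: float = -0.4
    beta_phase_offset: float = math.pi / 4
    #: "harmonic": th_b = 2*th_a + offset (time-shift consistent when
    #: f_beta = 2*f_alpha, the default); "shifted": th_b = th_a + offset.
    beta_phase_rule: str = "harmonic"

    def __post_init__(self) -> None:
        if self.a_alpha < 0 or self.a_beta < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.f_alpha <= 0 or self.f_beta <= 0:
            raise ValueError("frequencies must be positive")
        if self.beta_phase_rule not in ("harmonic", "shifted"):
            raise ValueError(f"unknown beta_phase_rule {self.beta_phase_rule!r}")

    def beta_phase(self, theta_alpha):
        """Beta starting phase(s) derived from the alpha phase(s)."""
        if self.beta_phase_rule == "harmonic":
            return 2.0 * np.asarray(theta_alpha) + self.beta_phase_offset
        return np.asarray(theta_alpha) + self.beta_phase_offset


@dataclass(frozen=True)
class PhaseConfig:
    """von Mises starting-phase distribution across the population.

    ``kappa`` is the concentration: ``kappa = 1`` models a synchronous
    population, ``kappa = 1e-6`` an asynchronous one (effectively uniform
    phases).  ``seed`` is the master seed of the simulation.
    """

    mu0: float = 0.0
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be nonnegative, got {self.kappa}")


@dataclass(frozen=True)
class ModulationProfile:
    """Shared amplitude-modulation profile A(t).

    ``inverted_gaussian`` mimics a stimulus-induced amplitude suppression:
    ``A(t) = 1 - depth * exp(-(t - center)^2 / (2 sigma^2))`` with
    ``sigma = sigma_left`` before the trough and ``sigma_right`` after,
    allowing an asymmetric recovery.  ``samples`` supplies an explicit
    nonnegative trace (e.g. a stochastic envelope for resting-state runs).
    """

    kind: str = "constant"
    depth: float = 0.8
    center: float = 0.5
    sigma_left: float = 0.1
    sigma_right: float = 0.2
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "inverted_gaussian", "samples"):
            raise ValueError(f"unknown modulation kind {self.kind!r}")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"depth must lie in [0, 1], got {self.depth}")
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise ValueError("Gaussian flank widths must be positive")
        if self.kind == "samples":
            if self.samples is None:
                raise ValueError("kind='samples' requires an explicit trace")
            arr = np.asarray(self.samples, dtype=np.float64)
            if (arr < 0).any():
                raise ValueError("modulation samples must be nonnegative")
            object.__setattr__(self, "samples", arr)


@dataclass(frozen=True)
class PopulationConfig:
    """Full description of one oscillator population and its noise."""

    n_oscillators: int = 30000
    params: OscillatorParams = field(default_factory=OscillatorParams)
    phases: PhaseConfig = field(default_factory=PhaseConfig)
    modulation: ModulationProfile = field(default_factory=ModulationProfile)
    # Defaults give a single-epoch alpha-band SNR of roughly 10 dB for the
    # default synchronous population (N = 30000, kappa = 1); scale them with
    # n_oscillators to preserve that SNR in scaled-down runs.
    pink_sigma: float = 10000.0
    white_sigma: float = 3000.0
    fs: float = 1000.0
    duration: float = 1.0
    n_epochs: int = 100

    def __post_init__(self) -> None:
        if self.n_oscillators < 1:
            raise ValueError("population needs at least one oscillator")
        if self.fs <= 2.0 * self.params.f_beta:
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for f_beta={self.params.f_beta} Hz"
            )
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.pink_sigma < 0 or self.white_sigma < 0:
            raise ValueError("noise sigmas must be nonnegative")


def _wrap_phase(theta: np.ndarray) -> np.ndarray:
    return (theta + math.pi) % (2.0 * math.pi) - math.pi


def _sample_phases(n: int, mu0: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if n < 1:
        raise ValueError("need at least one phase")
    return _wrap_phase(rng.vonmises(mu0, max(kappa, 1e-12), size=n))


def sample_phases(n: int, cfg: PhaseConfig) -> np.ndarray:
    """Draw ``n`` starting phases in [-pi, pi) from von Mises(mu0, kappa)."""
    return _sample_phases(n, cfg.mu0, cfg.kappa, derive_rng(cfg.seed, PHASE_STREAM))


def pink_noise(
    n_samples: int,
    fs: float,
    seed: int | np.random.Generator,
    sigma: float = 1.0,
) -> np.ndarray:
    """Pink (1/f power spectral density) noise via inverse-Fourier synthesis.

    Spectral magnitudes are set proportional to ``f**-0.5`` (power ~ 1/f),
    phases drawn uniformly, the DC bin zeroed, and the inverse transform
    rescaled so the trace has standard deviation ``sigma`` and zero mean.
    """
    if n_samples < 2:
        raise ValueError("pink noise needs at least 2 samples")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(seed, PINK_STREAM)
    n_freq = n_samples // 2 + 1
    k = np.arange(n_freq, dtype=np.float64)
    mag = np.zeros(n_freq)
    mag[1:] = k[1:] ** -0.5
    spec = mag * np.exp(2j * math.pi * rng.random(n_freq))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    if sigma == 0.0:
        return np.zeros(n_samples)
    return x * (sigma / x.std())


def render_modulation(profile: ModulationProfile, fs: float, duration: float) -> np.ndarray:
    """Evaluate the amplitude-modulation profile A(t) on the sampling grid."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = time_grid(fs, duration)
    if profile.kind == "constant":
        return np.ones_like(t)
    if profile.kind == "samples":
        if len(profile.samples) != len(t):
            raise ValueError(
                f"modulation trace has {len(profile.samples)} samples, grid has {len(t)}"
            )
        return np.asarray(profile.samples, dtype=np.float64)
    sigma = np.where(t < profile.center, profile.sigma_left, profile.sigma_right)
    return 1.0 - profile.depth * np.exp(-((t - profile.center) ** 2) / (2.0 * sigma**2))


def oscillator_signal(
    params: OscillatorParams,
    theta_alpha: float,
    profile: ModulationProfile,
    fs: float,
    duration: float,
) -> np.ndarray:
    """Trace of a single oscillator: ``A(t) * [alpha + beta + r]``."""
    if duration * params.f_alpha < 1.0:
        raise ValueError("duration must cover at least one alpha cycle")
    t = time_grid(fs, duration)
    a = render_modulation(profile, fs, duration)
    th_b = float(params.beta_phase(theta_alpha))
    return a * (
        params.a_alpha * np.sin(2.0 * math.pi * params.f_alpha * t + theta_alpha)
        + params.a_beta * np.sin(2.0 * math.pi * params.f_beta * t + th_b)
        + params.r
    )


def simulate_epoch(
    cfg: PopulationConfig,
    epoch_seed: int,
    return_phases: bool = False,
):
    """One compound epoch ``X(t) = sum_i mu_i(t) + noise``.

    Phases are freshly sampled from the configured von Mises distribution;
    pink and white noise come from independent sub-streams of
    ``epoch_seed``.  The population sum is evaluated exactly through the
    complex resultants of the alpha and beta phasors.
    """
    p = cfg.params
    t = time_grid(cfg.fs, cfg.duration)
    a = render_modulation(cfg.modulation, cfg.fs, cfg.duration)
    theta = _sample_phases(
        cfg.n_oscillators, cfg.phases.mu0, cfg.phases.kappa, derive_rng(epoch_seed, PHASE_STREAM)
    )
    z_alpha = np.exp(1j * theta).sum()
    z_beta = np.exp(1j * p.beta_phase(theta)).sum()
    x = a * (
        p.a_alpha * np.imag(z_alpha * np.exp(2j * math.pi * p.f_alpha * t))
        + p.a_beta * np.imag(z_beta * np.exp(2j * math.pi * p.f_beta * t))
        + cfg.n_oscillators * p.r
    )
    if cfg.pink_sigma > 0:
        x = x + pink_noise(len(t), cfg.fs, derive_rng(epoch_seed, PINK_STREAM), cfg.pink_sigma)
    if cfg.white_sigma > 0:
        x = x + derive_rng(epoch_seed, WHITE_STREAM).normal(0.0, cfg.white_sigma, len(t))
    if return_phases:
        return x, theta
    return x


def epoch_seeds(cfg: PopulationConfig) -> list[int]:
    """Per-epoch seeds derived from the master seed ``cfg.phases.seed``."""
    return [derive_seed(cfg.phases.seed, EPOCH_STREAM, k) for k in range(cfg.n_epochs)]


def simulate_epochs(cfg: PopulationConfig) -> np.ndarray:
    """K independent epochs (K x T matrix), fresh phase draws each epoch."""
    return np.stack([simulate_epoch(cfg, s) for s in epoch_seeds(cfg)])


def smooth_envelope(
    n_samples: int,
    fs: float,
    seed: int,
    cutoff: float = 1.0,
    floor: float = 0.2,
    order: int = 4,
) -> np.ndarray:
    """Smooth positive amplitude envelope for resting-state-like modulation.

    Rectified Gaussian noise, zero-phase low-passed at ``cutoff`` Hz,
    rescaled to unit mean and clipped from below at ``floor`` so the
    oscillation never fully vanishes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(seed, SOURCE_STREAM)
    g = rng.standard_normal(n_samples)
    env = np.abs(lowpass(g, cutoff, fs, order=order))
    env /= env.mean()
    return np.maximum(env, floor)


@dataclass(frozen=True)
class MixtureSource:
    """A source feeding the sensor mixture: a population or an explicit trace."""

    weights: np.ndarray
    population: PopulationConfig | None = None
    trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=np.float64))
        if (self.population is None) == (self.trace is None):
            raise ValueError("specify exactly one of population or trace")
        if self.trace is not None:
            object.__setattr__(self, "trace", np.asarray(self.trace, dtype=np.float64))


@dataclass(frozen=True)
class MixtureConfig:
    """Forward-mixed multichannel recording: sources x mixing weights + noise."""

    n_channels: int
    sources: Sequence[MixtureSource]
    sensor_noise_sigma: float = 0.0
    #: independent pink noise per channel, emulating the spatially diverse
    #: 1/f background of real recordings (not collinear with any source)
    sensor_pink_sigma: float = 0.0
    seed: int = 0
    fs: float | None = None

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise ValueError("mixture needs at least one source")
        for i, src in enumerate(self.sources):
            if src.weights.shape != (self.n_channels,):
                raise ValueError(
                    f"source {i}: mixing vector has shape {src.weights.shape}, "
                    f"expected ({self.n_channels},)"
                )
        rates = {s.population.fs for s in self.sources if s.population is not None}
        if self.fs is not None:
            rates.add(float(self.fs))
        if len(rates) > 1:
            raise ValueError(f"inconsistent sampling rates: {sorted(rates)}")
        if not rates:
            raise ValueError("fs required when all sources are raw traces")
        object.__setattr__(self, "fs", float(rates.pop()))


def simulate_mixture(cfg: MixtureConfig) -> tuple[Recording, dict]:
    """Render sources, mix them onto channels, add sensor noise.

    Returns the :class:`Recording` together with a ground-truth dictionary
    (source traces, mixing weights, oscillatory means) for recovery scoring.
    """
    traces = []
    r_values = []
    for i, src in enumerate(cfg.sources):
        if src.trace is not None:
            traces.append(src.trace)
            r_values.append(None)
        else:
            traces.append(simulate_epoch(src.population, derive_seed(cfg.seed, SOURCE_STREAM, i)))
            r_values.append(src.population.params.r)
    lengths = {len(tr) for tr in traces}
    if len(lengths) != 1:
        raise ValueError(f"source traces have mismatched lengths: {sorted(lengths)}")
    sources = np.stack(traces)
    weights = np.stack([src.weights for src in cfg.sources])  # (n_sources, n_channels)
    data = weights.T @ sources
    if cfg.sensor_noise_sigma > 0:
        data = data + derive_rng(cfg.seed, SENSOR_STREAM).normal(
            0.0, cfg.sensor_noise_sigma, data.shape
        )
    if cfg.sensor_pink_sigma > 0:
        for ch in range(cfg.n_channels):
            data[ch] += pink_noise(
                data.shape[1],
                cfg.fs,
                derive_rng(cfg.seed, SENSOR_STREAM, ch),
                cfg.sensor_pink_sigma,
            )
    rec = Recording(
        data,
        cfg.fs,
        meta={
            "seed": cfg.seed,
            "n_sources": len(cfg.sources),
            "sensor_noise_sigma": cfg.sensor_noise_sigma,
            "source_r": r_values,
        },
    )
    ground_truth = {"sources": sources, "weights": weights, "r": r_values}
    return rec, ground_truth


def replace_kappa(cfg: PopulationConfig, kappa: float) -> PopulationConfig:
    """Same population with a different phase concentration (shared seeds)."""
    return replace(cfg, phases=replace(cfg.phases, kappa=kappa))


def _gaussian_topography(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth single-lobe mixing vector, dominant entries positive."""
    center = rng.integers(0, n_channels)
    return np.exp(-0.5 * ((np.arange(n_channels) - center) / 1.5) ** 2) + 0.1


def single_source_mixture(
    seed: int,
    r: float = -0.4,
    fs: float = 250.0,
    duration: float = 90.0,
    n_channels: int = 6,
    n_oscillators: int = 300,
    kappa: float = 1.0,
    pink_sigma: float = 30.0,
    white_sigma: float = 10.0,
    sensor_noise_sigma: float = 20.0,
    sensor_pink_sigma: float = 60.0,
    envelope_cutoff: float = 1.0,
) -> tuple[Recording, dict]:
    """Standard recovery fixture: one alpha population mixed onto sensors.

    A partially synchronous population (kappa = 1) with oscillatory mean
    ``r``, amplitude-modulated by a seeded smooth stochastic envelope, is
    projected through a smooth positive single-lobe topography; channels
    carry independent pink background plus white sensor noise.  The ground
    truth returned alongside allows recovery and sign scoring.
    """
    n = int(round(fs * duration))
    env = smooth_envelope(n, fs, derive_rng(seed, 21), cutoff=envelope_cutoff, floor=0.2)
    pop = PopulationConfig(
        n_oscillators=n_oscillators,
        params=OscillatorParams(r=r),
        phases=PhaseConfig(mu0=0.0, kappa=kappa, seed=seed),
        modulation=ModulationProfile(kind="samples", samples=env),
        pink_sigma=pink_sigma,
        white_sigma=white_sigma,
        fs=fs,
        duration=duration,
        n_epochs=1,
    )
    weights = _gaussian_topography(n_channels, derive_rng(seed, 22))
    cfg = MixtureConfig(
        n_channels=n_channels,
        sources=[MixtureSource(weights=weights, population=pop)],
        sensor_noise_sigma=sensor_noise_sigma,
        sensor_pink_sigma=sensor_pink_sigma,
        seed=seed,
    )
    return simulate_mixture(cfg)


def two_source_mixture(
    seed: int,
    n_channels: int = 8,
    fs: float = 250.0,
    duration: float = 60.0,
    f_alpha_strong: float = 10.0,
    f_alpha_weak: float = 11.5,
    weak_scale: float = 0.4,
    sensor_noise_sigma: float = 20.0,
    sensor_pink_sigma: float = 60.0,
) -> tuple[Recording, dict]:
    """Two-source fixture: a dominant and a weaker alpha population.

    The stronger source oscillates at ``f_alpha_strong``, the weaker (scaled
    population size) at ``f_alpha_weak``; topographies are independent
    smooth lobes.  Used to score whether spatial filtering recovers the
    dominant source as component 1.
    """
    n = int(round(fs * duration))
    pops = []
    for i, (f0, n_osc) in enumerate(
        [(f_alpha_strong, 300), (f_alpha_weak, int(300 * weak_scale))]
    ):
        env = smooth_envelope(n, fs, derive_rng(seed, 23, i), cutoff=1.0, floor=0.2)
        pops.append(
            PopulationConfig(
                n_oscillators=n_osc,
                params=OscillatorParams(f_alpha=f0, f_beta=2 * f0, r=-0.4),
                phases=PhaseConfig(mu0=0.0, kappa=1.0, seed=derive_seed(seed, 24, i)),
                modulation=ModulationProfile(kind="samples", samples=env),
                pink_sigma=30.0,
                white_sigma=10.0,
                fs=fs,
                duration=duration,
                n_epochs=1,
            )
        )
    rng = derive_rng(seed, 25)
    sources = [MixtureSource(weights=_gaussian_topography(n_channels, rng), population=p) for p in pops]
    cfg = MixtureConfig(
        n_channels=n_channels,
        sources=sources,
        sensor_noise_sigma=sensor_noise_sigma,
        sensor_pink_sigma=sensor_pink_sigma,
        seed=seed,
    )
    return simulate_mixture(cfg)
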