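"""Generative model: phase sampling, noise, modulation, population sums."""

import math

import numpy as np
import pytest
from scipy.special import i0, i1

import oscbaseline as ob
from oscbaseline.synthetic import (
    derive_rng,
    epoch_seeds,
    render_modulation,
    simulate_epoch,
    smooth_envelope,
    time_grid,
)


def circular_stats(phases: np.ndarray) -> tuple[float, float]:
    """Independent oracle: resultant vector of the raw phase sample."""
    z = np.exp(1j * phases).mean()
    return float(np.angle(z)), float(np.abs(z))


class TestSamplePhases:
    @pytest.mark.parametrize("kappa", [1e-6, 1.0, 10.0])
    def test_matches_von_mises_theory(self, kappa):
        """Empirical resultant length converges to the Bessel ratio I1/I0."""
        phases = ob.sample_phases(10_000, ob.PhaseConfig(mu0=0.0, kappa=kappa, seed=5))
        assert phases.min() >= -math.pi and phases.max() < math.pi
        _, res = circular_stats(phases)
        assert res == pytest.approx(i1(kappa) / i0(kappa), abs=0.05)

    def test_circular_mean_at_mu0(self):
        phases = ob.sample_phases(10_000, ob.PhaseConfig(mu0=math.pi / 2, kappa=1.0, seed=6))
        mean_ang, res = circular_stats(phases)
        assert mean_ang == pytest.approx(math.pi / 2, abs=0.05)
        assert res == pytest.approx(i1(1) / i0(1), abs=0.05)

    def test_concentration_limit_collapses_to_mu0(self):
        phases = ob.sample_phases(5, ob.PhaseConfig(mu0=0.0, kappa=1e8, seed=7))
        assert np.all(np.abs(phases) < 1e-3)

    def test_asynchronous_sample_is_nearly_uniform(self):
        phases = ob.sample_phases(10_000, ob.PhaseConfig(mu0=0.0, kappa=1e-6, seed=8))
        _, res = circular_stats(phases)
        assert res < 0.03

    def test_deterministic_under_fixed_seed(self):
        cfg = ob.PhaseConfig(mu0=0.3, kappa=2.0, seed=9)
        assert np.array_equal(ob.sample_phases(100, cfg), ob.sample_phases(100, cfg))

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            ob.PhaseConfig(kappa=-1.0)


class TestPinkNoise:
    def test_deterministic_and_scaled(self):
        a = ob.pink_noise(4096, 1000.0, seed=1, sigma=2.0)
        b = ob.pink_noise(4096, 1000.0, seed=1, sigma=2.0)
        assert np.array_equal(a, b)
        assert a.std() == pytest.approx(2.0, rel=1e-9)
        assert abs(a.mean()) < 1e-12
        assert np.array_equal(ob.pink_noise(4096, 1000.0, seed=1, sigma=0.0), np.zeros(4096))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_psd_slope_is_one_over_f(self, seed):
        """Least-squares log-log slope of the Welch PSD over 1-100 Hz."""
        x = ob.pink_noise(2**20, 1000.0, seed=seed)
        f, psd = ob.welch_psd(x, 1000.0)
        m = (f >= 1.0) & (f <= 100.0)
        slope = np.polyfit(np.log(f[m]), np.log(psd[m]), 1)[0]
        assert -1.2 < slope < -0.8

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ob.pink_noise(1, 1000.0, seed=0)


class TestRenderModulation:
    def test_constant_is_all_ones(self, constant_profile):
        assert np.array_equal(render_modulation(constant_profile, 1000.0, 0.5), np.ones(500))

    def test_full_depth_trough_reaches_zero(self):
        prof = ob.ModulationProfile(kind="inverted_gaussian", depth=1.0, center=0.5)
        a = render_modulation(prof, 1000.0, 1.0)
        assert a[500] == pytest.approx(0.0, abs=1e-12)
        assert np.all(a >= 0)

    def test_asymmetric_flanks_use_right_width_after_center(self, gaussian_profile):
        a = render_modulation(gaussian_profile, 1000.0, 1.0)
        expected = 1.0 - 0.8 * math.exp(-(0.1**2) / (2 * 0.2**2))
        assert a[600] == pytest.approx(expected, rel=1e-12)
        # continuity at the trough center
        assert abs(a[500] - a[499]) < 1e-3

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            ob.ModulationProfile(kind="inverted_gaussian", depth=1.5)

    def test_explicit_samples_roundtrip(self):
        tr = np.linspace(0.0, 1.0, 250)
        prof = ob.ModulationProfile(kind="samples", samples=tr)
        assert np.array_equal(render_modulation(prof, 250.0, 1.0), tr)
        with pytest.raises(ValueError, match="nonnegative"):
            ob.ModulationProfile(kind="samples", samples=-tr)


class TestOscillatorSignal:
    def test_time_mean_equals_oscillatory_mean(self, default_params, constant_profile):
        """Integer alpha/beta cycles cancel: the trace mean is exactly r."""
        x = ob.oscillator_signal(default_params, 0.7, constant_profile, 1000.0, 1.0)
        assert x.mean() == pytest.approx(-0.4, abs=1e-9)

    def test_reduces_to_pure_sine(self, constant_profile):
        params = ob.OscillatorParams(a_beta=0.0, r=0.0)
        x = ob.oscillator_signal(params, 0.0, constant_profile, 1000.0, 1.0)
        t = time_grid(1000.0, 1.0)
        assert np.allclose(x, np.sin(2 * math.pi * 10.0 * t), atol=1e-12)

    def test_linear_in_modulation(self, default_params, constant_profile):
        x1 = ob.oscillator_signal(default_params, 0.3, constant_profile, 1000.0, 1.0)
        doubled = ob.ModulationProfile(kind="samples", samples=2.0 * np.ones(1000))
        x2 = ob.oscillator_signal(default_params, 0.3, doubled, 1000.0, 1.0)
        assert np.allclose(x2, 2.0 * x1, rtol=1e-12)

    def test_sub_cycle_duration_rejected(self, default_params, constant_profile):
        with pytest.raises(ValueError, match="alpha cycle"):
            ob.oscillator_signal(default_params, 0.0, constant_profile, 1000.0, 0.05)


class TestSimulateEpoch:
    def test_phasor_reduction_matches_brute_force(self, gaussian_profile):
        """The O(N+T) resultant evaluation equals per-oscillator summation."""
        cfg = ob.PopulationConfig(
            n_oscillators=50,
            phases=ob.PhaseConfig(mu0=0.2, kappa=2.0, seed=3),
            modulation=gaussian_profile,
            pink_sigma=0.0,
            white_sigma=0.0,
        )
        x, thetas = simulate_epoch(cfg, epoch_seed=99, return_phases=True)
        brute = sum(
            ob.oscillator_signal(cfg.params, th, gaussian_profile, cfg.fs, cfg.duration)
            for th in thetas
        )
        assert np.allclose(x, brute, atol=1e-8 * np.abs(brute).max())

    def test_identical_phases_superpose(self, constant_profile):
        cfg = ob.PopulationConfig(
            n_oscillators=3,
            phases=ob.PhaseConfig(mu0=0.4, kappa=1e12, seed=1),
            modulation=constant_profile,
            pink_sigma=0.0,
            white_sigma=0.0,
        )
        x = simulate_epoch(cfg, epoch_seed=5)
        single = ob.oscillator_signal(cfg.params, 0.4, constant_profile, cfg.fs, cfg.duration)
        assert np.allclose(x, 3.0 * single, rtol=1e-5, atol=1e-5)

    def test_time_mean_tracks_population_offset(self, constant_profile):
        """Mean of X over 1 s is N*r regardless of phase dispersion."""
        for kappa in (1e-6, 1.0):
            cfg = ob.PopulationConfig(
                n_oscillators=500,
                phases=ob.PhaseConfig(kappa=kappa, seed=4),
                modulation=constant_profile,
                pink_sigma=0.0,
                white_sigma=0.0,
            )
            x = simulate_epoch(cfg, epoch_seed=6)
            assert x.mean() == pytest.approx(500 * -0.4, rel=0.01)

    def test_alpha_amplitude_scaling_with_synchrony(self, constant_profile):
        """Coherent sums grow like N, random-phasor sums like sqrt(N).

        Checked against direct complex summation of the sampled phases
        (the random-phasor oracle) and as an N-ratio law.
        """
        for kappa, lo, hi in [(1e8, 3.9, 4.1), (1e-6, 1.5, 2.6)]:
            amps = {}
            for n_osc in (1000, 4000):
                cfg = ob.PopulationConfig(
                    n_oscillators=n_osc,
                    phases=ob.PhaseConfig(kappa=kappa, seed=13),
                    modulation=constant_profile,
                    pink_sigma=0.0,
                    white_sigma=0.0,
                )
                resultants = []
                for k, es in enumerate(epoch_seeds(cfg)[:40]):
                    _, thetas = simulate_epoch(cfg, es, return_phases=True)
                    resultants.append(np.abs(np.exp(1j * thetas).sum()))
                amps[n_osc] = np.mean(resultants)
            ratio = amps[4000] / amps[1000]
            assert lo < ratio < hi

    def test_envelope_magnitude_matches_phasor_oracle(self, constant_profile):
        """Alpha-band Hilbert envelope equals a_alpha * |sum of phasors|."""
        cfg = ob.PopulationConfig(
            n_oscillators=400,
            phases=ob.PhaseConfig(kappa=0.5, seed=21),
            modulation=constant_profile,
            pink_sigma=0.0,
            white_sigma=0.0,
            duration=2.0,
        )
        x, thetas = simulate_epoch(cfg, epoch_seed=8, return_phases=True)
        env = ob.hilbert_envelope(ob.alpha_band_signal(x, 10.0, cfg.fs))
        oracle = np.abs(np.exp(1j * thetas).sum())
        interior = env[500:-500]
        assert np.median(interior) == pytest.approx(oracle, rel=0.02)


class TestSimulateEpochs:
    def test_single_epoch_matches_derived_seed(self, small_population):
        import dataclasses

        cfg = dataclasses.replace(small_population, n_epochs=1)
        epochs = ob.simulate_epochs(cfg)
        assert epochs.shape == (1, 1000)
        assert np.array_equal(epochs[0], simulate_epoch(cfg, epoch_seeds(cfg)[0]))

    def test_deterministic(self, small_population):
        assert np.array_equal(ob.simulate_epochs(small_population), ob.simulate_epochs(small_population))

    def test_zero_mean_epochs_cancel_in_average(self):
        """Random-phase alpha cancels across epochs: |E|/K stays small."""
        cfg = ob.PopulationConfig(
            n_oscillators=1000,
            params=ob.OscillatorParams(r=0.0),
            phases=ob.PhaseConfig(kappa=1e-6, seed=31),
            pink_sigma=0.0,
            white_sigma=0.0,
            n_epochs=100,
        )
        e = ob.simulate_epochs(cfg).sum(axis=0)
        assert np.abs(e).max() / cfg.n_epochs < 0.02 * cfg.n_oscillators * 1.0

    def test_epoch_average_tracks_modulated_offset(self, gaussian_profile):
        """E(t)/(K N) follows r * A(t) once residual alpha is removed."""
        cfg = ob.PopulationConfig(
            n_oscillators=1000,
            phases=ob.PhaseConfig(kappa=1e-6, seed=32),
            modulation=gaussian_profile,
            pink_sigma=0.0,
            white_sigma=0.0,
            n_epochs=100,
        )
        e = ob.simulate_epochs(cfg).sum(axis=0) / (cfg.n_epochs * cfg.n_oscillators)
        from oscbaseline.filters import lowpass

        smoothed = lowpass(e, 3.0, cfg.fs, order=4)
        a = render_modulation(gaussian_profile, cfg.fs, cfg.duration)
        assert np.corrcoef(smoothed, -0.4 * a)[0, 1] > 0.95


class TestSmoothEnvelope:
    def test_positive_unit_mean_floor(self):
        env = smooth_envelope(50_000, 250.0, seed=3)
        assert env.min() >= 0.2
        assert env.mean() == pytest.approx(1.0, abs=0.05)


class TestSimulateMixture:
    def _trace_source(self, n=25_000, fs=250.0, seed=0):
        t = np.arange(n) / fs
        return np.sin(2 * math.pi * 10.0 * t + seed)

    def test_unit_mixing_isolates_channel(self):
        tr = self._trace_source()
        cfg = ob.MixtureConfig(
            n_channels=3,
            sources=[ob.MixtureSource(weights=np.array([1.0, 0.0, 0.0]), trace=tr)],
            fs=250.0,
        )
        rec, truth = ob.simulate_mixture(cfg)
        assert np.array_equal(rec.data[0], tr)
        assert np.all(rec.data[1:] == 0)
        assert np.array_equal(truth["sources"][0], tr)

    def test_two_orthogonal_sources_show_both_spectral_peaks(self):
        n, fs = 50_000, 250.0
        t = np.arange(n) / fs
        s9 = np.sin(2 * math.pi * 9.0 * t)
        s11 = np.sin(2 * math.pi * 11.0 * t)
        cfg = ob.MixtureConfig(
            n_channels=2,
            sources=[
                ob.MixtureSource(weights=np.array([1.0, 0.0]), trace=s9),
                ob.MixtureSource(weights=np.array([0.0, 1.0]), trace=s11),
            ],
            sensor_noise_sigma=0.05,
            fs=fs,
        )
        rec, _ = ob.simulate_mixture(cfg)
        f, psd = ob.welch_psd(rec.data, fs)
        assert f[np.argmax(psd[0])] == pytest.approx(9.0, abs=0.1)
        assert f[np.argmax(psd[1])] == pytest.approx(11.0, abs=0.1)

    def test_deterministic_under_seed(self):
        rec1, _ = ob.single_source_mixture(seed=77)
        rec2, _ = ob.single_source_mixture(seed=77)
        assert np.array_equal(rec1.data, rec2.data)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mixing vector"):
            ob.MixtureConfig(
                n_channels=3,
                sources=[ob.MixtureSource(weights=np.ones(2), trace=np.ones(100))],
                fs=250.0,
            )


class TestSeeding:
    def test_derive_rng_is_stable_and_stream_separated(self):
        a = derive_rng(1, 0).random(5)
        b = derive_rng(1, 0).random(5)
        c = derive_rng(1, 1).random(5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
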