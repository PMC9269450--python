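# oscbaseline

Simulation and detection of **non-zero-mean neural oscillations** via the
**baseline-shift index (BSI)**.

## The problem

Ongoing rhythms such as the EEG alpha rhythm need not oscillate around
zero.  If a rhythm has a non-zero oscillatory mean `r`, then modulating its
amplitude `A(t)` produces a slow baseline shift `∝ A(t)·r` that survives
trial averaging even when the oscillatory phases are random — so part of
what looks like an "evoked response" can be amplitude modulation of an
offset rhythm.  This package is for researchers who want to (a) simulate
populations of oscillators where this mechanism is under full control, and
(b) detect it in multichannel EEG-like recordings.

The detection chain, per recording:

1. **Spectrum** — Welch PSD (10-s windows, 0.1 Hz resolution), individual
   alpha peak in 8–13 Hz, and two SNR covariates
   `Ra = P_a / P_n` (power at peak ± 1 Hz over flanking bands) and
   `Rlf = P_lf / P_n` (0.1–3 Hz over 0.1–7 Hz).
2. **SSD** — spatio-spectral decomposition: spatial filters `w` solving
   `C_s w = λ C_n w` (signal-band vs flanking-band covariance), keeping the
   five components with the highest alpha SNR.
3. **BSI** — per component: Hilbert envelope `V_alpha` of the peak ± 2 Hz
   band-passed trace; low-frequency signal `V_bs` (3 Hz low-pass,
   0.1 Hz high-pass); 20 percentile bins of `V_alpha`; BSI = Pearson
   correlation (or regression slope) over the bin means.  `sign(BSI)`
   mirrors `sign(r)`.
4. **Permutation test** — `V_bs` is cut into 5 random contiguous segments
   (≤ 90 s each), shuffled, and re-binned against the original envelope;
   500 surrogates give the p-value.

The simulator builds populations of `N` oscillators
`μ(t) = A(t)[A_α sin(2πf_α t + θ_α) + A_β sin(2πf_β t + θ_β) + r]` with von
Mises-distributed phases (concentration `κ` controls spatial synchrony),
pink (1/f) and white noise, epoch sets with fresh phases per epoch, and
forward-mixed multichannel recordings with known ground truth.

## Worked example

```python
import oscbaseline as ob

# one alpha source with oscillatory mean r = -0.4, mixed onto 6 channels
rec, truth = ob.single_source_mixture(seed=2024, r=-0.4)

cfg = ob.PipelineConfig(resample_to=None, notch=None, n_perm=500, seed=1)
result = ob.run_pipeline(rec, cfg)
print("peak:", result.spectral.peak_freq)
print(result.bsi_table.round(3).to_string(index=False))
```

prints

```
peak: 10.0
 component  peak_freq  ratio_alpha  ratio_lowfreq  bsi_pearson  bsi_slope  p_value  significant
         1       10.0       84.228          2.230       -0.979     -0.785    0.024         True
         2       10.0        1.036          1.828       -0.718     -0.343    0.084        False
         3       10.0        0.807          1.800       -0.780     -0.515    0.060        False
         4       10.0        0.726          1.862        0.670      0.298    0.156        False
         5       10.0        0.733          1.823       -0.296     -0.146    0.578        False
```

Component 1 is the recovered alpha source: its alpha SNR (`ratio_alpha`
≈ 84) towers over the remaining components (≈ 1, pure background), its BSI
of −0.979 recovers the negative oscillatory mean the source was simulated
with, and the permutation test rejects the null (p = 0.024 < 0.05).  The
remaining components carry no source content and stay non-significant.

A command-line interface mirrors the library
(`oscbaseline {simulate | spectrum | ssd | bsi | evoked | pipeline}`);
recordings travel as TSV or raw float64 binary with a JSON sidecar, configs
as TOML or YAML.  Exit code 3 flags recordings without an alpha peak.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and limitations.

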