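# radarvitals

Non-contact respiration and heart-rate estimation from a 77 GHz FMCW
(frequency-modulated continuous-wave) millimeter-wave radar, for radar and
biomedical-signal engineers who want the full processing chain — from raw
I/Q chirp data to breathing/heart rates — reproducible in Python without
hardware.

An FMCW radar transmits linear frequency sweeps ("chirps"). For a subject at
range R₀ the mixer output of each chirp is a beat tone at f_b = 2KR₀/c
(K the chirp slope), and the tone's *phase* tracks chest displacement with
sub-wavelength sensitivity: ψ = 4πx(t)/λ. Sampling one chirp per frame gives
a slow-time phase series that carries breathing (~0.1–0.6 Hz, millimetres)
and heartbeat (~0.8–2.5 Hz, ~0.1 mm). The package implements:

1. **Preprocessing** — fast-time FFT to a range/slow-time matrix; static
   clutter removed by subtracting each range bin's slow-time mean
   y(m,n) = y₀(m,n) − (1/N)Σₙ y₀(m,n); target bin chosen by maximal
   slow-time variance.
2. **Phase extraction** — DC offset estimated by nonlinear least-squares
   circle fitting of the I/Q constellation and subtracted; phase
   demodulated with the extended DACM recursion
   ψ(n) = Σᵢ [I(i)ΔQ(i) − Q(i)ΔI(i)]/(I(i)²+Q(i)²) (no ±π wraps); a
   first-order phase difference boosts the weak heartbeat.
3. **Impulse denoising** — the package's core: *iterative VMD
   wavelet-interval-thresholding*. Variational mode decomposition (ADMM,
   α = 2000, τ = 0, ε = 10⁻⁷; mode count chosen by a lag-1 noise/signal
   cross-correlation scan over K = 2..8) splits the signal; the
   highest-frequency mode is wavelet-denoised (sym4, 4 levels, universal
   soft threshold); the removed noise component is circularly shifted to a
   random offset, added back, re-decomposed, and every mode
   interval-thresholded (whole between-zero-crossing units kept/shrunk/
   zeroed against Tᵢ = C√(2Eᵢ ln N), Eᵢ = E₁/(βρⁱ), C = 0.025, β = 0.719,
   ρ = 2.01); the loop runs A = 30 times and the versions are averaged, so
   the randomised noise cancels while the signal stays coherent.
4. **Rate estimation** — respiration from an FFT peak refined by a chirp-z
   zoom (≥100× finer grid); heartbeat isolated by an elliptic band-pass
   (0.7–3.3 Hz) plus notch filters at 2–4× the measured respiratory
   frequency, then estimated two ways (spectral FFT-CZT and time-domain
   peak seeking with a five-point spike-rejecting peak test) and arbitrated
   by an SNR-style confidence score s = E_peak/(E_signal − E_peak).

A synthetic-data module generates ground-truth-labelled I/Q cubes (beat
tones with breathing + harmonics + heartbeat phase modulation, clutter, DC
offsets, phase noise, white noise, interference bursts) so the entire chain
is testable end to end.

## Worked example

`python examples/01_simulate_and_process.py` simulates a subject at 1 m
(18 breaths/min, 78 bpm heartbeat, moderate clutter/noise/bursts) and runs
the full pipeline:

```
selected range bin : 21 (true beat bin 21)
respiration        : 17.90 bpm (truth 18.00, error 0.53%)
heart rate         : 78.35 bpm (truth 78.00, error 0.44%)
  spectral estimate 78.35 bpm, peak-seek 78.26 bpm, confidence 4.22 -> chose fft_czt
denoising SNR gain : respiration +0.15 dB, heart +0.03 dB
```

The range FFT put the beat tone exactly in the predicted bin; both vital
rates come back within half a percent; the confidence score (4.22 ≫ 0.4)
let the decision rule trust the finer spectral estimate. The other examples
demonstrate impulse denoising (`02`), VMD waveform separation (`03`) and
the decision rule on published-style estimate pairs (`04`).

A thin CLI wraps the same library calls:

```bash
radarvitals simulate --seed 5 --out cube.bin
radarvitals process --raw cube.bin --out results/
radarvitals evaluate --reports results/ --refs refs.csv
```

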