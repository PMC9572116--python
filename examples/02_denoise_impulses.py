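"""Impulse denoising on a synthetic phase-difference signal.

A two-tone signal (breathing 0.3 Hz, heartbeat 1.2 Hz, amplitudes as they
appear after phase differencing) is corrupted with isolated impulses; the
iterative VMD wavelet-interval-threshold denoiser should raise the spectral
SNR at both tone peaks.
"""

import numpy as np

from radarvitals import (
    ImpairmentModel, VMDParams, WITParams, inject_impulses, ivmd_wit,
)

fs = 20.0
t = np.arange(255) / fs
clean = 0.3 * np.sin(2 * np.pi * 0.3 * t) + 0.12 * np.sin(2 * np.pi * 1.2 * t)
noisy, positions = inject_impulses(
    clean, ImpairmentModel(impulse_rate=0.03, impulse_amp=1.0, seed=3))
print(f"{positions.size} impulses injected at frames {positions.tolist()}")

denoised, diag = ivmd_wit(noisy, WITParams(seed=1), VMDParams())
print(f"first decomposition used K1={diag.K1} modes; "
      f"per-iteration K2 in {min(diag.K2_per_iteration)}..{max(diag.K2_per_iteration)}")


def snr_db(x, f):
    e = np.abs(np.fft.rfft(x)) ** 2
    fr = np.fft.rfftfreq(len(x), 1 / fs)
    p = int(np.argmin(np.abs(fr - f)))
    p = p - 1 + int(np.argmax(e[p - 1:p + 2]))
    e3 = e[p - 1:p + 2].sum()
    return 10 * np.log10(e3 / (e.sum() - e3))


for name, f in (("breathing 0.3 Hz", 0.3), ("heartbeat 1.2 Hz", 1.2)):
    print(f"{name}: SNR {snr_db(noisy, f):6.2f} dB -> {snr_db(denoised, f):6.2f} dB")
print(f"correlation with clean signal: {np.corrcoef(denoised, clean)[0, 1]:.4f}")
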