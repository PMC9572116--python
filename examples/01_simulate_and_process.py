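"""Simulate one radar observation and run the full pipeline.

A subject breathing at 18 breaths/min with a 78 bpm heartbeat sits 1 m from
the radar; the scene includes clutter, DC offsets, white noise and
interference bursts.  The pipeline should recover both rates to ~1 bpm.
"""

import radarvitals as rv

config = rv.RadarConfig()  # 77 GHz, 256 frames at 20 Hz -> 12.8 s window
motion = rv.ChestMotionModel(
    R0=1.0,
    breath_amp=1e-3, breath_freq=0.3,   # 1 mm chest travel, 18 breaths/min
    heart_amp=1e-4, heart_freq=1.3,     # 0.1 mm ripple, 78 bpm
)
cube = rv.simulate_cube(config, motion, rv.typical_impairments(seed=7))

report = rv.run_pipeline(cube, resp_ref_bpm=18.0, heart_ref_bpm=78.0)

print(f"selected range bin : {report.bin_index} "
      f"(true beat bin {round(config.beat_frequency(1.0) / config.Fs * config.n_samples)})")
print(f"respiration        : {report.resp_bpm:.2f} bpm "
      f"(truth 18.00, error {report.resp_err_pct:.2f}%)")
print(f"heart rate         : {report.heart_bpm:.2f} bpm "
      f"(truth 78.00, error {report.heart_err_pct:.2f}%)")
print(f"  spectral estimate {60 * report.heart.f_fft_czt:.2f} bpm, "
      f"peak-seek {60 * report.heart.f_peek:.2f} bpm, "
      f"confidence {report.heart.s_fft:.2f} -> chose {report.heart.chosen}")
print(f"denoising SNR gain : respiration "
      f"{report.snr_resp_after - report.snr_resp_before:+.2f} dB, "
      f"heart {report.snr_heart_after - report.snr_heart_before:+.2f} dB")
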