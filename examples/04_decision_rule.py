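"""The confidence-gated heart-rate decision on published-style estimates.

Three situations: a confident spectral peak close to the time-domain count
(spectral wins), a diffuse spectrum (count wins), and two estimates too far
apart to corroborate each other (count wins).
"""

from radarvitals import decide_heart_rate, relative_error

cases = [
    ("confident + agreeing", 1.3657, 1.4063, 3.0, 83),
    ("diffuse spectrum", 1.0547, 1.0989, 0.2, 66),
    ("estimates disagree", 3.5245, 1.4063, 5.0, 84),
]

for label, f_czt, f_peek, s_fft, ref_bpm in cases:
    d = decide_heart_rate(f_czt, f_peek, s_fft)
    err = relative_error(d.final, ref_bpm)
    print(f"{label:22s}: spectral {f_czt:.4f} Hz / count {f_peek:.4f} Hz, "
          f"confidence {s_fft:.1f} -> {d.chosen} = {d.final:.4f} Hz "
          f"({err:.2f}% vs {ref_bpm} bpm reference)")
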