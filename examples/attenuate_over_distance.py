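"""Atmospheric attenuation of a broadband signal over a 10 m path.

Passes the same up-chirp through two atmospheres and compares how much
energy each frequency region loses.
"""

import numpy as np

from cisim import EnvironmentConditions, apply_atmospheric_attenuation, chirp_source

sig = chirp_source(2.0)  # 0 -> 11.025 kHz linear sweep
conditions = {
    "cold & dry   (0 degC,  0 % RH)": EnvironmentConditions(0, 0, distance=10.0),
    "body temp    (36 degC, 40 % RH)": EnvironmentConditions(36, 40, distance=10.0),
}

freqs = np.fft.rfftfreq(len(sig), 1 / sig.sample_rate)
p_in = np.abs(np.fft.rfft(sig.samples)) ** 2
bands = {"0.2-1 kHz": (200, 1000), "2-4 kHz": (2000, 4000), "8-11 kHz": (8000, 11025)}

for label, env in conditions.items():
    out = apply_atmospheric_attenuation(sig, env)
    p_out = np.abs(np.fft.rfft(out.samples)) ** 2
    losses = []
    for name, (lo, hi) in bands.items():
        m = (freqs >= lo) & (freqs < hi)
        loss_db = -10 * np.log10(p_out[m].sum() / p_in[m].sum())
        losses.append(f"{name}: {loss_db:5.3f} dB")
    print(f"{label}:  " + "  ".join(losses))

print("\nOver 10 m the low band is untouched while the top octave loses a")
print("measurable fraction; the warm, moist condition absorbs more at this")
print("frequency range because its O2/N2 relaxation frequencies sit higher.")
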