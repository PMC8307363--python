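"""Absolute humidity and the air-absorption coefficient.

Computes absolute humidity from temperature and relative humidity with
the Magnus saturation-pressure formula, then shows how the atmospheric
absorption of sound depends on frequency and humidity.
"""

import numpy as np

from cisim import EnvironmentConditions, absolute_humidity, absorption_coefficient

print("Absolute humidity (g water vapor per m^3 of air):")
for t, rh in [(-40, 10), (0, 20), (20, 60), (20, 85), (36, 40)]:
    print(f"  {t:>4} degC, {rh:>3} % RH -> {absolute_humidity(t, rh):6.2f} g/m^3")
print("Warm air holds far more vapor; at fixed temperature AH is linear in RH.\n")

print("Absorption coefficient alpha (dB per km) at 20 degC, 1 atm:")
freqs = [500, 1000, 2000, 4000, 8000]
print("  f (Hz)   RH=20%   RH=80%")
for f in freqs:
    a_dry = absorption_coefficient(f, EnvironmentConditions(20, 20)) * 1000
    a_moist = absorption_coefficient(f, EnvironmentConditions(20, 80)) * 1000
    print(f"  {f:>6}   {a_dry:6.2f}   {a_moist:6.2f}")
print("Absorption is negligible below ~2 kHz, grows roughly with f^2, and")
print("dry air absorbs several times more than moist air at high frequency.")
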