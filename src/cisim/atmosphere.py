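"""Atmospheric humidity and sound-absorption model.

Sound travelling from a source to a cochlear-implant microphone is
attenuated by air absorption, which depends on frequency, temperature,
humidity and static pressure.  This module provides

* the Magnus saturation-vapor-pressure approximation and the absolute
  humidity it implies (g of water vapor per m^3 of air),
* the ISO 9613-1 / ANSI S1.26 pure-tone absorption coefficient
  ``alpha`` in dB/m (classical losses plus O2 and N2 vibrational
  relaxation), and
* a zero-phase linear filter that applies the distance-dependent
  attenuation to an audio signal.

Amplitude gain over a path of length ``x`` metres is
``10 ** (-alpha_dB(f) * x / 20)``; the plane-wave pressure law
``p = p0 * exp(-alpha' x / 2)`` with a power attenuation coefficient
``alpha'`` in Np/m is equivalent, with ``alpha_dB = 10 * alpha' / ln 10``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MagnusConstants",
    "EnvironmentConditions",
    "AbsorptionCurve",
    "saturation_vapor_pressure",
    "absolute_humidity",
    "molar_water_fraction",
    "absorption_coefficient",
    "attenuation_gain",
    "apply_atmospheric_attenuation",
]

#: Reference static pressure (kPa) and reference air temperature (K)
#: used by the ISO 9613-1 relaxation-frequency expressions.
REFERENCE_PRESSURE_KPA = 101.325
REFERENCE_TEMPERATURE_K = 293.15

T_MIN_C = -40.0
T_MAX_C = 100.0


@dataclass(frozen=True)
class MagnusConstants:
    """Constants of the Magnus saturation-vapor-pressure approximation.

    ``psat(t) = A * exp(m * t / (Tn + t))`` with ``t`` in deg C and the
    result in hPa.  Valid for -40 <= t <= 100 deg C.
    """

    m: float = 17.62
    Tn: float = 243.12  # deg C
    A: float = 6.112  # hPa

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.Tn > 0 and self.A > 0):
            raise ValueError("Magnus constants must be strictly positive")


@dataclass(frozen=True)
class EnvironmentConditions:
    """Ambient conditions along the acoustic path.

    Parameters
    ----------
    temperature : float
        Air temperature in degrees Celsius, within [-40, 100].
    relative_humidity : float
        Relative humidity in percent, within [0, 100].
    pressure : float
        Static pressure in kilopascal (default one standard atmosphere).
    distance : float
        Propagation distance from source to microphone in metres.
    """

    temperature: float
    relative_humidity: float
    pressure: float = REFERENCE_PRESSURE_KPA
    distance: float = 1.0

    def __post_init__(self) -> None:
        if not (T_MIN_C <= self.temperature <= T_MAX_C):
            raise ValueError(
                "temperature must be greater or equal to -40 degC, "
                "and less or equal to 100 degC; got "
                f"{self.temperature!r}"
            )
        if not (0.0 <= self.relative_humidity <= 100.0):
            raise ValueError(
                f"relative_humidity must lie in [0, 100] %; got "
                f"{self.relative_humidity!r}"
            )
        if not self.pressure > 0:
            raise ValueError(f"pressure must be positive; got {self.pressure!r}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0 m; got {self.distance!r}")


@dataclass(frozen=True)
class AbsorptionCurve:
    """Sampled absorption coefficient: ``alpha[i]`` in dB/m at ``frequencies[i]`` Hz."""

    frequencies: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        if f.shape != a.shape:
            raise ValueError("frequencies and alpha must have the same length")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(a < 0):
            raise ValueError("alpha must be nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "alpha", a)


def saturation_vapor_pressure(
    t: float, constants: MagnusConstants = MagnusConstants()
) -> float:
    """Saturation vapor pressure of water in air, hPa, by the Magnus formula.

    Strictly increasing on the validity range [-40, 100] deg C.
    """
    t = float(t)
    if not (T_MIN_C <= t <= T_MAX_C):
        raise ValueError(
            "temperature must be greater or equal to -40 degC, "
            f"and less or equal to 100 degC; got {t!r}"
        )
    return constants.A * float(np.exp(constants.m * t / (constants.Tn + t)))


def absolute_humidity(
    t: float, rh: float, constants: MagnusConstants = MagnusConstants()
) -> float:
    """Absolute humidity in g/m^3 from temperature (degC) and RH (%).

    ``AH = 216.7 * (RH/100) * psat(t) / (273.15 + t)`` with ``psat`` in hPa.
    Linear in ``rh`` at fixed ``t`` and monotone increasing in ``t``.
    """
    rh = float(rh)
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"relative humidity must lie in [0, 100] %; got {rh!r}")
    psat = saturation_vapor_pressure(t, constants)
    return 216.7 * (rh / 100.0) * psat / (273.15 + float(t))


def molar_water_fraction(env: EnvironmentConditions) -> float:
    """Molar concentration of water vapor, percent of total moles.

    ``h = RH * psat / p`` with ``psat`` and ``p`` in the same units; this
    is the humidity variable the absorption-coefficient formula uses.
    """
    if env.pressure == 0:
        raise ValueError("pressure must be nonzero")
    psat_kpa = saturation_vapor_pressure(env.temperature) / 10.0
    return env.relative_humidity * psat_kpa / env.pressure


def absorption_coefficient(frequency, env: EnvironmentConditions):
    """Pure-tone atmospheric absorption coefficient, dB/m (ISO 9613-1).

    Sum of classical (viscous/thermal) absorption and the O2 and N2
    vibrational-relaxation terms; the relaxation frequencies depend on
    the molar water fraction, temperature ratio T/293.15 K and pressure
    ratio p/101.325 kPa.  Approximately quadratic in frequency well
    below the relaxation frequencies, and increasing with frequency.

    ``frequency`` may be a scalar or an array; the result matches its shape.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")

    T = 273.15 + env.temperature
    T0 = REFERENCE_TEMPERATURE_K
    pr = REFERENCE_PRESSURE_KPA
    pa = env.pressure
    h = molar_water_fraction(env)  # percent

    fr_o = (pa / pr) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = (
        (pa / pr)
        * (T / T0) ** (-0.5)
        * (9.0 + 280.0 * h * np.exp(-4.170 * ((T / T0) ** (-1.0 / 3.0) - 1.0)))
    )

    classical = 1.84e-11 * (pr / pa) * (T / T0) ** 0.5
    oxygen = 0.01275 * np.exp(-2239.1 / T) / (fr_o + f**2 / fr_o)
    nitrogen = 0.1068 * np.exp(-3352.0 / T) / (fr_n + f**2 / fr_n)
    alpha = 8.686 * f**2 * (classical + (T / T0) ** (-2.5) * (oxygen + nitrogen))
    return alpha if alpha.shape else float(alpha)


def absorption_curve(frequencies, env: EnvironmentConditions) -> AbsorptionCurve:
    """Evaluate the absorption coefficient on a frequency grid."""
    f = np.asarray(frequencies, dtype=float)
    return AbsorptionCurve(frequencies=f, alpha=absorption_coefficient(f, env))


def attenuation_gain(env: EnvironmentConditions, frequencies):
    """Amplitude gain over the path ``env.distance`` at each frequency.

    ``gain(f) = 10 ** (-alpha_dB(f) * x / 20)``; identically 1 when
    ``x = 0`` and multiplicative over concatenated path segments.
    """
    alpha = np.asarray(absorption_coefficient(frequencies, env), dtype=float)
    return 10.0 ** (-alpha * env.distance / 20.0)


def apply_atmospheric_attenuation(signal, env: EnvironmentConditions):
    """Apply air absorption over ``env.distance`` metres to an audio signal.

    Zero-phase frequency-domain multiplication: the real FFT of the
    samples is scaled by :func:`attenuation_gain` evaluated at each bin
    frequency, then inverted.  Output length equals input length; with
    ``distance = 0`` the signal round-trips to FFT precision.

    Parameters
    ----------
    signal : AudioSignal
        Input audio (see :mod:`cisim.signal_chain`).
    env : EnvironmentConditions
        Atmospheric conditions and path length.
    """
    from .signal_chain import AudioSignal  # local import: avoids cycle

    x = np.asarray(signal.samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot attenuate an empty signal")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / signal.sample_rate)
    spectrum *= attenuation_gain(env, freqs)
    y = np.fft.irfft(spectrum, n=x.size)
    return AudioSignal(samples=y, sample_rate=signal.sample_rate)
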