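"""Humidity quantities and the atmospheric absorption filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisim import (
    AudioSignal,
    EnvironmentConditions,
    MagnusConstants,
    absolute_humidity,
    absorption_coefficient,
    apply_atmospheric_attenuation,
    attenuation_gain,
    molar_water_fraction,
    saturation_vapor_pressure,
)
from cisim.signal_chain import chirp_source


def iso_alpha_reference(f, t_c, rh, p_kpa=101.325):
    """Independent literal transcription of the ISO 9613-1 equations.

    Kept deliberately separate from the library implementation: every
    constant is written out and the terms are evaluated step by step.
    """
    T = 273.15 + t_c
    psat_hpa = 6.112 * np.exp(17.62 * t_c / (243.12 + t_c))
    h = rh * (psat_hpa / 10.0) / p_kpa
    pa_over_pr = p_kpa / 101.325
    tr = T / 293.15
    f_ro = pa_over_pr * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    f_rn = pa_over_pr / np.sqrt(tr) * (
        9.0 + 280.0 * h * np.exp(-4.170 * (tr ** (-1.0 / 3.0) - 1.0))
    )
    term_cl = 1.84e-11 / pa_over_pr * np.sqrt(tr)
    term_o = 0.01275 * np.exp(-2239.1 / T) * (f_ro + f**2 / f_ro) ** -1
    term_n = 0.1068 * np.exp(-3352.0 / T) * (f_rn + f**2 / f_rn) ** -1
    return 8.686 * f**2 * (term_cl + tr ** (-5.0 / 2.0) * (term_o + term_n))


class TestSaturationVaporPressure:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.0, 6.112),  # exp(0) = 1 leaves the prefactor
            (20.0, 23.326),  # frozen from independent scalar evaluation
            (-40.0, 0.19021),  # same oracle, lower validity bound
        ],
    )
    def test_known_values(self, t, expected):
        assert saturation_vapor_pressure(t) == pytest.approx(expected, rel=1e-4)

    def test_strictly_increasing_on_validity_range(self):
        t = np.linspace(-40, 100, 141)
        p = np.array([saturation_vapor_pressure(ti) for ti in t])
        assert np.all(np.diff(p) > 0)

    @pytest.mark.parametrize("t", [-40.01, 100.01, -273.0])
    def test_out_of_range_temperature_rejected(self, t):
        with pytest.raises(ValueError, match="-40"):
            saturation_vapor_pressure(t)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(ValueError):
            MagnusConstants(m=-1.0)


class TestAbsoluteHumidity:
    @pytest.mark.parametrize(
        "t, rh, printed, decimals",
        [(-40, 10, 0.02, 2), (0, 20, 0.97, 2), (20, 85, 14.7, 1)],
    )
    def test_worked_values_at_printed_precision(self, t, rh, printed, decimals):
        assert round(absolute_humidity(t, rh), decimals) == printed

    def test_worked_value_20c_60rh(self):
        # literal Magnus evaluation gives ~10.35; the tabulated-psat
        # variant prints 10.37 -- both inside +/-0.03
        assert absolute_humidity(20, 60) == pytest.approx(10.37, abs=0.03)

    def test_zero_humidity_gives_zero(self):
        assert absolute_humidity(35.0, 0.0) == 0.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        t=st.floats(-40, 100),
        rh=st.floats(0.1, 100),
        scale=st.floats(0.1, 1.0),
    )
    def test_linear_in_relative_humidity(self, t, rh, scale):
        full = absolute_humidity(t, rh)
        part = absolute_humidity(t, rh * scale)
        assert part == pytest.approx(scale * full, rel=1e-12)

    def test_monotone_increasing_in_temperature(self):
        grid = np.linspace(-40, 100, 57)
        for rh in (5.0, 40.0, 100.0):
            ah = np.array([absolute_humidity(t, rh) for t in grid])
            assert np.all(np.diff(ah) > 0)

    def test_out_of_range_rh_rejected(self):
        with pytest.raises(ValueError):
            absolute_humidity(20, 101)


class TestMolarWaterFraction:
    def test_zero_rh(self):
        env = EnvironmentConditions(20, 0)
        assert molar_water_fraction(env) == 0.0

    def test_saturated_at_20c(self):
        env = EnvironmentConditions(20, 100)
        # 23.326 hPa / 1013.25 hPa x 100
        assert molar_water_fraction(env) == pytest.approx(2.302, rel=1e-3)

    def test_monotone_in_rh(self):
        fracs = [
            molar_water_fraction(EnvironmentConditions(20, rh))
            for rh in np.linspace(0, 100, 11)
        ]
        assert np.all(np.diff(fracs) > 0)


class TestAbsorptionCoefficient:
    def test_negligible_at_low_frequency(self):
        env = EnvironmentConditions(20, 50)
        assert absorption_coefficient(10.0, env) < 1e-4

    def test_increases_with_frequency(self):
        env = EnvironmentConditions(20, 50)
        assert absorption_coefficient(4000, env) > absorption_coefficient(1000, env)

    def test_dry_air_absorbs_more_at_4khz(self):
        dry = EnvironmentConditions(20, 20)
        moist = EnvironmentConditions(20, 80)
        assert absorption_coefficient(4000, dry) > absorption_coefficient(4000, moist)

    @pytest.mark.parametrize(
        "f, t, rh",
        [(1000, 20, 70), (4000, 20, 50), (8000, 0, 30), (2000, 36, 40), (500, -20, 60)],
    )
    def test_matches_independent_transcription(self, f, t, rh):
        env = EnvironmentConditions(t, rh)
        assert absorption_coefficient(f, env) == pytest.approx(
            iso_alpha_reference(f, t, rh), rel=1e-12
        )

    def test_quadratic_well_below_relaxation(self):
        env = EnvironmentConditions(20, 50)
        a1 = absorption_coefficient(20.0, env)
        a2 = absorption_coefficient(40.0, env)
        assert a2 / a1 == pytest.approx(4.0, rel=0.05)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            absorption_coefficient(-1.0, EnvironmentConditions(20, 50))


class TestAttenuationGain:
    def test_unit_gain_at_zero_distance(self):
        env = EnvironmentConditions(20, 50, distance=0.0)
        gains = attenuation_gain(env, np.array([100.0, 1000.0, 8000.0]))
        assert np.all(gains == 1.0)

    def test_doubling_distance_squares_gain(self):
        f = np.array([500.0, 2000.0, 8000.0])
        g1 = attenuation_gain(EnvironmentConditions(20, 50, distance=7.0), f)
        g2 = attenuation_gain(EnvironmentConditions(20, 50, distance=14.0), f)
        assert g2 == pytest.approx(g1**2, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(x1=st.floats(0.0, 50.0), x2=st.floats(0.0, 50.0))
    def test_composes_over_distance(self, x1, x2):
        f = np.array([1000.0, 4000.0, 10000.0])
        g12 = attenuation_gain(EnvironmentConditions(15, 30, distance=x1 + x2), f)
        g1 = attenuation_gain(EnvironmentConditions(15, 30, distance=x1), f)
        g2 = attenuation_gain(EnvironmentConditions(15, 30, distance=x2), f)
        assert g12 == pytest.approx(g1 * g2, rel=1e-9)

    def test_single_tone_closed_form(self):
        env = EnvironmentConditions(20, 50, distance=10.0)
        alpha = absorption_coefficient(4000.0, env)
        gain = attenuation_gain(env, np.array([4000.0]))[0]
        assert gain == pytest.approx(10 ** (-alpha * 10.0 / 20.0), rel=1e-12)


class TestApplyAtmosphericAttenuation:
    def test_zero_distance_is_identity(self):
        sig = chirp_source(0.5)
        out = apply_atmospheric_attenuation(
            sig, EnvironmentConditions(20, 50, distance=0.0)
        )
        assert np.max(np.abs(out.samples - sig.samples)) < 1e-9

    def test_pure_tone_amplitude_matches_per_tone_gain(self):
        fs = 22050
        t = np.arange(fs) / fs
        sig = AudioSignal(np.sin(2 * np.pi * 4000 * t), fs)
        env = EnvironmentConditions(20, 50, distance=10.0)
        out = apply_atmospheric_attenuation(sig, env)
        expected = 10 ** (-absorption_coefficient(4000.0, env) * 10.0 / 20.0)
        ratio = out.rms() / sig.rms()
        assert ratio == pytest.approx(expected, rel=0.01)

    def test_output_rms_never_exceeds_input(self):
        sig = chirp_source(0.5)
        out = apply_atmospheric_attenuation(
            sig, EnvironmentConditions(30, 20, distance=25.0)
        )
        assert out.rms() <= sig.rms()

    def test_environment_conditions_change_the_spectrum(self):
        # the two conditions the simulations compare: high frequencies
        # are attenuated more than low in both, and the spectra differ
        sig = chirp_source(1.0)
        cold_dry = apply_atmospheric_attenuation(
            sig, EnvironmentConditions(0, 0, distance=10.0)
        )
        warm_moist = apply_atmospheric_attenuation(
            sig, EnvironmentConditions(36, 40, distance=10.0)
        )
        p_cold = np.abs(np.fft.rfft(cold_dry.samples)) ** 2
        p_warm = np.abs(np.fft.rfft(warm_moist.samples)) ** 2
        assert not np.allclose(p_cold, p_warm)
        p_in = np.abs(np.fft.rfft(sig.samples)) ** 2
        freqs = np.fft.rfftfreq(len(sig), 1 / sig.sample_rate)
        lo = (freqs > 200) & (freqs < 1000)
        hi = freqs > 8000
        for p_out in (p_cold, p_warm):
            loss_lo = 1 - np.sum(p_out[lo]) / np.sum(p_in[lo])
            loss_hi = 1 - np.sum(p_out[hi]) / np.sum(p_in[hi])
            assert loss_hi > loss_lo

    def test_linearity(self):
        rng = np.random.default_rng(5)
        fs = 22050
        s1 = rng.standard_normal(4096)
        s2 = rng.standard_normal(4096)
        env = EnvironmentConditions(25, 60, distance=15.0)

        def f(x):
            return apply_atmospheric_attenuation(AudioSignal(x, fs), env).samples

        combined = f(2.0 * s1 - 0.5 * s2)
        assert combined == pytest.approx(2.0 * f(s1) - 0.5 * f(s2), abs=1e-10)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(6)
        fs = 22050
        x = rng.standard_normal(8192)
        env = EnvironmentConditions(20, 50, distance=10.0)
        y = apply_atmospheric_attenuation(AudioSignal(x, fs), env).samples
        spec = np.fft.fft(x)
        gains = attenuation_gain(env, np.abs(np.fft.fftfreq(x.size, 1 / fs)))
        expected_energy = np.sum(gains**2 * np.abs(spec) ** 2) / x.size
        assert np.sum(y**2) == pytest.approx(expected_energy, rel=1e-6)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            apply_atmospheric_attenuation(
                AudioSignal(np.array([]), 22050), EnvironmentConditions(20, 50)
            )


class TestEnvironmentConditions:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(temperature=-41, relative_humidity=50),
            dict(temperature=101, relative_humidity=50),
            dict(temperature=20, relative_humidity=-1),
            dict(temperature=20, relative_humidity=120),
            dict(temperature=20, relative_humidity=50, pressure=0),
            dict(temperature=20, relative_humidity=50, distance=-1),
        ],
    )
    def test_invalid_conditions_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnvironmentConditions(**kwargs)
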