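"""End-to-end cochlear-implant speech-processor chain.

Stages, in order: source -> optional atmospheric attenuation -> DC
blocking -> optional additive noise -> optional spectral denoising ->
8-channel analysis filter bank -> per-channel envelope extraction ->
biphasic stimulation-pulse generation.  :func:`run_scenario` wires the
stages together from a :class:`ScenarioConfig` and returns every
intermediate signal plus summary metrics; a fixed seed makes the whole
run bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.signal

from .atmosphere import EnvironmentConditions, apply_atmospheric_attenuation

__all__ = [
    "AudioSignal",
    "ScenarioConfig",
    "PulseTrainSet",
    "ScenarioResult",
    "chirp_source",
    "dc_block",
    "add_noise",
    "envelope_extract",
    "generate_pulses",
    "run_scenario",
]

DEFAULT_SAMPLE_RATE = 22050

#: Continuous-interleaved stimulation defaults: per-channel pulse rate
#: (pulses/s) and per-phase width (samples).  Full-scale envelope maps
#: to pulse amplitude PULSE_FULL_SCALE, so trains lie in (-6, 6).
DEFAULT_PULSE_RATE = 900.0
DEFAULT_PULSE_WIDTH = 10
PULSE_FULL_SCALE = 6.0


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio waveform: amplitude samples plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation run.

    ``noise`` is one of ``"none" | "gaussian" | "uniform"``; ``snr_db``
    is required exactly when noise is enabled.  ``environment`` enables
    the atmospheric pre-distortion stage.  Runs with equal configs and
    seeds produce bitwise-identical outputs.
    """

    source: str = "vowel"  # "chirp" | "vowel" | "tone" | path to a WAV file
    filter: str = "fir"  # "fir" | "iir"
    noise: str = "none"
    snr_db: Optional[float] = None
    denoise: bool = False
    environment: Optional[EnvironmentConditions] = None
    seed: int = 0
    duration: float = 5.0
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.filter.lower() not in ("fir", "iir"):
            raise ValueError(f"filter must be 'fir' or 'iir'; got {self.filter!r}")
        if self.noise not in ("none", "gaussian", "uniform"):
            raise ValueError(
                f"noise must be 'none', 'gaussian' or 'uniform'; got {self.noise!r}"
            )
        if self.noise == "none" and self.snr_db is not None:
            raise ValueError("snr_db set but noise is 'none'")
        if self.noise != "none" and self.snr_db is None:
            raise ValueError(f"noise {self.noise!r} requires snr_db")


@dataclass(frozen=True)
class PulseTrainSet:
    """Eight per-channel biphasic stimulation-pulse sequences.

    ``trains`` has shape (8, n_samples); every individual pulse has a
    positive phase followed by an equal negative phase, so its samples
    sum to zero (charge balance).
    """

    trains: np.ndarray
    sample_rate: float
    pulse_rate: float
    pulse_width: int

    def __post_init__(self) -> None:
        t = np.asarray(self.trains, dtype=float)
        if t.ndim != 2 or t.shape[0] != 8:
            raise ValueError("trains must have shape (8, n)")
        object.__setattr__(self, "trains", t)


def chirp_source(
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    f_start: float = 0.0,
    f_end: Optional[float] = None,
) -> AudioSignal:
    """Linear up-chirp at unit amplitude sweeping ``f_start``..``f_end`` Hz.

    ``f_end`` defaults to the Nyquist frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyquist = sample_rate / 2.0
    if f_end is None:
        f_end = nyquist
    if not (0 <= f_start < f_end <= nyquist):
        raise ValueError(
            f"need 0 <= f_start < f_end <= Nyquist; got {f_start}, {f_end}"
        )
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    x = scipy.signal.chirp(t, f0=f_start, f1=f_end, t1=duration, method="linear")
    return AudioSignal(samples=x, sample_rate=sample_rate)


def dc_block(signal: AudioSignal, pole: float = 0.995) -> AudioSignal:
    """First-order DC-blocking high-pass ``H(z) = (1 - z^-1)/(1 - pole z^-1)``.

    Gain at DC is exactly zero; at Nyquist it is ``2 / (1 + pole)``.
    """
    if not (0.0 < pole < 1.0):
        raise ValueError(f"pole must lie in (0, 1); got {pole!r}")
    y = scipy.signal.lfilter([1.0, -1.0], [1.0, -pole], signal.samples)
    return AudioSignal(samples=y, sample_rate=signal.sample_rate)


def add_noise(
    signal: AudioSignal, kind: str, snr_db: float, seed: int
) -> AudioSignal:
    """Add Gaussian or symmetric-uniform noise at an exact empirical SNR.

    The raw noise realization is rescaled so that the per-realization
    power ratio matches ``snr_db`` exactly, hence the measured SNR of
    the returned signal equals the request to float precision.
    """
    x = signal.samples
    p_signal = float(np.mean(x**2))
    if p_signal == 0:
        raise ValueError("signal has zero power; SNR is undefined")
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        d = rng.standard_normal(x.size)
    elif kind == "uniform":
        d = rng.uniform(-1.0, 1.0, x.size)
    else:
        raise ValueError(f"noise kind must be 'gaussian' or 'uniform'; got {kind!r}")
    p_noise_target = p_signal / 10.0 ** (snr_db / 10.0)
    d *= np.sqrt(p_noise_target / np.mean(d**2))
    return AudioSignal(samples=x + d, sample_rate=signal.sample_rate)


def envelope_extract(band: AudioSignal, cutoff: float = 200.0) -> AudioSignal:
    """Envelope of one subband: full-wave rectification + one-pole lowpass.

    The lowpass has unit DC gain, so a steady tone of amplitude ``a``
    settles to a mean envelope near ``2a/pi``.
    """
    if not (0 < cutoff < band.sample_rate / 2):
        raise ValueError(
            f"cutoff must lie in (0, Nyquist); got {cutoff!r} at fs={band.sample_rate}"
        )
    rectified = np.abs(band.samples)
    a = float(np.exp(-2.0 * np.pi * cutoff / band.sample_rate))
    env = scipy.signal.lfilter([1.0 - a], [1.0, -a], rectified)
    return AudioSignal(samples=env, sample_rate=band.sample_rate)


def generate_pulses(
    envelopes: list[AudioSignal],
    pulse_rate: float = DEFAULT_PULSE_RATE,
    pulse_width: int = DEFAULT_PULSE_WIDTH,
    amplitude_scale: float = 1.0,
) -> PulseTrainSet:
    """Sample the 8 envelopes into interleaved biphasic pulse trains.

    Each channel emits ``floor(duration * pulse_rate)`` pulses; channel
    ``c`` starts ``c / (8 * pulse_rate)`` seconds late so no two
    channels stimulate simultaneously (continuous interleaved
    scheduling).  A pulse at onset sample ``n0`` is ``+A`` for
    ``pulse_width`` samples then ``-A`` for ``pulse_width`` samples,
    with ``A = envelope[n0] * amplitude_scale``.
    """
    if len(envelopes) != 8:
        raise ValueError(f"expected 8 envelopes; got {len(envelopes)}")
    fs = envelopes[0].sample_rate
    if any(e.sample_rate != fs for e in envelopes):
        raise ValueError("all envelopes must share one sample rate")
    if pulse_rate * pulse_width * 2 > fs:
        raise ValueError(
            f"pulses too wide for rate: {pulse_rate} pps x {2 * pulse_width} "
            f"samples exceeds fs={fs}"
        )
    n = len(envelopes[0])
    duration = n / fs
    n_pulses = int(np.floor(duration * pulse_rate))
    trains = np.zeros((8, n))
    for c, env in enumerate(envelopes):
        offset = c / (8.0 * pulse_rate)
        for k in range(n_pulses):
            n0 = int(round((k / pulse_rate + offset) * fs))
            n1 = n0 + pulse_width
            n2 = n1 + pulse_width
            if n2 > n:
                break
            amp = env.samples[n0] * amplitude_scale
            trains[c, n0:n1] = amp
            trains[c, n1:n2] = -amp
    return PulseTrainSet(
        trains=trains, sample_rate=fs, pulse_rate=pulse_rate, pulse_width=pulse_width
    )


@dataclass(frozen=True)
class ScenarioResult:
    """Everything :func:`run_scenario` computes.

    Intermediate signals are kept so the pipeline can be inspected and
    exported stage by stage; ``metrics`` holds per-channel RMS values
    and, for noise scenarios, the SNR before and after denoising.
    """

    config: ScenarioConfig
    source: AudioSignal
    received: AudioSignal  # after optional atmospheric attenuation
    dc_blocked: AudioSignal
    noisy: Optional[AudioSignal]
    denoised: Optional[AudioSignal]
    processed: AudioSignal  # signal entering the filter bank
    bands: list[AudioSignal]
    envelopes: list[AudioSignal]
    pulses: PulseTrainSet
    metrics: dict


def _measure_snr(reference: np.ndarray, test: np.ndarray) -> float:
    noise = test - reference
    return float(
        10.0 * np.log10(np.mean(reference**2) / np.mean(noise**2))
    )


def _make_source(config: ScenarioConfig) -> AudioSignal:
    from .io import make_fixture, read_wav  # local import: avoids cycle

    if config.source == "chirp":
        return chirp_source(config.duration, config.sample_rate)
    if config.source in ("vowel", "tone"):
        return make_fixture(
            config.source, config.duration, config.sample_rate, seed=config.seed
        )
    return read_wav(config.source)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run the full processing chain described by ``config``.

    Returns every stage output plus summary metrics.  With a fixed
    seed, reruns are bitwise identical.
    """
    from .denoise import denoise_signal  # local import: avoids cycle
    from .filterbank import analyze, default_band_edges, design_bank

    source = _make_source(config)

    received = source
    if config.environment is not None:
        received = apply_atmospheric_attenuation(source, config.environment)

    blocked = dc_block(received)

    noisy = None
    denoised = None
    processed = blocked
    metrics: dict = {}
    if config.noise != "none":
        noisy = add_noise(blocked, config.noise, config.snr_db, seed=config.seed)
        processed = noisy
        metrics["snr_in_db"] = _measure_snr(blocked.samples, noisy.samples)
    if config.denoise:
        denoised = denoise_signal(processed)
        processed = denoised
        if noisy is not None:
            n = min(len(blocked), len(denoised))
            metrics["snr_out_db"] = _measure_snr(
                blocked.samples[:n], denoised.samples[:n]
            )

    bank = design_bank(
        config.filter, default_band_edges(), sample_rate=config.sample_rate
    )
    bands = analyze(processed, bank)
    envelopes = [envelope_extract(b) for b in bands]

    peak = max(float(np.max(np.abs(e.samples))) for e in envelopes)
    scale = PULSE_FULL_SCALE / peak if peak > 0 else 1.0
    pulses = generate_pulses(envelopes, amplitude_scale=scale)

    metrics["channel_rms"] = [b.rms() for b in bands]
    metrics["envelope_rms"] = [e.rms() for e in envelopes]
    return ScenarioResult(
        config=config,
        source=source,
        received=received,
        dc_blocked=blocked,
        noisy=noisy,
        denoised=denoised,
        processed=processed,
        bands=bands,
        envelopes=envelopes,
        pulses=pulses,
        metrics=metrics,
    )
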