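"""WAV / CSV / JSON input-output, scenario configuration and fixtures.

WAV files are read and written through :mod:`scipy.io.wavfile`: PCM16
is mapped to float in [-1, 1), float32 passes through unchanged, and
stereo inputs are downmixed to mono with a warning.  Scenario
configuration files are TOML; every run can emit a :class:`RunManifest`
recording the configuration, seed and output paths so that reruns are
bitwise reproducible.
"""

from __future__ import annotations

import json
import tomllib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.io.wavfile

from . import __version__
from .atmosphere import EnvironmentConditions
from .signal_chain import AudioSignal, ScenarioConfig, chirp_source

__all__ = [
    "read_wav",
    "write_wav",
    "load_config",
    "make_fixture",
    "RunManifest",
    "write_csv",
    "read_csv",
]

_CONFIG_KEYS = {
    "source",
    "filter",
    "noise",
    "snr_db",
    "denoise",
    "seed",
    "duration",
    "sample_rate",
    "temperature",
    "relative_humidity",
    "pressure",
    "distance",
}


def read_wav(path) -> AudioSignal:
    """Read a mono (or downmixed stereo) WAV file as float samples.

    PCM16 samples are scaled by 1/32768 into [-1, 1); float32 data is
    passed through.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such WAV file: {path}")
    try:
        rate, data = scipy.io.wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"malformed WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input downmixed to mono", stacklevel=2)
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")
    return AudioSignal(samples=samples, sample_rate=float(rate))


def write_wav(path, signal: AudioSignal, subtype: str = "float32") -> None:
    """Write a mono WAV file, ``subtype`` either ``"float32"`` or ``"pcm16"``."""
    path = Path(path)
    if subtype == "float32":
        data = signal.samples.astype(np.float32)
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise ValueError(f"subtype must be 'float32' or 'pcm16'; got {subtype!r}")
    scipy.io.wavfile.write(path, int(signal.sample_rate), data)


def load_config(path) -> ScenarioConfig:
    """Load a scenario configuration from a TOML key/value file.

    Unknown keys are rejected; an empty file yields the full default
    configuration.  Environment keys (``temperature``,
    ``relative_humidity``, ``pressure``, ``distance``) jointly define
    the optional atmospheric stage.
    """
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    env = None
    if "temperature" in raw or "relative_humidity" in raw:
        env = EnvironmentConditions(
            temperature=raw.get("temperature", 20.0),
            relative_humidity=raw.get("relative_humidity", 50.0),
            pressure=raw.get("pressure", 101.325),
            distance=raw.get("distance", 1.0),
        )
    elif "pressure" in raw or "distance" in raw:
        raise ValueError(
            "pressure/distance given without temperature or relative_humidity"
        )
    kwargs = {k: raw[k] for k in raw if k in ScenarioConfig.__dataclass_fields__}
    return ScenarioConfig(environment=env, **kwargs)


def _formant_shape(freqs: np.ndarray, center: float, bandwidth: float) -> np.ndarray:
    # magnitude of a single resonance, unit peak
    return 1.0 / np.sqrt(1.0 + ((freqs - center) / (bandwidth / 2.0)) ** 2)


def make_fixture(
    kind: str,
    duration: float = 5.0,
    sample_rate: float = 22050,
    seed: int = 0,
    tone_freq: float = 1000.0,
) -> AudioSignal:
    """Deterministic test sources: ``chirp``, ``tone`` or ``vowel``.

    The vowel is a synthetic stand-in for a voice recording: a harmonic
    stack at F0 = 120 Hz shaped by two formant resonances (700 and
    1200 Hz) plus gentle spectral rolloff, bandlimited to 8.5 kHz, with
    seed-controlled harmonic phases.  Like an utterance, it starts
    after a short silence (0.15 s) and is modulated by a 4 Hz raised-
    cosine syllabic envelope with near-silent troughs.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = round(duration * sample_rate)
    t = np.arange(n) / sample_rate
    if kind == "chirp":
        return chirp_source(duration, sample_rate)
    if kind == "tone":
        return AudioSignal(
            samples=np.sin(2 * np.pi * tone_freq * t), sample_rate=sample_rate
        )
    if kind == "vowel":
        rng = np.random.default_rng(seed)
        f0 = 120.0
        f_max = min(8500.0, sample_rate / 2.0)
        harmonics = np.arange(1, int(f_max // f0) + 1)
        freqs = harmonics * f0
        weights = (
            _formant_shape(freqs, 700.0, 120.0)
            + 0.6 * _formant_shape(freqs, 1200.0, 150.0)
        ) / np.sqrt(freqs / f0)
        phases = rng.uniform(0, 2 * np.pi, harmonics.size)
        x = np.zeros(n)
        for w, f, ph in zip(weights, freqs, phases):
            x += w * np.sin(2 * np.pi * f * t + ph)
        lead = 0.15  # onset silence, s
        syllables = 0.5 * (1.0 - np.cos(2 * np.pi * 4.0 * (t - lead)))
        syllables[t < lead] = 0.0
        x *= syllables
        x /= np.max(np.abs(x))
        return AudioSignal(samples=x, sample_rate=sample_rate)
    raise ValueError(f"fixture kind must be 'chirp', 'tone' or 'vowel'; got {kind!r}")


@dataclass(frozen=True)
class RunManifest:
    """Record of one simulation run: config echo, seed, outputs, metrics."""

    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    @classmethod
    def from_run(cls, config: ScenarioConfig, outputs: dict, metrics: dict):
        cfg = asdict(config)
        return cls(
            config=cfg,
            seed=config.seed,
            version=__version__,
            outputs={k: str(v) for k, v in outputs.items()},
            metrics=metrics,
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def write_csv(path, header: list[str], columns: list[np.ndarray]) -> None:
    """Write columns as CSV with full double precision."""
    data = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    np.savetxt(path, data, delimiter=",", header=",".join(header), comments="",
               fmt="%.17g")


def read_csv(path):
    """Read a CSV written by :func:`write_csv`; returns (header, columns)."""
    path = Path(path)
    header = path.read_text().splitlines()[0].split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return header, [data[:, i] for i in range(data.shape[1])]
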