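"""Noise-adaptive spectral denoiser.

Short-time spectral enhancement with decision-directed a-priori SNR
estimation.  For the additive model ``y(n) = x(n) + d(n)`` with STFT
``Y_m(k)``, each frame ``m`` computes

* the a-posteriori SNR  ``gamma_m(k) = |Y_m(k)|^2 / lambda_d(k)``,
* the decision-directed a-priori SNR
  ``xi_m(k) = alpha_dd |X_{m-1}(k)|^2 / lambda_d(k)
             + (1 - alpha_dd) max(gamma_m(k) - 1, xi_min)``,
* a Wiener gain ``G = xi / (1 + xi)`` applied to the complex spectrum,

where ``lambda_d`` is the noise variance per bin, tracked during
speech-absent frames with a first-order smoother, and ``X_{m-1}`` is
the previous frame's enhanced spectrum.  A variant using the previous
*noisy* spectrum ``Y_{m-1}`` in place of ``X_{m-1}`` is available via
``use_noisy_memory``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .signal_chain import AudioSignal

__all__ = [
    "StftConfig",
    "SpectralState",
    "stft",
    "istft",
    "posteriori_snr",
    "decision_directed_xi",
    "spectral_gain",
    "update_noise_psd",
    "enhance_spectra",
    "denoise_signal",
]

#: Noise-variance floor relative to full-scale power, guarding the
#: divisions in the SNR formulas.
NOISE_FLOOR = 1e-12


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform framing.

    A periodic Hann window with 50 % overlap; inversion uses the dual
    window, so the analysis/synthesis round trip is exact to numerical
    precision for interior samples.
    """

    frame_length: int = 512
    hop: int = 256
    window: str = "hann"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_length):
            raise ValueError("need 0 < hop <= frame_length")

    def transform(self, sample_rate: float) -> ShortTimeFFT:
        if self.window != "hann":
            raise ValueError(f"unsupported window {self.window!r}")
        win = hann(self.frame_length, sym=False)
        return ShortTimeFFT(win, hop=self.hop, fs=sample_rate, fft_mode="onesided")


@dataclass(frozen=True)
class SpectralState:
    """Per-bin state of the decision-directed recursion.

    ``noise_variance`` is lambda_d(k); ``prev_clean_power`` is
    |X_{m-1}(k)|^2.  ``alpha_dd`` weights the previous frame's enhanced
    spectrum against the current maximum-likelihood estimate; ``beta``
    smooths the noise-variance tracker.
    """

    noise_variance: np.ndarray
    prev_clean_power: np.ndarray
    alpha_dd: float = 0.98
    xi_min: float = 1e-3
    beta: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_dd <= 1.0):
            raise ValueError("alpha_dd must lie in [0, 1]")
        if not self.xi_min > 0:
            raise ValueError("xi_min must be > 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        lam = np.asarray(self.noise_variance, dtype=float)
        if np.any(lam < 0):
            raise ValueError("noise_variance must be nonnegative")
        object.__setattr__(self, "noise_variance", lam)
        object.__setattr__(
            self, "prev_clean_power", np.asarray(self.prev_clean_power, dtype=float)
        )


def stft(signal: AudioSignal, cfg: StftConfig = StftConfig()) -> np.ndarray:
    """Complex spectrogram, shape (n_bins, n_frames)."""
    if len(signal) < cfg.frame_length:
        raise ValueError(
            f"signal ({len(signal)} samples) shorter than one frame "
            f"({cfg.frame_length})"
        )
    return cfg.transform(signal.sample_rate).stft(signal.samples)


def istft(
    spectra: np.ndarray,
    cfg: StftConfig = StftConfig(),
    sample_rate: float = 22050,
    n_samples: int = None,
) -> AudioSignal:
    """Invert :func:`stft`; ``n_samples`` truncates to the original length."""
    sft = cfg.transform(sample_rate)
    x = sft.istft(spectra, k1=n_samples)
    return AudioSignal(samples=x, sample_rate=sample_rate)


def posteriori_snr(power_spectrum: np.ndarray, noise_variance: np.ndarray):
    """A-posteriori SNR ``gamma = |Y|^2 / lambda_d`` per bin."""
    lam = np.asarray(noise_variance, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("noise_variance must be strictly positive (floor it first)")
    return np.asarray(power_spectrum, dtype=float) / lam


def decision_directed_xi(state: SpectralState, gamma: np.ndarray) -> np.ndarray:
    """Decision-directed a-priori SNR estimate per bin.

    Convex combination of the previous enhanced-spectrum SNR and the
    current maximum-likelihood estimate, floored at ``xi_min``:
    ``xi = alpha_dd |X_{m-1}|^2/lambda_d + (1-alpha_dd) max(gamma-1, xi_min)``.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("gamma must be nonnegative")
    lam = state.noise_variance
    if np.any(lam <= 0):
        raise ValueError("noise_variance must be strictly positive")
    return state.alpha_dd * state.prev_clean_power / lam + (
        1.0 - state.alpha_dd
    ) * np.maximum(gamma - 1.0, state.xi_min)


def spectral_gain(xi) -> np.ndarray:
    """Wiener suppression gain ``G = xi / (1 + xi)``, in [0, 1)."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("xi must be nonnegative")
    return xi / (1.0 + xi)


def update_noise_psd(
    state: SpectralState, current_power: np.ndarray, speech_absent: bool
) -> SpectralState:
    """First-order smoothing of the noise variance during noise-only frames.

    ``lambda_d <- beta lambda_d + (1 - beta) |Y|^2`` when speech is
    absent; frozen otherwise.  The result is floored to keep the SNR
    divisions defined.
    """
    if not speech_absent:
        return state
    lam = state.beta * state.noise_variance + (1.0 - state.beta) * np.asarray(
        current_power, dtype=float
    )
    return replace(state, noise_variance=np.maximum(lam, NOISE_FLOOR))


def enhance_spectra(
    spectra: np.ndarray,
    alpha_dd: float = 0.98,
    xi_min: float = 1e-3,
    beta: float = 0.9,
    n_init_frames: int = 6,
    use_noisy_memory: bool = False,
) -> np.ndarray:
    """Run the decision-directed recursion over a noisy spectrogram.

    Returns the enhanced complex spectrogram; since the Wiener gain is
    below one, every output bin magnitude is at most the input's.
    See :func:`denoise_signal` for the noise tracking and detection
    details.
    """
    power = np.abs(spectra) ** 2
    n_bins, n_frames = spectra.shape
    n_init = min(n_init_frames, n_frames)
    lam0 = np.maximum(power[:, :n_init].mean(axis=1), NOISE_FLOOR)
    state = SpectralState(
        noise_variance=lam0,
        prev_clean_power=np.zeros(n_bins),
        alpha_dd=alpha_dd,
        xi_min=xi_min,
        beta=beta,
    )

    enhanced = np.empty_like(spectra)
    for m in range(n_frames):
        frame_power = power[:, m]
        speech_absent = float(frame_power.sum()) < 1.5 * float(
            state.noise_variance.sum()
        )
        state = update_noise_psd(state, frame_power, speech_absent)
        gamma = posteriori_snr(frame_power, state.noise_variance)
        xi = decision_directed_xi(state, gamma)
        gain = spectral_gain(xi)
        enhanced[:, m] = gain * spectra[:, m]
        memory = frame_power if use_noisy_memory else np.abs(enhanced[:, m]) ** 2
        state = replace(state, prev_clean_power=memory)
    return enhanced


def denoise_signal(
    noisy: AudioSignal,
    cfg: StftConfig = StftConfig(),
    alpha_dd: float = 0.98,
    xi_min: float = 1e-3,
    beta: float = 0.9,
    n_init_frames: int = 6,
    use_noisy_memory: bool = False,
) -> AudioSignal:
    """Enhance a noisy signal; output has the input's length.

    The noise variance is initialized from the first ``n_init_frames``
    frames (assumed noise-only) and afterwards tracked during frames a
    simple energy detector flags as speech-absent: frame energy below
    1.5x the energy of the current noise estimate.  Comparing against
    the tracked estimate (rather than the initial one) lets the
    detector follow background-noise changes, and the 1.5x margin keeps
    steady signals at low SNR from being absorbed into the noise floor.
    Per frame the Wiener gain from the decision-directed a-priori SNR
    is applied to the complex spectrum; with ``use_noisy_memory`` the
    recursion's memory is the previous noisy rather than enhanced power.
    """
    spectra = stft(noisy, cfg)
    enhanced = enhance_spectra(
        spectra,
        alpha_dd=alpha_dd,
        xi_min=xi_min,
        beta=beta,
        n_init_frames=n_init_frames,
        use_noisy_memory=use_noisy_memory,
    )
    return istft(enhanced, cfg, noisy.sample_rate, n_samples=len(noisy))
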