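"""8-channel analysis filter bank.

The speech signal is split into eight contiguous subbands on a
normalized-frequency axis (fractions of Nyquist, i.e. x pi rad/sample).
The four low bands are equally wide (0.04 each) and each higher band is
twice as wide as its lower neighbour, reflecting the greater
information density of speech at low frequencies:

    ch0 (0, 0.04)    ch1 (0.04, 0.08)  ch2 (0.08, 0.12)  ch3 (0.12, 0.16)
    ch4 (0.16, 0.24) ch5 (0.24, 0.32)  ch6 (0.32, 0.48)  ch7 (0.48, 1.0)

Two realizations are provided: a linear-phase FIR bank built as a
three-stage cascade of low-band/high-band splits (an unbalanced binary
tree, so that every channel passes exactly three stage filters), and an
IIR bank of Butterworth biquad cascades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .signal_chain import AudioSignal

__all__ = [
    "BandEdges",
    "DesignedBank",
    "default_band_edges",
    "five_channel_center_frequencies",
    "design_fir_bank",
    "design_iir_bank",
    "design_bank",
    "analyze",
    "magnitude_response",
]

_DEFAULT_EDGES = (
    (0.0, 0.04),
    (0.04, 0.08),
    (0.08, 0.12),
    (0.12, 0.16),
    (0.16, 0.24),
    (0.24, 0.32),
    (0.32, 0.48),
    (0.48, 1.0),
)

# Five-channel implant center frequencies (Hz) for four speech ranges.
_FIVE_CHANNEL_TABLE = {
    "350-6500": (398, 781, 1573, 3028, 5798),
    "250-6500": (289, 640, 1395, 2860, 5728),
    "250-8500": (293, 693, 1607, 3496, 7418),
    "70-8500": (120, 448, 1251, 3108, 7410),
}

# Cascade tree: each channel is the product of three stage filters,
# ('lp'|'hp', cutoff in Nyquist units).  Stage 1 splits at 0.16,
# stage 2 at 0.08 / 0.32, stage 3 at 0.04, 0.12 / 0.24, 0.48.
_FIR_TREE = (
    (("lp", 0.16), ("lp", 0.08), ("lp", 0.04)),
    (("lp", 0.16), ("lp", 0.08), ("hp", 0.04)),
    (("lp", 0.16), ("hp", 0.08), ("lp", 0.12)),
    (("lp", 0.16), ("hp", 0.08), ("hp", 0.12)),
    (("hp", 0.16), ("lp", 0.32), ("lp", 0.24)),
    (("hp", 0.16), ("lp", 0.32), ("hp", 0.24)),
    (("hp", 0.16), ("hp", 0.32), ("lp", 0.48)),
    (("hp", 0.16), ("hp", 0.32), ("hp", 0.48)),
)


@dataclass(frozen=True)
class BandEdges:
    """Eight ordered (low, high) pairs in Nyquist units, partitioning (0, 1]."""

    edges: tuple

    def __post_init__(self) -> None:
        if len(self.edges) != 8:
            raise ValueError("expected 8 band-edge pairs")
        for lo, hi in self.edges:
            if not lo < hi:
                raise ValueError(f"band edges must satisfy low < high; got ({lo}, {hi})")
        for (lo0, hi0), (lo1, hi1) in zip(self.edges, self.edges[1:]):
            if hi0 != lo1:
                raise ValueError("adjacent bands must share an edge")

    def center(self, channel: int) -> float:
        """Representative band-center frequency (Nyquist units).

        Geometric mean of the edges; the midpoint for channel 0 whose
        lower edge is 0.
        """
        lo, hi = self.edges[channel]
        return (lo + hi) / 2.0 if lo == 0.0 else float(np.sqrt(lo * hi))

    def width(self, channel: int) -> float:
        lo, hi = self.edges[channel]
        return hi - lo


@dataclass(frozen=True)
class DesignedBank:
    """Designed 8-channel bank.

    ``kind`` is ``"fir"`` (per-channel composite linear-phase taps) or
    ``"iir"`` (per-channel second-order-section cascades).
    """

    kind: str
    edges: BandEdges
    sample_rate: float
    fir_taps: tuple = ()  # 8 symmetric tap arrays when kind == "fir"
    sos: tuple = ()  # 8 SOS arrays when kind == "iir"

    @property
    def n_channels(self) -> int:
        return 8


def default_band_edges() -> BandEdges:
    """The standard 8-band partition of the normalized frequency axis."""
    return BandEdges(edges=_DEFAULT_EDGES)


def five_channel_center_frequencies(range_label: str):
    """Center frequencies (Hz) of the 5-channel implant for a speech range.

    ``range_label`` is one of ``"350-6500"``, ``"250-6500"``,
    ``"250-8500"``, ``"70-8500"`` (an en-dash is accepted too).
    """
    key = range_label.replace("–", "-")
    if key not in _FIVE_CHANNEL_TABLE:
        raise KeyError(
            f"unknown frequency range {range_label!r}; valid labels: "
            + ", ".join(sorted(_FIVE_CHANNEL_TABLE))
        )
    return _FIVE_CHANNEL_TABLE[key]


def _stage_filter(kind: str, cutoff: float, numtaps: int) -> np.ndarray:
    return scipy.signal.firwin(
        numtaps, cutoff, window="hamming", pass_zero=(kind == "lp")
    )


def _normalize_peak(taps: np.ndarray) -> np.ndarray:
    w, h = scipy.signal.freqz(taps, worN=8192)
    return taps / np.max(np.abs(h))


def design_fir_bank(
    edges: BandEdges = None,
    sample_rate: float = 22050,
    order_per_stage: int = 128,
) -> DesignedBank:
    """Linear-phase FIR bank as a 3-stage cascade of band splits.

    Each stage is a Hamming windowed-sinc lowpass/highpass of
    ``order_per_stage`` (even, >= 16); the three stage kernels on each
    channel's tree path are convolved into one composite symmetric FIR,
    then peak-normalized to 0 dB.
    """
    if edges is None:
        edges = default_band_edges()
    if order_per_stage < 16 or order_per_stage % 2:
        raise ValueError("order_per_stage must be even and >= 16")
    numtaps = order_per_stage + 1
    # Hamming main-lobe transition width in Nyquist units; if it spans
    # more than twice the narrowest band the splits stop separating.
    transition = 6.6 / numtaps
    narrowest = min(edges.width(c) for c in range(8))
    if transition > 2 * narrowest:
        raise ValueError(
            f"order_per_stage={order_per_stage} gives transition width "
            f"{transition:.3f} (Nyquist units), too wide for the narrowest "
            f"band ({narrowest}); increase the order to at least "
            f"{int(np.ceil(6.6 / (2 * narrowest))) * 2}"
        )
    taps = []
    for path in _FIR_TREE:
        composite = np.array([1.0])
        for kind, cutoff in path:
            composite = np.convolve(composite, _stage_filter(kind, cutoff, numtaps))
        taps.append(_normalize_peak(composite))
    return DesignedBank(
        kind="fir", edges=edges, sample_rate=sample_rate, fir_taps=tuple(taps)
    )


def design_iir_bank(
    edges: BandEdges = None,
    sample_rate: float = 22050,
    sections_per_channel: int = 2,
) -> DesignedBank:
    """IIR bank: per-channel Butterworth cascades of biquads.

    Channel 0 (lower edge 0) is a lowpass, channel 7 (upper edge at
    Nyquist) a highpass, the rest bandpass; each channel's gain is
    normalized to 0 dB at its band-center frequency.  Bilinear-design
    Butterworth sections are stable by construction.
    """
    if edges is None:
        edges = default_band_edges()
    if sections_per_channel < 1:
        raise ValueError("sections_per_channel must be >= 1")
    order = 2 * sections_per_channel
    all_sos = []
    for c, (lo, hi) in enumerate(edges.edges):
        if lo == 0.0:
            sos = scipy.signal.butter(order, hi, btype="lowpass", output="sos")
        elif hi >= 1.0:
            sos = scipy.signal.butter(order, lo, btype="highpass", output="sos")
        else:
            sos = scipy.signal.butter(
                sections_per_channel, [lo, hi], btype="bandpass", output="sos"
            )
        _, h = scipy.signal.sosfreqz(sos, worN=[np.pi * edges.center(c)])
        gain = np.abs(h[0])
        if gain == 0:
            raise ValueError(f"channel {c} design has zero band-center gain")
        sos = sos.copy()
        sos[0, :3] /= gain
        poles = np.concatenate([np.roots(sec[3:]) for sec in sos])
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(f"channel {c} design is unstable")
        all_sos.append(sos)
    return DesignedBank(
        kind="iir", edges=edges, sample_rate=sample_rate, sos=tuple(all_sos)
    )


def design_bank(kind: str, edges: BandEdges = None, sample_rate: float = 22050):
    """Design an FIR or IIR bank with default parameters."""
    kind = kind.lower()
    if kind == "fir":
        return design_fir_bank(edges, sample_rate)
    if kind == "iir":
        return design_iir_bank(edges, sample_rate)
    raise ValueError(f"bank kind must be 'fir' or 'iir'; got {kind!r}")


def analyze(signal: AudioSignal, bank: DesignedBank) -> list[AudioSignal]:
    """Decompose a signal into the 8 subband signals (same length each)."""
    if signal.sample_rate != bank.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: signal {signal.sample_rate} Hz vs "
            f"bank {bank.sample_rate} Hz"
        )
    outs = []
    for c in range(8):
        if bank.kind == "fir":
            y = scipy.signal.lfilter(bank.fir_taps[c], [1.0], signal.samples)
        else:
            y = scipy.signal.sosfilt(bank.sos[c], signal.samples)
        outs.append(AudioSignal(samples=y, sample_rate=signal.sample_rate))
    return outs


def magnitude_response(
    bank: DesignedBank, n_points: int = 1024, floor_db: float = -80.0
):
    """Per-channel magnitude responses in dB over normalized frequency.

    Returns ``(frequencies, curves)`` with ``frequencies`` in Nyquist
    units and ``curves`` of shape (8, n_points), peak-normalized to
    0 dB and clipped at ``floor_db`` for display.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    w = np.linspace(0, np.pi, n_points, endpoint=False)
    curves = np.empty((8, n_points))
    for c in range(8):
        if bank.kind == "fir":
            _, h = scipy.signal.freqz(bank.fir_taps[c], worN=w)
        else:
            _, h = scipy.signal.sosfreqz(bank.sos[c], worN=w)
        mag = np.abs(h)
        mag /= mag.max()
        with np.errstate(divide="ignore"):
            curves[c] = np.maximum(20.0 * np.log10(mag), floor_db)
    return w / np.pi, curves
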