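# Methods

This note records the models implemented in `cisim`, the parameter
choices that matter, and the design decisions taken where more than one
reasonable construction existed.

## Atmospheric model

Saturation vapor pressure uses the Magnus approximation
`p_sat(t) = 6.112 hPa · exp(17.62 t / (243.12 °C + t))`, valid for
−40 °C ≤ t ≤ 100 °C; temperatures outside that range are rejected.
Absolute humidity follows as `AH = 216.7 (RH/100) p_sat / (273.15 + t)`
g/m³. Evaluated literally, AH(20 °C, 60 %) = 10.35 g/m³; tabulated
saturation pressures (≈23.39 hPa at 20 °C instead of the Magnus
23.33 hPa) give the also-circulating 10.37 g/m³. We keep a single
internal vapor-pressure model (Magnus) for consistency — the molar
water fraction that drives the absorption model uses the same
`p_sat` — and accept the ±0.02 g/m³ difference from tabulated values.

The pure-tone absorption coefficient α(f) in dB/m is the ISO 9613-1 /
ANSI S1.26 closed form: a classical term `1.84·10⁻¹¹ (p_r/p)(T/T₀)^½`
plus O₂ and N₂ vibrational-relaxation terms scaled by `(T/T₀)^(−5/2)`,
with relaxation frequencies computed from the molar water fraction
`h = RH·p_sat/p` (percent), `T₀ = 293.15 K`, `p_r = 101.325 kPa`. Two
properties matter downstream: α grows approximately as f² below the
relaxation frequencies, becoming significant (per metre) only above
~2 kHz; and at 4 kHz dry air (RH 20 %) absorbs several times more than
moist air (RH 80 %) at 20 °C. Note the model's ordering of the two
showcase conditions: at every audio frequency α(36 °C, 40 %) exceeds
α(0 °C, 0 %), because at exactly 0 % humidity both relaxation channels
nearly shut off and only classical absorption remains. Comparisons
between environments are therefore always made per frequency bin
against the implemented model, not against a global "colder = more
attenuated" rule.

Attenuation over a path of `x` metres is applied as a zero-phase
frequency-domain multiplication: the real FFT of the signal is scaled
by `10^(−α(f)·x/20)` at each bin frequency and inverted. The
amplitude-gain convention is equivalent to the plane-wave pressure law
`p = p₀ e^(−α′x/2)` with a power coefficient α′ in Np/m via
`α_dB = 10 α′ / ln 10`. Default distance is 1 m (conventional
reference distance) when conditions are given without a path length.
Geometric spreading, ground reflection and refraction are out of scope.

## Filter bank

Band edges are fractions of Nyquist (×π rad/sample): four bands of
width 0.04 from 0, then 0.08, 0.08, 0.16 and 0.52 ending at 1.0. A
uniform depth-3 binary split tree cannot produce these unequal widths,
so the FIR cascade is an *unbalanced* tree: stage 1 splits at 0.16,
stage 2 at 0.08 (low side) and 0.32 (high side), stage 3 at 0.04, 0.12,
0.24 and 0.48 — every channel is the product of exactly three stage
filters. Stage filters are Hamming windowed-sinc designs of order 128
(129 taps); the three kernels on a path are convolved into one
composite linear-phase FIR and peak-normalized to 0 dB. The Hamming
main-lobe transition (6.6/129 ≈ 0.051 in Nyquist units) is wider than
the narrowest band (0.04), which is acceptable because adjacent
channels share the transition; an order too small for the splits to
separate (transition wider than twice the narrowest band) is rejected
with advice to raise it. Measured worst-case stopband level one
transition width outside any band is ≈ −53 dB, comfortably beyond the
40 dB separation target. Full-rate filtering is used throughout (no
halfband decimation).

The IIR bank uses per-channel Butterworth designs realized as
second-order sections (default two biquads = 4th order): channel 0 is a
lowpass (its lower edge is 0; DC removal belongs to the chain's DC
blocker, not the bank), channel 7 a highpass to Nyquist, the rest
bandpass. Each channel is gain-normalized at its band-center frequency
(geometric mean of the edges; midpoint for channel 0). Stability is
checked by pole modulus after normalization.

The five-channel center-frequency table (four speech ranges between
70 and 8500 Hz) is shipped as constants; its derivation is not modeled
and it is independent of the 8-channel bank.

## Signal chain

Sampling rate is fixed at 22 050 Hz. The DC blocker is
`H(z) = (1 − z⁻¹)/(1 − 0.995 z⁻¹)` — an exact null at DC, Nyquist gain
2/(1+pole). Noise injection scales the raw Gaussian or symmetric-
uniform realization so the *empirical* per-realization SNR equals the
request exactly, making measured SNRs reproducible to float precision
under a fixed seed. Noise is injected after DC blocking and before
denoising, matching the block order of the modeled processor.

Envelopes are full-wave rectification followed by a one-pole lowpass at
200 Hz with unit DC gain (steady tone of amplitude a settles near
2a/π). Pulse generation uses continuous-interleaved scheduling: 900
pulses/s per channel, biphasic pulses of 10 + 10 samples, channel c
delayed by c/(8·900) s so channels never stimulate simultaneously.
Pulses that would run past the signal end are dropped whole, preserving
charge balance. In `run_scenario` the pulse amplitude scale maps the
largest envelope value across channels to 6.0, so trains lie in
(−6, 6); rate, width and interleaving are conventions of this
implementation (the modeled system does not pin them) and are exposed
as parameters.

## Denoiser

STFT framing is a periodic Hann window of 512 samples with hop 256;
inversion uses the dual-window synthesis of `scipy.signal.ShortTimeFFT`,
so the round trip is exact to numerical precision and no COLA
constraint is imposed on parameter choices. Per frame m and bin k:
`γ = |Y|²/λ_d`, `ξ = α_dd |X̂_{m−1}|²/λ_d + (1−α_dd) max(γ−1, ξ_min)`
with defaults α_dd = 0.98 and ξ_min = 10⁻³, then the Wiener gain
ξ/(1+ξ) multiplies the complex spectrum. The Wiener rule is our choice
of estimator; the decision-directed recursion is agnostic to it and a
different gain could be substituted. A variant recursion that remembers
the previous *noisy* power |Y_{m−1}|² instead of the enhanced power is
available (`use_noisy_memory=True`) for studying the feedback-error
behavior of the standard recursion.

Noise tracking: λ_d is initialized from the first 6 frames, which the
caller must ensure are noise-only (utterances recorded with a lead-in
silence satisfy this naturally), and afterwards updated by
`λ_d ← β λ_d + (1−β)|Y|²` with β = 0.9 during frames flagged
speech-absent, floored at 10⁻¹² to guard the divisions. The detector
flags a frame speech-absent when its energy is below 1.5× the energy of
the **currently tracked** noise estimate. Two alternatives were
rejected: comparing against the *initial* noise energy cannot follow a
changing background, and a 2× margin is degenerate at 0 dB SNR — there
a steady signal-plus-noise frame has exactly twice the noise energy, so
the decision flips with the noise realization and the tracker
sporadically absorbs the signal, making the SNR improvement
irreproducible across seeds. With the 1.5× adaptive threshold the
improvement on a 0 dB tone-in-noise is stable to within a few tenths of
a dB across seeds.

Scale behavior: scaling the input by c scales the output by c (power
quantities scale by c², γ and ξ are scale-free) except far below the
absolute λ_d floor.

## Synthetic sources

The chirp is a unit-amplitude linear sweep (default 0 Hz to Nyquist).
The "vowel" fixture stands in for a voice recording: a harmonic stack
at F0 = 120 Hz weighted by two formant resonances (700 Hz and 1200 Hz)
and 1/√n rolloff, bandlimited to 8.5 kHz, with seed-controlled harmonic
phases. Like a real utterance it has a 0.15 s onset silence and a 4 Hz
raised-cosine syllabic envelope with near-silent troughs — exactly the
temporal structure the noise tracker relies on. What it does **not**
emulate: consonants and transients, pitch movement, coarticulation,
speaker variability, room reverberation, or microphone coloration.
Tests passing on it show the chain's signal-processing behavior
(routing, envelopes, SNR bookkeeping), not speech-intelligibility
outcomes on real recordings.

## Problem sizes and numerical choices

Scenario runs in the test suite and acceptance script use 5 s of audio
at 22 050 Hz (110 250 samples) for the scenario-level comparisons and
1.5–3 s for unit-level checks; the SNR-improvement and envelope-
correlation comparisons pair runs on identical seeds so that noise
realizations cancel. Envelope-peak comparisons use `argmax` with ties
broken by the earlier index (no ties arise for the chirp). CSV output
is full double precision for bit-stable round trips. WAV I/O supports
PCM16 (scaled by 1/32768) and float32; stereo files are downmixed with
a warning.

## Known limitations

- No electrode/tissue electrical model, loudness mapping, or
  psychoacoustic evaluation: outputs are normalized pulse trains.
- The IIR bank's channels overlap more than the FIR cascade's
  (Butterworth skirts), so tone-routing energy fractions are lower
  (~82 % vs >99 % at band centers), though the dominant channel always
  agrees between the two banks.
- The denoiser's energy-based detector is a deliberate minimal design;
  it will misclassify long steady high-SNR tones as background if they
  persist from the very first frame (no lead-in).
- Atmospheric absorption is the only propagation effect modeled.
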