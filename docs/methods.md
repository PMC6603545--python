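# Methods

## Signal model and transform

The codec operates on non-overlapping 64-s windows of skin conductance
sampled at 2 Hz (128 samples, µS, non-negative). Four analysis levels of
the Daubechies-3 filter pair produce the flat vector
`W4 = [A4(12) | D4(12) | D3(20) | D2(35) | D1(66)]`, 145 coefficients.

Boundary handling is whole-sample symmetric extension: the input is
mirrored by four samples on each side (border sample repeated), and for an
odd-length intermediate vector one further mirrored sample is appended on
the right so the final stride-2 window is complete. With the filters taken
in natural orientation (unit L2 norm, `Σh0 = √2`, `Σh1 = 0`) this is
numerically identical to PyWavelets' `mode="symmetric"` decomposition, and
`pywt.waverec` is therefore an exact synthesis inverse; the test suite
pins this equivalence against both a direct-summation oracle and
`pywt.wavedec`. One output-length convention deserves note: a plain
"halve the padded length" rule cannot yield the level lengths
(66, 35, 20, 12) for odd inputs; the implemented `floor((N+5)/2)` rule —
the standard convention of mainstream wavelet libraries — does, and is
what makes the fixed 145-coefficient layout self-consistent.

## Quantization and block format

Windows are expressed in 0.01 µS units (the sensor resolution) before the
transform, and coefficients are truncated toward zero on integer cast,
mirroring a fixed-point Q15.16 → Q15.0 conversion; round-half variants
were deliberately not used. A4 entries are clamped to unsigned 12 bits
(0–4095; a tonic level of 6.4 µS maps to A4 ≈ 2560, so the field
accommodates the full validated sensor range with headroom), details to
signed 8 bits. Clamping is recorded on the `QuantizedCoeffs` as a
saturation flag rather than raised as an error.

Top-K selection force-includes all twelve A4 positions for `K ≥ 12`
rather than relying on A4 magnitudes always dominating; detail positions
are then ranked by quantized magnitude with ties resolved to the lowest
index (the behaviour of a strict-greater maximum scan). The selection sets
are nested in K by construction.

The block is a sequence of little-endian 16-bit words: twelve A-words
(12-bit value, 4-bit nibble), `ceil(min(K−12,6)/2)` packed detail-value
words, and one value+address word per detail beyond the sixth, giving

    bits(K) = 192 + 16·ceil(min(K−12,6)/2) + 16·max(0, K−18),  K ≥ 12
    bits(K) = 16·K,                                            K < 12

which reproduces the operating points CR(k) = 4096/bits(k) ∈
{4.2, 8.8, 14.2, 17.1, 19.7, 23.3} at k ∈ {64, 32, 21, 18, 14, 11}. For
`K < 12` only the K largest-magnitude A4 entries survive; since dropped
positions would otherwise be unrecoverable, each A-word's nibble carries
the entry's A4 position (0–11) in this mode — the retained count in the
container record header disambiguates the two layouts. The container
format is `"EDW1"` followed by `[uint32 t0_seconds, uint8 k, payload]`
records; K is container metadata and CR accounting counts payload bits
only.

## Reconstruction and its non-monotonicity

Decoding populates an empty 145-vector with the retained values, zeros
elsewhere, and applies the inverse transform. Because symmetric extension
is redundant, the synthesis atoms of boundary-supported coefficients are
not mutually orthogonal; as a consequence reconstruction RMSErr is *not*
strictly non-increasing in K. Adding one boundary coefficient can raise
RMSErr by up to a few times 1e-4 µS (a few percent of one 0.01 µS
quantization step) even with quantization disabled. The effect is
confined to single steps of the K sweep and vanishes in population means;
the unit suite asserts the true behaviour (overall decrease across the
sweep, single-step increases below 1e-3 µS).

Reconstructed windows are clipped at 0 µS, since conductance is
physically non-negative; for realistic baselines the clip never binds.

## Metrics

PRD uses the non-mean-subtracted denominator; RMSErr is reported in µS;
%Energy is per level and scale-invariant; feature relative error is the
signed relative difference of population feature sums. The raw side of CR
is fixed at 32 bits/sample × 2 Hz (64 bits/s, 4096 bits per window). The
storage-duration helper offers two conventions: a first-principles rule
`hours = bytes·8·CR / 64 / 3600` (48 kB uncompressed → 1.71 h) and a
proportional mode `hours = base·CR` reproducing a published duration
table whose implied base (0.60 h on 48 kB) is inconsistent with the
64 bits/s arithmetic; neither is asserted as ground truth.

## SCR detection

Phasic features come from a bespoke, fully specified trough-to-peak
detector rather than an external toolkit: an event onset is a local
minimum (anchored at the end of any flat run), the peak is the next local
maximum, amplitude is trough-to-peak, and the event counts when the rise
is at least `min_amplitude` (default 0.01 µS, the sensor resolution, which
the literature leaves unspecified — results that depend on it are treated
as qualitative). Duration runs from onset until the signal first falls to
peak − amplitude/2, truncated at the window end; AUC = ½·amp·dur. A new
event may begin only after the previous peak; compound SCRs are not
deconvolved. Because compression impact is measured by running the *same*
detector on original and reconstructed signals, the evaluation design is
insensitive to the specific detector choice; absolute phasic counts are
not comparable across detectors.

## Synthetic data

The generator emulates in-lab stress-protocol EDA: a tonic baseline as a
bounded Gaussian random walk (default start 2 µS, step SD 0.01 µS at 2 Hz,
reflected into a plausible band), Poisson SCR arrivals (default 2/min),
lognormal amplitudes (log-mean −1.5, log-SD 0.45 ⇒ median ≈ 0.22 µS, bulk
0.1–0.5 µS), a difference-of-exponentials pulse (0.7 s rise, 4 s decay —
the canonical SCR morphology), additive white noise (SD 0.01 µS), all
clipped to the sensor-plausible 0–10 µS. Ground-truth pulse times and
amplitudes are returned for recall scoring. It deliberately omits motion
artifacts, electrode-contact dropouts, site-dependent amplitude scaling
and circadian tonic trends; passing tests therefore demonstrate codec
correctness and the qualitative tonic/phasic error ordering on clean
signals, not field robustness.

The dataset-preparation filter is a causal, minimum-order Chebyshev
type-II low-pass (0.6 Hz passband edge at 3 dB, 0.9 Hz stopband at 74 dB,
order 5 at 2 Hz — matching the closed-form order bound) applied forward
with a DC-matched initial state, so constant input passes unchanged. It
belongs to dataset preparation only and is not part of the codec. A
zero-phase (forward-backward) application was considered and rejected in
favour of the causal form an embedded front end would realise.

## Problem sizes

Population analyses default to 60–140 windows drawn from 640-s seeded
sessions with baselines uniform in 1–6 µS; the K sweep uses
{11, 14, 18, 21, 32, 64}. These sizes give stable means (the A4 energy
share, for instance, varies by < 0.05 percentage points across seeds)
while keeping any analysis runnable in seconds.

## Known limitations

* `K = 11` (CR 23.3×) drops one A4 coefficient and zero-fills it on
  decode, producing a localized µS-scale reconstruction dip; tonic errors
  at this operating point are dominated by that design choice, not by the
  wavelet stage.
* Strict RMSErr monotonicity in K fails at the 1e-4 µS scale (boundary
  non-orthogonality, above).
* The detector's amplitude threshold interacts with quantization: SCRs
  near 0.01 µS flicker in and out after reconstruction, so phasic
  relative errors are conservative (pessimistic) for corpora rich in tiny
  events.
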