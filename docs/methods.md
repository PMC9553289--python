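# Methods

This note documents the models and numerical choices behind
`mosaicspeech`, in the spirit of a methods appendix: what each stage
computes, which parameters matter, and what the synthetic fixtures do and
do not establish.

## Filter banks

Five fixed banks tile 50–7000 Hz contiguously. The 20-band bank follows
critical bandwidths; the 4-band bank follows the language-universal
boundaries 50 / 570 / 1600 / 3400 / 7000 Hz found by factor analysis of
multilingual speech spectra; the 2-, 8- and 16-band banks merge or halve
the 4-band bands on the critical-band scale. The passband tables are
hard-coded constants — the critical-band derivation is documentation, not
code — since the printed boundaries, not any formula, define the stimuli.

Each filter is an **upward frequency glide convolved with its temporal
reversal**: the glide is synthesized in the frequency domain with a
prescribed magnitude (square root of the target response) and a linearly
increasing group delay confined to the middle 70% of an 8192-sample
buffer, and the convolution squares the magnitude while making the
16383-tap FIR exactly symmetric (linear phase). The target amplitude
response has a unity plateau and squared-raised-cosine transitions with
−3 dB at the nominal band edge and −50 dB about 95 Hz outside it, reaching
an exact zero at the transition end. Design parameters:

| parameter | default | why |
|---|---|---|
| transition −3 → −50 dB | 95 Hz | matches the ~100-Hz transition target while leaving the 100-Hz-out attenuation contract (≥50 dB) real margin; measured minimum over all 50 filters ≈ 57.9 dB |
| transition shape | squared raised cosine (C¹-smooth) | smoothness at both transition ends keeps inter-bin spectral leakage ~20 dB below the stopband contract; a power-complementary (√raised-cosine) edge has a quartic-root kink whose leakage floor (~39 dB) violates it |
| glide half-length | 8192 samples | ample time-bandwidth for the narrowest (100-Hz) critical bands; group delay (8191 samples) is integer and compensated exactly |
| edge handling | lowest transition narrowed so the response is identically zero at DC; transitions capped for bands narrower than ~84 Hz | keeps bandpass DC gain exactly 0 and plateaus nonempty |

Adjacent bands cross at −3 dB, so a bank's summed power response is unity
to within ~0.3 dB across junctions (exact complementarity was traded for
the leakage floor above). Band outputs are delay-compensated, so they are
time-aligned with the input — the per-unit power average assumes this.

## Power grid and synthesis

`compute_power_grid` takes the plain mean square of each band over
half-open `D`-ms units (ramps included; the final partial unit is averaged
over its true length). Synthesis renders levels `√P` as stepwise envelopes
on **one continuous unit-RMS noise token per band** (per-unit tokens would
add boundary artifacts), and sums bands. Noise tokens are drawn from
per-band children of a `SeedSequence`, so every stimulus is bit-reproducible
from `(input, params, seed)`.

Envelope geometry: transitions between two sounding levels `a → b` are
5-ms root-of-raised-cosine crossfades centered on the unit boundary, in
the power domain — `env = √(a²·down² + b²·up²)` with `up² + down² = 1` per
sample — so the squared envelope passes `(a²+b²)/2` at the boundary and
crossfades are exactly energy-neutral overall. Transitions to or from
silence (stimulus onset/offset and gap edges) are RRC ramps lying wholly
inside the sounding segment, honoring "segments include their ramps" where
a gap is adjacent while avoiding a spurious `1/D`-Hz amplitude ripple
inside uninterrupted mosaic speech. Two consequences worth knowing:

- per-unit energy is exact only for moderate level steps; a centered
  crossfade moves `0.09·R·(a²−b²)` of energy across the boundary (R = ramp
  length), which is <1% for step sizes up to a few dB;
- a gap-flanked segment loses half a ramp of energy at each silent edge
  (−1.25 dB for a 20-ms segment at r=1, −0.8 dB at r=1.5), which is inside
  the ±1.5 dB power-conservation tolerance used throughout.

Round-trip fidelity (grid → mosaic → re-analyzed grid) holds to ±1.5 dB on
interior units, averaged over 20 noise seeds, for cells within ~10 dB of
the loudest simultaneous band. Cells much weaker than a spectral neighbour
are instead dominated by the neighbour's transition-region leakage — a
property of any contiguous filter bank (bands cross at −3 dB), most
pronounced for the 100-Hz-wide channels of the 20-band bank, and not a
synthesis defect. The acceptance-level check therefore uses the wide-band
(4-band, 40-ms) setting with speech-like ±5 dB cell dynamics.

## Interruption and stretching

The timeline builder keeps one parity of units (default `even`: sound at
stimulus onset) and places kept unit `u` at `[u·D, u·D + r·D)`, the gap
filling the remainder to the next kept onset; so segments are `r·D`, gaps
`(2−r)·D`, onset spacing `2D`, and the total is exactly `n·D` for every
`r` (a final over-running segment is truncated). Boundaries are converted
to samples by `round(ms · rate / 1000)` from absolute positions, so no
rounding drift accumulates and the output length equals the input length
exactly at every ratio. Stretching re-renders the same grid levels over a
longer noise extent — never waveform time-stretching — so the per-unit
information content is identical across ratios. At `r = 2` abutting
segments crossfade exactly as in uninterrupted mosaic speech.

## Modulation analyses

The MPS is the squared-magnitude 2-D FFT of a mean-removed dB-magnitude
spectrogram: Gaussian-tapered window of 30 ms (σ = window/6), 5-ms hop,
linear frequency axis truncated at 7 kHz — resolving temporal modulations
to 100 Hz and spectral modulations past 2 cyc/kHz, i.e. every region of
interest with margin; both are configurable. All four sign quadrants are
folded into the nonnegative quadrant with each cell landing exactly once,
so rectangle fractions over a partition sum to one to machine precision.
Fractions-of-total is the implemented normalization. A zero signal is an
error by documented choice.

The interruption modulation index lowpasses the Hilbert envelope at 60 Hz
(zero-phase FIR), removes the mean, and reports the Welch-PSD fraction
within ±10% of `1/(2D)` Hz. 50% duty-cycle gating at D = 20 ms yields
indices ≈ 0.7; stretching to r = 2 collapses them below 0.05. One caution:
a flat spectrogram does *not* concentrate MPS power near 0 Hz temporal
modulation — log-spectrogram speckle of noise spreads power out to roughly
1/(2π·σ_window) ≈ 30 Hz — so "stationarity" claims are tested via the
presence/absence of modulation ridges, not via near-DC concentration.

## Synthetic fixtures

`gen_utterance` is an additive formant synthesizer: a harmonic source
(1/k rolloff, f0 declining 130 → 100 Hz with light vibrato) shaped by
three per-pseudo-syllable vowel formant resonances (presets placed away
from the 4-band edges), a syllabic amplitude contour at 6.4 units/s, 4.3-s
default duration (≈27–28 pseudo-syllables), band-limited obstruent-like
noise bursts at syllable onsets, and a −35 dB breath-noise floor. All
spectral energy is confined below 7 kHz so the banks capture it. What it
emulates: realistic band-power dynamics across 50–7000 Hz, syllable-rate
envelope modulation, harmonicity for the periodicity-removal checks. What
it does not: phonetic content, coarticulation, or intelligibility — so
passing tests establish signal-processing correctness of the stimulus
chain, not perceptual results, which require human listeners.

An independent per-unit band-power oracle (`spectral_band_powers`, direct
periodogram-bin integration, no FIR filtering) cross-validates the power
grid to ±2 dB for cells within 10 dB of their band maximum; residual
disagreement concentrates where formant energy straddles a band edge
mid-transition or where the analysis filter's ~10-ms time spread crosses a
unit boundary.

## Experiment utilities

The design is the full 5 × 3 × 3 factorial (bands × segment duration ×
stretch ratio) plus an unprocessed control: 46 conditions, presented in 5
independently shuffled blocks per listener (230 trials). Block orders
derive from `(seed, block)` only, and sentence-to-condition assignment is
rotated cyclically by listener index — the ideal counterbalancing scheme.
Level calibration is pure RMS matching to a 1000-Hz reference tone
(absolute presentation level is hardware-dependent and out of scope).

Mora scoring aligns response to target by minimum edit distance (match
cost 0 under a symmetrized, transitively closed homophone relation;
substitution/insertion/deletion cost 1), breaking cost ties in favour of
matches. The shipped homophone list covers the standard kana mergers
(ぢ≡じ, づ≡ず and particle readings は≡わ, へ≡え, を≡お) and is fully
replaceable; blank responses score zero by construction. The response
table exports one row per target mora (listener, sentence, bands,
segment_ms, ratio, mora_index, correct), ready for a logistic mixed model;
fitting such a model is out of scope because it requires human data.

## Problem sizes

Default test and acceptance runs use 2-s fixtures for unit-level checks
and 4.3-s (default-scale) fixtures for duration invariance and the
demodulation property (3 utterances × 20 noise seeds × {20, 40} ms × three
ratios), which keeps the full suite in the minutes range on a single core
while exercising every stage at the stimuli's native scale.

## Known limitations

- Round-trip power fidelity degrades for grid cells ≫10 dB below a
  simultaneous neighbouring band (filter-bank leakage, see above).
- The glide's sweep law and duration are not observable in the response
  contract; any linear-phase construction meeting the measured contract is
  equivalent for these stimuli.
- Only ratios in [1, 2] are supported (segment shrinking and noise-filled
  gaps are different paradigms); band counts outside {2, 4, 8, 16, 20} have
  no named bank, though arbitrary contiguous passband lists are accepted
  programmatically.
- WAV I/O is deliberately strict: mono 16-bit PCM only, no resampling.
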