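"""Mosaic-speech synthesis: frequency x time power grids and noise vocoding.

A waveform is split into contiguous frequency bands, each band is cut into
fixed-duration time units, and the mean-square power of every (band, unit)
cell is recorded in a PowerGrid.  Synthesis runs the grid backwards: each
band's level sequence sqrt(power) becomes a stepwise amplitude envelope
with 5-ms root-of-raised-cosine ramps, the envelope modulates a unit-RMS
bandpassed noise carrier, and the modulated noises are summed across
frequency.  The result carries only the per-cell average power of the
original: periodicity and temporal fine structure are gone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filterbank import FilterBankSpec, apply_filterbank, design_bandpass, filter_waveform, get_bank
from .waveform import Waveform

DEFAULT_RAMP_MS = 5.0


@dataclass
class PowerGrid:
    """Band x time-unit matrix of mean-square powers (linear units).

    The central intermediate representation: everything the mosaic stimulus
    retains of the original signal lives here.
    """

    powers: np.ndarray  # shape (n_bands, n_units)
    segment_ms: float
    rate: int
    bank: FilterBankSpec
    n_samples: int
    ramp_ms: float = DEFAULT_RAMP_MS

    def __post_init__(self) -> None:
        p = np.asarray(self.powers, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError("powers must be a 2-D (band x unit) array")
        if (p < 0).any():
            raise ValueError("powers must be nonnegative")
        if p.shape[0] != self.bank.n_bands:
            raise ValueError("band count does not match the filter bank")
        expected_units = -(-self.n_samples // self.unit_samples)  # ceil
        if p.shape[1] != expected_units:
            raise ValueError(
                f"unit count {p.shape[1]} does not match "
                f"ceil(n_samples / unit): {expected_units}"
            )
        self.powers = p

    @property
    def unit_samples(self) -> int:
        return int(round(self.segment_ms * self.rate / 1000.0))

    @property
    def n_bands(self) -> int:
        return self.powers.shape[0]

    @property
    def n_units(self) -> int:
        return self.powers.shape[1]

    def unit_bounds(self, i: int) -> tuple[int, int]:
        """Half-open sample interval of unit i (last unit may be partial)."""
        u = self.unit_samples
        return i * u, min((i + 1) * u, self.n_samples)

    def to_csv(self, path) -> None:
        header = (
            f"# mosaic power grid: bands={self.bank.name} "
            f"segment_ms={self.segment_ms} rate={self.rate} "
            f"ramp_ms={self.ramp_ms} n_samples={self.n_samples}"
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.powers, delimiter=",")


@dataclass(frozen=True)
class Envelope:
    """A nonnegative per-sample amplitude envelope."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if (arr < 0).any():
            raise ValueError("envelope samples must be nonnegative")
        object.__setattr__(self, "samples", arr)


def _check_segment(segment_ms: float, ramp_ms: float) -> None:
    if segment_ms <= 2.0 * ramp_ms:
        raise ValueError(
            f"segment duration {segment_ms} ms must exceed twice the "
            f"ramp duration ({ramp_ms} ms)"
        )


def compute_power_grid(
    wave: Waveform,
    bank: FilterBankSpec | int,
    segment_ms: float,
    ramp_ms: float = DEFAULT_RAMP_MS,
) -> PowerGrid:
    """Filter into bands and average power over fixed-duration time units.

    Cell (b, i) is the plain mean square of band b over the half-open unit
    interval [i*D, (i+1)*D); the final partial unit is averaged over its
    actual length.
    """
    if isinstance(bank, int):
        bank = get_bank(bank)
    _check_segment(segment_ms, ramp_ms)
    if len(wave) == 0:
        raise ValueError("cannot analyze an empty waveform")
    unit = int(round(segment_ms * wave.rate / 1000.0))
    n_units = -(-len(wave) // unit)
    bands = apply_filterbank(wave, bank)
    powers = np.empty((bank.n_bands, n_units))
    for b, bw in enumerate(bands):
        x2 = bw.samples**2
        for i in range(n_units):
            lo, hi = i * unit, min((i + 1) * unit, len(wave))
            powers[b, i] = x2[lo:hi].mean()
    return PowerGrid(
        powers=powers, segment_ms=segment_ms, rate=wave.rate, bank=bank,
        n_samples=len(wave), ramp_ms=ramp_ms,
    )


def _ramp_up(n: int) -> np.ndarray:
    """Root-of-raised-cosine rise sampled at half-sample offsets; with the
    matching fall, up^2 + down^2 == 1 per sample."""
    t = (np.arange(n) + 0.5) / n
    return np.sin(np.pi * t / 2.0)


def envelope_from_intervals(
    intervals: list[tuple[int, int, float]],
    ramp_samples: int,
    total_len: int,
) -> np.ndarray:
    """Stepwise envelope over sounding intervals with RRC transitions.

    ``intervals`` are non-overlapping, ordered (start, end, level) sample
    intervals; everywhere else is silence.  Where two sounding intervals
    abut, the transition is a power-complementary root-of-raised-cosine
    crossfade centered on the boundary (the squared envelope moves from
    a^2 to b^2 through (a^2+b^2)/2).  Transitions to and from silence are
    RRC ramps lying wholly inside the sounding interval.
    """
    env = np.zeros(total_len)
    R = ramp_samples
    up = _ramp_up(R)
    down = up[::-1]
    iv = [(s, e, lv) for s, e, lv in intervals if e > s]
    for s, e, lv in iv:
        if lv < 0:
            raise ValueError("envelope level must be nonnegative")
        env[s:e] = lv
    for k, (s, e, lv) in enumerate(iv):
        if lv == 0:
            continue
        prev_lv = iv[k - 1][2] if k > 0 and iv[k - 1][1] == s else 0.0
        next_lv = iv[k + 1][2] if k + 1 < len(iv) and iv[k + 1][0] == e else 0.0
        seg = e - s
        r_on = min(R, seg)
        if prev_lv == 0:  # onset from silence: ramp inside this interval
            env[s:s + r_on] = lv * _ramp_up(r_on)
        elif k > 0:  # crossfade centered on the boundary
            a, b = prev_lv, lv
            w0 = max(s - R // 2, 0)
            w1 = min(w0 + R, total_len)
            n = w1 - w0
            env[w0:w1] = np.sqrt(a * a * down[:n] ** 2 + b * b * up[:n] ** 2)
        if next_lv == 0:  # offset into silence: ramp inside this interval
            r_off = min(R, seg)
            env[e - r_off:e] = lv * _ramp_up(r_off)[::-1]
    return env


def build_envelope(
    level_sequence: np.ndarray,
    segment_ms: float,
    ramp_ms: float,
    rate: int,
    total_len: int,
) -> Envelope:
    """Per-unit amplitude levels -> stepwise envelope with 5-ms RRC ramps.

    Consecutive nonzero levels are joined by power-complementary RRC
    crossfades centered on the unit boundary; edges adjacent to silence
    (stimulus onset/offset and zero-level units) carry their ramps inside
    the sounding unit.
    """
    levels = np.asarray(level_sequence, dtype=np.float64)
    if (levels < 0).any():
        raise ValueError("amplitude levels must be nonnegative")
    _check_segment(segment_ms, ramp_ms)
    unit = int(round(segment_ms * rate / 1000.0))
    ramp = int(round(ramp_ms * rate / 1000.0))
    intervals = [
        (i * unit, min((i + 1) * unit, total_len), float(lv))
        for i, lv in enumerate(levels)
        if i * unit < total_len
    ]
    return Envelope(envelope_from_intervals(intervals, ramp, total_len), rate)


def make_band_noise(
    low_hz: float,
    high_hz: float,
    n_samples: int,
    rate: int,
    seed,
    *,
    trans_low: float | None = None,
    trans_high: float | None = None,
) -> Waveform:
    """Unit-RMS Gaussian noise bandpassed to [low_hz, high_hz].

    Reproducible: the same seed yields bit-identical output.
    """
    filt = design_bandpass(low_hz, high_hz, rate,
                           trans_low=trans_low, trans_high=trans_high)
    if n_samples <= len(filt.coefficients):
        raise ValueError(
            f"need more than {len(filt.coefficients)} samples of noise "
            f"(the filter length); got {n_samples}"
        )
    rng = np.random.default_rng(seed)
    white = Waveform(rng.standard_normal(n_samples), rate)
    shaped = filter_waveform(white, filt)
    rms = np.sqrt(np.mean(shaped.samples**2))
    return shaped.replace(shaped.samples / rms)


def _band_noises(grid: PowerGrid, seed) -> list[Waveform]:
    """One independent full-length noise token per band, derived from seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(grid.n_bands)
    widths = grid.bank.transition_widths()
    # short grids: draw a token at least as long as the noise filter and trim
    n = max(grid.n_samples, 2 * 8192)
    out = []
    for (lo, hi), (wlo, whi), child in zip(grid.bank.passbands, widths, children):
        tok = make_band_noise(lo, hi, n, grid.rate, child,
                              trans_low=wlo, trans_high=whi)
        out.append(tok.replace(tok.samples[:grid.n_samples]))
    return out


def synthesize_mosaic(grid: PowerGrid, seed=0) -> Waveform:
    """Render a PowerGrid as mosaic speech.

    Each band's envelope levels are sqrt(power); the envelope modulates a
    unit-RMS band noise, and bands are summed.  In expectation the per-unit
    per-band power of the output matches the grid.
    """
    out = np.zeros(grid.n_samples)
    if not grid.powers.any():
        return Waveform(out, grid.rate)
    noises = _band_noises(grid, seed)
    for b in range(grid.n_bands):
        env = build_envelope(
            np.sqrt(grid.powers[b]), grid.segment_ms, grid.ramp_ms,
            grid.rate, grid.n_samples,
        )
        out += env.samples * noises[b].samples
    return Waveform(out, grid.rate)


def mosaicize(
    wave: Waveform,
    bank: FilterBankSpec | int,
    segment_ms: float,
    seed=0,
    ramp_ms: float = DEFAULT_RAMP_MS,
) -> Waveform:
    """Analyze and resynthesize: the mosaic-speech transform.

    Output has exactly the input's length and (approximately) its
    broadband power, but all within-cell structure is replaced by noise.
    """
    grid = compute_power_grid(wave, bank, segment_ms, ramp_ms)
    return synthesize_mosaic(grid, seed)
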