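"""Critical-band bandpass filter banks and linear-phase FIR design.

Five fixed banks (2, 4, 8, 16 and 20 bands) tile 50-7000 Hz contiguously.
The 20-band setting follows critical bandwidths; the 4-band setting follows
the language-universal frequency boundaries found by factor analysis of
multilingual speech spectra (50 / 570 / 1600 / 3400 / 7000 Hz), with the
2-, 8- and 16-band settings obtained by merging or halving those bands on
the critical-band scale.

Each bandpass filter is built as an upward frequency glide convolved with
its temporal reversal, which squares the glide's magnitude spectrum and
yields an exactly linear-phase (symmetric) FIR.  The glide is synthesized
in the frequency domain with raised-cosine magnitude edges and a linearly
increasing group delay, so the filter's magnitude response is prescribed:
unity plateau, -3 dB at the nominal band edges, roughly -50 dB about
95 Hz outside them, and an exact zero at (and beyond) the outer end of
each transition.  Adjacent bands of a bank cross at their shared edge at
-3 dB, so a contiguous bank tiles the 50-7000 Hz range with near-unity
summed power response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

from .waveform import Waveform

#: Fraction of the transition width from its outer (zero) end at which the
#: filter magnitude crosses -3 dB; follows from the raised-cosine edge shape.
_U3 = 0.74064
#: ... and at which it crosses -50 dB.
_U50 = 0.15212
#: Distance in Hz from the -3 dB point to the -50 dB point of a transition.
TRANSITION_3_TO_50_DB_HZ = 95.0
#: Full width (Hz) of each raised-cosine transition.
DEFAULT_TRANSITION_HZ = TRANSITION_3_TO_50_DB_HZ / (_U3 - _U50)

#: Half-length of the frequency-domain glide in samples; the final filter
#: has 2 * GLIDE_LEN - 1 taps.
GLIDE_LEN = 8192

_TABLE_BANKS: dict[int, tuple[tuple[float, float], ...]] = {
    20: (
        (50, 150), (150, 250), (250, 350), (350, 450), (450, 570),
        (570, 700), (700, 840), (840, 1000), (1000, 1170), (1170, 1370),
        (1370, 1600), (1600, 1850), (1850, 2150), (2150, 2500), (2500, 2900),
        (2900, 3400), (3400, 4000), (4000, 4800), (4800, 5800), (5800, 7000),
    ),
    16: (
        (50, 175), (175, 300), (300, 425), (425, 570),
        (570, 770), (770, 1000), (1000, 1270), (1270, 1600),
        (1600, 1925), (1925, 2320), (2320, 2800), (2800, 3400),
        (3400, 4000), (4000, 4800), (4800, 5800), (5800, 7000),
    ),
    8: (
        (50, 300), (300, 570), (570, 1000), (1000, 1600),
        (1600, 2320), (2320, 3400), (3400, 4800), (4800, 7000),
    ),
    4: ((50, 570), (570, 1600), (1600, 3400), (3400, 7000)),
    2: ((50, 1600), (1600, 7000)),
}

SUPPORTED_BAND_COUNTS = tuple(sorted(_TABLE_BANKS))


@dataclass(frozen=True)
class FilterBankSpec:
    """An ordered, contiguous set of bandpass passbands in Hz."""

    name: str
    passbands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pb = tuple((float(lo), float(hi)) for lo, hi in self.passbands)
        if not pb:
            raise ValueError("filter bank needs at least one passband")
        for lo, hi in pb:
            if not lo < hi:
                raise ValueError(f"degenerate passband ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(pb, pb[1:]):
            if hi != lo2:
                raise ValueError("passbands must be contiguous and ascending")
        object.__setattr__(self, "passbands", pb)

    @property
    def n_bands(self) -> int:
        return len(self.passbands)

    @property
    def edges(self) -> tuple[float, ...]:
        """Band boundaries low_0, low_1, ..., high_last."""
        return tuple(lo for lo, _ in self.passbands) + (self.passbands[-1][1],)

    def transition_widths(self) -> tuple[tuple[float, float], ...]:
        """Per-band (low-edge, high-edge) transition full widths in Hz.

        All edges use the default width except the lowest edge of the
        lowest band, which is narrowed so the response is identically zero
        at DC.
        """
        return tuple(
            (_default_transitions(lo, hi)) for lo, hi in self.passbands
        )

    def to_table(self) -> list[dict]:
        return [
            {"band": k + 1, "low_hz": lo, "high_hz": hi}
            for k, (lo, hi) in enumerate(self.passbands)
        ]


def get_bank(n_bands: int) -> FilterBankSpec:
    """Return one of the five fixed filter banks (2, 4, 8, 16 or 20 bands)."""
    try:
        passbands = _TABLE_BANKS[n_bands]
    except (KeyError, TypeError):
        raise ValueError(
            f"unsupported band count {n_bands!r}; supported: {SUPPORTED_BAND_COUNTS}"
        ) from None
    return FilterBankSpec(name=str(n_bands), passbands=passbands)


@dataclass(eq=False)
class FIRFilter:
    """A linear-phase FIR bandpass filter with its design metadata."""

    coefficients: np.ndarray
    rate: float
    passband: tuple[float, float]
    _grid_cache: np.ndarray | None = field(default=None, repr=False)

    @property
    def delay_samples(self) -> int:
        return (len(self.coefficients) - 1) // 2

    def response_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies, |H|) on a 1-Hz grid from 0 to Nyquist."""
        n = int(round(self.rate))
        if self._grid_cache is None:
            self._grid_cache = np.abs(np.fft.rfft(self.coefficients, n))
        freqs = np.fft.rfftfreq(n, 1.0 / self.rate)
        return freqs, self._grid_cache

    def max_passband_gain(self) -> float:
        freqs, mag = self.response_grid()
        lo, hi = self.passband
        sel = (freqs >= lo) & (freqs <= hi)
        return float(mag[sel].max())


def _default_transitions(low_hz: float, high_hz: float) -> tuple[float, float]:
    width = high_hz - low_hz
    cap = width / (2.0 * (1.0 - _U3))  # keep a nonempty plateau
    w_lo = min(DEFAULT_TRANSITION_HZ, cap, low_hz / _U3)  # zero at/above DC
    w_hi = min(DEFAULT_TRANSITION_HZ, cap)
    return w_lo, w_hi


def _glide_edge_up(freqs: np.ndarray, edge: float, width: float) -> np.ndarray:
    """Rising raised-cosine glide-amplitude edge.

    Reaches zero ``_U3 * width`` below the nominal edge and one
    ``(1 - _U3) * width`` above it; the squared (filter) response then
    crosses -3 dB exactly at the nominal edge.  C1-smooth at both ends,
    which keeps the convolved filter's inter-bin leakage far below the
    stopband contract.
    """
    if width <= 0:
        return (freqs >= edge).astype(float)
    u = np.clip((freqs - (edge - _U3 * width)) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def target_magnitude(
    freqs: np.ndarray,
    low_hz: float,
    high_hz: float,
    trans_low: float,
    trans_high: float,
) -> np.ndarray:
    """Prescribed filter amplitude response: unity plateau with squared
    raised-cosine transitions, -3 dB at the nominal edges."""
    up = _glide_edge_up(freqs, low_hz, trans_low)
    down = _glide_edge_up(-freqs, -high_hz, trans_high)
    return (up * down) ** 2


@lru_cache(maxsize=128)
def _design_cached(
    low_hz: float, high_hz: float, rate: float, trans_low: float, trans_high: float,
    glide_len: int,
) -> FIRFilter:
    freqs = np.fft.rfftfreq(glide_len, 1.0 / rate)
    # glide amplitude: sqrt of the target magnitude, so the convolution of
    # the glide with its reversal squares it back
    amp = np.sqrt(target_magnitude(freqs, low_hz, high_hz, trans_low, trans_high))

    # linearly increasing group delay across the swept range (an upward
    # glide), confined to the middle of the buffer to avoid wrap-around
    f_start = max(0.0, low_hz - _U3 * trans_low)
    f_stop = min(rate / 2.0, high_hz + _U3 * trans_high)
    t_total = glide_len / rate
    t0, t1 = 0.15 * t_total, 0.85 * t_total
    frac = np.clip((freqs - f_start) / max(f_stop - f_start, 1e-9), 0.0, 1.0)
    tau = t0 + frac * (t1 - t0)
    df = rate / glide_len
    phase = -2.0 * np.pi * np.cumsum(tau) * df
    glide = np.fft.irfft(amp * np.exp(1j * phase), glide_len)

    coeff = fftconvolve(glide, glide[::-1])
    coeff = 0.5 * (coeff + coeff[::-1])  # enforce exact symmetry

    filt = FIRFilter(coefficients=coeff, rate=rate, passband=(low_hz, high_hz))
    peak = filt.max_passband_gain()
    filt.coefficients = coeff / peak
    filt._grid_cache = filt._grid_cache / peak
    return filt


def design_bandpass(
    low_hz: float,
    high_hz: float,
    rate: float,
    *,
    trans_low: float | None = None,
    trans_high: float | None = None,
    glide_len: int = GLIDE_LEN,
) -> FIRFilter:
    """Design a linear-phase FIR bandpass via glide convolution.

    The measured magnitude response has at most +-2 dB ripple over
    [low+50, high-50] Hz and >= 50 dB attenuation 100 Hz or more outside
    the passband edges (the -3 dB -> -50 dB transition spans about 95 Hz,
    with an exact design zero at the transition end).

    Parameters
    ----------
    trans_low, trans_high : float, optional
        Full transition widths in Hz (the -3 dB point sits a fixed
        fraction inside each transition).  Defaults shrink for bands
        narrower than ~84 Hz, and at the low edge so the response is
        identically zero at DC.
    """
    if not (0 < low_hz < high_hz < rate / 2.0):
        raise ValueError(
            f"invalid passband ({low_hz}, {high_hz}) at rate {rate}: "
            "need 0 < low < high < rate/2"
        )
    d_lo, d_hi = _default_transitions(low_hz, high_hz)
    if trans_low is None:
        trans_low = d_lo
    if trans_high is None:
        trans_high = d_hi
    return _design_cached(
        float(low_hz), float(high_hz), float(rate),
        float(trans_low), float(trans_high), int(glide_len),
    )


def bank_filters(spec: FilterBankSpec, rate: float) -> list[FIRFilter]:
    """Design all filters of a bank; shared edges use matched transition
    widths so adjacent responses cross at -3 dB."""
    return [
        design_bandpass(lo, hi, rate, trans_low=wlo, trans_high=whi)
        for (lo, hi), (wlo, whi) in zip(spec.passbands, spec.transition_widths())
    ]


def filter_waveform(wave: Waveform, filt: FIRFilter) -> Waveform:
    """Apply a linear-phase FIR with group-delay compensation (output is
    time-aligned with the input and has the same length)."""
    if len(wave) == 0:
        raise ValueError("cannot filter an empty waveform")
    full = fftconvolve(wave.samples, filt.coefficients)
    d = filt.delay_samples
    return wave.replace(full[d:d + len(wave)])


def apply_filterbank(wave: Waveform, spec: FilterBankSpec) -> list[Waveform]:
    """Split a waveform into time-aligned band signals, one per passband."""
    if len(wave) == 0:
        raise ValueError("cannot filter an empty waveform")
    return [filter_waveform(wave, f) for f in bank_filters(spec, wave.rate)]


def measure_response(filt: FIRFilter, probe_hz: float) -> float:
    """Magnitude response at probe_hz in dB re the maximum passband gain."""
    if not (0 < probe_hz < filt.rate / 2.0):
        raise ValueError(f"probe frequency {probe_hz} outside (0, rate/2)")
    n = np.arange(len(filt.coefficients))
    h = np.dot(filt.coefficients, np.exp(-2j * np.pi * probe_hz / filt.rate * n))
    ref = filt.max_passband_gain()
    mag = np.abs(h) / ref
    return float(20.0 * np.log10(max(mag, 1e-300)))


def stopband_attenuation_db(filt: FIRFilter, margin_hz: float = 100.0) -> float:
    """Minimum attenuation (positive dB) at >= margin_hz outside the passband,
    evaluated on a 1-Hz grid."""
    freqs, mag = filt.response_grid()
    lo, hi = filt.passband
    sel = (freqs <= lo - margin_hz) | (freqs >= hi + margin_hz)
    sel &= freqs > 0
    if not sel.any():
        return float("inf")
    worst = mag[sel].max() / filt.max_passband_gain()
    return float(-20.0 * np.log10(max(worst, 1e-300)))


def passband_ripple_db(filt: FIRFilter, plateau_margin_hz: float = 50.0) -> float:
    """Maximum |deviation| from 0 dB over [low+margin, high-margin] (or the
    plateau midpoint when the band is narrower than two margins)."""
    freqs, mag = filt.response_grid()
    lo, hi = filt.passband
    p_lo, p_hi = lo + plateau_margin_hz, hi - plateau_margin_hz
    if p_lo > p_hi:
        p_lo = p_hi = (lo + hi) / 2.0
    sel = (freqs >= p_lo) & (freqs <= p_hi)
    if not sel.any():
        sel = np.argmin(np.abs(freqs - (lo + hi) / 2.0))
    rel = mag[sel] / filt.max_passband_gain()
    db = 20.0 * np.log10(np.clip(rel, 1e-300, None))
    return float(np.max(np.abs(db)))
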