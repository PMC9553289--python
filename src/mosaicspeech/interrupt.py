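"""Periodic interruption and segment stretching of mosaic speech.

Interruption replaces every other time unit with a silent gap of the same
duration (a 50% duty cycle).  Stretching lengthens each retained mosaic
segment by a ratio r in [1, 2] while the following gap is scaled by (2-r),
so segment onsets stay 2D apart and the total stimulus duration never
changes: at r=1 segments and gaps alternate at the original duration, at
r=2 the segments abut with no gap.  Stretching is performed by
re-synthesis from the PowerGrid -- the same per-unit level is rendered
over a longer noise stretch -- never by waveform time-stretching, so the
segment content stays statistically identical, only longer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .filterbank import get_bank
from .mosaic import (
    DEFAULT_RAMP_MS,
    PowerGrid,
    _band_noises,
    compute_power_grid,
    envelope_from_intervals,
    synthesize_mosaic,
)
from .waveform import Waveform

PHASES = ("even", "odd")


@dataclass(frozen=True)
class StimulusParams:
    """Everything that defines one interrupted/stretched mosaic stimulus."""

    n_bands: int
    segment_ms: float
    stretch_ratio: float
    phase: str = "even"
    seed: int = 0
    interrupt: bool = True
    ramp_ms: float = DEFAULT_RAMP_MS

    def __post_init__(self) -> None:
        if not 1.0 <= self.stretch_ratio <= 2.0:
            raise ValueError(
                f"stretch ratio {self.stretch_ratio} outside [1, 2] "
                "(shrinking segments or negative gaps are unsupported)"
            )
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.segment_ms <= 2.0 * self.ramp_ms:
            raise ValueError("segment duration must exceed twice the ramp")


@dataclass(frozen=True)
class TimelineEntry:
    onset_ms: float
    offset_ms: float
    kind: str  # "segment" or "gap"
    source_unit: int | None = None  # original unit index for segments

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Timeline:
    """Gapless tiling of [0, total_ms] into segments and silent gaps."""

    entries: tuple[TimelineEntry, ...]
    total_ms: float

    @property
    def segments(self) -> tuple[TimelineEntry, ...]:
        return tuple(e for e in self.entries if e.kind == "segment")

    @property
    def gaps(self) -> tuple[TimelineEntry, ...]:
        return tuple(e for e in self.entries if e.kind == "gap")

    def to_rows(self) -> list[dict]:
        return [
            {"onset_ms": e.onset_ms, "offset_ms": e.offset_ms,
             "kind": e.kind, "source_unit": e.source_unit}
            for e in self.entries
        ]


def interrupt_grid(grid: PowerGrid, phase: str = "even") -> PowerGrid:
    """Zero all bands of every unit in the discarded phase.

    ``phase`` names the *kept* parity; kept units are unchanged and the
    grid shape is preserved, so the operation is idempotent.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    keep = 0 if phase == "even" else 1
    powers = grid.powers.copy()
    mask = (np.arange(grid.n_units) % 2) != keep
    powers[:, mask] = 0.0
    return dc_replace(grid, powers=powers)


def build_timeline(
    n_units: int,
    segment_ms: float,
    stretch_ratio: float,
    phase: str = "even",
) -> Timeline:
    """Lay out stretched segments and shrunken gaps over n_units * D ms.

    Kept unit u starts at its original onset u*D and extends r*D; the gap
    fills the remainder up to the next kept onset (2D later), hence lasts
    (2-r)*D.  A final kept segment is truncated at the total duration.
    """
    if n_units < 1:
        raise ValueError("need at least one unit")
    if not 1.0 <= stretch_ratio <= 2.0:
        raise ValueError(
            f"stretch ratio {stretch_ratio} outside [1, 2]: the gap would be "
            "negative or the segment shrunk"
        )
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    D = float(segment_ms)
    r = float(stretch_ratio)
    total = n_units * D
    first = 0 if phase == "even" else 1
    entries: list[TimelineEntry] = []
    cursor = 0.0
    for u in range(first, n_units, 2):
        onset = u * D
        if onset > cursor:
            entries.append(TimelineEntry(cursor, onset, "gap"))
        offset = min(onset + r * D, total)
        entries.append(TimelineEntry(onset, offset, "segment", u))
        cursor = offset
    if cursor < total:
        entries.append(TimelineEntry(cursor, total, "gap"))
    return Timeline(tuple(entries), total)


def synthesize_interrupted_stretched(
    grid: PowerGrid, params: StimulusParams
) -> Waveform:
    """Render kept units over their stretched intervals, gaps silent.

    Per band, each kept unit's level sqrt(power) spans its timeline
    interval with RRC ramps inside the segment at segment-gap boundaries;
    at r=2 adjacent segments crossfade exactly as in uninterrupted mosaic
    speech.  Output duration equals the grid's source duration for every
    stretch ratio.
    """
    tl = build_timeline(grid.n_units, grid.segment_ms, params.stretch_ratio,
                        params.phase)
    total_len = grid.n_samples
    rate = grid.rate

    def to_samp(ms: float) -> int:
        return min(int(round(ms * rate / 1000.0)), total_len)

    ramp = int(round(grid.ramp_ms * rate / 1000.0))
    noises = _band_noises(grid, params.seed)
    out = np.zeros(total_len)
    for b in range(grid.n_bands):
        intervals = [
            (to_samp(e.onset_ms), to_samp(e.offset_ms),
             float(np.sqrt(grid.powers[b, e.source_unit])))
            for e in tl.segments
        ]
        env = envelope_from_intervals(intervals, ramp, total_len)
        out += env * noises[b].samples
    return Waveform(out, rate)


def make_stimulus(wave: Waveform, params: StimulusParams) -> Waveform:
    """Full pipeline: filter bank -> power grid -> interrupt -> stretch ->
    noise-vocoded synthesis.  With ``interrupt=False`` (requires r=1) this
    reduces to plain mosaicization."""
    bank = get_bank(params.n_bands)
    grid = compute_power_grid(wave, bank, params.segment_ms, params.ramp_ms)
    if not params.interrupt:
        if params.stretch_ratio != 1.0:
            raise ValueError("stretching requires interruption")
        return synthesize_mosaic(grid, params.seed)
    kept = interrupt_grid(grid, params.phase)
    return synthesize_interrupted_stretched(kept, params)
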