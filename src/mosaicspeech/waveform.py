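"""Minimal mono waveform container used across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RATE = 44_100


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal: float samples plus a sample rate in Hz.

    Samples are stored as float64 on a nominal [-1, 1] full scale (16-bit
    PCM maps to this range on read/write).
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"waveform must be mono (1-D), got shape {arr.shape}")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def replace(self, samples: np.ndarray) -> "Waveform":
        """New Waveform with the same rate and different samples."""
        return Waveform(samples, self.rate)
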