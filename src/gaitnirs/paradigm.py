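"""Block-design task paradigm: alternating active-movement and rest periods.

The study paradigm is 10 blocks of 30 s active robotic-assisted gait followed
by 30 s rest, i.e. a 600 s recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Paradigm", "default_paradigm"]


@dataclass(frozen=True)
class Paradigm:
    """Timing of the active blocks of a block-design task.

    Attributes
    ----------
    block_onsets
        Start times (s) of the active periods, strictly increasing.
    active_duration
        Length of each active period (s).
    rest_duration
        Length of the rest period following each block (s).
    """

    block_onsets: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(60 * b) for b in range(10))
    )
    active_duration: float = 30.0
    rest_duration: float = 30.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.block_onsets, dtype=float)
        if onsets.size == 0:
            raise ValueError("paradigm needs at least one block")
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("block onsets must be strictly increasing")
        if np.any(np.diff(onsets) < self.active_duration):
            raise ValueError("active blocks overlap")
        if self.active_duration <= 0 or self.rest_duration < 0:
            raise ValueError("durations must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.block_onsets)

    @property
    def span(self) -> float:
        """Total paradigm duration (s): last block end plus its rest period."""
        return float(self.block_onsets[-1] + self.active_duration + self.rest_duration)

    def n_samples(self, fs: float) -> int:
        return int(round(self.span * fs))

    def boxcar(self, fs: float, n_samples: int | None = None) -> np.ndarray:
        """0/1 indicator of the active periods sampled at ``fs`` Hz."""
        if n_samples is None:
            n_samples = self.n_samples(fs)
        t = np.arange(n_samples) / fs
        box = np.zeros(n_samples)
        for onset in self.block_onsets:
            box[(t >= onset) & (t < onset + self.active_duration)] = 1.0
        return box

    def to_dict(self) -> dict:
        return {
            "block_onsets": list(self.block_onsets),
            "active_duration": self.active_duration,
            "rest_duration": self.rest_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        return cls(
            block_onsets=tuple(d["block_onsets"]),
            active_duration=d["active_duration"],
            rest_duration=d["rest_duration"],
        )


def default_paradigm() -> Paradigm:
    """The study block design: 10 × (30 s active + 30 s rest) = 600 s."""
    return Paradigm()
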