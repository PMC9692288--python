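"""Raw recording container: two-wavelength intensity series plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import Montage
from .paradigm import Paradigm

__all__ = ["Recording"]


@dataclass
class Recording:
    """A raw continuous-wave fNIRS acquisition.

    Attributes
    ----------
    montage, paradigm
        Probe geometry and task timing metadata.
    fs
        Sampling rate, Hz.
    intensity
        Array of shape ``(n_samples, n_channels, n_wavelengths)``; channel
        axis follows ``montage.channels`` order (long channels first, then
        short), wavelength axis follows ``wavelengths``.
    wavelengths
        Nominal wavelengths in nm, default (760, 850).
    subject, session
        Identifiers (session uses the T0/T1/T2 convention).
    """

    montage: Montage
    paradigm: Paradigm
    fs: float
    intensity: np.ndarray
    wavelengths: tuple[float, float] = (760.0, 850.0)
    subject: str = "S01"
    session: str = "T0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (n_samples, n_channels, n_wavelengths)")
        n, c, w = self.intensity.shape
        if c != self.montage.n_channels:
            raise ValueError(
                f"channel axis mismatch: intensity has {c} channels, "
                f"montage defines {self.montage.n_channels}"
            )
        if w != len(self.wavelengths):
            raise ValueError(
                f"wavelength axis mismatch: intensity has {w}, expected {len(self.wavelengths)}"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
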