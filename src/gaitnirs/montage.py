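"""Probe montage: optode and channel geometry for a continuous-wave fNIRS cap.

The default montage reproduces the *topology* of the study probe — 16 sources,
10 detectors, 34 long (cortical) channels over prefrontal, frontal, premotor
and motor regions plus 4 short-separation channels — on a schematic flattened
2-D scalp map.  The layout is synthetic: channel positions are used for
nearest-short-channel pairing and plotting only, and the recorded
source–detector separations are the nominal values (30 mm long, 8 mm short),
not distances recomputed from the schematic coordinates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Channel",
    "Montage",
    "default_montage",
    "load_brodmann_lookup",
    "DEFAULT_LONG_SEPARATION_MM",
    "DEFAULT_SHORT_SEPARATION_MM",
]

DEFAULT_LONG_SEPARATION_MM = 30.0
DEFAULT_SHORT_SEPARATION_MM = 8.0


@dataclass(frozen=True)
class Channel:
    """A source–detector pair.

    Parameters
    ----------
    index
        1-based channel number (user-facing convention).
    source, detector
        Labels of the optodes forming the pair; must exist in the montage.
    separation_mm
        Nominal source–detector distance in millimetres.
    is_short
        True for short-separation channels that sample only superficial
        (scalp/skull) tissue and serve as systemic-physiology regressors.
    brodmann
        Brodmann-area annotation, or None when unknown.
    position
        (x, y) channel midpoint on the schematic scalp map, millimetres.
    """

    index: int
    source: str
    detector: str
    separation_mm: float
    is_short: bool
    brodmann: str | None
    position: tuple[float, float]


@dataclass
class Montage:
    """Optode positions plus the channel list derived from them."""

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ch in self.channels:
            if ch.source not in self.sources:
                raise ValueError(f"channel {ch.index} references unknown source {ch.source!r}")
            if ch.detector not in self.detectors:
                raise ValueError(f"channel {ch.index} references unknown detector {ch.detector!r}")
            if ch.separation_mm <= 0:
                raise ValueError(f"channel {ch.index} has non-positive separation")

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if not c.is_short]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.is_short]

    @property
    def n_long(self) -> int:
        return len(self.long_channels)

    @property
    def n_short(self) -> int:
        return len(self.short_channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def separations_mm(self, short: bool = False) -> np.ndarray:
        chans = self.short_channels if short else self.long_channels
        return np.array([c.separation_mm for c in chans], dtype=float)

    def to_dict(self) -> dict:
        return {
            "sources": {k: list(v) for k, v in self.sources.items()},
            "detectors": {k: list(v) for k, v in self.detectors.items()},
            "channels": [
                {
                    "index": c.index,
                    "source": c.source,
                    "detector": c.detector,
                    "separation_mm": c.separation_mm,
                    "is_short": c.is_short,
                    "brodmann": c.brodmann,
                    "position": list(c.position),
                }
                for c in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            sources={k: tuple(v) for k, v in d["sources"].items()},
            detectors={k: tuple(v) for k, v in d["detectors"].items()},
            channels=[
                Channel(
                    index=c["index"],
                    source=c["source"],
                    detector=c["detector"],
                    separation_mm=c["separation_mm"],
                    is_short=c["is_short"],
                    brodmann=c.get("brodmann"),
                    position=tuple(c["position"]),
                )
                for c in d["channels"]
            ],
        )


def load_brodmann_lookup() -> dict[int, str | None]:
    """Channel number -> Brodmann-area label for the default study montage.

    Only the channels named in the published post-hoc comparison table carry a
    label; the rest map to None.
    """
    lookup: dict[int, str | None] = {}
    path = resources.files("gaitnirs.data") / "channel_brodmann.csv"
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    for row in rows[1:]:
        lookup[int(row[0])] = row[1] if row[1] else None
    return lookup


# Channel midpoints: four rows sweeping prefrontal (top, y=90) to motor
# (y=0) cortex, 10 + 8 + 8 + 8 channels left-to-right.
_ROW_Y = (90.0, 60.0, 30.0, 0.0)
_ROW_COUNTS = (10, 8, 8, 8)
# Short channels, one per scalp quadrant.
_SHORT_POS = ((-60.0, 75.0), (60.0, 75.0), (-60.0, 15.0), (60.0, 15.0))


def default_montage() -> Montage:
    """Build the default 16-source / 10-detector study montage.

    34 long channels at 30 mm nominal separation cover a 4-row schematic map;
    4 short channels at 8 mm sit one per quadrant.  Long channels use
    detectors D1–D6, short channels the dedicated detectors D7–D10.
    Brodmann labels come from the bundled lookup table.
    """
    positions: list[tuple[float, float]] = []
    for y, count in zip(_ROW_Y, _ROW_COUNTS):
        xs = np.linspace(-90.0, 90.0, count)
        positions.extend((float(x), y) for x in xs)

    n_long = len(positions)  # 34
    ba = load_brodmann_lookup()

    # Deterministic optode assignment: cycle sources over S1..S16 and long
    # detectors over D1..D6; lcm(16, 6) = 48 > 34 so every pair is unique.
    src_of = [i % 16 for i in range(n_long)]
    det_of = [i % 6 for i in range(n_long)]

    channels: list[Channel] = []
    for i, pos in enumerate(positions):
        channels.append(
            Channel(
                index=i + 1,
                source=f"S{src_of[i] + 1}",
                detector=f"D{det_of[i] + 1}",
                separation_mm=DEFAULT_LONG_SEPARATION_MM,
                is_short=False,
                brodmann=ba.get(i + 1),
                position=pos,
            )
        )

    # Optode positions: centroid of the channels each optode participates in.
    sources: dict[str, tuple[float, float]] = {}
    detectors: dict[str, tuple[float, float]] = {}
    for opt, idxs in (
        [(f"S{s + 1}", [i for i in range(n_long) if src_of[i] == s]) for s in range(16)]
        + [(f"D{d + 1}", [i for i in range(n_long) if det_of[i] == d]) for d in range(6)]
    ):
        pts = np.array([positions[i] for i in idxs])
        centroid = tuple(np.round(pts.mean(axis=0), 2))
        if opt.startswith("S"):
            sources[opt] = centroid
        else:
            detectors[opt] = centroid

    # Short channels: source = nearest source optode, dedicated detector.
    src_labels = list(sources)
    src_pos = np.array([sources[s] for s in src_labels])
    for k, pos in enumerate(_SHORT_POS):
        nearest = src_labels[int(np.argmin(np.linalg.norm(src_pos - np.array(pos), axis=1)))]
        det = f"D{7 + k}"
        detectors[det] = pos
        channels.append(
            Channel(
                index=n_long + k + 1,
                source=nearest,
                detector=det,
                separation_mm=DEFAULT_SHORT_SEPARATION_MM,
                is_short=True,
                brodmann=None,
                position=pos,
            )
        )

    return Montage(sources=sources, detectors=detectors, channels=channels)
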