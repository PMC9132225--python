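"""8x8 planar electrode grid geometry and cortical-layer assignment.

The recording dish is a MED64-style array: 64 square electrodes (50 um a
side) on a regular 8x8 grid with 150 um pitch.  A coronal slice is laid on
the dish so that each grid *column* falls into one cortical compartment:
superficial layers (II-III), deep layers (V-VI), or outside the region of
interest.  Stimulation is delivered through one electrode located in the
deep layers; channels are numbered 1-64 in row-major order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

SUPERFICIAL = "superficial"
DEEP = "deep"
OUTSIDE = "outside"
LAYERS = (SUPERFICIAL, DEEP, OUTSIDE)


def _default_layer_of_column() -> dict[int, str]:
    # Column 0 sits outside the cortical plate; columns 1-3 cover layers
    # II-III and columns 4-7 layers V-VI, matching a slice oriented with
    # the pia toward low column indices.
    layers = {0: OUTSIDE}
    layers.update({c: SUPERFICIAL for c in (1, 2, 3)})
    layers.update({c: DEEP for c in (4, 5, 6, 7)})
    return layers


@dataclass(frozen=True)
class GridLayout:
    """Electrode grid geometry, stimulation site and layer map.

    Coordinates are 0-based ``(row, col)``; channel ids are 1-64 in
    row-major order (``id = row * n_cols + col + 1``).
    """

    n_rows: int = 8
    n_cols: int = 8
    electrode_size_um: float = 50.0
    pitch_um: float = 150.0
    stim_channel: tuple[int, int] = (3, 5)
    layer_of_column: dict[int, str] = field(default_factory=_default_layer_of_column)

    def __post_init__(self) -> None:
        r, c = self.stim_channel
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
            raise ValueError(f"stim_channel {self.stim_channel} is off the grid")
        missing = [c for c in range(self.n_cols) if c not in self.layer_of_column]
        if missing:
            raise ValueError(f"layer_of_column missing columns {missing}")
        bad = {c: l for c, l in self.layer_of_column.items() if l not in LAYERS}
        if bad:
            raise ValueError(f"unknown layer labels {bad}")
        if self.layer_of_column[c] != DEEP:
            raise ValueError("stimulation channel must lie in the deep layers")
        if self.pitch_um <= 0 or self.electrode_size_um <= 0:
            raise ValueError("pitch and electrode size must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def stim_channel_id(self) -> int:
        return self.channel_id(*self.stim_channel)

    def channel_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) is off the grid")
        return row * self.n_cols + col + 1

    def rc(self, channel_id: int) -> tuple[int, int]:
        if not 1 <= channel_id <= self.n_channels:
            raise ValueError(f"channel id {channel_id} out of range")
        return divmod(channel_id - 1, self.n_cols)

    def layer_of_channel(self, channel_id: int) -> str:
        _, col = self.rc(channel_id)
        return self.layer_of_column[col]

    def distance_um(self, channel_id: int, other_id: int | None = None) -> float:
        """Euclidean distance between electrode centers (default: to stim site)."""
        r1, c1 = self.rc(channel_id)
        r2, c2 = self.rc(other_id) if other_id is not None else self.stim_channel
        return self.pitch_um * math.hypot(r1 - r2, c1 - c2)

    def neighbors8(self, channel_id: int) -> list[int]:
        """Ids of the up-to-8 adjacent electrodes (grid border truncates)."""
        row, col = self.rc(channel_id)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                r, c = row + dr, col + dc
                if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
                    out.append(self.channel_id(r, c))
        return out

    def on_border(self, channel_id: int) -> bool:
        row, col = self.rc(channel_id)
        return row in (0, self.n_rows - 1) or col in (0, self.n_cols - 1)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "electrode_size_um": self.electrode_size_um,
            "pitch_um": self.pitch_um,
            "stim_channel": list(self.stim_channel),
            "layer_of_column": {str(k): v for k, v in self.layer_of_column.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridLayout":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            electrode_size_um=float(d["electrode_size_um"]),
            pitch_um=float(d["pitch_um"]),
            stim_channel=tuple(d["stim_channel"]),
            layer_of_column={int(k): v for k, v in d["layer_of_column"].items()},
        )
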