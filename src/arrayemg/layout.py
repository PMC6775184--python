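"""Electrode-array geometry for the 96-channel forearm grid.

The array wraps the forearm and is logically split into two panels: the
flexor panel on the inner arm (groups A1–A32 plus C1–C16) and the extensor
panel on the outer arm (B1–B32 plus C17–C32).  Each panel is a 4-row ×
12-column grid; channels are wired in a zigzag pattern down/up alternating
columns, four electrodes per column, mirroring how 4-electrode ribbon
groups are laid onto the skin.

`ChannelMask` maps each (finger, direction) pair to the block of electrodes
over the expected anatomical location of that finger's flexor or extensor
muscle belly.  Masks are data, not code: the default assigns each finger a
contiguous 4-row × 2-column block, ordered Thumb→Pinky along the
proximal–distal axis, and alternative masks can be loaded from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml

FINGERS = ("Thumb", "Index", "Middle", "Ring", "Pinky")
DIRECTIONS = ("flexion", "extension")
FLEXOR = "flexor"
EXTENSOR = "extensor"
N_ROWS = 4
N_COLS = 12


@dataclass(frozen=True)
class Electrode:
    """One recording site: label, wiring group, panel side, grid position."""

    label: str
    group: str  # A, B or C
    side: str  # flexor | extensor
    row: int
    col: int


class ArrayLayout:
    """Immutable collection of electrodes with grid lookups."""

    def __init__(self, electrodes: Iterable[Electrode]):
        self.electrodes = tuple(electrodes)
        self.labels = tuple(e.label for e in self.electrodes)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        self._by_label = {e.label: e for e in self.electrodes}
        self._index = {e.label: i for i, e in enumerate(self.electrodes)}

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def electrode(self, label: str) -> Electrode:
        return self._by_label[label]

    def index_of(self, label: str) -> int:
        return self._index[label]

    def side_labels(self, side: str) -> tuple[str, ...]:
        return tuple(e.label for e in self.electrodes if e.side == side)

    def neighbors(self, label: str) -> tuple[str, ...]:
        """Labels at Chebyshev distance 1 on the same panel."""
        e = self._by_label[label]
        out = []
        for other in self.electrodes:
            if other.side != e.side or other.label == label:
                continue
            if max(abs(other.row - e.row), abs(other.col - e.col)) <= 1:
                out.append(other.label)
        return tuple(out)

    def grid_map(self, weights: Mapping[str, float] | np.ndarray, side: str) -> np.ndarray:
        """Place per-channel weights on a (N_ROWS, N_COLS) panel grid.

        ``weights`` is either a mapping label→weight or an array in layout
        channel order.  Positions without an electrode are NaN.
        """
        if not isinstance(weights, Mapping):
            arr = np.asarray(weights, dtype=float)
            if arr.shape != (len(self),):
                raise ValueError(
                    f"weight vector length {arr.shape} does not match layout ({len(self)})"
                )
            weights = {lab: arr[i] for i, lab in enumerate(self.labels)}
        grid = np.full((N_ROWS, N_COLS), np.nan)
        for e in self.electrodes:
            if e.side == side and e.label in weights:
                grid[e.row, e.col] = weights[e.label]
        return grid

    @classmethod
    def default(cls) -> "ArrayLayout":
        """The 96-channel layout: A/B panels of 32 plus C split 16/16."""
        electrodes: list[Electrode] = []

        def add_block(group: str, first: int, count: int, side: str, col_offset: int) -> None:
            n_cols = count // N_ROWS
            idx = first
            for j in range(n_cols):
                rows = range(N_ROWS) if j % 2 == 0 else range(N_ROWS - 1, -1, -1)
                for r in rows:
                    electrodes.append(Electrode(f"{group}{idx}", group, side, r, col_offset + j))
                    idx += 1

        add_block("A", 1, 32, FLEXOR, 0)
        add_block("C", 1, 16, FLEXOR, 8)
        add_block("B", 1, 32, EXTENSOR, 0)
        add_block("C", 17, 16, EXTENSOR, 8)
        return cls(electrodes)


@dataclass
class ChannelMask:
    """(finger, direction) → anatomically plausible electrode labels."""

    mapping: dict[tuple[str, str], tuple[str, ...]]

    def labels(self, finger: str, direction: str) -> tuple[str, ...]:
        if finger not in FINGERS:
            raise KeyError(f"unknown finger {finger!r}")
        if direction not in DIRECTIONS:
            raise KeyError(f"unknown direction {direction!r}")
        labels = self.mapping.get((finger, direction), ())
        if not labels:
            raise ValueError(f"empty channel mask for ({finger}, {direction})")
        return labels

    def validate(self, layout: ArrayLayout) -> None:
        for (finger, direction), labels in self.mapping.items():
            want_side = FLEXOR if direction == "flexion" else EXTENSOR
            for lab in labels:
                if lab not in layout:
                    raise ValueError(f"mask label {lab!r} not in layout")
                if layout.electrode(lab).side != want_side:
                    raise ValueError(
                        f"mask label {lab!r} for ({finger}, {direction}) is on the "
                        f"{layout.electrode(lab).side} side"
                    )

    @classmethod
    def default(cls, layout: ArrayLayout | None = None) -> "ChannelMask":
        """One 4×2 electrode block per finger per side, Thumb→Pinky along columns."""
        layout = layout or ArrayLayout.default()
        mapping: dict[tuple[str, str], tuple[str, ...]] = {}
        for i, finger in enumerate(FINGERS):
            cols = (2 * i, 2 * i + 1)
            for direction, side in (("flexion", FLEXOR), ("extension", EXTENSOR)):
                labels = tuple(
                    e.label
                    for e in layout.electrodes
                    if e.side == side and e.col in cols
                )
                mapping[(finger, direction)] = labels
        mask = cls(mapping)
        mask.validate(layout)
        return mask

    def to_yaml(self, path) -> None:
        doc = {f"{f}:{d}": list(labels) for (f, d), labels in self.mapping.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ChannelMask":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        mapping = {}
        for key, labels in doc.items():
            finger, direction = key.split(":")
            mapping[(finger, direction)] = tuple(labels)
        return cls(mapping)


def mask_block_center(finger: str, side: str) -> tuple[float, float]:
    """Grid (row, col) center of the default mask block for a finger's side."""
    i = FINGERS.index(finger)
    return (N_ROWS - 1) / 2.0, 2 * i + 0.5
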