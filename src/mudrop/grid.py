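"""Electrode-array geometry.

The actuation array is a ``rows x cols`` grid of square electrodes.  Electrode
index ``i`` maps to ``(row, col) = (i // cols, i % cols)``.  Every electrode
owns a half-open pixel rectangle (its *footprint*) on the camera canvas;
coordinates are (row, col), 0-based, origin at the top-left.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ElectrodeGrid:
    rows: int
    cols: int
    electrode_px: int
    gap_px: int = 2
    margin_px: int = 14
    reservoir_ids: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.electrode_px < 1:
            raise ValueError("rows, cols and electrode_px must all be >= 1")
        if self.gap_px < 0 or self.margin_px < 0:
            raise ValueError("gap_px and margin_px must be >= 0")
        n = self.rows * self.cols
        for r in self.reservoir_ids:
            if not 0 <= r < n:
                raise ValueError(f"reservoir id {r} outside [0, {n})")

    # -- index arithmetic ---------------------------------------------------
    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def rc(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n_electrodes:
            raise ValueError(f"electrode index {index} outside grid")
        return divmod(index, self.cols)

    def index(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"({row}, {col}) outside grid")
        return row * self.cols + col

    def neighbors(self, index: int) -> list[int]:
        """4-neighborhood on the grid, ascending index order."""
        r, c = self.rc(index)
        out = []
        for rr, cc in ((r - 1, c), (r, c - 1), (r, c + 1), (r + 1, c)):
            if 0 <= rr < self.rows and 0 <= cc < self.cols:
                out.append(self.index(rr, cc))
        return out

    # -- pixel geometry -----------------------------------------------------
    @property
    def pitch(self) -> int:
        return self.electrode_px + self.gap_px

    def footprint(self, index: int) -> tuple[int, int, int, int]:
        """Half-open pixel rectangle ``(top, left, bottom, right)``."""
        r, c = self.rc(index)
        top = self.margin_px + r * self.pitch
        left = self.margin_px + c * self.pitch
        return (top, left, top + self.electrode_px, left + self.electrode_px)

    def footprint_area(self) -> int:
        return self.electrode_px * self.electrode_px

    def center(self, index: int) -> tuple[float, float]:
        t, l, b, r = self.footprint(index)
        return ((t + b) / 2.0, (l + r) / 2.0)

    def canvas_shape(self) -> tuple[int, int]:
        h = 2 * self.margin_px + self.rows * self.electrode_px + (self.rows - 1) * self.gap_px
        w = 2 * self.margin_px + self.cols * self.electrode_px + (self.cols - 1) * self.gap_px
        return (h, w)

    def electrode_at(self, point: tuple[float, float]) -> int:
        """Electrode whose footprint contains ``point``; ties cannot occur
        (footprints are disjoint half-open rectangles).  Points in a gap or
        margin fall back to the nearest footprint center, lowest index first.
        """
        pr, pc = point
        for i in range(self.n_electrodes):
            t, l, b, r = self.footprint(i)
            if t <= pr < b and l <= pc < r:
                return i
        best, best_d = 0, float("inf")
        for i in range(self.n_electrodes):
            cr, cc = self.center(i)
            d = (cr - pr) ** 2 + (cc - pc) ** 2
            if d < best_d:
                best, best_d = i, d
        return best


def make_grid(
    rows: int,
    cols: int,
    electrode_px: int,
    reservoir_ids: list[int] | tuple[int, ...] = (),
    gap_px: int = 2,
    margin_px: int = 14,
) -> ElectrodeGrid:
    """Build an :class:`ElectrodeGrid`, validating all invariants."""
    return ElectrodeGrid(
        rows=rows,
        cols=cols,
        electrode_px=electrode_px,
        gap_px=gap_px,
        margin_px=margin_px,
        reservoir_ids=tuple(reservoir_ids),
    )


def default_grid() -> ElectrodeGrid:
    """3x3 array whose canvas is exactly 128x128 px — the desk-scale default
    used by the synthetic training distribution (32 px electrodes, 2 px gaps,
    14 px margins)."""
    return make_grid(3, 3, 32)
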