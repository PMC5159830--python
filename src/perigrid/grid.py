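"""Fiducial grid layout for the patterned perifusion coverslip.

The coverslip carries a photolithographically etched grid of squares, each
dual-labelled with its row (upper-left corner) and column (lower-right
corner) so that any field of view can be re-located after the coverslip is
removed, fixed and immunostained.  The default layout is 133 x 133 squares
of 150 µm — 17,689 uniquely addressed squares, sized so one square fills the
field of a 40x objective.

Coordinates are in µm with the origin at the grid's top-left corner and y
increasing downward (image convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridLayout", "make_grid_layout"]

DEFAULT_SQUARE_SIZE_UM = 150.0
DEFAULT_N_ROWS = 133
DEFAULT_N_COLS = 133


@dataclass(frozen=True)
class GridLayout:
    """Geometry and addressing of the coverslip fiducial grid.

    Square identifiers follow the etched labelling convention
    ``"R<row>C<col>"`` with 1-based row/column numbers, e.g. ``"R001C001"``
    for the top-left square.
    """

    square_size_um: float = DEFAULT_SQUARE_SIZE_UM
    n_rows: int = DEFAULT_N_ROWS
    n_cols: int = DEFAULT_N_COLS

    def __post_init__(self) -> None:
        if not self.square_size_um > 0:
            raise ValueError(f"square_size_um must be > 0, got {self.square_size_um}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid needs at least one row and one column, got "
                f"{self.n_rows} x {self.n_cols}"
            )

    @property
    def n_squares(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width_um(self) -> float:
        return self.n_cols * self.square_size_um

    @property
    def height_um(self) -> float:
        return self.n_rows * self.square_size_um

    def square_id(self, row: int, col: int) -> str:
        """Unique identifier of the square at 0-based (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"square ({row}, {col}) outside {self.n_rows} x {self.n_cols} grid")
        return f"R{row + 1:03d}C{col + 1:03d}"

    def parse_square_id(self, square_id: str) -> tuple[int, int]:
        """Inverse of :meth:`square_id`; returns 0-based (row, col)."""
        try:
            r_part, c_part = square_id[1:].split("C")
            row, col = int(r_part) - 1, int(c_part) - 1
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed square id {square_id!r}") from exc
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"square id {square_id!r} outside grid")
        return row, col

    def square_ids(self) -> list[str]:
        return [
            self.square_id(r, c) for r in range(self.n_rows) for c in range(self.n_cols)
        ]

    def locate(self, x_um: float, y_um: float) -> str:
        """Map a position (µm, grid frame) to the id of the square containing it.

        Squares are half-open ``[x0, x0 + s) x [y0, y0 + s)`` except on the
        grid's far edges, which are closed so boundary points stay inside.
        """
        col = int(np.floor(x_um / self.square_size_um))
        row = int(np.floor(y_um / self.square_size_um))
        if x_um == self.width_um:
            col = self.n_cols - 1
        if y_um == self.height_um:
            row = self.n_rows - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"position ({x_um}, {y_um}) µm lies outside the grid")
        return self.square_id(row, col)

    def square_origin_um(self, square_id: str) -> tuple[float, float]:
        """Top-left corner (x, y) of a square, in µm."""
        row, col = self.parse_square_id(square_id)
        return col * self.square_size_um, row * self.square_size_um


def make_grid_layout(
    square_size_um: float = DEFAULT_SQUARE_SIZE_UM,
    n_rows: int = DEFAULT_N_ROWS,
    n_cols: int = DEFAULT_N_COLS,
) -> GridLayout:
    """Build a coverslip grid layout.

    The default (150 µm squares, 133 x 133) reproduces the 17,689-square
    reference coverslip.
    """
    return GridLayout(square_size_um=square_size_um, n_rows=n_rows, n_cols=n_cols)
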