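"""Equal-area raster grid and the layers registered to it.

All spatial data in the package live on a single :class:`Grid`: a regular
lattice of equal-area cells with a shared nodata mask.  Continuous fields
(environmental predictors, modelled suitability) are :class:`Layer` objects;
presence/absence and protection status are :class:`BinaryMask` objects.
Cell membership uses half-open intervals ``[x0, x0 + dx)`` so rasterization
of point records is deterministic; points on the maximum edge fall outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Raised when a layer does not share the grid of previously loaded data."""


@dataclass(frozen=True)
class Grid:
    """Regular equal-area lattice shared by every raster layer.

    Parameters
    ----------
    n_rows, n_cols
        Lattice shape.  Row 0 is the northernmost (maximum-y) row, matching
        raster conventions.
    x0, y0
        Map coordinates of the outer corner of cell (0, 0): the minimum x and
        the *maximum* y of the grid extent.
    dx, dy
        Cell size in map units; both strictly positive.
    cell_area
        Area of one cell in km².
    nodata_mask
        Boolean array of shape ``(n_rows, n_cols)``; True marks cells outside
        the analysis region.  Defaults to no masked cells.
    """

    n_rows: int
    n_cols: int
    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1.0
    dy: float = 1.0
    cell_area: float = 1.0
    nodata_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid shape must be positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        mask = self.nodata_mask
        if mask is None:
            mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise GridMismatchError(
                    f"nodata mask shape {mask.shape} != grid shape {self.shape}"
                )
        mask = mask.copy()
        mask.setflags(write=False)
        object.__setattr__(self, "nodata_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        """Number of valid (non-masked) cells."""
        return int((~self.nodata_mask).sum())

    def compatible(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.dx, other.dx)
            and np.isclose(self.dy, other.dy)
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.array_equal(self.nodata_mask, other.nodata_mask)
        )

    def require_compatible(self, other: "Grid") -> None:
        if not self.compatible(other):
            raise GridMismatchError("layers are registered to different grids")

    # ---- coordinate transforms -------------------------------------------

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell (row, col) containing map point (x, y); None if outside.

        Membership is half-open: ``x0 <= x < x0 + n_cols*dx`` and
        ``y0 - n_rows*dy < y <= y0``.
        """
        col = int(np.floor((x - self.x0) / self.dx))
        row = int(np.floor((self.y0 - y) / self.dy))
        # points exactly on the top/left edge belong to row/col 0
        if x == self.x0:
            col = 0
        if y == self.y0:
            row = 0
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def cells_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized cell_of; returns (n, 2) int array, -1 rows when outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - y) / self.dy).astype(int)
        col[x == self.x0] = 0
        row[y == self.y0] = 0
        out = np.stack([row, col], axis=1)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        out[bad] = -1
        return out

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Map coordinates (x, y) of a cell center."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y


@dataclass
class Layer:
    """Continuous per-cell field registered to a :class:`Grid`.

    Values must be finite on non-masked cells; masked cells hold NaN.
    """

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        valid = ~self.grid.nodata_mask
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("layer has non-finite values on unmasked cells")
        self.values[~valid] = np.nan

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of values on unmasked cells (row-major order)."""
        return self.values[~self.grid.nodata_mask]

    def copy_with(self, values: np.ndarray) -> "Layer":
        return Layer(self.grid, values)


@dataclass
class BinaryMask:
    """Per-cell 0/1 indicator registered to a :class:`Grid` (e.g. PA network,
    binary species range).  Off the nodata mask all values are 0 or 1."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {vals.shape} != grid shape {self.grid.shape}"
            )
        valid = ~self.grid.nodata_mask
        v = vals[valid]
        if not np.all(np.isin(v[np.isfinite(v.astype(float))], (0, 1))):
            raise ValueError("binary mask holds values outside {0, 1}")
        out = np.zeros(self.grid.shape, dtype=np.uint8)
        out[valid] = vals[valid].astype(np.uint8)
        self.values = out

    @property
    def as_bool(self) -> np.ndarray:
        """Boolean array; False on nodata cells."""
        return (self.values == 1) & ~self.grid.nodata_mask

    @property
    def area_km2(self) -> float:
        return float(self.as_bool.sum()) * self.grid.cell_area

    def count(self) -> int:
        return int(self.as_bool.sum())

    def intersection_count(self, other: "BinaryMask") -> int:
        self.grid.require_compatible(other.grid)
        return int((self.as_bool & other.as_bool).sum())
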