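"""Regular-grid plumbing: grid geometry, layer stacks, and text-raster I/O.

Coordinates are planar map units on a regular grid. Cells are indexed
row-major and 0-based, with row 0 at the *bottom* (south) edge so that y
increases with row index; a point maps to the cell containing it via
half-open intervals ``[edge, edge + cell_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular raster grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; must be positive.
    cell_size : float
        Edge length of a (square) cell in map units.
    origin_x, origin_y : float
        Map coordinates of the lower-left corner of the grid.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as two ``(n_rows, n_cols)`` arrays."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices (half-open cells)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        if np.any((row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)):
            raise ValueError("point outside grid extent")
        return row, col

    def center_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


@dataclass
class EnvStack:
    """Ordered stack of co-registered environmental layers with a validity mask.

    All statistics downstream (normalization, PCA, county summaries) are
    computed over masked-in cells only.
    """

    spec: GridSpec
    layers: np.ndarray  # (n_layers, n_rows, n_cols)
    layer_names: list[str]
    mask: np.ndarray = field(default=None)  # boolean (n_rows, n_cols)

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (n_layers, n_rows, n_cols) array")
        if self.layers.shape[1:] != self.spec.shape:
            raise ValueError("layer shape does not match GridSpec")
        if len(self.layer_names) != self.layers.shape[0]:
            raise ValueError("one name per layer required")
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.spec.shape:
            raise ValueError("mask shape does not match GridSpec")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    def values_at(self, rows, cols) -> np.ndarray:
        """Covariate matrix (n_points, n_layers) at the given cells."""
        return self.layers[:, rows, cols].T

    def masked_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of masked-in cell values."""
        return self.layers[:, self.mask].T

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.layer_names.index(name)]


def write_ascii_grid(path, grid: np.ndarray, spec: GridSpec,
                     mask: np.ndarray | None = None, fmt: str = "%.10g") -> None:
    """Write one layer as an ESRI ASCII grid (rows written north to south)."""
    data = np.array(grid, dtype=float)
    if mask is not None:
        data[~mask] = NODATA
    header = (
        f"ncols {spec.n_cols}\nnrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\nyllcorner {spec.origin_y!r}\n"
        f"cellsize {spec.cell_size!r}\nNODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data[::-1], fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, spec, mask)."""
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    spec = GridSpec(
        n_rows=int(head["nrows"]), n_cols=int(head["ncols"]),
        cell_size=head["cellsize"],
        origin_x=head["xllcorner"], origin_y=head["yllcorner"],
    )
    mask = data != head.get("nodata_value", NODATA)
    data[~mask] = np.nan
    return data, spec, mask
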