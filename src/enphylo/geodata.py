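"""Gridded environmental data model, raster I/O, occurrence handling.

All geometry is planar, in kilometres: inputs in geographic coordinates must
be projected before use.  A grid is addressed by 0-based ``(row, col)`` with
row 0 at the origin edge; a point ``(x, y)`` falls in the cell

    row = floor((y - y0) / cell_size),  col = floor((x - x0) / cell_size)

i.e. cell membership is half-open ``[edge, next_edge)`` on both axes and the
vertical axis increases with the row index.

Rasters are stored one layer per file in ESRI ASCII grid format (plain
text), which round-trips float64 values exactly via ``%.17g`` formatting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError

NODATA = -9999.0

Cell = tuple[int, int]


@dataclass
class EnvStack:
    """Aligned multi-layer environmental grid with a shared nodata mask.

    Attributes
    ----------
    layer_names : list of str
        Unique variable identifiers, one per layer.
    values : ndarray, shape (n_layers, nrows, ncols)
        Layer values; entries under ``nodata_mask`` are undefined.
    cell_size : float
        Cell edge length in km.
    origin : (float, float)
        ``(x0, y0)`` of the low-index grid corner, in km.
    nodata_mask : ndarray of bool, shape (nrows, ncols)
        True marks unusable cells (union across layers).
    """

    layer_names: list[str]
    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InputError("values must have shape (n_layers, nrows, ncols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise InputError("layer_names length does not match values")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise InputError("layer_names must be unique")
        if self.cell_size <= 0:
            raise InputError("cell_size must be positive")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape[1:]:
            raise AlignmentError("nodata_mask shape does not match layers")

    # -- basic geometry -------------------------------------------------
    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def nrows(self) -> int:
        return self.values.shape[1]

    @property
    def ncols(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def same_grid(self, other: "EnvStack") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def point_to_cell(self, x: float, y: float) -> Cell:
        x0, y0 = self.origin
        return (
            int(np.floor((y - y0) / self.cell_size)),
            int(np.floor((x - x0) / self.cell_size)),
        )

    def cell_center(self, cell: Cell) -> tuple[float, float]:
        r, c = cell
        x0, y0 = self.origin
        return (x0 + (c + 0.5) * self.cell_size, y0 + (r + 0.5) * self.cell_size)

    def in_bounds(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.nrows and 0 <= c < self.ncols

    def valid_cells(self) -> list[Cell]:
        """All on-grid cells off the nodata mask, in row-major order."""
        rows, cols = np.nonzero(~self.nodata_mask)
        return list(zip(rows.tolist(), cols.tolist()))

    def values_at(
        self, cells: Sequence[Cell], layers: Sequence[str] | None = None
    ) -> np.ndarray:
        """Environmental matrix (n_cells x n_layers) at the given cells."""
        idx = (
            range(self.n_layers)
            if layers is None
            else [self.layer_names.index(n) for n in layers]
        )
        cells = list(cells)
        rows = np.array([r for r, _ in cells], dtype=int)
        cols = np.array([c for _, c in cells], dtype=int)
        return np.stack([self.values[i, rows, cols] for i in idx], axis=1)

    def copy(self) -> "EnvStack":
        return EnvStack(
            list(self.layer_names),
            self.values.copy(),
            self.cell_size,
            tuple(self.origin),
            self.nodata_mask.copy(),
        )

    def subset(self, names: Sequence[str]) -> "EnvStack":
        idx = [self.layer_names.index(n) for n in names]
        return EnvStack(
            list(names),
            self.values[idx].copy(),
            self.cell_size,
            tuple(self.origin),
            self.nodata_mask.copy(),
        )


@dataclass
class OccurrenceSet:
    """Rasterized occurrences of one species: unique valid cells."""

    species_id: str
    points: list[tuple[float, float]]
    cell_ids: list[Cell]


@dataclass
class BackgroundSample:
    """Cells drawn to represent the available environment."""

    cell_ids: list[Cell]

    @property
    def count(self) -> int:
        return len(self.cell_ids)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid, one layer per file)
# ---------------------------------------------------------------------------

def write_layer(path: str | Path, grid: np.ndarray, cell_size: float,
                origin: tuple[float, float], nodata_mask: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid (text)."""
    path = Path(path)
    nrows, ncols = grid.shape
    out = grid.astype(float).copy()
    out[nodata_mask] = NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.17g}\n")
        fh.write(f"yllcorner {origin[1]:.17g}\n")
        fh.write(f"cellsize {cell_size:.17g}\n")
        fh.write(f"NODATA_value {NODATA:.17g}\n")
        for r in range(nrows):
            fh.write(" ".join(f"{v:.17g}" for v in out[r]) + "\n")


def _read_layer(path: Path) -> tuple[np.ndarray, float, tuple[float, float], float]:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.array(rows, dtype=float)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InputError(f"{path}: grid body does not match header dimensions")
    nodata = header.get("nodata_value", NODATA)
    return grid, header["cellsize"], (header["xllcorner"], header["yllcorner"]), nodata


def load_env_stack(paths: Sequence[str | Path]) -> EnvStack:
    """Load aligned single-layer rasters into one :class:`EnvStack`.

    Layer names are taken from the file stems.  The nodata mask is the
    union of per-layer nodata cells.  Grids that disagree in shape, origin
    or cell size raise :class:`AlignmentError`.
    """
    if not paths:
        raise InputError("no raster paths given")
    layers, names = [], []
    ref_cs = ref_origin = ref_shape = None
    mask = None
    for p in paths:
        p = Path(p)
        grid, cs, origin, nodata = _read_layer(p)
        if ref_shape is None:
            ref_cs, ref_origin, ref_shape = cs, origin, grid.shape
            mask = np.zeros(grid.shape, dtype=bool)
        elif grid.shape != ref_shape or not np.isclose(cs, ref_cs) or not np.allclose(origin, ref_origin):
            raise AlignmentError(f"{p} does not align with the first raster")
        mask |= grid == nodata
        layers.append(grid)
        names.append(p.stem)
    return EnvStack(names, np.stack(layers), ref_cs, ref_origin, mask)


def write_env_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack to ``directory`` as ``<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, name in enumerate(stack.layer_names):
        p = directory / f"{name}.asc"
        write_layer(p, stack.values[i], stack.cell_size, stack.origin,
                    stack.nodata_mask)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Occurrence handling
# ---------------------------------------------------------------------------

def clean_occurrences(
    raw: pd.DataFrame,
    bbox: tuple[float, float, float, float],
    min_precision: int = 2,
) -> pd.DataFrame:
    """Filter raw occurrence records.

    Keeps rows whose stated coordinate precision (decimal places of the
    source record, column ``precision``) is at least ``min_precision``,
    drops exact duplicates, and drops rows outside ``bbox``
    (xmin, xmax, ymin, ymax).  Precision is read from the table, never
    inferred from trailing zeros.
    """
    df = raw.copy()
    if "precision" in df.columns:
        df = df[df["precision"] >= min_precision]
    df = df.drop_duplicates()
    xmin, xmax, ymin, ymax = bbox
    df = df[(df["x"] >= xmin) & (df["x"] <= xmax)
            & (df["y"] >= ymin) & (df["y"] <= ymax)]
    return df.reset_index(drop=True)


def rasterize_occurrences(
    points: Sequence[tuple[float, float]],
    stack: EnvStack,
    species_id: str = "species",
) -> OccurrenceSet:
    """Assign points to grid cells, deduplicating per cell.

    Points on nodata cells (or off-grid) are dropped with a warning; if no
    point lands on a usable cell an :class:`InputError` is raised.
    """
    seen: set[Cell] = set()
    cells: list[Cell] = []
    kept_points: list[tuple[float, float]] = []
    n_dropped = 0
    for x, y in points:
        cell = stack.point_to_cell(x, y)
        if not stack.in_bounds(cell) or stack.nodata_mask[cell]:
            n_dropped += 1
            continue
        kept_points.append((x, y))
        if cell not in seen:
            seen.add(cell)
            cells.append(cell)
    if n_dropped:
        warnings.warn(
            f"{species_id}: dropped {n_dropped} point(s) off-grid or on nodata cells"
        )
    if not cells:
        raise InputError(f"{species_id}: no occurrence falls on a usable cell")
    return OccurrenceSet(species_id, kept_points, cells)


def sample_background(
    stack: EnvStack,
    n: int,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> BackgroundSample:
    """Draw ``n`` background cells uniformly without replacement.

    Cells come from the valid (non-nodata) portion of the grid, optionally
    intersected with a caller-supplied boolean ``mask`` (e.g. an ecoregion).
    If fewer cells are available than requested the draw is capped with a
    warning.  Deterministic under ``seed``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    avail = ~stack.nodata_mask
    if mask is not None:
        avail = avail & np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(avail)
    n_avail = rows.size
    if n_avail == 0:
        raise InputError("no valid cells available for background sampling")
    if n > n_avail:
        warnings.warn(f"requested {n} background cells, only {n_avail} available")
        n = n_avail
    pick = rng.choice(n_avail, size=n, replace=False)
    pick.sort()
    return BackgroundSample([(int(rows[i]), int(cols[i])) for i in pick])


# ---------------------------------------------------------------------------
# Collinearity screening
# ---------------------------------------------------------------------------

def collinearity_filter(
    stack: EnvStack,
    sample_cells: Sequence[Cell],
    r_threshold: float = 0.7,
) -> list[str]:
    """Greedy collinearity elimination over sampled cells.

    While any retained pair has |Pearson r| > ``r_threshold``, the layer
    with the largest mean absolute correlation to all other retained layers
    is removed (ties broken by keeping the earlier layer in input order).
    Constant (zero-variance) layers are removed first with a warning.
    Survivors are returned in input order.
    """
    if stack.n_layers < 2:
        raise InputError("need at least 2 layers")
    if len(sample_cells) < 3:
        raise InputError("need at least 3 sample cells")
    X = stack.values_at(sample_cells)
    names = list(stack.layer_names)
    sds = X.std(axis=0)
    keep = [i for i in range(len(names)) if sds[i] > 0]
    if len(keep) < len(names):
        dropped = [names[i] for i in range(len(names)) if sds[i] == 0]
        warnings.warn(f"removing constant layer(s): {dropped}")
    while len(keep) > 1:
        sub = X[:, keep]
        with np.errstate(invalid="ignore"):
            corr = np.abs(np.corrcoef(sub.T))
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= r_threshold:
            break
        mean_abs = corr.mean(axis=1)
        # ties: np.argmax keeps the first maximum, so flip to drop the later one
        worst_rev = int(np.argmax(mean_abs[::-1]))
        worst = len(keep) - 1 - worst_rev
        keep.pop(worst)
    return [names[i] for i in keep]
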