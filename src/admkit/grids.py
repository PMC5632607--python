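"""Raster data model and plain-text (ESRI ASCII grid) I/O.

All rasters in the pipeline live on regular square-cell grids, row 0 at the
top, 0-based indices.  Cell (r, c) covers the half-open square

    [origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]

with ``s`` the cell size; a point maps to the cell containing it, and points
exactly on the right/bottom edge of the grid are clipped inward.  Invalid
cells are carried as a boolean mask in memory and as a declared nodata value
on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import AlignmentError, ParameterError, ScaleError

NODATA = -9999.0

CONTINUOUS = "continuous_0_100"
ORDINAL = "ordinal_1_10"


class GridGeometry(NamedTuple):
    """Placement of a raster in map coordinates (top-left corner origin)."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.origin_y - self.n_rows * self.cell_size

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col); max-edge points are clipped inward."""
        if not (self.origin_x <= x <= self.x_max and self.y_min <= y <= self.origin_y):
            raise ParameterError(f"point ({x}, {y}) outside grid bounds")
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        return min(row, self.n_rows - 1), min(col, self.n_cols - 1)

    def cells_of(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point -> cell mapping. points is (N, 2); returns (N, 2) int."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        inside = (
            (pts[:, 0] >= self.origin_x)
            & (pts[:, 0] <= self.x_max)
            & (pts[:, 1] >= self.y_min)
            & (pts[:, 1] <= self.origin_y)
        )
        if not inside.all():
            bad = pts[~inside][0]
            raise ParameterError(f"point ({bad[0]}, {bad[1]}) outside grid bounds")
        col = np.floor((pts[:, 0] - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - pts[:, 1]) / self.cell_size).astype(int)
        return np.column_stack(
            [np.minimum(row, self.n_rows - 1), np.minimum(col, self.n_cols - 1)]
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of shape (n_rows, n_cols)."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)


def _require_same_geometry(a: GridGeometry, b: GridGeometry, what: str = "raster") -> None:
    if a != b:
        raise AlignmentError(f"{what} is not aligned: {b} != {a}")


@dataclass
class EnvStack:
    """Aligned multi-layer environmental raster with a shared validity mask."""

    layer_names: list[str]
    values: np.ndarray  # (n_layers, n_rows, n_cols) float
    geometry: GridGeometry
    valid_mask: np.ndarray  # (n_rows, n_cols) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 3:
            raise ParameterError("EnvStack values must be (layers, rows, cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ParameterError("one name per layer required")
        if self.values.shape[1:] != (self.geometry.n_rows, self.geometry.n_cols):
            raise AlignmentError("values shape disagrees with geometry")
        if self.valid_mask.shape != self.values.shape[1:]:
            raise AlignmentError("valid_mask shape disagrees with values")
        if not self.valid_mask.any():
            raise ParameterError("EnvStack needs at least one valid cell")
        if not np.isfinite(self.values[:, self.valid_mask]).all():
            raise ParameterError("non-finite value on a valid cell")

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.geometry.n_rows

    @property
    def n_cols(self) -> int:
        return self.geometry.n_cols

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.layer_names.index(name)]

    def valid_values(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of environments at valid cells."""
        return self.values[:, self.valid_mask].T

    def standardized(self) -> "EnvStack":
        """Layers rescaled to mean 0, sd 1 over valid cells (invalid cells nan)."""
        out = np.full_like(self.values, np.nan)
        for i in range(self.n_layers):
            v = self.values[i][self.valid_mask]
            sd = v.std()
            if sd == 0:
                raise ParameterError(f"layer {self.layer_names[i]} is constant")
            out[i][self.valid_mask] = (v - v.mean()) / sd
        return EnvStack(list(self.layer_names), out, self.geometry, self.valid_mask.copy())


@dataclass
class SuitabilityModel:
    """Continuous (0-100) or ordinal (1-10) habitat-suitability raster."""

    species: str
    engine: str  # enfa | envelope | mahalanobis | external
    grid: np.ndarray
    scale: str  # CONTINUOUS or ORDINAL
    geometry: GridGeometry
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise AlignmentError("suitability grid disagrees with geometry")
        v = self.grid[self.valid_mask]
        if self.scale == CONTINUOUS:
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ScaleError("continuous scores must lie in [0, 100]")
        elif self.scale == ORDINAL:
            if v.size and (not np.allclose(v, np.round(v)) or v.min() < 1 or v.max() > 10):
                raise ScaleError("ordinal scores must be integers in [1, 10]")
        else:
            raise ParameterError(f"unknown scale {self.scale!r}")

    def default_thresholds(self) -> list[float]:
        """Candidate threshold scan matching the score scale."""
        if self.scale == ORDINAL:
            return [float(t) for t in range(1, 11)]
        return [3.0, 20.0, 40.0, 60.0, 70.0, 80.0, 90.0]


@dataclass
class BinaryModel:
    """Thresholded presence/absence raster (PDM before, ADM after habitat masking)."""

    species: str
    kind: str  # "PDM" | "ADM"
    grid: np.ndarray  # 0/1 on valid cells
    geometry: GridGeometry
    valid_mask: np.ndarray
    threshold_used: float
    threshold_rule: str  # kappa | roc | external
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.grid.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise AlignmentError("binary grid disagrees with geometry")
        if not np.isin(self.grid[self.valid_mask], (0, 1)).all():
            raise ParameterError("binary grid must be 0/1 on valid cells")

    @property
    def presence(self) -> np.ndarray:
        return (self.grid == 1) & self.valid_mask

    @property
    def absence(self) -> np.ndarray:
        return (self.grid == 0) & self.valid_mask


@dataclass
class LandCover:
    """Categorical land-cover raster, typically finer than the model grid."""

    class_grid: np.ndarray  # int codes
    legend: dict[int, str]
    geometry: GridGeometry
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.class_grid = np.asarray(self.class_grid, dtype=int)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.class_grid.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise AlignmentError("land-cover grid disagrees with geometry")

    def subcell_ratio(self, model_geometry: GridGeometry) -> int:
        """Integer number of land-cover cells per model cell side."""
        ratio = model_geometry.cell_size / self.geometry.cell_size
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise AlignmentError(
                f"land-cover cell size {self.geometry.cell_size} does not divide "
                f"model cell size {model_geometry.cell_size}"
            )
        r = int(round(ratio))
        ok = (
            self.geometry.n_rows == model_geometry.n_rows * r
            and self.geometry.n_cols == model_geometry.n_cols * r
            and np.isclose(self.geometry.origin_x, model_geometry.origin_x)
            and np.isclose(self.geometry.origin_y, model_geometry.origin_y)
        )
        if not ok:
            raise AlignmentError("land cover does not cover the model grid exactly")
        return r

    def dominant_classes(self, model_geometry: GridGeometry) -> np.ndarray:
        """Modal subcell class per model cell; ties broken by lowest code."""
        r = self.subcell_ratio(model_geometry)
        R, C = model_geometry.n_rows, model_geometry.n_cols
        blocks = self.class_grid.reshape(R, r, C, r).transpose(0, 2, 1, 3).reshape(R, C, r * r)
        codes = np.array(sorted(self.legend), dtype=int)
        counts = (blocks[..., None] == codes).sum(axis=2)  # (R, C, n_codes)
        # argmax returns the first (lowest-code) maximum: the documented tie-break
        return codes[np.argmax(counts, axis=2)]


@dataclass
class HabitatTable:
    """Species -> suitable land-cover class codes."""

    mapping: dict[str, frozenset[int]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "HabitatTable":
        import pandas as pd

        from .errors import SchemaError

        df = pd.read_csv(path)
        missing = {"species", "class_code"} - set(df.columns)
        if missing:
            raise SchemaError(f"habitat table missing columns: {sorted(missing)}")
        mapping = {
            sp: frozenset(int(c) for c in grp["class_code"])
            for sp, grp in df.groupby("species")
        }
        return cls(mapping)

    def classes_for(self, species: str) -> frozenset[int]:
        if species not in self.mapping:
            raise KeyError(f"species {species!r} not in habitat table")
        return self.mapping[species]

    def validate_against(self, legend: Mapping[int, str]) -> None:
        for sp, codes in self.mapping.items():
            unknown = codes - set(legend)
            if unknown:
                raise ParameterError(
                    f"habitat table for {sp!r} references unknown classes {sorted(unknown)}"
                )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text, exact round-trip via %.17g)
# ---------------------------------------------------------------------------

def write_grid(
    path: str | Path,
    grid: np.ndarray,
    geometry: GridGeometry,
    valid_mask: np.ndarray | None = None,
    nodata: float = NODATA,
    fmt: str = "%.17g",
) -> Path:
    """Write one raster layer as an ESRI ASCII grid."""
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    out = grid.copy()
    if valid_mask is not None:
        out[~np.asarray(valid_mask, dtype=bool)] = nodata
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_x!r}\n"
        f"yllcorner {geometry.y_min!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)
    return path


def read_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, GridGeometry]:
    """Read an ESRI ASCII grid -> (values with nan at invalid, valid_mask, geometry)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise IOError(f"{path}: missing ASCII-grid header field {req}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise IOError(f"{path}: body shape {data.shape} != header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    geometry = GridGeometry(
        n_rows, n_cols, header["xllcorner"], header["yllcorner"] + n_rows * cell, cell
    )
    nodata = header.get("nodata_value", NODATA)
    mask = data != nodata
    values = data.copy()
    values[~mask] = np.nan
    return values, mask, geometry


def read_env_stack(paths: Sequence[str | Path]) -> EnvStack:
    """Read aligned single-band rasters into an EnvStack (no silent resampling).

    Layer names are file stems.  The shared validity mask is the intersection
    of the per-layer masks.  A layer on a different grid raises
    :class:`AlignmentError` naming the offending file.
    """
    if not paths:
        raise ParameterError("read_env_stack needs at least one raster")
    layers, names = [], []
    geometry = None
    mask = None
    for p in paths:
        values, m, geo = read_grid(p)
        if geometry is None:
            geometry, mask = geo, m
        else:
            _require_same_geometry(geometry, geo, what=str(p))
            mask = mask & m
        layers.append(values)
        names.append(Path(p).stem)
    values = np.stack(layers)
    values[:, ~mask] = np.nan
    return EnvStack(names, values, geometry, mask)


def write_env_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write one .asc per layer into a directory; returns the paths in layer order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return [
        write_grid(directory / f"{name}.asc", stack.values[i], stack.geometry, stack.valid_mask)
        for i, name in enumerate(stack.layer_names)
    ]


def write_landcover(lc: LandCover, path: str | Path, legend_path: str | Path | None = None) -> Path:
    p = write_grid(path, lc.class_grid.astype(float), lc.geometry, lc.valid_mask, fmt="%d")
    if legend_path is not None:
        import json

        Path(legend_path).write_text(
            json.dumps({str(k): v for k, v in sorted(lc.legend.items())}, indent=1)
        )
    return p


def write_binary_model(model: BinaryModel, path: str | Path) -> Path:
    """Write a PDM/ADM as 0/1 ASCII grid plus a .meta.json sidecar."""
    import json

    p = write_grid(path, model.grid.astype(float), model.geometry, model.valid_mask, fmt="%d")
    meta = {
        "species": model.species,
        "kind": model.kind,
        "threshold_used": model.threshold_used,
        "threshold_rule": model.threshold_rule,
        "metadata": model.metadata,
    }
    Path(str(p) + ".meta.json").write_text(json.dumps(meta, indent=1))
    return p


def read_binary_model(path: str | Path) -> BinaryModel:
    import json

    values, mask, geometry = read_grid(path)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    grid = np.zeros(values.shape, dtype=np.uint8)
    grid[mask] = values[mask].astype(np.uint8)
    return BinaryModel(
        meta.get("species", Path(path).stem),
        meta.get("kind", "PDM"),
        grid,
        geometry,
        mask,
        meta.get("threshold_used", 0.0),
        meta.get("threshold_rule", "external"),
        meta.get("metadata", {}),
    )


def read_landcover(path: str | Path, legend: Mapping[int, str] | str | Path) -> LandCover:
    values, mask, geometry = read_grid(path)
    if not isinstance(legend, Mapping):
        import json

        legend = {int(k): v for k, v in json.loads(Path(legend).read_text()).items()}
    grid = np.zeros(values.shape, dtype=int)
    grid[mask] = values[mask].astype(int)
    return LandCover(grid, dict(legend), geometry, mask)
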