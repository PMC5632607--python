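"""Species occurrence points: CSV I/O, cell mapping, de-duplication, splits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .grids import GridGeometry

MUSEUM = "museum"
FIELD = "field"


@dataclass
class OccurrenceSet:
    """Presence points for one species from one source (museum or field)."""

    species: str
    points: np.ndarray  # (N, 2) map coordinates (x, y)
    source: str
    site_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.source not in (MUSEUM, FIELD):
            raise ParameterError(f"source must be museum or field, got {self.source!r}")
        if self.site_ids is not None:
            self.site_ids = np.asarray(self.site_ids)
            if len(self.site_ids) != len(self.points):
                raise ParameterError("one site id per point required")

    def __len__(self) -> int:
        return len(self.points)

    def cells(self, geometry: GridGeometry) -> np.ndarray:
        """(N, 2) row/col of each point (duplicates kept)."""
        return geometry.cells_of(self.points)

    def distinct_cells(self, geometry: GridGeometry) -> np.ndarray:
        """Unique (row, col) cells containing at least one point."""
        if len(self) == 0:
            return np.empty((0, 2), dtype=int)
        return np.unique(self.cells(geometry), axis=0)

    def subset(self, idx: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(
            self.species,
            self.points[idx],
            self.source,
            None if self.site_ids is None else self.site_ids[idx],
        )


def read_occurrences(path: str | Path, species: str, source: str) -> OccurrenceSet:
    """Load one species/source slice of a points CSV (columns species,x,y,source)."""
    df = pd.read_csv(path)
    missing = {"species", "x", "y", "source"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    sel = df[(df["species"] == species) & (df["source"] == source)]
    if len(sel) == 0:
        warnings.warn(f"no {source} occurrences for {species!r} in {path}", stacklevel=2)
    site_ids = sel["site_id"].to_numpy() if "site_id" in df.columns else None
    return OccurrenceSet(species, sel[["x", "y"]].to_numpy(dtype=float), source, site_ids)


def write_occurrences(sets: list[OccurrenceSet], path: str | Path) -> Path:
    frames = []
    for occ in sets:
        frame = pd.DataFrame(
            {"species": occ.species, "x": occ.points[:, 0], "y": occ.points[:, 1],
             "source": occ.source}
        )
        if occ.site_ids is not None:
            frame["site_id"] = occ.site_ids
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["species", "x", "y", "source"]
    )
    out.to_csv(path, index=False)
    return Path(path)


def train_test_split(
    occ: OccurrenceSet, test_fraction: float = 0.25, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded 75/25-style shuffle split of presence records."""
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(occ))
    n_test = max(1, int(round(test_fraction * len(occ))))
    if n_test >= len(occ):
        raise ParameterError("too few records to split")
    return occ.subset(order[n_test:]), occ.subset(order[:n_test])
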