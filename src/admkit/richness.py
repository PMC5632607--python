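"""Stacked-model species richness and its cross-tabulation with ecoregions."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

from .errors import AlignmentError, ParameterError
from .grids import BinaryModel, GridGeometry


@dataclass
class RichnessModel:
    """Cellwise count of co-occurring species over stacked binary models."""

    grid: np.ndarray  # int richness, 0 on invalid cells
    n_species: int
    geometry: GridGeometry
    valid_mask: np.ndarray
    class_breaks: list[tuple[int, int]]

    def richness_class(self) -> np.ndarray:
        """Class index (1-based) per cell; 0 for richness 0 or invalid."""
        out = np.zeros(self.grid.shape, dtype=int)
        for i, (lo, hi) in enumerate(self.class_breaks, start=1):
            out[(self.grid >= lo) & (self.grid <= hi) & self.valid_mask] = i
        return out


def default_class_breaks(n_species: int) -> list[tuple[int, int]]:
    """Low/medium/high richness intervals partitioning [1, n_species]."""
    if n_species <= 3:
        return [(1, n_species)]
    third = max(1, n_species // 3)
    return [(1, third), (third + 1, 2 * third + 1), (2 * third + 2, n_species)]


def stack_richness(
    adms: list[BinaryModel], class_breaks: list[tuple[int, int]] | None = None
) -> RichnessModel:
    """Cellwise sum of presence indicators across aligned binary models."""
    if not adms:
        raise ParameterError("need at least one binary model")
    geo = adms[0].geometry
    for adm in adms[1:]:
        if adm.geometry != geo:
            raise AlignmentError(f"model for {adm.species!r} is on a different grid")
    mask = np.logical_and.reduce([a.valid_mask for a in adms])
    grid = np.sum([a.presence for a in adms], axis=0).astype(int)
    grid[~mask] = 0
    n = len(adms)
    if class_breaks is None:
        class_breaks = default_class_breaks(n)
    lo = min(b[0] for b in class_breaks)
    hi = max(b[1] for b in class_breaks)
    covered = sorted(r for b in class_breaks for r in range(b[0], b[1] + 1))
    if lo != 1 or hi != n or covered != list(range(1, n + 1)):
        raise ParameterError(f"class breaks {class_breaks} do not partition [1, {n}]")
    return RichnessModel(grid, n, geo, mask, class_breaks)


def read_ecoregions(path: str | Path) -> list[tuple[str, "shapely.Geometry"]]:
    """(name, polygon) pairs from a GeoJSON FeatureCollection, in file order."""
    gj = json.loads(Path(path).read_text())
    regions = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = shape(feat["geometry"])
        name = feat.get("properties", {}).get("name", f"region_{i}")
        regions.append((name, geom))
    return regions


def richness_by_region(
    rm: RichnessModel, regions: list[tuple[str, "shapely.Geometry"]]
) -> pd.DataFrame:
    """Percent of each richness class's cells inside each region.

    Cells are assigned by center inclusion to the first containing region in
    file order; the remainder is reported as ``outside``.  Per class the
    percentages sum to 100; a class with no cells is reported as zeros and
    flagged empty.
    """
    cx, cy = rm.geometry.cell_centers()
    assignment = np.full(rm.grid.shape, -1, dtype=int)
    for i, (name, geom) in enumerate(regions):
        if geom.is_empty or not geom.is_valid or geom.area == 0:
            warnings.warn(f"degenerate polygon {name!r} skipped", stacklevel=2)
            continue
        inside = shapely.intersects_xy(geom, cx.ravel(), cy.ravel()).reshape(cx.shape)
        assignment[(assignment == -1) & inside] = i
    classes = rm.richness_class()
    rows = []
    for ci, (lo, hi) in enumerate(rm.class_breaks, start=1):
        members = (classes == ci) & rm.valid_mask
        total = int(members.sum())
        row: dict = {"richness_class": f"{lo}-{hi}", "n_cells": total, "empty": total == 0}
        for i, (name, _) in enumerate(regions):
            n = int((members & (assignment == i)).sum())
            row[name] = 100.0 * n / total if total else 0.0
        n_out = int((members & (assignment == -1)).sum())
        row["outside"] = 100.0 * n_out / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
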