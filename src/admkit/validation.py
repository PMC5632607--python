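"""Field validation of actual distribution models (ADMs).

Two procedures mirror standard ground-truthing practice for gridded
distribution models: *site* validation rasterizes the field presences to
distinct model cells and counts how many the ADM predicts present, and
*buffer* validation builds fixed-radius disks around the field points
(overlapping disks merged), collects the valid cells whose centers fall in
the union, and counts predicted-presence cells among them.  A Pearson
correlation between per-species museum and field record counts checks that
field effort sampled species roughly in their historical proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import MultiPoint

from .errors import ParameterError
from .grids import BinaryModel
from .occurrences import OccurrenceSet


@dataclass
class ValidationReport:
    """Per-species validation rows plus mean/sd summaries."""

    rows: pd.DataFrame  # one row per species
    summary: dict[str, float]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def site_success(adm: BinaryModel, field: OccurrenceSet) -> dict[str, float]:
    """Cell-level validation: distinct field-presence cells vs ADM presence."""
    if len(field) == 0:
        warnings.warn(f"no field points for {field.species!r}", stacklevel=2)
        return {
            "species": field.species, "total_presence_cells": 0,
            "true_presences": 0, "false_absences": 0, "site_success_pct": np.nan,
        }
    cells = field.distinct_cells(adm.geometry)
    pres = adm.presence[cells[:, 0], cells[:, 1]]
    total, true = len(cells), int(pres.sum())
    return {
        "species": field.species,
        "total_presence_cells": total,
        "true_presences": true,
        "false_absences": total - true,
        "site_success_pct": 100.0 * true / total,
    }


def buffer_success(adm: BinaryModel, field: OccurrenceSet, radius: float) -> dict[str, float]:
    """Area validation: ADM presence within merged disks around field points.

    Buffer membership is by cell-center inclusion (boundary counts), so the
    cell containing each point always belongs to its own buffer whenever
    ``radius >= cell_size / sqrt(2)``.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if len(field) == 0:
        warnings.warn(f"no field points for {field.species!r}", stacklevel=2)
        return {
            "species": field.species, "total_buffer_cells": 0,
            "true_buffer_cells": 0, "false_buffer_cells": 0, "buffer_success_pct": np.nan,
        }
    union = MultiPoint(field.points).buffer(radius)
    cx, cy = adm.geometry.cell_centers()
    inside = shapely.intersects_xy(union, cx.ravel(), cy.ravel()).reshape(cx.shape)
    members = inside & adm.valid_mask
    total = int(members.sum())
    if total == 0:
        warnings.warn(f"buffers cover no valid cell for {field.species!r}", stacklevel=2)
        return {
            "species": field.species, "total_buffer_cells": 0,
            "true_buffer_cells": 0, "false_buffer_cells": 0, "buffer_success_pct": np.nan,
        }
    true = int((members & adm.presence).sum())
    return {
        "species": field.species,
        "total_buffer_cells": total,
        "true_buffer_cells": true,
        "false_buffer_cells": total - true,
        "buffer_success_pct": 100.0 * true / total,
    }


def proportionality_test(
    museum_counts: np.ndarray, field_counts: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between museum and field record counts."""
    m = np.asarray(museum_counts, dtype=float)
    f = np.asarray(field_counts, dtype=float)
    if len(m) != len(f):
        raise ParameterError("count vectors must have equal length")
    if len(m) < 3:
        raise ParameterError("need at least 3 species")
    if m.std() == 0 or f.std() == 0:
        warnings.warn("zero variance in a count vector: correlation undefined", stacklevel=2)
        return np.nan, np.nan
    r, p = stats.pearsonr(m, f)
    return float(r), float(p)


def batch_validate(
    adms: list[BinaryModel],
    field_sets: list[OccurrenceSet],
    radius: float,
) -> ValidationReport:
    """Site and buffer validation for every species, with mean/population-sd summary.

    Summaries are computed over species with at least one field presence
    cell, using the population (n) denominator for the standard deviation.
    """
    if not adms:
        raise ParameterError("need at least one species")
    rows = []
    for adm, field in zip(adms, field_sets):
        row = site_success(adm, field)
        row.update({k: v for k, v in buffer_success(adm, field, radius).items()
                    if k != "species"})
        rows.append(row)
    df = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for col in ("site_success_pct", "buffer_success_pct"):
        vals = df[col].dropna().to_numpy()
        summary[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
        summary[f"{col}_sd"] = float(vals.std(ddof=0)) if len(vals) else np.nan
    return ValidationReport(df, summary)
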