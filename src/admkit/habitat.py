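"""Reduce potential distributions (PDM) to actual distributions (ADM).

A PDM presence cell survives the habitat mask when the fraction of its
finer-resolution land-cover subcells falling in the species' suitable
classes reaches ``suitable_fraction`` (default: majority).  The ADM presence
set is by construction a subset of the PDM presence set.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .grids import BinaryModel, HabitatTable, LandCover


def reduce_to_adm(
    pdm: BinaryModel,
    lc: LandCover,
    habitat: HabitatTable,
    species: str | None = None,
    suitable_fraction: float = 0.5,
) -> BinaryModel:
    """Mask a PDM against suitable land cover at subcell resolution."""
    if not 0 < suitable_fraction <= 1:
        raise ParameterError("suitable_fraction must be in (0, 1]")
    species = species or pdm.species
    classes = habitat.classes_for(species)  # KeyError if absent
    habitat.validate_against(lc.legend)
    ratio = lc.subcell_ratio(pdm.geometry)
    R, C = pdm.geometry.n_rows, pdm.geometry.n_cols
    suitable = np.isin(lc.class_grid, sorted(classes)) & lc.valid_mask
    frac = (
        suitable.reshape(R, ratio, C, ratio).sum(axis=(1, 3)) / (ratio * ratio)
    )
    grid = np.zeros((R, C), dtype=np.uint8)
    grid[pdm.presence & (frac >= suitable_fraction)] = 1
    adm = BinaryModel(
        species, "ADM", grid, pdm.geometry, pdm.valid_mask.copy(),
        pdm.threshold_used, pdm.threshold_rule,
        metadata={
            **pdm.metadata,
            "suitable_fraction": suitable_fraction,
            "habitat_classes": sorted(classes),
        },
    )
    assert not np.any(adm.presence & ~pdm.presence), "ADM must be a subset of its PDM"
    return adm


def area_summary(model: BinaryModel) -> dict[str, float]:
    """Presence cell count and fraction of the valid area."""
    n_presence = int(model.presence.sum())
    n_valid = int(model.valid_mask.sum())
    return {
        "presence_cells": n_presence,
        "valid_cells": n_valid,
        "presence_fraction": n_presence / n_valid if n_valid else 0.0,
    }
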