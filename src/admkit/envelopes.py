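"""Auxiliary suitability engines and the external-raster adapter.

Two simple deterministic engines support multi-engine workflows (cross-engine
pseudoabsence sampling, engine comparison) alongside ENFA: a per-layer
percentile envelope and a rank-normalized Mahalanobis distance.  Rasters
produced by external modeling software enter the pipeline through
:func:`ingest_external`, either on the continuous 0-100 scale or as ordinal
1-10 scores.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .errors import AlignmentError, FitError, NotFittedError, ScaleError
from .grids import (
    CONTINUOUS,
    ORDINAL,
    EnvStack,
    GridGeometry,
    SuitabilityModel,
    read_grid,
)
from .occurrences import OccurrenceSet


def _presence_matrix(stack: EnvStack, occ: OccurrenceSet, min_cells: int) -> np.ndarray:
    cells = occ.distinct_cells(stack.geometry)
    cells = cells[stack.valid_mask[cells[:, 0], cells[:, 1]]]
    if len(cells) < min_cells:
        raise FitError(f"need >= {min_cells} distinct presence cells, got {len(cells)}")
    return stack.values[:, cells[:, 0], cells[:, 1]].T  # (n_presence, V)


class PercentileEnvelope(BaseEstimator):
    """Per-layer percentile envelope (Bioclim-style).

    The score of a cell on layer ``i`` is ``2 * min(F_i, 1 - F_i)`` with
    ``F_i`` the mid-rank empirical CDF of the presence sample, so presence
    medians score 1 and cells outside the presence range score 0; the cell
    score is 100 times the minimum over layers.
    """

    def __init__(self, min_presences: int = 5):
        self.min_presences = min_presences

    def fit(self, stack: EnvStack, occ: OccurrenceSet) -> "PercentileEnvelope":
        self.presence_values_ = _presence_matrix(stack, occ, self.min_presences)
        self.layer_names_ = list(stack.layer_names)
        self.species_ = occ.species
        return self

    def predict(self, stack: EnvStack) -> SuitabilityModel:
        if not hasattr(self, "presence_values_"):
            raise NotFittedError("PercentileEnvelope is not fitted")
        if list(stack.layer_names) != self.layer_names_:
            raise AlignmentError("stack layers differ from the fitted layer set")
        X = stack.valid_values()
        n = self.presence_values_.shape[0]
        score = np.ones(len(X))
        for i in range(X.shape[1]):
            p = np.sort(self.presence_values_[:, i])
            below = np.searchsorted(p, X[:, i], side="left")
            at = np.searchsorted(p, X[:, i], side="right") - below
            F = (below + 0.5 * at) / n  # mid-rank empirical CDF
            score = np.minimum(score, 2.0 * np.minimum(F, 1.0 - F))
        grid = np.zeros((stack.n_rows, stack.n_cols))
        grid[stack.valid_mask] = 100.0 * score
        return SuitabilityModel(
            self.species_, "envelope", grid, CONTINUOUS, stack.geometry, stack.valid_mask.copy()
        )


class MahalanobisSuitability(BaseEstimator):
    """Rank-normalized Mahalanobis distance to the presence centroid.

    Scores are ``100 * (1 - rank(d^2) / n_valid_cells)`` with average ranks
    for ties — a monotone, distribution-free transform of the squared
    distance under the (ridge-regularized) presence covariance.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, stack: EnvStack, occ: OccurrenceSet) -> "MahalanobisSuitability":
        P = _presence_matrix(stack, occ, stack.n_layers + 2)
        self.centroid_ = P.mean(axis=0)
        S = np.cov(P, rowvar=False)
        eig = np.linalg.eigvalsh(S)
        if eig.min() < 1e-10 * max(eig.max(), 1.0):
            warnings.warn("near-singular presence covariance; adding ridge", stacklevel=2)
            S = S + self.ridge * np.eye(S.shape[0])
        self.precision_ = np.linalg.inv(S)
        self.layer_names_ = list(stack.layer_names)
        self.species_ = occ.species
        return self

    def squared_distances(self, stack: EnvStack) -> np.ndarray:
        """d^2 to the presence centroid for each valid cell (row-major order)."""
        if not hasattr(self, "precision_"):
            raise NotFittedError("MahalanobisSuitability is not fitted")
        if list(stack.layer_names) != self.layer_names_:
            raise AlignmentError("stack layers differ from the fitted layer set")
        D = stack.valid_values() - self.centroid_
        return np.einsum("ij,jk,ik->i", D, self.precision_, D)

    def predict(self, stack: EnvStack) -> SuitabilityModel:
        from scipy.stats import rankdata

        d2 = self.squared_distances(stack)
        score = 100.0 * (1.0 - rankdata(d2, method="average") / len(d2))
        grid = np.zeros((stack.n_rows, stack.n_cols))
        grid[stack.valid_mask] = score
        return SuitabilityModel(
            self.species_, "mahalanobis", grid, CONTINUOUS, stack.geometry,
            stack.valid_mask.copy(),
        )


def envelope_predict(stack: EnvStack, occ: OccurrenceSet, **params) -> SuitabilityModel:
    return PercentileEnvelope(**params).fit(stack, occ).predict(stack)


def mahalanobis_predict(stack: EnvStack, occ: OccurrenceSet, **params) -> SuitabilityModel:
    return MahalanobisSuitability(**params).fit(stack, occ).predict(stack)


def ingest_external(
    path: str | Path,
    scale: str,
    species: str = "external_sp",
    expected_geometry: GridGeometry | None = None,
) -> SuitabilityModel:
    """Adapter for suitability rasters produced outside the package.

    Continuous rasters are clipped to [0, 100]; ordinal rasters must already
    be integers in 1..10.  A geometry mismatch against the expected model
    grid is an alignment error, never a silent resample.
    """
    values, mask, geometry = read_grid(path)
    if expected_geometry is not None and geometry != expected_geometry:
        raise AlignmentError(f"{path}: grid {geometry} does not match {expected_geometry}")
    grid = np.where(mask, values, 0.0)
    if scale == CONTINUOUS:
        grid = np.clip(grid, 0.0, 100.0)
    elif scale == ORDINAL:
        v = grid[mask]
        if v.size and (not np.allclose(v, np.round(v)) or v.min() < 1 or v.max() > 10):
            raise ScaleError(f"{path}: ordinal raster must hold integers in 1..10")
    else:
        raise ScaleError(f"unknown scale tag {scale!r}")
    return SuitabilityModel(species, "external", grid, scale, geometry, mask)
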