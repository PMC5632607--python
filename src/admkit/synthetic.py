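"""Synthetic landscapes, virtual species, and simulated surveys.

The generators emulate the statistical structure the analysis assumes:
spatially autocorrelated, mutually correlated climate-like layers; a virtual
species with a planted Gaussian niche in standardized environmental space
(known marginality = offset of the niche optimum from the regional mean,
known tolerance = niche width); museum-style presence-only sampling
concentrated in good habitat, optionally clustered around collection
hotspots; a patchy categorical land cover at a finer grid; and a stratified
point-count field survey restricted to the species' habitat class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    DegenerateNicheError,
    ParameterError,
    SamplingError,
    StratificationError,
)
from .grids import EnvStack, GridGeometry, LandCover
from .occurrences import FIELD, MUSEUM, OccurrenceSet

#: land-cover class names used by :func:`gen_landcover`, in code order;
#: class 1 plays the role of the focal natural habitat.
LANDCOVER_NAMES = (
    "dry_forest",
    "moist_forest",
    "agriculture",
    "grassland",
    "scrub",
    "urban",
    "wetland",
    "bare",
)


@dataclass
class VirtualSpecies:
    """A planted Gaussian niche with known marginality and tolerance."""

    species: str
    niche_center: np.ndarray  # per layer, standardized units
    niche_width: np.ndarray  # per layer, > 0
    truth_suitability: np.ndarray  # (rows, cols) in [0, 1]; 0 on invalid cells
    suitable_classes: frozenset[int]
    geometry: GridGeometry
    valid_mask: np.ndarray


def gen_env_stack(
    seed: int,
    n_layers: int = 6,
    n_rows: int = 100,
    n_cols: int = 100,
    autocorr_range: float = 8.0,
    n_latent: int = 3,
    idiosyncratic: float = 0.35,
    cell_size: float = 1000.0,
    valid_mask: np.ndarray | None = None,
) -> EnvStack:
    """Correlated, spatially smooth standardized environmental layers.

    Each layer is a seeded random mixture of ``n_latent`` shared latent
    fields plus an ``idiosyncratic`` own field (all smoothed white noise,
    Gaussian kernel of sd ``autocorr_range`` cells), then standardized to
    global mean 0 / sd 1 over valid cells.  The latent-factor mixing mimics
    the strong collinearity of bioclimatic variable sets, whose effective
    dimensionality is far below the layer count.
    """
    if n_layers < 2:
        raise ParameterError("need at least 2 layers")
    if n_rows <= 0 or n_cols <= 0:
        raise ParameterError("grid dimensions must be positive")
    if autocorr_range < 0:
        raise ParameterError("autocorr_range must be >= 0")
    if not 1 <= n_latent <= n_layers:
        raise ParameterError("n_latent must be in [1, n_layers]")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n_latent, n_rows, n_cols))
    own = rng.standard_normal((n_layers, n_rows, n_cols))
    if autocorr_range > 0:
        for f in (*latent, *own):
            f[:] = gaussian_filter(f, sigma=autocorr_range, mode="reflect")
    loadings = rng.standard_normal((n_layers, n_latent))
    fields = np.tensordot(loadings, latent, axes=1) + idiosyncratic * own
    geometry = GridGeometry(n_rows, n_cols, 0.0, n_rows * cell_size, cell_size)
    if valid_mask is None:
        valid_mask = np.ones((n_rows, n_cols), dtype=bool)
    names = [f"bc{i + 1}" for i in range(n_layers)]
    stack = EnvStack(names, fields, geometry, np.asarray(valid_mask, dtype=bool))
    return stack.standardized()


def gen_virtual_species(
    stack: EnvStack,
    seed: int,
    marginality_target: float = 1.0,
    tolerance_target: float = 0.5,
    suitable_classes: frozenset[int] = frozenset({1}),
    species: str = "virtual_sp",
    min_core_cells: int = 50,
) -> VirtualSpecies:
    """Plant a Gaussian niche with known marginality and tolerance.

    The niche optimum is placed at Euclidean norm ``1.96 * marginality_target``
    in standardized space, so the ENFA global-marginality estimator targets
    ``marginality_target``.  Its direction is taken from the standardized
    environment of a randomly drawn valid cell whose norm is close to the
    target norm, which keeps the optimum inside the realized environment
    (a uniformly random direction in >= 6 dimensions usually points where no
    cells exist).  Per-layer widths start at ``tolerance_target`` and are
    calibrated so the suitability-weighted sd of each layer is ~ the target.
    """
    if marginality_target < 0:
        raise ParameterError("marginality_target must be >= 0")
    if tolerance_target <= 0:
        raise ParameterError("tolerance_target must be > 0")
    rng = np.random.default_rng(seed)
    Z = stack.valid_values()  # (n_valid, V)
    V = Z.shape[1]
    target_norm = 1.96 * marginality_target

    def calibrate(center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        width = np.full(V, float(tolerance_target))
        for _ in range(8):
            suit = np.exp(-0.5 * (((Z - center) / width) ** 2).sum(axis=1))
            total = suit.sum()
            if total <= 0 or not np.isfinite(total):
                raise DegenerateNicheError("planted niche has no usable suitability mass")
            wmean = (suit[:, None] * Z).sum(axis=0) / total
            wsd = np.sqrt((suit[:, None] * (Z - wmean) ** 2).sum(axis=0) / total)
            if np.any(wsd <= 0):
                raise DegenerateNicheError("degenerate suitability-weighted spread")
            width = np.clip(width * tolerance_target / wsd,
                            0.25 * tolerance_target, 8.0 * tolerance_target)
        suit = np.exp(-0.5 * (((Z - center) / width) ** 2).sum(axis=1))
        return width, suit

    if target_norm == 0:
        anchors = [np.zeros(V)]
    else:
        norms = np.linalg.norm(Z, axis=1)
        # anchor among the cells whose conditions are closest in norm to the
        # target; degenerate anchors (too few core cells) are redrawn
        n_cand = min(100, len(norms))
        candidates = np.argsort(np.abs(norms - target_norm))[:n_cand]
        draws = rng.choice(candidates, size=min(25, n_cand), replace=False)
        anchors = [Z[i] / np.linalg.norm(Z[i]) * target_norm for i in draws]

    center = width = suit = None
    best_core = -1
    for cand in anchors:
        w, s = calibrate(cand)
        core = int((s > 0.5).sum())
        if core > best_core:
            center, width, suit, best_core = cand, w, s, core
        if core >= min_core_cells:
            break
    if best_core < min_core_cells:
        raise DegenerateNicheError(
            f"only {best_core} cells with suitability > 0.5 "
            f"(need >= {min_core_cells}); relax marginality/tolerance targets"
        )
    truth = np.zeros((stack.n_rows, stack.n_cols))
    truth[stack.valid_mask] = suit
    return VirtualSpecies(
        species, center, width, truth, frozenset(suitable_classes),
        stack.geometry, stack.valid_mask.copy(),
    )


def sample_occurrences(
    vs: VirtualSpecies,
    n: int,
    seed: int,
    clustering: float = 0.0,
    gamma: float = 2.0,
    replace: bool = True,
    source: str = MUSEUM,
) -> OccurrenceSet:
    """Museum-style presence sample: cells ~ truth^gamma, points uniform in cell.

    ``clustering`` > 0 multiplies the sampling weights by a smooth hotspot
    field (a few seeded Gaussian bumps centered on good habitat), mimicking
    collection effort concentrated around accessible localities.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if gamma < 1:
        raise ParameterError("gamma must be >= 1")
    rng = np.random.default_rng(seed)
    geo = vs.geometry
    weights = np.where(vs.valid_mask, vs.truth_suitability, 0.0) ** gamma
    weights[~vs.valid_mask] = 0.0
    if clustering > 0:
        flat = weights.ravel()
        if flat.sum() <= 0:
            raise SamplingError("no cell with positive suitability")
        hot = rng.choice(flat.size, size=5, p=flat / flat.sum())
        bump = np.zeros_like(weights)
        bump[np.unravel_index(hot, weights.shape)] = 1.0
        bump = gaussian_filter(bump, sigma=5.0)
        if bump.max() > 0:
            weights = weights * (1.0 + clustering * bump / bump.max())
    flat = weights.ravel()
    total = flat.sum()
    if total <= 0:
        raise SamplingError("no cell with positive sampling weight")
    n_nonzero = int((flat > 0).sum())
    if not replace and n > n_nonzero:
        raise SamplingError(f"requested {n} cells without replacement, only {n_nonzero} eligible")
    drawn = rng.choice(flat.size, size=n, replace=replace, p=flat / total)
    rows, cols = np.unravel_index(drawn, weights.shape)
    u = rng.random((n, 2))
    x = geo.origin_x + (cols + u[:, 0]) * geo.cell_size
    y = geo.origin_y - (rows + u[:, 1]) * geo.cell_size
    return OccurrenceSet(vs.species, np.column_stack([x, y]), source)


def gen_landcover(
    stack: EnvStack,
    seed: int,
    n_classes: int = 4,
    patch_scale: float = 4.0,
    subcell_ratio: int = 4,
    class_shares: np.ndarray | None = None,
) -> LandCover:
    """Patchy categorical land cover on a ``subcell_ratio``-times finer grid.

    A smooth random field at the fine grid is cut at quantiles, producing
    contiguous patches; ``class_shares`` (default equal) sets the area
    quantiles.  Class codes are 1..n_classes; class 1 stands for the focal
    natural habitat (dry forest analog).
    """
    if n_classes < 2:
        raise ParameterError("need at least 2 classes")
    if subcell_ratio < 1:
        raise ParameterError("subcell_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    k = int(subcell_ratio)
    R, C = stack.n_rows * k, stack.n_cols * k
    field = rng.standard_normal((R, C))
    field = gaussian_filter(field, sigma=patch_scale * k, mode="reflect")
    fine_mask = np.repeat(np.repeat(stack.valid_mask, k, axis=0), k, axis=1)
    if class_shares is None:
        class_shares = np.full(n_classes, 1.0 / n_classes)
    class_shares = np.asarray(class_shares, dtype=float)
    if len(class_shares) != n_classes or np.any(class_shares <= 0):
        raise ParameterError("class_shares must be positive, one per class")
    qs = np.cumsum(class_shares / class_shares.sum())[:-1]
    cuts = np.quantile(field[fine_mask], qs)
    grid = np.zeros((R, C), dtype=int)
    grid[fine_mask] = 1 + np.searchsorted(cuts, field[fine_mask], side="right")
    legend = {
        code: LANDCOVER_NAMES[(code - 1) % len(LANDCOVER_NAMES)]
        for code in range(1, n_classes + 1)
    }
    geom = stack.geometry
    fine_geom = GridGeometry(R, C, geom.origin_x, geom.origin_y, geom.cell_size / k)
    return LandCover(grid, legend, fine_geom, fine_mask)


def simulate_field_survey(
    vs: VirtualSpecies,
    lc: LandCover,
    n_sites: int = 46,
    points_per_site: int = 30,
    min_point_spacing: float = 200.0,
    detection_prob: float = 0.8,
    seed: int = 0,
    min_truth: float = 0.05,
    truth_weight: float = 1.0,
) -> OccurrenceSet:
    """Stratified point-count survey restricted to the species' habitat class.

    Sites are model cells whose dominant land-cover class is suitable for the
    species and whose true suitability reaches ``min_truth``, drawn without
    replacement with probability proportional to ``truth ** truth_weight``
    (surveys of this kind are placed where the surveyors expect the species,
    not uniformly over the region; ``truth_weight=0`` gives uniform
    stratified placement).  Within each site (one
    model cell) up to ``points_per_site`` count points are packed at least
    ``min_point_spacing`` apart by seeded rejection sampling.  Each point
    yields a detection with probability ``detection_prob *
    truth_suitability`` of its cell; detections are emitted as field
    occurrences tagged with their site id.
    """
    if not 0 < detection_prob <= 1:
        raise ParameterError("detection_prob must be in (0, 1]")
    if n_sites < 1:
        raise ParameterError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    geo = vs.geometry
    dominant = lc.dominant_classes(geo)
    eligible = (
        vs.valid_mask
        & np.isin(dominant, sorted(vs.suitable_classes))
        & (vs.truth_suitability >= min_truth)
    )
    rows, cols = np.nonzero(eligible)
    if len(rows) < n_sites:
        raise StratificationError(
            f"only {len(rows)} habitat-eligible cells for {n_sites} sites"
        )
    w = vs.truth_suitability[rows, cols] ** truth_weight
    pick = rng.choice(len(rows), size=n_sites, replace=False, p=w / w.sum())
    s = geo.cell_size
    xs, ys, ids = [], [], []
    for site, (r, c) in enumerate(zip(rows[pick], cols[pick])):
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < points_per_site and tries < 50 * points_per_site:
            tries += 1
            px = geo.origin_x + (c + rng.random()) * s
            py = geo.origin_y - (r + rng.random()) * s
            if all(np.hypot(px - qx, py - qy) >= min_point_spacing for qx, qy in placed):
                placed.append((px, py))
        p_detect = detection_prob * vs.truth_suitability[r, c]
        for px, py in placed:
            if rng.random() < p_detect:
                xs.append(px)
                ys.append(py)
                ids.append(site)
    return OccurrenceSet(
        vs.species, np.column_stack([xs, ys]) if xs else np.empty((0, 2)), FIELD,
        np.asarray(ids, dtype=int),
    )
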