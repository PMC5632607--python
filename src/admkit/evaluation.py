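"""Model accuracy: pseudoabsences, confusion metrics, ROC/AUC, thresholds.

Presence-only models are evaluated against pseudoabsences drawn from the
area another engine predicts as absence (cross-engine sampling, so a model
is never tested against its own absences).  A finite scan of candidate
thresholds yields per-threshold confusion matrices; two rules pick the
binarization threshold — maximum Cohen's kappa, and the ROC point closest
to (sensitivity, specificity) = (1, 1) — and a Wilcoxon signed-rank test
compares the two threshold sets across species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SamplingError, SelectionError
from .grids import BinaryModel, ORDINAL, SuitabilityModel
from .occurrences import OccurrenceSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Presence/absence cross-tabulation with the derived accuracy measures."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def sensitivity(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else np.nan

    @property
    def specificity(self) -> float:
        d = self.TN + self.FP
        return self.TN / d if d else np.nan

    @property
    def omission(self) -> float:
        d = self.TP + self.FN
        return self.FN / d if d else np.nan

    @property
    def commission(self) -> float:
        d = self.FP + self.TN
        return self.FP / d if d else np.nan

    @property
    def overall(self) -> float:
        return (self.TP + self.TN) / self.N if self.N else np.nan

    @property
    def kappa(self) -> float:
        """Cohen's kappa: chance-corrected agreement."""
        n = self.N
        if n == 0:
            return np.nan
        po = (self.TP + self.TN) / n
        pe = (
            (self.TP + self.FP) * (self.TP + self.FN)
            + (self.FN + self.TN) * (self.FP + self.TN)
        ) / n**2
        if pe == 1.0:
            return np.nan
        return (po - pe) / (1.0 - pe)


@dataclass
class ThresholdReport:
    """Threshold scan for one species x engine, with the two selected cutoffs."""

    species: str
    engine: str
    thresholds: list[float]
    matrices: list[ConfusionMatrix]
    auc: float
    kappa_threshold: float | None = None
    roc_threshold: float | None = None
    notes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, cm in zip(self.thresholds, self.matrices):
            rows.append(
                {
                    "species": self.species,
                    "engine": self.engine,
                    "threshold": t,
                    "TP": cm.TP,
                    "FP": cm.FP,
                    "FN": cm.FN,
                    "TN": cm.TN,
                    "kappa": cm.kappa,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                }
            )
        return pd.DataFrame(rows)


def sample_pseudoabsences(
    absence_model: BinaryModel,
    n: int,
    seed: int,
    exclusion: OccurrenceSet | None = None,
    engine_under_test: str | None = None,
) -> OccurrenceSet:
    """Uniform pseudoabsence points from another engine's predicted absence.

    ``n`` distinct absence cells are drawn without replacement (cells holding
    any exclusion point are ineligible) and one point is placed at each drawn
    cell's center.  Testing an engine against its own absences defeats the
    cross-engine design, so that combination only warns if the caller tags it.
    """
    if engine_under_test is not None and engine_under_test == absence_model.metadata.get("engine"):
        warnings.warn(
            "pseudoabsences drawn from the engine under test; cross-engine sampling intended",
            stacklevel=2,
        )
    eligible = absence_model.absence.copy()
    if exclusion is not None and len(exclusion):
        cells = exclusion.cells(absence_model.geometry)
        eligible[cells[:, 0], cells[:, 1]] = False
    rows, cols = np.nonzero(eligible)
    if len(rows) < n:
        raise SamplingError(f"need {n} eligible absence cells, only {len(rows)} available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    geo = absence_model.geometry
    x = geo.origin_x + (cols[pick] + 0.5) * geo.cell_size
    y = geo.origin_y - (rows[pick] + 0.5) * geo.cell_size
    return OccurrenceSet(absence_model.species, np.column_stack([x, y]), "museum")


def _scores_at_points(model: SuitabilityModel, occ: OccurrenceSet) -> np.ndarray:
    cells = occ.cells(model.geometry)
    valid = model.valid_mask[cells[:, 0], cells[:, 1]]
    dropped = int((~valid).sum())
    if dropped:
        log.warning("%d %s point(s) on invalid cells dropped", dropped, occ.species)
    cells = cells[valid]
    return model.grid[cells[:, 0], cells[:, 1]]


def evaluate_at_threshold(
    model: SuitabilityModel,
    t: float,
    presences: OccurrenceSet,
    pseudoabsences: OccurrenceSet,
) -> ConfusionMatrix:
    """Confusion matrix with predicted presence := score >= t."""
    ps = _scores_at_points(model, presences)
    ab = _scores_at_points(model, pseudoabsences)
    return ConfusionMatrix(
        TP=int((ps >= t).sum()),
        FN=int((ps < t).sum()),
        FP=int((ab >= t).sum()),
        TN=int((ab < t).sum()),
    )


def metric_curve(
    model: SuitabilityModel,
    presences: OccurrenceSet,
    pseudoabsences: OccurrenceSet,
    thresholds: list[float] | None = None,
) -> ThresholdReport:
    """Per-threshold metrics over a candidate scan plus trapezoid AUC.

    The ROC polygon includes the degenerate endpoints (0,0) and (1,1) so the
    AUC is defined even for short scans; with candidate thresholds at every
    distinct score it equals the Mann-Whitney estimate exactly.
    """
    if thresholds is None:
        thresholds = model.default_thresholds()
    if not thresholds:
        raise ParameterError("empty threshold list")
    thresholds = sorted(float(t) for t in thresholds)
    matrices = [evaluate_at_threshold(model, t, presences, pseudoabsences) for t in thresholds]
    fpr = np.array([1.0 - cm.specificity for cm in matrices])
    tpr = np.array([cm.sensitivity for cm in matrices])
    pts = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr]), [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ThresholdReport(model.species, model.engine, thresholds, matrices, auc)


def select_kappa_threshold(report: ThresholdReport) -> float:
    """Candidate threshold maximizing kappa; ties go to the lowest threshold."""
    best_t, best_k = None, -np.inf
    for t, cm in zip(report.thresholds, report.matrices):
        k = cm.kappa
        if np.isfinite(k) and k > best_k:
            best_t, best_k = t, k
    if best_t is None:
        raise SelectionError("kappa undefined at every candidate threshold")
    report.kappa_threshold = best_t
    return best_t


def select_roc_threshold(report: ThresholdReport) -> float:
    """Candidate closest to the perfect-classification ROC corner (0, 1).

    Minimizes sqrt((1-sens)^2 + (1-spec)^2); ties go to the lowest threshold.
    """
    best_t, best_d = None, np.inf
    for t, cm in zip(report.thresholds, report.matrices):
        s, p = cm.sensitivity, cm.specificity
        if not (np.isfinite(s) and np.isfinite(p)):
            continue
        d = np.hypot(1.0 - s, 1.0 - p)
        if d < best_d:
            best_t, best_d = t, d
    if best_t is None:
        raise SelectionError("sensitivity/specificity undefined at every threshold")
    report.roc_threshold = best_t
    return best_t


def select_youden_threshold(report: ThresholdReport) -> float:
    """Config alternative to the distance rule: maximize sens + spec - 1."""
    best_t, best_j = None, -np.inf
    for t, cm in zip(report.thresholds, report.matrices):
        j = cm.sensitivity + cm.specificity - 1.0
        if np.isfinite(j) and j > best_j:
            best_t, best_j = t, j
    if best_t is None:
        raise SelectionError("Youden's J undefined at every threshold")
    return best_t


def binarize(model: SuitabilityModel, t: float, rule_tag: str = "external") -> BinaryModel:
    """Presence/absence PDM: presence iff score >= t; invalid cells preserved."""
    lo, hi = (1.0, 10.0) if model.scale == ORDINAL else (0.0, 100.0)
    if not lo <= t <= hi + 1e-9:
        raise ParameterError(f"threshold {t} outside the {model.scale} scale")
    grid = np.zeros(model.grid.shape, dtype=np.uint8)
    grid[model.valid_mask & (model.grid >= t)] = 1
    return BinaryModel(
        model.species, "PDM", grid, model.geometry, model.valid_mask.copy(), t, rule_tag,
        metadata={"engine": model.engine},
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test (exact for n <= 20 via midrank convolution)
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; |differences| are ranked with midranks for
    ties; the statistic is ``W = min(W+, W-)``.  For n <= 20 the p-value is
    exact over all 2^n sign assignments (computed by convolving the doubled
    midranks, which is equivalent to full enumeration); larger samples use
    the normal approximation with tie correction.

    Returns (W, p).  If every difference is zero the test is degenerate and
    (0, 1) is returned.
    """
    d = np.array([a - b for a, b in pairs], dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all differences zero: degenerate Wilcoxon test", stacklevel=2)
        return 0.0, 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    total = w_plus + w_minus

    if n <= 20:
        # doubled midranks are integers: exact distribution of 2*W+ by convolution
        r2 = np.round(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: len(dist) - r]
            dist = dist + shifted
        dist /= dist.sum()
        w2 = int(round(2 * W))
        hi2 = int(round(2 * (total - W)))
        p = float(dist[: w2 + 1].sum() + dist[hi2:].sum())
        return W, min(p, 1.0)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    from scipy.stats import norm

    z = (W - mean + 0.5) / np.sqrt(var)  # continuity-corrected
    return W, float(min(1.0, 2.0 * norm.cdf(z)))
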