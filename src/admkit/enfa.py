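"""Ecological Niche Factor Analysis (ENFA) suitability engine.

ENFA contrasts the environmental space occupied by a species (presence
cells) against the global environmental space of the study region.  With
layers standardized to global mean 0 / sd 1:

* the *marginality vector* ``m`` is the mean standardized environment over
  presence cells; the global marginality index ``M = ||m|| / 1.96`` is ~1
  when the species mean sits about two global standard deviations from the
  regional mean;
* the first factor axis is ``m / ||m||``; the remaining *specialization*
  axes maximize the ratio of global to presence variance in the subspace
  orthogonal to the marginality axis (generalized symmetric eigenproblem on
  the global and presence covariances projected into that subspace), so a
  large eigenvalue means the species tolerates a narrow slice of the
  available conditions along that axis;
* the global tolerance index is ``T = 1 / sqrt(mean eigenvalue)``: T = 1
  when the presence sample is as spread as the region, small T for
  specialists.

Suitability scoring uses a median-count rule: along each retained factor, a
cell scores the fraction of presence cells at least as far from the
presence median as the cell itself; factor scores are combined with
eigenvalue weights and stretched to 0-100.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .errors import AlignmentError, FitError, NotFittedError
from .grids import CONTINUOUS, EnvStack, SuitabilityModel
from .occurrences import OccurrenceSet

MARGINALITY_NORM = 1.96  # ENFA convention: M ~ 1 means a ~2-sigma offset

#: absolute tolerance for "as extreme as" ties in the median-count rule, so
#: integer counts do not depend on BLAS evaluation order when a scored cell
#: is itself a presence cell
TIE_TOL = 1e-9


class EnfaSuitability(BaseEstimator):
    """ENFA marginality/specialization model with median-count suitability.

    Parameters
    ----------
    retain_fraction:
        Retained factors are the smallest set (always including the
        marginality axis) whose summed |eigenvalue| reaches this fraction of
        the total — a deterministic analog of broken-stick selection.
    ridge:
        Diagonal regularization added to a near-singular presence covariance
        (collinear climate layers make this common).
    """

    def __init__(self, retain_fraction: float = 0.8, ridge: float = 1e-6):
        self.retain_fraction = retain_fraction
        self.ridge = ridge

    # -- fitting ------------------------------------------------------------

    def fit(self, stack: EnvStack, occ: OccurrenceSet) -> "EnfaSuitability":
        V = stack.n_layers
        self.layer_names_ = list(stack.layer_names)
        self.geometry_ = stack.geometry
        self.species_ = occ.species

        # standardization frozen at fit time so re-scoring is reproducible
        G_raw = stack.valid_values()
        self.mean_ = G_raw.mean(axis=0)
        self.sd_ = G_raw.std(axis=0)
        if np.any(self.sd_ == 0):
            raise FitError("constant environmental layer")
        G = (G_raw - self.mean_) / self.sd_

        cells = occ.distinct_cells(stack.geometry)
        on_valid = stack.valid_mask[cells[:, 0], cells[:, 1]]
        cells = cells[on_valid]
        if len(cells) < V + 2:
            raise FitError(
                f"need >= {V + 2} distinct presence cells on valid ground, got {len(cells)}"
            )
        self.presence_cells_ = cells
        P = (stack.values[:, cells[:, 0], cells[:, 1]].T - self.mean_) / self.sd_

        m = P.mean(axis=0)
        self.marginality_vector_ = m
        self.global_marginality_ = float(np.linalg.norm(m) / MARGINALITY_NORM)

        Sg = np.cov(G, rowvar=False)
        Sp = np.cov(P, rowvar=False)
        Sp = self._regularize(Sp)

        if np.linalg.norm(m) > 1e-9:
            u1 = m / np.linalg.norm(m)
        else:  # species indistinguishable from global mean: fall back to presence PC1
            warnings.warn(
                "zero marginality vector; using first presence principal axis",
                stacklevel=2,
            )
            _, vecs = linalg.eigh(Sp)
            u1 = vecs[:, -1]

        B = linalg.null_space(u1[None, :])  # (V, V-1) orthonormal complement
        Gg = B.T @ Sg @ B
        Gp = self._regularize(B.T @ Sp @ B)
        lam, vecs = linalg.eigh(Gg, Gp)
        order = np.argsort(lam)[::-1]
        lam = np.clip(lam[order], 0.0, None)
        W = B @ vecs[:, order]
        W /= np.linalg.norm(W, axis=0, keepdims=True)

        lam1 = float((u1 @ Sg @ u1) / (u1 @ Sp @ u1))
        self.factors_ = np.column_stack([u1, W])  # (V, V), column 0 = marginality axis
        self.eigenvalues_ = np.concatenate([[lam1], lam])
        self.global_tolerance_ = float(1.0 / np.sqrt(self.eigenvalues_.sum() / V))

        self.retained_ = self._select_retained(self.eigenvalues_)
        scores = P @ self.factors_[:, self.retained_]  # (n_presence, k)
        self.presence_factor_scores_ = scores
        self.factor_medians_ = np.median(scores, axis=0)
        return self

    def _regularize(self, S: np.ndarray) -> np.ndarray:
        eig = np.linalg.eigvalsh(S)
        if eig.min() < 1e-10 * max(eig.max(), 1.0):
            warnings.warn(
                "near-singular presence covariance; adding ridge regularization",
                stacklevel=3,
            )
            S = S + self.ridge * np.eye(S.shape[0])
        return S

    def _select_retained(self, lam: np.ndarray) -> np.ndarray:
        """Smallest factor set (marginality axis first) reaching retain_fraction."""
        a = np.abs(lam)
        order = np.concatenate([[0], 1 + np.argsort(a[1:])[::-1]])
        cum = np.cumsum(a[order])
        total = cum[-1]
        if total == 0:
            return np.array([0])
        k = int(np.searchsorted(cum, self.retain_fraction * total) + 1)
        return order[: min(k, len(lam))]

    # -- scoring ------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "factors_"):
            raise NotFittedError("EnfaSuitability is not fitted")

    def _standardize(self, stack: EnvStack) -> np.ndarray:
        if list(stack.layer_names) != self.layer_names_:
            raise AlignmentError("stack layers differ from the fitted layer set")
        return (stack.valid_values() - self.mean_) / self.sd_

    def predict(self, stack: EnvStack) -> SuitabilityModel:
        """Habitat suitability 0-100 on the stack's valid cells.

        Along each retained factor ``k`` with presence scores ``s_p`` and
        presence median ``med_k``, a cell ``x`` gets

            HS_k(x) = #{p : |s_p - med_k| >= |score_k(x) - med_k|} / N

        and the combined score is the |eigenvalue|-weighted mean of the
        HS_k, times 100.
        """
        self._check_fitted()
        Z = self._standardize(stack)
        scores = Z @ self.factors_[:, self.retained_]
        n_p = self.presence_factor_scores_.shape[0]
        w = np.abs(self.eigenvalues_[self.retained_])
        if w.sum() == 0:
            w = np.ones_like(w)
        hs = np.zeros(len(Z))
        for j in range(len(self.retained_)):
            dev_p = np.sort(np.abs(self.presence_factor_scores_[:, j] - self.factor_medians_[j]))
            dev_x = np.abs(scores[:, j] - self.factor_medians_[j])
            counts = n_p - np.searchsorted(dev_p, dev_x - TIE_TOL, side="left")
            hs += w[j] * counts / n_p
        hs = 100.0 * hs / w.sum()
        grid = np.zeros((stack.n_rows, stack.n_cols))
        grid[stack.valid_mask] = hs
        return SuitabilityModel(
            self.species_, "enfa", grid, CONTINUOUS, stack.geometry, stack.valid_mask.copy()
        )

    # -- reporting ----------------------------------------------------------

    def variable_importance(self) -> pd.DataFrame:
        """Per-layer marginality and specialization scores with ranks.

        Marginality score = |m_i|.  Specialization score =
        sum over non-marginality factors of |eigenvalue| * |loading|.
        """
        self._check_fitted()
        marg = np.abs(self.marginality_vector_)
        spec = (np.abs(self.eigenvalues_[1:]) * np.abs(self.factors_[:, 1:])).sum(axis=1)
        df = pd.DataFrame(
            {
                "layer": self.layer_names_,
                "marginality_score": marg,
                "specialization_score": spec,
            }
        )
        df["marginality_rank"] = df["marginality_score"].rank(ascending=False, method="min").astype(int)
        df["specialization_rank"] = df["specialization_score"].rank(ascending=False, method="min").astype(int)
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model so rasters can be re-scored later."""
        self._check_fitted()
        payload = {
            "species": self.species_,
            "layer_names": self.layer_names_,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "marginality_vector": self.marginality_vector_.tolist(),
            "global_marginality": self.global_marginality_,
            "global_tolerance": self.global_tolerance_,
            "factors": self.factors_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "retained": self.retained_.tolist(),
            "presence_factor_scores": self.presence_factor_scores_.tolist(),
            "factor_medians": self.factor_medians_.tolist(),
            "params": {"retain_fraction": self.retain_fraction, "ridge": self.ridge},
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnfaSuitability":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.species_ = payload["species"]
        model.layer_names_ = payload["layer_names"]
        model.mean_ = np.asarray(payload["mean"])
        model.sd_ = np.asarray(payload["sd"])
        model.marginality_vector_ = np.asarray(payload["marginality_vector"])
        model.global_marginality_ = payload["global_marginality"]
        model.global_tolerance_ = payload["global_tolerance"]
        model.factors_ = np.asarray(payload["factors"])
        model.eigenvalues_ = np.asarray(payload["eigenvalues"])
        model.retained_ = np.asarray(payload["retained"], dtype=int)
        model.presence_factor_scores_ = np.asarray(payload["presence_factor_scores"])
        model.factor_medians_ = np.asarray(payload["factor_medians"])
        return model


# -- functional wrappers ----------------------------------------------------

def enfa_fit(stack: EnvStack, occ: OccurrenceSet, **params) -> EnfaSuitability:
    """Fit an ENFA model; thin wrapper over :class:`EnfaSuitability`."""
    return EnfaSuitability(**params).fit(stack, occ)


def enfa_suitability(model: EnfaSuitability, stack: EnvStack) -> SuitabilityModel:
    return model.predict(stack)


def variable_importance(model: EnfaSuitability) -> pd.DataFrame:
    return model.variable_importance()
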