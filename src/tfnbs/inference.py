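"""Threshold-free network-based statistics (TFNBS) with permutation inference.

The omnibus question — at which connections does streamline count differ
between groups? — is answered by (i) an edge-wise partial F for the group
factor adjusted for gender, (ii) TFCE-style enhancement of the F matrix over
the connectome graph, and (iii) an edge-wise permutation null: group labels
are shuffled, the F matrix and its enhancement are recomputed under the
same grid policy, and each edge's p-value is the exceedance rate of its own
null scores.  Benjamini-Hochberg FDR across the tested edges defines the
significant subnetwork.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .atlas import DEFAULT_EDGE_INDEX, EdgeIndex
from .cohort import CohortDataset, apply_detection_filter
from .enhance import enhance_edge_stats
from .glm import bh_fdr, f_statistics


class TFNBS(BaseEstimator):
    """Edge-wise TFNBS group test, shaped as a scikit-learn selector.

    Parameters
    ----------
    e_exponent, h_exponent
        Extension and height exponents of the enhancement integral.
    n_steps
        Equal threshold steps spanning (0, h_max].
    grid
        ``"adaptive"`` rescales the grid to each permutation's own maximum
        statistic (the default; keeps the integral comparable across
        permutations); ``"fixed"`` reuses the observed maximum throughout.
    n_permutations, random_state
        Monte-Carlo null size and its seed.
    fdr_q
        FDR level defining the significant edge set.

    Attributes (after :meth:`fit`)
    ------------------------------
    fstat_ : raw edge-wise F values (excluded edges forced to zero)
    scores_ : enhanced edge scores
    pvalues_ : edge-wise permutation p (NaN outside the tested mask)
    pvalues_fdr_ : BH-adjusted p (NaN outside the tested mask)
    significant_ : boolean mask of the significant subnetwork
    df_ : (df1, df2) of the F test
    """

    def __init__(
        self,
        e_exponent: float = 0.5,
        h_exponent: float = 3.0,
        n_steps: int = 100,
        n_permutations: int = 10000,
        fdr_q: float = 0.05,
        grid: str = "adaptive",
        random_state: int | None = None,
        edge_index: EdgeIndex | None = None,
    ):
        self.e_exponent = e_exponent
        self.h_exponent = h_exponent
        self.n_steps = n_steps
        self.n_permutations = n_permutations
        self.fdr_q = fdr_q
        self.grid = grid
        self.random_state = random_state
        self.edge_index = edge_index

    # -- internals -------------------------------------------------------

    def _edge_index(self) -> EdgeIndex:
        return self.edge_index if self.edge_index is not None else DEFAULT_EDGE_INDEX

    def _enhance(self, fstat: np.ndarray, h_max: float | None) -> np.ndarray:
        return enhance_edge_stats(
            fstat,
            e_exponent=self.e_exponent,
            h_exponent=self.h_exponent,
            n_steps=self.n_steps,
            h_max=h_max,
            edge_index=self._edge_index(),
        )

    # -- estimator API ---------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        covariates: np.ndarray | None = None,
        edge_mask: np.ndarray | None = None,
    ) -> "TFNBS":
        """Run the omnibus test.

        ``X`` is (n_subjects, n_edges) of NOS values in canonical edge
        order, ``y`` the group labels; ``covariates`` (e.g. gender) stay
        attached to subjects under permutation.  ``edge_mask`` excludes
        edges (detection filter); excluded edges get zero statistic and no
        p-value.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        index = self._edge_index()
        if X.ndim != 2 or X.shape[1] != len(index):
            raise ValueError(f"X must be (n_subjects, {len(index)})")
        if self.grid not in ("adaptive", "fixed"):
            raise ValueError("grid must be 'adaptive' or 'fixed'")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        mask = (
            np.ones(X.shape[1], dtype=bool)
            if edge_mask is None
            else np.asarray(edge_mask, dtype=bool)
        )
        if not mask.any():
            raise ValueError("edge mask excludes every edge")

        fstat, df1, df2 = f_statistics(X, y, covariates)
        fstat = np.where(mask, fstat, 0.0)
        obs_max = float(fstat.max())
        scores = self._enhance(fstat, obs_max if obs_max > 0 else None)

        rng = np.random.default_rng(self.random_state)
        exceed = np.zeros(X.shape[1], dtype=np.int64)
        n = X.shape[0]
        for _ in range(self.n_permutations):
            perm_y = y[rng.permutation(n)]
            f_null, _, _ = f_statistics(X, perm_y, covariates)
            f_null = np.where(mask, f_null, 0.0)
            h_max = float(f_null.max()) if self.grid == "adaptive" else obs_max
            null_scores = self._enhance(f_null, h_max if h_max > 0 else None)
            exceed += null_scores >= scores - 1e-12

        pvalues = np.full(X.shape[1], np.nan)
        pvalues[mask] = (exceed[mask] + 1) / (self.n_permutations + 1)
        reject, p_adj = bh_fdr(pvalues[mask], q=self.fdr_q)
        p_fdr = np.full(X.shape[1], np.nan)
        p_fdr[mask] = p_adj
        significant = np.zeros(X.shape[1], dtype=bool)
        significant[mask] = reject
        # zero raw statistic can never be significant, whatever the null says
        significant &= fstat > 0

        self.n_features_in_ = X.shape[1]
        self.groups_ = np.array(sorted(set(y.tolist())))
        self.df_ = (df1, df2)
        self.fstat_ = fstat
        self.scores_ = scores
        self.pvalues_ = pvalues
        self.pvalues_fdr_ = p_fdr
        self.significant_ = significant
        self.tested_mask_ = mask
        return self

    def get_support(self, indices: bool = False) -> np.ndarray:
        if not hasattr(self, "significant_"):
            raise RuntimeError("TFNBS instance is not fitted")
        return np.flatnonzero(self.significant_) if indices else self.significant_

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-edge results with ROI names (tested edges only)."""
        index = self._edge_index()
        rows = []
        for k in np.flatnonzero(self.tested_mask_):
            a, b = index.names(k)
            rows.append(
                {
                    "edge": int(k),
                    "roi_a": a,
                    "roi_b": b,
                    "F": self.fstat_[k],
                    "score": self.scores_[k],
                    "p_perm": self.pvalues_[k],
                    "p_fdr": self.pvalues_fdr_[k],
                    "significant": bool(self.significant_[k]),
                }
            )
        return pd.DataFrame(rows)


def tfnbs_inference(
    cohort: CohortDataset,
    n_permutations: int = 10000,
    e_exponent: float = 0.5,
    h_exponent: float = 3.0,
    n_steps: int = 100,
    fdr_q: float = 0.05,
    grid: str = "adaptive",
    seed: int | None = None,
    min_detection_fraction: float = 0.5,
    use_gender_covariate: bool = True,
) -> TFNBS:
    """Cohort-level TFNBS: detection filter, gender adjustment, inference.

    Applies the detection filter (edges present in at least
    ``min_detection_fraction`` of subjects), then fits :class:`TFNBS` on the
    surviving edges with gender as a covariate of no interest.
    """
    mask = apply_detection_filter(cohort, min_detection_fraction)
    model = TFNBS(
        e_exponent=e_exponent,
        h_exponent=h_exponent,
        n_steps=n_steps,
        n_permutations=n_permutations,
        fdr_q=fdr_q,
        grid=grid,
        random_state=seed,
        edge_index=cohort.edge_index,
    )
    covariates = cohort.gender if use_gender_covariate else None
    return model.fit(cohort.nos_edges(), cohort.groups, covariates=covariates, edge_mask=mask)
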