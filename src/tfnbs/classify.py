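"""Nested leave-one-out classification of patients from connectome features.

One outer fold per subject: the held-out subject never touches feature
selection, hyperparameter tuning or model fitting.  Within each training
fold the pipeline is (1) a two-group TFNBS comparison selecting the
significant edges (or a permutation F test for non-edge scalar features),
(2) recursive feature elimination with the subset size chosen by inner
stratified cross-validated accuracy, and (3) a linear SVM whose cost C is
grid-searched by inner cross-validation.  Features are standardized with
training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .atlas import DEFAULT_EDGE_INDEX, EdgeIndex
from .cohort import CohortDataset
from .glm import bh_fdr, f_statistics
from .inference import TFNBS

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


def rfe_select(
    X: np.ndarray,
    y: np.ndarray,
    step: int = 1,
    inner_folds: int = 5,
    c_value: float = 1.0,
) -> np.ndarray:
    """Recursive feature elimination with CV-chosen subset size.

    A linear SVM is refit while iteratively dropping the feature with the
    smallest squared weight; candidate subset sizes are scored by inner
    stratified cross-validated accuracy and ties are broken toward fewer
    features.  Returns the selected column indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] == 0:
        raise ValueError("no candidate features")
    if len(set(y.tolist())) < 2:
        raise ValueError("need two classes for feature elimination")
    if X.shape[1] == 1:
        return np.array([0])
    svm = SVC(kernel="linear", C=c_value)
    ranking = RFE(svm, n_features_to_select=1, step=step).fit(X, y).ranking_
    cv = StratifiedKFold(n_splits=min(inner_folds, np.bincount(_codes(y)).min()))
    best_size, best_score = 1, -np.inf
    for size in range(1, X.shape[1] + 1):
        subset = ranking <= size
        score = cross_val_score(clone(svm), X[:, subset], y, cv=cv).mean()
        if score > best_score + 1e-12:  # ties keep the smaller size
            best_size, best_score = size, score
    return np.flatnonzero(ranking <= best_size)


def tune_svm(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    inner_folds: int = 5,
) -> tuple[SVC, float]:
    """Linear-SVM cost selection by inner stratified CV accuracy.

    Ties go to the smallest C (strongest regularization); the winning model
    is refit on the full training fold.
    """
    if not c_grid:
        raise ValueError("empty C grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=min(inner_folds, np.bincount(_codes(y)).min()))
    best_c, best_score = None, -np.inf
    for c in sorted(c_grid):
        score = cross_val_score(SVC(kernel="linear", C=c), X, y, cv=cv).mean()
        if score > best_score + 1e-12:
            best_c, best_score = c, score
    model = SVC(kernel="linear", C=best_c).fit(X, y)
    return model, float(best_c)


def _codes(y: np.ndarray) -> np.ndarray:
    levels = sorted(set(np.asarray(y).tolist()))
    return np.array([levels.index(v) for v in np.asarray(y)])


class ConnectomeSVMClassifier(BaseEstimator, ClassifierMixin):
    """TFNBS feature selection + RFE + tuned linear SVM, as one estimator.

    Parameters
    ----------
    selection_permutations, fdr_q, e_exponent, h_exponent, n_steps
        Configuration of the within-fold TFNBS selection stage.
    c_grid, inner_folds, rfe_step
        Classifier tuning: SVM cost grid, inner stratified folds, RFE step.
    k_fallback
        When the selection stage finds no significant feature, fall back to
        the ``k_fallback`` features with the smallest permutation p
        (statistic value breaking ties), so every fold yields a model.
    edge_columns
        Boolean mask of X columns that are connectome edges in canonical
        order (enhanced over the graph); remaining columns are scalar ROI
        features tested by permutation F without enhancement.  ``None``
        treats all columns as edges when X has exactly one column per edge,
        otherwise as scalars.
    """

    def __init__(
        self,
        selection_permutations: int = 1000,
        fdr_q: float = 0.05,
        e_exponent: float = 0.5,
        h_exponent: float = 3.0,
        n_steps: int = 100,
        c_grid: tuple[float, ...] = DEFAULT_C_GRID,
        inner_folds: int = 5,
        rfe_step: int = 1,
        k_fallback: int = 10,
        edge_columns: np.ndarray | None = None,
        edge_index: EdgeIndex | None = None,
        random_state: int | None = None,
    ):
        self.selection_permutations = selection_permutations
        self.fdr_q = fdr_q
        self.e_exponent = e_exponent
        self.h_exponent = h_exponent
        self.n_steps = n_steps
        self.c_grid = c_grid
        self.inner_folds = inner_folds
        self.rfe_step = rfe_step
        self.k_fallback = k_fallback
        self.edge_columns = edge_columns
        self.edge_index = edge_index
        self.random_state = random_state

    # -- selection stage -------------------------------------------------

    def _edge_mask(self, n_columns: int) -> np.ndarray:
        index = self.edge_index if self.edge_index is not None else DEFAULT_EDGE_INDEX
        if self.edge_columns is not None:
            mask = np.asarray(self.edge_columns, dtype=bool)
            if mask.size != n_columns:
                raise ValueError("edge_columns mask does not match X")
            if mask.sum() not in (0, len(index)):
                raise ValueError("edge columns must cover the full edge set")
            return mask
        if n_columns == len(index):
            return np.ones(n_columns, dtype=bool)
        return np.zeros(n_columns, dtype=bool)

    def _select(self, X: np.ndarray, y: np.ndarray, covariates) -> np.ndarray:
        """Stage 1: significant columns by TFNBS (edges) / permutation F."""
        is_edge = self._edge_mask(X.shape[1])
        pvals = np.full(X.shape[1], np.nan)
        stat = np.zeros(X.shape[1])
        if is_edge.any():
            model = TFNBS(
                e_exponent=self.e_exponent,
                h_exponent=self.h_exponent,
                n_steps=self.n_steps,
                n_permutations=self.selection_permutations,
                fdr_q=self.fdr_q,
                random_state=self.random_state,
                edge_index=self.edge_index,
            ).fit(X[:, is_edge], y, covariates=covariates)
            pvals[is_edge] = model.pvalues_
            stat[is_edge] = model.scores_
        if (~is_edge).any():
            sub = X[:, ~is_edge]
            f_obs, _, _ = f_statistics(sub, y, covariates)
            rng = np.random.default_rng(self.random_state)
            exceed = np.zeros(sub.shape[1], dtype=np.int64)
            for _ in range(self.selection_permutations):
                f_null, _, _ = f_statistics(sub, y[rng.permutation(y.size)], covariates)
                exceed += f_null >= f_obs - 1e-12
            pvals[~is_edge] = (exceed + 1) / (self.selection_permutations + 1)
            stat[~is_edge] = f_obs
        reject, _ = bh_fdr(pvals, q=self.fdr_q)
        selected = np.flatnonzero(reject)
        if selected.size == 0:
            order = np.lexsort((-stat, pvals))
            selected = np.sort(order[: min(self.k_fallback, X.shape[1])])
        return selected

    # -- estimator API ---------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = sorted(set(y.tolist()))
        if len(classes) != 2:
            raise ValueError("binary classification only")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("each class needs at least two training subjects")
        candidates = self._select(X, y, covariates)
        self.candidates_ = candidates
        scaler = StandardScaler().fit(X[:, candidates])
        Xs = scaler.transform(X[:, candidates])
        kept = rfe_select(Xs, y, step=self.rfe_step, inner_folds=self.inner_folds)
        self.selected_ = candidates[kept]
        self.scaler_ = StandardScaler().fit(X[:, self.selected_])
        svm, best_c = tune_svm(
            self.scaler_.transform(X[:, self.selected_]),
            y,
            c_grid=self.c_grid,
            inner_folds=self.inner_folds,
        )
        self.svm_ = svm
        self.best_c_ = best_c
        self.classes_ = np.array(classes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.svm_.predict(self.scaler_.transform(X[:, self.selected_]))


# -- leave-one-out evaluation --------------------------------------------


@dataclass
class FoldResult:
    """One outer fold: held-out subject, its prediction and the fitted fold.

    ``candidate_features`` is the stage-1 (group-difference) selection;
    ``selected_features`` the subset surviving recursive elimination.
    """

    subject_id: str
    true_label: str
    predicted_label: str
    selected_features: list[int]
    candidate_features: list[int]
    best_c: float


@dataclass
class ClassificationReport:
    """Aggregated LOOCV output: per-fold results, metrics, stability.

    ``stability`` counts the features entering the final SVM;
    ``candidate_stability`` counts the stage-1 group-difference selection,
    the level at which fold-to-fold feature stability is usually quoted.
    """

    folds: list[FoldResult]
    metrics: dict[str, float]
    stability: pd.Series
    candidate_stability: pd.Series
    positive_class: str

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [f.subject_id for f in self.folds],
                "true_label": [f.true_label for f in self.folds],
                "predicted_label": [f.predicted_label for f in self.folds],
                "best_c": [f.best_c for f in self.folds],
                "selected_features": [
                    ";".join(map(str, f.selected_features)) for f in self.folds
                ],
                "candidate_features": [
                    ";".join(map(str, f.candidate_features)) for f in self.folds
                ],
            }
        )


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = "MSA"
) -> dict[str, float]:
    """Accuracy, balanced accuracy, sensitivity and specificity.

    Sensitivity is the recall of the ``positive`` (patient-of-interest)
    class, specificity the recall of the comparison class.  Raw accuracy is
    correct over total; balanced accuracy is the mean of the two recalls,
    the convention robust to the cohort's unequal group sizes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("no predictions to score")
    pos = y_true == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must appear among the true labels")
    sensitivity = float((y_pred[pos] == positive).mean())
    specificity = float((y_pred[~pos] != positive).mean())
    return {
        "accuracy": float((y_pred == y_true).mean()),
        "balanced_accuracy": (sensitivity + specificity) / 2,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


def feature_stability(fold_features: list[list[int]], n_features: int) -> np.ndarray:
    """Per-feature selection frequency across outer folds."""
    if not fold_features:
        raise ValueError("no folds")
    counts = np.zeros(n_features)
    for features in fold_features:
        counts[np.asarray(features, dtype=int)] += 1
    return counts / len(fold_features)


def select_features_fold(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    estimator: ConnectomeSVMClassifier | None = None,
) -> np.ndarray:
    """Feature list one training fold would use (selection + RFE only)."""
    est = clone(estimator) if estimator is not None else ConnectomeSVMClassifier()
    est.fit(X, y, covariates=covariates)
    return est.selected_


def loocv_classify(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    subject_ids: list[str] | None = None,
    estimator: ConnectomeSVMClassifier | None = None,
    positive: str = "MSA",
    feature_names: list[str] | None = None,
) -> ClassificationReport:
    """Leave-one-out evaluation of the nested selection + SVM pipeline.

    Every fold refits the full pipeline on the other N-1 subjects; the
    held-out subject contributes only its prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n)]
    base = estimator if estimator is not None else ConnectomeSVMClassifier()
    folds: list[FoldResult] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        cov = None if covariates is None else np.asarray(covariates, dtype=float)[train]
        model = clone(base).fit(X[train], y[train], covariates=cov)
        pred = model.predict(X[i : i + 1])[0]
        folds.append(
            FoldResult(
                subject_id=subject_ids[i],
                true_label=str(y[i]),
                predicted_label=str(pred),
                selected_features=[int(k) for k in model.selected_],
                candidate_features=[int(k) for k in model.candidates_],
                best_c=model.best_c_,
            )
        )
    metrics = classification_metrics(
        np.array([f.true_label for f in folds]),
        np.array([f.predicted_label for f in folds]),
        positive=positive,
    )
    freq = feature_stability([f.selected_features for f in folds], X.shape[1])
    cand = feature_stability([f.candidate_features for f in folds], X.shape[1])
    names = feature_names if feature_names is not None else [str(k) for k in range(X.shape[1])]
    return ClassificationReport(
        folds=folds,
        metrics=metrics,
        stability=pd.Series(freq, index=names, name="selection_frequency"),
        candidate_stability=pd.Series(cand, index=names, name="candidate_frequency"),
        positive_class=positive,
    )


def cohort_feature_matrix(
    cohort: CohortDataset, features: str = "nos"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, edge_column_mask, names) for a feature specification.

    ``features`` is ``"nos"``, a feature-table name (``"FA"``, ``"MD"``,
    ``"volume"``), or a ``+``-joined combination such as ``"nos+volume"``
    (column-wise concatenation; standardization happens within folds).
    """
    blocks, masks, names = [], [], []
    for part in features.split("+"):
        part = part.strip()
        if part.lower() == "nos":
            block = cohort.nos_edges()
            blocks.append(block)
            masks.append(np.ones(block.shape[1], dtype=bool))
            names.extend("|".join(cohort.edge_index.names(k)) for k in range(block.shape[1]))
        else:
            key = {"fa": "FA", "md": "MD", "volume": "volume"}.get(part.lower(), part)
            table = cohort.features(key)
            blocks.append(table.to_numpy(dtype=float))
            masks.append(np.zeros(table.shape[1], dtype=bool))
            names.extend(f"{key}:{c}" for c in table.columns)
    return np.hstack(blocks), np.concatenate(masks), names


def loocv_classify_cohort(
    cohort: CohortDataset,
    contrast: tuple[str, str] = ("PD", "MSA"),
    features: str = "nos",
    estimator: ConnectomeSVMClassifier | None = None,
    positive: str = "MSA",
) -> ClassificationReport:
    """LOOCV over a two-group sub-cohort for a given feature specification."""
    sub = cohort.subset(contrast)
    X, edge_mask, names = cohort_feature_matrix(sub, features)
    base = estimator if estimator is not None else ConnectomeSVMClassifier()
    base = clone(base)
    base.set_params(edge_columns=edge_mask, edge_index=sub.edge_index)
    return loocv_classify(
        X,
        sub.groups,
        covariates=sub.gender,
        subject_ids=sub.ids,
        estimator=base,
        positive=positive,
        feature_names=names,
    )
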