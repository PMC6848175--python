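"""Subject records, connectivity matrices and cohort-level edge operations.

A cohort couples per-subject symmetric number-of-streamlines (NOS) matrices
with a subject table (diagnostic group, gender, optional covariates) and
optional per-ROI feature tables (FA, MD, volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, EdgeIndex, ROIAtlas, edge_flatten

GROUPS = ("HC", "PD", "MSA")


@dataclass
class SubjectRecord:
    """One participant: identifier, diagnostic group, gender, covariates.

    ``gender`` is coded 0/1 (female/male); it is a covariate of no interest
    in every analysis, so it must be present.
    """

    id: str
    group: str
    gender: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.gender not in (0, 1):
            raise ValueError("gender must be coded 0/1")


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric, nonnegative, zero-diagonal NOS matrix."""

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("streamline counts cannot be negative")
        if np.diagonal(v).any():
            raise ValueError("diagonal must be zero (no self-connections)")
        self.values = v


class CohortDataset:
    """Aligned stack of subjects, NOS matrices and optional ROI feature tables.

    Parameters
    ----------
    subjects
        Subject records, one per participant.
    matrices
        Connectivity matrices aligned (by position and id) with ``subjects``.
        May be omitted for feature-only cohorts.
    feature_tables
        Mapping of feature name (``"FA"``, ``"MD"``, ``"volume"`` ...) to a
        DataFrame with one row per subject (index = subject id) and one
        column per ROI label.
    """

    def __init__(
        self,
        subjects: list[SubjectRecord],
        matrices: list[ConnectivityMatrix] | None = None,
        feature_tables: dict[str, pd.DataFrame] | None = None,
        atlas: ROIAtlas = DEFAULT_ATLAS,
    ):
        if not subjects:
            raise ValueError("cohort must contain at least one subject")
        self.subjects = list(subjects)
        self.atlas = atlas
        self.edge_index = EdgeIndex(atlas)
        self.matrices = list(matrices) if matrices is not None else None
        self.feature_tables = dict(feature_tables) if feature_tables else {}
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        if self.matrices is not None:
            if len(self.matrices) != len(self.subjects):
                raise ValueError("matrices are not aligned with subjects")
            for s, m in zip(self.subjects, self.matrices):
                if s.id != m.subject_id:
                    raise ValueError(f"matrix/subject id mismatch: {m.subject_id} vs {s.id}")
                if m.values.shape != (atlas.n_nodes, atlas.n_nodes):
                    raise ValueError("matrix shape does not match atlas")
        for name, table in self.feature_tables.items():
            missing = set(ids) - set(table.index)
            if missing:
                raise ValueError(f"feature table {name!r} is missing subjects {sorted(missing)}")

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def gender(self) -> np.ndarray:
        return np.array([s.gender for s in self.subjects], dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        try:
            return np.array([s.covariates[name] for s in self.subjects], dtype=float)
        except KeyError:
            raise KeyError(f"covariate {name!r} missing for some subject") from None

    def nos_edges(self) -> np.ndarray:
        """All subjects' NOS matrices flattened to an (n_subjects, 153) array."""
        if self.matrices is None:
            raise ValueError("cohort has no connectivity matrices")
        return np.stack([edge_flatten(m.values, self.edge_index) for m in self.matrices])

    def features(self, name: str) -> pd.DataFrame:
        if name not in self.feature_tables:
            raise KeyError(f"no feature table named {name!r}")
        table = self.feature_tables[name]
        return table.loc[self.ids, list(self.atlas.labels)]

    def subset(self, groups: tuple[str, ...] | list[str]) -> "CohortDataset":
        """Cohort restricted to the given groups, order preserved."""
        keep = [i for i, s in enumerate(self.subjects) if s.group in groups]
        if not keep:
            raise ValueError(f"no subjects in groups {groups}")
        subjects = [self.subjects[i] for i in keep]
        matrices = [self.matrices[i] for i in keep] if self.matrices is not None else None
        tables = {
            name: t.loc[[self.subjects[i].id for i in keep]]
            for name, t in self.feature_tables.items()
        }
        return CohortDataset(subjects, matrices, tables, atlas=self.atlas)


# -- edge-level operations ----------------------------------------------


def symmetrize_counts(raw: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Fold a directed streamline-count matrix into an undirected one.

    Streamlines seeded in region i and reaching j are counted together with
    those seeded in j and reaching i: ``out[i, j] = raw[i, j] + raw[j, i]``
    off the diagonal, yielding a symmetric NOS matrix.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("raw count matrix must be square")
    if (raw < 0).any():
        raise ValueError("raw streamline counts cannot be negative")
    if np.diagonal(raw).any():
        raise ValueError("raw diagonal must be zero")
    out = raw + raw.T
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(subject_id=subject_id, values=out)


def apply_detection_filter(cohort: CohortDataset, min_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of edges detected in at least ``min_fraction`` of subjects.

    An edge counts as detected in a subject when its NOS is strictly
    positive; it is kept when detected in at least
    ``ceil(min_fraction * n_subjects)`` subjects.  Spurious connections
    reconstructed in only a few subjects are thereby excluded from all
    downstream testing.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    edges = cohort.nos_edges()
    needed = int(np.ceil(min_fraction * len(cohort)))
    return (edges > 0).sum(axis=0) >= needed


def edge_zscore_summary(cohort: CohortDataset, edges: np.ndarray) -> np.ndarray:
    """Per-subject mean z-score over an edge set.

    Each edge is standardized across all subjects pooled (sample SD, ddof=1);
    the summary for a subject is the mean standardized NOS over ``edges``.
    Zero-variance edges carry no group information and are excluded with a
    warning.
    """
    edges = np.asarray(edges)
    if edges.dtype == bool:
        edges = np.flatnonzero(edges)
    if edges.size == 0:
        raise ValueError("edge set is empty")
    values = cohort.nos_edges()[:, edges]
    sd = values.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all requested edges have zero variance")
    if not usable.all():
        warnings.warn(
            f"excluding {int((~usable).sum())} zero-variance edge(s) from z-score summary",
            RuntimeWarning,
            stacklevel=2,
        )
    z = (values[:, usable] - values[:, usable].mean(axis=0)) / sd[usable]
    return z.mean(axis=1)
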