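"""Delimited-text readers and writers for cohorts and results.

On disk a cohort is a directory containing ``subjects.csv`` (columns ``id``,
``group``, ``gender`` plus optional covariates), ``manifest.csv`` mapping
``subject_id`` to a matrix file, one 18x18 CSV per subject with ROI labels
as header row and index column, and optional ``features_<NAME>.csv`` tables
(rows = subjects, columns = ROI labels).  Readers validate labels against
the atlas rather than trusting column order, and every error names the
offending file or column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .atlas import DEFAULT_ATLAS, ROIAtlas
from .cohort import CohortDataset, ConnectivityMatrix, SubjectRecord

_RESERVED = {"id", "group", "gender"}


def write_cohort(cohort: CohortDataset, directory: str | Path) -> Path:
    """Serialize a cohort to a directory of CSV files (full precision)."""
    directory = Path(directory)
    (directory / "matrices").mkdir(parents=True, exist_ok=True)
    labels = list(cohort.atlas.labels)

    rows = []
    for s in cohort.subjects:
        row = {"id": s.id, "group": s.group, "gender": s.gender}
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "subjects.csv", index=False)

    manifest = []
    if cohort.matrices is not None:
        for m in cohort.matrices:
            rel = f"matrices/{m.subject_id}.csv"
            pd.DataFrame(m.values, index=labels, columns=labels).to_csv(directory / rel)
            manifest.append({"subject_id": m.subject_id, "path": rel})
    pd.DataFrame(manifest, columns=["subject_id", "path"]).to_csv(
        directory / "manifest.csv", index=False
    )

    for name, table in cohort.feature_tables.items():
        table.loc[cohort.ids, labels].to_csv(directory / f"features_{name}.csv")
    return directory


def read_cohort(directory: str | Path, atlas: ROIAtlas = DEFAULT_ATLAS) -> CohortDataset:
    """Load a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    subjects_path = directory / "subjects.csv"
    manifest_path = directory / "manifest.csv"
    if not subjects_path.exists():
        raise FileNotFoundError(f"missing subject table: {subjects_path}")
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")

    table = pd.read_csv(subjects_path, dtype={"id": str})
    for column in ("id", "group", "gender"):
        if column not in table.columns:
            raise ValueError(f"{subjects_path} is missing required column {column!r}")
    covariate_columns = [c for c in table.columns if c not in _RESERVED]
    subjects = [
        SubjectRecord(
            id=row["id"],
            group=row["group"],
            gender=int(row["gender"]),
            covariates={c: float(row[c]) for c in covariate_columns if pd.notna(row[c])},
        )
        for _, row in table.iterrows()
    ]

    manifest = pd.read_csv(manifest_path, dtype=str)
    matrices: list[ConnectivityMatrix] | None
    if len(manifest):
        by_id = dict(zip(manifest["subject_id"], manifest["path"]))
        matrices = []
        for s in subjects:
            if s.id not in by_id:
                raise ValueError(f"{manifest_path} has no matrix entry for subject {s.id!r}")
            matrices.append(_read_matrix(directory / by_id[s.id], s.id, atlas))
    else:
        matrices = None

    features = {}
    for path in sorted(directory.glob("features_*.csv")):
        name = path.stem.removeprefix("features_")
        frame = pd.read_csv(path, index_col=0)
        missing = set(atlas.labels) - set(frame.columns)
        if missing:
            raise ValueError(f"{path} is missing ROI columns {sorted(missing)}")
        frame.index = frame.index.astype(str)
        features[name] = frame[list(atlas.labels)]
    return CohortDataset(subjects, matrices, features, atlas=atlas)


def _read_matrix(path: Path, subject_id: str, atlas: ROIAtlas) -> ConnectivityMatrix:
    if not path.exists():
        raise FileNotFoundError(f"missing matrix file: {path}")
    frame = pd.read_csv(path, index_col=0)
    if list(frame.columns) != list(atlas.labels) or list(frame.index) != list(atlas.labels):
        # accept any ordering of the right label set, realigning to the atlas
        if set(frame.columns) != set(atlas.labels) or set(frame.index) != set(atlas.labels):
            raise ValueError(f"{path}: ROI labels do not match the atlas")
        frame = frame.loc[list(atlas.labels), list(atlas.labels)]
    return ConnectivityMatrix(subject_id=subject_id, values=frame.to_numpy(dtype=float))


def write_stats_frame(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_stats_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _checksum(path: Path) -> str:
    import hashlib

    return hashlib.sha256(path.read_bytes()).hexdigest()


def input_checksums(directory: str | Path) -> dict[str, str]:
    """sha256 of every CSV in a cohort directory, keyed by relative path."""
    directory = Path(directory)
    return {
        str(p.relative_to(directory)): _checksum(p)
        for p in sorted(directory.rglob("*.csv"))
    }
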