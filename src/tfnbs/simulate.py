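"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: per-group
Gaussian edge-wise streamline counts truncated at a nonnegative floor, with
group sizes and male/female splits matching the published cohort, plus
optional per-ROI scalar features (FA, MD, volume).  Edges are sampled
independently by default — only marginal means and SDs are published — with
an optional equicorrelation hook for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import edge_unflatten
from .cohort import GROUPS, CohortDataset, ConnectivityMatrix, SubjectRecord
from .params import GroupEdgeParams, GroupFeatureParams


@dataclass
class GeneratorConfig:
    """Cohort composition and sampling options.

    Defaults reproduce the published sample: 54 HC, 65 PD and 31 MSA
    subjects with male/female splits 26/28, 48/17 and 19/12.  ``floor``
    truncates the edge-wise Gaussians (streamline counts cannot be
    negative).  ``gender_effect`` shifts male subjects' edge means by that
    many within-group SDs, for validating covariate adjustment; it is zero
    by default so gender is a pure nuisance variable.  ``equicorrelation``
    (rho in [0, 1)) shares a latent factor across edges within subject.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 54, "PD": 65, "MSA": 31}
    )
    gender_counts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"HC": (26, 28), "PD": (48, 17), "MSA": (19, 12)}
    )
    seed: int | None = None
    floor: float = 0.0
    gender_effect: float = 0.0
    equicorrelation: float = 0.0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"need at least 2 subjects per group (got {n} for {g})")
        for g, (m, f) in self.gender_counts.items():
            if m < 0 or f < 0:
                raise ValueError("gender counts must be nonnegative")
        if not 0 <= self.equicorrelation < 1:
            raise ValueError("equicorrelation must be in [0, 1)")

    def genders_for(self, group: str, rng: np.random.Generator) -> np.ndarray:
        """0/1 gender codes for one group, male fraction per configuration."""
        n = self.n_per_group[group]
        m, f = self.gender_counts.get(group, (0, 0))
        if m + f > 0:
            n_male = int(round(n * m / (m + f)))
        else:
            n_male = n // 2
        genders = np.array([1] * n_male + [0] * (n - n_male))
        rng.shuffle(genders)
        return genders


def _sample_truncated(
    mean: np.ndarray, sd: np.ndarray, size: int, floor: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` rows from per-edge Normal(mean, sd) truncated at ``floor``."""
    out = np.empty((size, mean.size))
    positive = sd > 0
    if positive.any():
        a = (floor - mean[positive]) / sd[positive]
        out[:, positive] = stats.truncnorm.rvs(
            a[None, :],
            np.inf,
            loc=mean[None, positive],
            scale=sd[None, positive],
            size=(size, int(positive.sum())),
            random_state=rng,
        )
    if (~positive).any():
        out[:, ~positive] = np.maximum(mean[~positive], floor)[None, :]
    return out


def simulate_nos_cohort(
    params: GroupEdgeParams, config: GeneratorConfig | None = None
) -> CohortDataset:
    """Generate a three-group cohort of symmetric NOS matrices.

    Each subject's value at each edge is an independent draw from the
    group's truncated Gaussian.  With ``equicorrelation`` rho > 0, a latent
    standard-normal factor per subject contributes sqrt(rho) of each edge's
    (pre-truncation) z-score and the result is clipped at the floor instead
    of properly truncated.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    matrices: list[ConnectivityMatrix] = []
    for group in GROUPS:
        if group not in config.n_per_group:
            continue
        n = config.n_per_group[group]
        mean, sd = params.means[group], params.sds[group]
        genders = config.genders_for(group, rng)
        rho = config.equicorrelation
        if rho > 0:
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, mean.size))
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            values = np.maximum(mean[None, :] + sd[None, :] * z, config.floor)
        else:
            values = _sample_truncated(mean, sd, n, config.floor, rng)
        if config.gender_effect:
            values = values + config.gender_effect * sd[None, :] * genders[:, None]
            values = np.maximum(values, config.floor)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            subjects.append(SubjectRecord(id=sid, group=group, gender=int(genders[i])))
            matrices.append(
                ConnectivityMatrix(
                    subject_id=sid, values=edge_unflatten(values[i], params.edge_index)
                )
            )
    return CohortDataset(subjects, matrices, atlas=params.edge_index.atlas)


def simulate_feature_table(
    params: GroupFeatureParams,
    config: GeneratorConfig | None = None,
    features: tuple[str, ...] = ("FA", "MD"),
) -> dict[str, pd.DataFrame]:
    """Per-ROI scalar feature tables (rows = subjects, columns = ROI labels).

    Values are Gaussian with the group's printed mean/SD (null-parameter
    ROIs are group-invariant), floored at zero since FA, MD and volumes are
    nonnegative.  Subject ids match :func:`simulate_nos_cohort` under the
    same configuration so the tables can be attached to a simulated cohort.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    labels = list(params.atlas.labels)
    tables: dict[str, pd.DataFrame] = {}
    index = [
        f"{group}{i + 1:03d}"
        for group in GROUPS
        if group in config.n_per_group
        for i in range(config.n_per_group[group])
    ]
    for feature in features:
        rows = []
        for group in GROUPS:
            if group not in config.n_per_group:
                continue
            n = config.n_per_group[group]
            mean = np.array([params.mean_sd(feature, roi, group)[0] for roi in labels])
            sd = np.array([params.mean_sd(feature, roi, group)[1] for roi in labels])
            rows.append(np.maximum(mean[None, :] + sd[None, :] * rng.standard_normal((n, len(labels))), 0.0))
        tables[feature] = pd.DataFrame(np.vstack(rows), index=index, columns=labels)
    return tables
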