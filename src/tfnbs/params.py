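"""Published group-level summary parameters driving the synthetic generator.

The study cohort (54 healthy controls, 65 Parkinson's disease, 31 multiple
system atrophy patients) is summarized in print as per-edge NOS means/SDs
for the ten connections that differed between groups, and per-ROI FA and MD
means/SDs for the structures that differed.  Those printed numbers, stored
here verbatim, parameterize the synthetic cohorts used throughout the test
and acceptance suites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import DEFAULT_ATLAS, DEFAULT_EDGE_INDEX, EdgeIndex, ROIAtlas
from .cohort import GROUPS

_M = 1e6  # NOS tables are printed on a x10^6 scale

#: the ten connections with significantly reduced NOS, as printed:
#: (ROI a, ROI b) -> {group: (mean, sd)} in streamlines
PUBLISHED_EDGE_PARAMS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("Left-Pallidum", "Left-Putamen"): {
        "HC": (1.4874 * _M, 0.2522 * _M),
        "PD": (1.5197 * _M, 0.2627 * _M),
        "MSA": (1.2184 * _M, 0.2599 * _M),
    },
    ("Left-Hippocampus", "Left-Thalamus"): {
        "HC": (1.023 * _M, 0.2549 * _M),
        "PD": (0.9295 * _M, 0.2975 * _M),
        "MSA": (0.7847 * _M, 0.2147 * _M),
    },
    ("Left-Pallidum", "Left-VentralDC"): {
        "HC": (1.1713 * _M, 0.4372 * _M),
        "PD": (1.2162 * _M, 0.4139 * _M),
        "MSA": (0.8819 * _M, 0.3154 * _M),
    },
    ("Left-VentralDC", "Left-Cerebellum"): {
        "HC": (0.7598 * _M, 0.2172 * _M),
        "PD": (0.8399 * _M, 0.2092 * _M),
        "MSA": (0.5747 * _M, 0.2734 * _M),
    },
    ("Right-Pallidum", "Right-Putamen"): {
        "HC": (1.3556 * _M, 0.2265 * _M),
        "PD": (1.4148 * _M, 0.2195 * _M),
        "MSA": (1.1536 * _M, 0.3044 * _M),
    },
    ("Right-Putamen", "Right-Thalamus"): {
        "HC": (0.7936 * _M, 0.2888 * _M),
        "PD": (0.6769 * _M, 0.2435 * _M),
        "MSA": (0.5442 * _M, 0.3885 * _M),
    },
    ("Right-Thalamus", "Right-VentralDC"): {
        "HC": (2.7867 * _M, 0.4611 * _M),
        "PD": (2.8886 * _M, 0.4822 * _M),
        "MSA": (2.4535 * _M, 0.5392 * _M),
    },
    ("Left-VentralDC", "Right-Cerebellum"): {
        "HC": (0.0918 * _M, 0.0623 * _M),
        "PD": (0.0834 * _M, 0.0503 * _M),
        "MSA": (0.0471 * _M, 0.0426 * _M),
    },
    ("Left-Cerebellum", "Right-Cerebellum"): {
        "HC": (4.4335 * _M, 1.4225 * _M),
        "PD": (4.1623 * _M, 1.2313 * _M),
        "MSA": (2.3522 * _M, 1.032 * _M),
    },
    ("Right-VentralDC", "Right-Cerebellum"): {
        "HC": (0.8462 * _M, 0.2694 * _M),
        "PD": (0.9045 * _M, 0.2629 * _M),
        "MSA": (0.5694 * _M, 0.2649 * _M),
    },
}

#: published per-ROI fractional anisotropy (unitless): ROI -> {group: (mean, sd)}
PUBLISHED_FA_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Left-Amygdala": {"HC": (0.2585, 0.019), "PD": (0.2535, 0.020), "MSA": (0.2689, 0.029)},
    "Left-VentralDC": {"HC": (0.4327, 0.024), "PD": (0.4279, 0.029), "MSA": (0.4116, 0.027)},
    "Right-Thalamus": {"HC": (0.4218, 0.024), "PD": (0.4155, 0.025), "MSA": (0.3997, 0.026)},
    "Right-VentralDC": {"HC": (0.4731, 0.033), "PD": (0.4766, 0.037), "MSA": (0.4462, 0.030)},
    "Right-Cerebellum": {"HC": (0.3351, 0.026), "PD": (0.3357, 0.020), "MSA": (0.2884, 0.041)},
}

#: published per-ROI mean diffusivity (mm^2/s): ROI -> {group: (mean, sd)}
PUBLISHED_MD_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "Left-Accumbens": {"HC": (8.755e-4, 5.5e-5), "PD": (9.095e-4, 6.7e-5), "MSA": (9.213e-4, 7.7e-5)},
    "Left-Putamen": {"HC": (7.739e-4, 4.5e-5), "PD": (7.914e-4, 4.9e-5), "MSA": (8.161e-4, 7.8e-5)},
    "Left-VentralDC": {"HC": (1.206e-3, 9.9e-5), "PD": (1.232e-3, 1.1e-4), "MSA": (1.313e-3, 1.0e-4)},
    "Right-Pallidum": {"HC": (7.725e-4, 4.3e-5), "PD": (7.794e-4, 4.5e-5), "MSA": (8.084e-4, 7.9e-5)},
    "Right-Thalamus": {"HC": (1.248e-3, 1.0e-4), "PD": (1.271e-3, 1.1e-4), "MSA": (1.350e-3, 1.1e-4)},
    "Right-Cerebellum": {"HC": (9.187e-4, 7.5e-5), "PD": (9.162e-4, 7.1e-5), "MSA": (1.141e-3, 1.9e-4)},
}

#: invented background-edge parameters, shared by all groups; the scale
#: matches the magnitude of the published edges so the detection filter and
#: standardization behave as they would on real counts
NULL_EDGE_MEAN = 1.0e6
NULL_EDGE_SD = 0.25e6


@dataclass
class GroupEdgeParams:
    """Per-edge, per-group Gaussian NOS parameters over the full edge set.

    ``means[g]`` and ``sds[g]`` are length-153 vectors aligned with the
    canonical edge order.  ``seeded_edges`` lists the flat indices that carry
    group differences (the published connections).
    """

    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    seeded_edges: np.ndarray
    edge_index: EdgeIndex = field(default_factory=lambda: DEFAULT_EDGE_INDEX)

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.means or g not in self.sds:
                raise ValueError(f"missing parameters for group {g}")
            if (self.sds[g] < 0).any():
                raise ValueError("SDs must be nonnegative")
            if self.means[g].shape != (len(self.edge_index),):
                raise ValueError("parameter vectors must cover every edge")

    @classmethod
    def from_edge_table(
        cls,
        edge_table: dict[tuple[str, str], dict[str, tuple[float, float]]] | None = None,
        null_mean: float = NULL_EDGE_MEAN,
        null_sd: float = NULL_EDGE_SD,
        edge_index: EdgeIndex | None = None,
    ) -> "GroupEdgeParams":
        """Build full-connectome parameters from a named-edge table.

        Edges absent from the table get the shared null parameters in every
        group, so only the listed connections carry group effects.
        """
        if edge_table is None:
            edge_table = PUBLISHED_EDGE_PARAMS
        index = edge_index if edge_index is not None else DEFAULT_EDGE_INDEX
        n = len(index)
        means = {g: np.full(n, null_mean, dtype=float) for g in GROUPS}
        sds = {g: np.full(n, null_sd, dtype=float) for g in GROUPS}
        seeded = []
        for (a, b), per_group in edge_table.items():
            k = index.index(a, b)
            seeded.append(k)
            for g, (m, s) in per_group.items():
                means[g][k] = m
                sds[g][k] = s
        return cls(means=means, sds=sds, seeded_edges=np.sort(np.array(seeded)), edge_index=index)


@dataclass
class GroupFeatureParams:
    """Per-ROI, per-group Gaussian parameters for scalar ROI features.

    ``tables[feature][roi][group] = (mean, sd)``; features are FA (unitless,
    means in [0, 1]), MD (mm^2/s) and optionally volume (mm^3).  ROIs absent
    from a table get the feature's null parameters in every group.
    """

    tables: dict[str, dict[str, dict[str, tuple[float, float]]]]
    null_params: dict[str, tuple[float, float]]
    atlas: ROIAtlas = field(default_factory=lambda: DEFAULT_ATLAS)

    def __post_init__(self) -> None:
        for feature, table in self.tables.items():
            for roi, per_group in table.items():
                self.atlas.index(roi)
                for g, (m, s) in per_group.items():
                    if s < 0:
                        raise ValueError(f"negative SD for {feature}/{roi}/{g}")
                    if feature == "FA" and not 0 <= m <= 1:
                        raise ValueError(f"FA mean out of [0, 1] for {roi}/{g}")

    def mean_sd(self, feature: str, roi: str, group: str) -> tuple[float, float]:
        table = self.tables[feature]
        if roi in table and group in table[roi]:
            return table[roi][group]
        return self.null_params[feature]


def load_printed_params() -> tuple[GroupEdgeParams, GroupFeatureParams]:
    """The published Gaussian parameters, ready to drive the generator.

    Returns the full-connectome edge parameters (ten published connections
    plus shared null edges) and the FA/MD feature parameters.  ROIs that the
    publication does not list (because they showed no group effect) take
    group-invariant null values of a typical subcortical magnitude.
    """
    edge_params = GroupEdgeParams.from_edge_table()
    feature_params = GroupFeatureParams(
        tables={"FA": PUBLISHED_FA_PARAMS, "MD": PUBLISHED_MD_PARAMS},
        null_params={"FA": (0.40, 0.025), "MD": (1.0e-3, 1.0e-4), "volume": (4000.0, 500.0)},
    )
    return edge_params, feature_params
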