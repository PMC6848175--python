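"""Subcortical ROI atlas and edge indexing.

The connectome nodes are the 18 subcortical structures segmented by
FreeSurfer's volume stream: bilateral nucleus accumbens, amygdala, caudate,
hippocampus, pallidum, putamen, thalamus, ventral diencephalon (hypothalamus,
subthalamic nucleus, substantia nigra, red nucleus, mammillary body) and
cerebellar white matter including the middle cerebellar peduncle.

The canonical node order is the FreeSurfer ``aseg`` listing order, left
hemisphere first, then right.  All edge-wise vectors in this package use the
row-major upper-triangle order induced by that node order, giving
18 * 17 / 2 = 153 undirected edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: structure names in FreeSurfer aseg listing order (per hemisphere)
_ASEG_ORDER = (
    "Cerebellum",
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
    "VentralDC",
)


def _default_labels() -> tuple[str, ...]:
    return tuple(f"{hemi}-{roi}" for hemi in ("Left", "Right") for roi in _ASEG_ORDER)


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered set of ROI labels defining node and edge indexing.

    Parameters
    ----------
    labels
        Unique ROI names; their order is the canonical node order.
    """

    labels: tuple[str, ...] = field(default_factory=_default_labels)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("atlas labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("atlas needs at least two ROIs")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label: {label!r}") from None


DEFAULT_ATLAS = ROIAtlas()


class EdgeIndex:
    """Bijection between unordered ROI pairs and flat edge positions.

    Edge ``k`` corresponds to the ``k``-th entry of the strict upper triangle
    of the node-by-node matrix in row-major order, i.e. the order produced by
    :func:`numpy.triu_indices`.
    """

    def __init__(self, atlas: ROIAtlas = DEFAULT_ATLAS):
        self.atlas = atlas
        n = atlas.n_nodes
        self.rows, self.cols = np.triu_indices(n, k=1)
        self._lookup = {
            (int(i), int(j)): k for k, (i, j) in enumerate(zip(self.rows, self.cols))
        }

    def __len__(self) -> int:
        return len(self.rows)

    def index(self, a: int | str, b: int | str) -> int:
        """Flat position of the edge between ROIs ``a`` and ``b`` (order-free)."""
        i = self.atlas.index(a) if isinstance(a, str) else int(a)
        j = self.atlas.index(b) if isinstance(b, str) else int(b)
        if i == j:
            raise KeyError("self-loops are not edges")
        key = (min(i, j), max(i, j))
        if key not in self._lookup:
            raise KeyError(f"node index out of range: {key}")
        return self._lookup[key]

    def pair(self, k: int) -> tuple[int, int]:
        return int(self.rows[k]), int(self.cols[k])

    def names(self, k: int) -> tuple[str, str]:
        i, j = self.pair(k)
        return self.atlas.labels[i], self.atlas.labels[j]


DEFAULT_EDGE_INDEX = EdgeIndex(DEFAULT_ATLAS)


def edge_flatten(matrix: np.ndarray, index: EdgeIndex = DEFAULT_EDGE_INDEX) -> np.ndarray:
    """Extract the strict upper triangle of a symmetric matrix as a flat vector."""
    matrix = np.asarray(matrix, dtype=float)
    n = index.atlas.n_nodes
    if matrix.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} matrix, got {matrix.shape}")
    return matrix[index.rows, index.cols].copy()


def edge_unflatten(vector: np.ndarray, index: EdgeIndex = DEFAULT_EDGE_INDEX) -> np.ndarray:
    """Rebuild a symmetric zero-diagonal matrix from a flat edge vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(index),):
        raise ValueError(f"expected {len(index)} edge values, got {vector.shape}")
    n = index.atlas.n_nodes
    out = np.zeros((n, n), dtype=float)
    out[index.rows, index.cols] = vector
    out[index.cols, index.rows] = vector
    return out
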