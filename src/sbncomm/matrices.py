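"""Core containers for weighted structural brain networks.

A structural brain network (SBN) is a weighted undirected graph whose nodes
are atlas-defined brain regions and whose edge weights summarise white-matter
connectivity.  Two containers are used throughout the package:

``ConnectomeMatrix``
    one subject-session graph, stored as a symmetric non-negative matrix with
    a zero diagonal;

``MetricStack``
    the nine per-edge diffusion metrics (FA, MD, RD, NS, PS, SLD, TV, TL, ED)
    for one subject-session, all sharing the same edge support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

#: The nine edge metrics: fractional anisotropy, mean diffusivity, radial
#: diffusivity, number of streamlines, percentage of streamlines, streamline
#: density, tract volume, tract length and inter-node Euclidean distance.
METRIC_NAMES = ("FA", "MD", "RD", "NS", "PS", "SLD", "TV", "TL", "ED")

#: Diffusivity-style metrics where a *large* value means a *weaker*
#: connection; they are flipped before being combined with the others.
INVERTED_METRICS = frozenset({"MD", "RD"})

_SYMMETRY_TOL = 1e-12


def as_weights(W) -> np.ndarray:
    """Coerce a ``ConnectomeMatrix`` or array-like to a float ndarray."""
    if isinstance(W, ConnectomeMatrix):
        return W.weights
    return np.asarray(W, dtype=float)


@dataclass
class ConnectomeMatrix:
    """A symmetric, non-negative, zero-diagonal weighted adjacency matrix."""

    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("adjacency matrix contains non-finite entries")
        if np.any(W < 0):
            raise ValueError("edge weights must be non-negative")
        asym = np.abs(W - W.T).max() if W.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        self.weights = W
        if self.node_labels is None:
            self.node_labels = [f"n{i + 1}" for i in range(W.shape[0])]
        elif len(self.node_labels) != W.shape[0]:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def sparsity(self) -> float:
        """Fraction of possible node pairs that carry an edge."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_array(self.weights), directed=False)
        return n_comp == 1

    def normalized(self) -> "ConnectomeMatrix":
        """Return a copy rescaled to a maximum edge weight of 1."""
        w_max = self.weights.max()
        W = self.weights / w_max if w_max > 0 else self.weights.copy()
        return ConnectomeMatrix(W, list(self.node_labels))

    def copy(self) -> "ConnectomeMatrix":
        return ConnectomeMatrix(self.weights.copy(), list(self.node_labels))


@dataclass
class MetricStack:
    """The nine per-edge metric matrices for one subject-session.

    All matrices are symmetric with zero diagonal and share the same zero
    pattern (the edge support of the underlying tractography graph).
    """

    metrics: dict[str, np.ndarray]
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        missing = [m for m in METRIC_NAMES if m not in self.metrics]
        if missing:
            raise ValueError(f"metric stack is missing {missing}")
        mats = {}
        shape = None
        support = None
        for name in METRIC_NAMES:
            M = ConnectomeMatrix(self.metrics[name]).weights  # validates
            if shape is None:
                shape = M.shape
                support = M > 0
            elif M.shape != shape:
                raise ValueError(f"metric {name} has shape {M.shape}, expected {shape}")
            elif not np.array_equal(M > 0, support):
                raise ValueError(f"metric {name} does not share the stack's zero pattern")
            mats[name] = M
        self.metrics = mats
        if self.node_labels is None:
            self.node_labels = [f"n{i + 1}" for i in range(shape[0])]

    @property
    def n_nodes(self) -> int:
        return next(iter(self.metrics.values())).shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.metrics[name]

    def connectome(self, name: str = "NS") -> ConnectomeMatrix:
        """The stack's graph under a single metric (default: streamline count)."""
        return ConnectomeMatrix(self.metrics[name].copy(), list(self.node_labels))
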