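"""Consensus clustering across a cohort of partitions.

The consensus matrix counts, for every node pair, how many of the supplied
partitions (subjects x sessions) place the two nodes in the same community;
dividing by the number of partitions turns the counts into co-clustering
probabilities.  Instead of iterative thresholding-and-reclustering, the
probability matrix is topologically filtered with the OMST algorithm in a
single data-driven pass and the community detection algorithm is applied to
the filtered graph, yielding the group-representative partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .construction import omst_filter
from .detection import AlgoSpec, HardPartition, _canonical_labels, _partition_labels, detect
from .matrices import ConnectomeMatrix
from .similarity import nmi_hard

__all__ = [
    "ConsensusMatrix",
    "build_consensus_matrix",
    "consensus_partition",
    "consensus_individual_similarity",
]


@dataclass
class ConsensusMatrix:
    """Co-clustering counts and probabilities over a set of partitions.

    The diagonal of ``probabilities`` is 1 by definition (a node always
    co-clusters with itself).
    """

    counts: np.ndarray
    probabilities: np.ndarray
    n_observations: int


def build_consensus_matrix(partitions: list) -> ConsensusMatrix:
    """Count pairwise co-memberships across partitions (same node order)."""
    if not partitions:
        raise ValueError("need at least one partition")
    labels = [_partition_labels(p) for p in partitions]
    n = labels[0].shape[0]
    if any(lab.shape[0] != n for lab in labels):
        raise ValueError("all partitions must share the node count")
    counts = np.zeros((n, n), dtype=int)
    for lab in labels:
        counts += lab[:, None] == lab[None, :]
    probabilities = counts / len(labels)
    np.fill_diagonal(probabilities, 1.0)
    return ConsensusMatrix(counts, probabilities, len(labels))


def consensus_partition(C: ConsensusMatrix, algo_spec: AlgoSpec, seed: int = 0) -> HardPartition:
    """Representative partition: OMST-filter the probabilities, then detect.

    The diagonal is zeroed before filtering (self-loops are meaningless to
    spanning trees).  A perfectly consistent cohort yields a block-diagonal
    probability matrix whose blocks are disconnected from each other; each
    connected component is therefore filtered and partitioned separately and
    the component partitions are concatenated with disjoint labels.
    """
    if algo_spec.soft:
        raise ValueError("consensus extraction requires a hard algorithm")
    P = C.probabilities.copy().astype(float)
    np.fill_diagonal(P, 0.0)
    n = P.shape[0]
    n_comp, comp = connected_components(csr_array(P), directed=False)
    labels = np.zeros(n, dtype=int)
    offset = 0
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if idx.size == 1:
            labels[idx] = offset + 1
            offset += 1
            continue
        block = ConnectomeMatrix(P[np.ix_(idx, idx)])
        filtered = omst_filter(block).filtered
        part, _ = detect(filtered, algo_spec, seed=seed)
        labels[idx] = part.as_array() + offset
        offset = labels.max()
    return HardPartition(
        _canonical_labels(labels).tolist(),
        algorithm=f"consensus:{algo_spec.name}",
        scale=algo_spec.effective_scale,
    )


def consensus_individual_similarity(representative: HardPartition, partitions: list) -> float:
    """Mean NMI between the representative and the individual partitions."""
    if not partitions:
        raise ValueError("need at least one individual partition")
    return float(np.mean([nmi_hard(representative, p) for p in partitions]))
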