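"""Community detection on weighted connectomes.

Hard partitions are found by a fast greedy multi-scale optimiser (Louvain
two-phase scheme: local node moves followed by community aggregation,
repeated until stable) that can maximise any of five quality criteria:

``newman``
    Newman-Girvan modularity Q on weighted degrees.
``rb``
    Reichardt-Bornholdt modularity with resolution gamma:
    Q(gamma) = (1/2m) sum_ij [A_ij - gamma d_i d_j / 2m] delta(c_i, c_j);
    gamma = 1 recovers Newman Q.
``rn``
    Ronhovde-Nussinov Potts objective: intra-community weight minus a
    penalty gamma per absent intra-community pair, normalised by total
    weight.
``afg``
    Arenas-Fernandez-Gomez resistance: Newman modularity of the graph with
    a self-loop of weight r on every node (large positive r shatters the
    partition, negative r coarsens it).
``stability``
    linearised Markov stability at time t:
    R(t) = (1 - t) + sum_c [t e_c/m - (d_c/2m)^2]; t = 1 recovers Newman Q.

Self-loops follow the usual weighted-graph convention (a loop of weight r
adds 2r to its node's strength).

Soft covers come from link communities: edges are clustered by
single-linkage on the Jaccard similarity of their endpoint neighbourhoods,
the dendrogram is cut at the level maximising partition density, and edge
communities are projected onto nodes, so nodes incident to edges from
several edge communities acquire multiple memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrices import ConnectomeMatrix, as_weights

__all__ = [
    "HARD_CRITERIA",
    "DEFAULT_SCALES",
    "AlgoSpec",
    "HardPartition",
    "SoftCover",
    "PartitionQuality",
    "criterion_value",
    "greedy_multiscale_partition",
    "detect_soft_cover",
    "detect",
    "detect_components",
]

HARD_CRITERIA = ("newman", "afg", "rb", "rn", "stability")

#: Default resolution/scale per criterion.  Each choice reduces to (or sits
#: near) plain Newman modularity, matching single-partition-per-algorithm
#: usage; scale scanning is available through the ``scale`` arguments.
DEFAULT_SCALES: dict[str, float] = {
    "newman": 1.0,
    "rb": 1.0,
    "rn": 0.25,
    "afg": 0.0,
    "stability": 1.0,
}

#: Community-detection algorithm registry: public name -> (criterion, soft).
ALGORITHMS: dict[str, tuple[str | None, bool]] = {
    "newman": ("newman", False),
    "mscd_afg": ("afg", False),
    "mscd_rb": ("rb", False),
    "mscd_rn": ("rn", False),
    "mscd_so": ("stability", False),
    "soft_link": (None, True),
}


@dataclass(frozen=True)
class AlgoSpec:
    """A community-detection algorithm choice: name, scale and seed."""

    name: str
    scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; "
                             f"registered: {sorted(ALGORITHMS)}")

    @property
    def soft(self) -> bool:
        return ALGORITHMS[self.name][1]

    @property
    def criterion(self) -> str | None:
        return ALGORITHMS[self.name][0]

    @property
    def effective_scale(self) -> float:
        if self.soft:
            return float("nan")
        return DEFAULT_SCALES[self.criterion] if self.scale is None else self.scale


@dataclass
class HardPartition:
    """One community id per node; ids are contiguous starting at 1."""

    labels: list[int]
    algorithm: str = ""
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.labels = _canonical_labels(np.asarray(self.labels)).tolist()

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return max(self.labels) if self.labels else 0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


@dataclass
class SoftCover:
    """Node x community binary membership matrix; every node is covered."""

    membership: np.ndarray
    algorithm: str = ""

    def __post_init__(self) -> None:
        M = np.asarray(self.membership)
        if M.ndim != 2 or M.shape[1] < 1:
            raise ValueError("membership must be an n x k matrix with k >= 1")
        if np.any(M.sum(axis=1) < 1):
            raise ValueError("every node must belong to at least one community")
        self.membership = (M > 0).astype(int)

    @property
    def n_nodes(self) -> int:
        return self.membership.shape[0]

    @property
    def n_communities(self) -> int:
        return self.membership.shape[1]


@dataclass
class PartitionQuality:
    Q: float
    criterion: str
    scale: float


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as 1..k in order of first appearance."""
    out = np.empty(labels.shape, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping) + 1)
    return out


def _partition_labels(partition) -> np.ndarray:
    if isinstance(partition, HardPartition):
        return partition.as_array()
    return np.asarray(partition, dtype=int)


def criterion_value(W, partition, criterion: str, scale: float | None = None) -> float:
    """Evaluate a partition-quality criterion (see module docstring)."""
    if criterion not in HARD_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {HARD_CRITERIA}")
    A = as_weights(W)
    labels = _partition_labels(partition)
    n = A.shape[0]
    if labels.shape[0] != n:
        raise ValueError("partition does not cover all nodes")
    scale = DEFAULT_SCALES[criterion] if scale is None else float(scale)

    two_m = A.sum()
    strengths = A.sum(axis=1)
    comms = np.unique(labels)

    if criterion == "rn":
        gamma = scale
        value = 0.0
        present = A > 0
        for c in comms:
            idx = labels == c
            n_c = int(idx.sum())
            S_c = A[np.ix_(idx, idx)].sum()
            adj_pairs = int(present[np.ix_(idx, idx)].sum())
            zero_pairs = n_c * (n_c - 1) - adj_pairs
            value += S_c - gamma * zero_pairs
        return float(value / two_m)

    tau, gamma, rr, const = {
        "newman": (1.0, 1.0, 0.0, 0.0),
        "rb": (1.0, scale, 0.0, 0.0),
        "afg": (1.0, 1.0, 2.0 * scale, 0.0),
        "stability": (scale, 1.0, 0.0, 1.0 - scale),
    }[criterion]
    M = two_m + n * rr
    value = const
    for c in comms:
        idx = labels == c
        n_c = int(idx.sum())
        S_c = A[np.ix_(idx, idx)].sum() + n_c * rr
        D_c = strengths[idx].sum() + n_c * rr
        value += (tau * S_c - gamma * D_c**2 / M) / M
    return float(value)


class _Level:
    """One aggregation level of the greedy optimiser.

    ``W`` is the supernode adjacency (diagonal = internal ordered-pair
    weight), ``E`` the ordered adjacent-pair counts (needed by the Potts
    criterion) and ``sizes`` the number of original nodes per supernode.
    """

    def __init__(self, W: np.ndarray, E: np.ndarray, sizes: np.ndarray):
        self.W = W
        self.E = E
        self.sizes = sizes
        self.k = W.shape[0]


def _local_moves(
    level: _Level,
    params: dict,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy node-to-community moves until no positive gain remains."""
    k = level.k
    W, E, sizes = level.W, level.E, level.sizes
    comm = np.arange(k) if init is None else init.copy()
    crit = params["criterion"]

    if crit == "rn":
        gamma, two_m = params["gamma"], params["two_m"]
        # original nodes per community
        comm_nodes = np.bincount(comm, weights=sizes, minlength=k)
    else:
        tau, gamma, rr, M = params["tau"], params["gamma"], params["rr"], params["M"]
        # row sums include the diagonal (internal ordered-pair weight), which
        # is exactly the loops-count-twice strength convention
        K = W.sum(axis=1) + sizes * rr
        comm_K = np.bincount(comm, weights=K, minlength=k)

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(k):
            a = comm[i]
            w_row = W[i].copy()
            w_row[i] = 0.0
            # candidate communities: neighbours plus the current one
            w_to = np.bincount(comm, weights=w_row, minlength=k)
            cands = np.unique(np.concatenate((comm[w_row > 0], [a])))
            if crit == "rn":
                e_row = E[i].astype(float).copy()
                e_row[i] = 0.0
                e_to = np.bincount(comm, weights=e_row, minlength=k)
                s_i = sizes[i]
                comm_nodes[a] -= s_i

                def gain(c):
                    # ordered pairs gained: 2 s_i n_c total, 2 e_to[c] adjacent
                    return (2 * w_to[c]
                            - gamma * (2 * s_i * comm_nodes[c] - 2 * e_to[c])) / two_m

                best_c, best_g = a, gain(a)
                for c in cands:
                    g = gain(c)
                    if g > best_g + 1e-12 or (abs(g - best_g) <= 1e-12 and c < best_c):
                        best_c, best_g = c, g
                comm_nodes[best_c] += s_i
            else:
                K_i = K[i]
                comm_K[a] -= K_i

                def gain(c):
                    return (tau * 2 * w_to[c] - gamma * 2 * K_i * comm_K[c] / M) / M

                best_c, best_g = a, gain(a)
                for c in cands:
                    g = gain(c)
                    if g > best_g + 1e-12 or (abs(g - best_g) <= 1e-12 and c < best_c):
                        best_c, best_g = c, g
                comm_K[best_c] += K_i
            if best_c != a:
                comm[i] = best_c
                improved = True
    return comm


def _aggregate(level: _Level, comm: np.ndarray) -> tuple[_Level, np.ndarray]:
    uniq, inv = np.unique(comm, return_inverse=True)
    k_new = uniq.size
    P = np.zeros((level.k, k_new))
    P[np.arange(level.k), inv] = 1.0
    W_new = P.T @ level.W @ P
    E_new = P.T @ level.E @ P
    sizes_new = P.T @ level.sizes
    return _Level(W_new, E_new, sizes_new), inv


def _move_deltas(A: np.ndarray, E0: np.ndarray, comm: np.ndarray, params: dict):
    """Vectorised move gains at node level.

    Returns (delta, delta_empty): ``delta[i, c]`` is the objective change of
    moving node i to community c, ``delta_empty[i]`` of isolating node i into
    a fresh community.  Moves to the current community score 0 by definition.
    """
    n = A.shape[0]
    k = int(comm.max()) + 1
    onehot = np.zeros((n, k))
    onehot[np.arange(n), comm] = 1.0
    Wnc = A @ onehot
    crit = params["criterion"]
    if crit == "rn":
        gamma, two_m = params["gamma"], params["two_m"]
        sizes_c = np.bincount(comm, minlength=k).astype(float)
        n_excl = sizes_c[None, :] - onehot
        Enc = E0 @ onehot
        g = (2 * Wnc - gamma * (2 * n_excl - 2 * Enc)) / two_m
    else:
        tau, gamma, rr, M = params["tau"], params["gamma"], params["rr"], params["M"]
        K = A.sum(axis=1) + rr
        comm_K = np.bincount(comm, weights=K, minlength=k)
        D_excl = comm_K[None, :] - K[:, None] * onehot
        g = (tau * 2 * Wnc - gamma * 2 * K[:, None] * D_excl / M) / M
    g_own = g[np.arange(n), comm]
    return g - g_own[:, None], -g_own


def _kl_refine(A: np.ndarray, E0: np.ndarray, labels: np.ndarray, params: dict) -> np.ndarray:
    """Kernighan-Lin style refinement: one tentative move per node per pass,
    locking moved nodes and allowing downhill steps, then reverting to the
    best configuration seen.  Escapes single-move local optima such as
    balanced splits of chain-like graphs.  Deterministic (first-best ties).
    """
    n = A.shape[0]
    labels = labels.copy()
    while True:
        comm = labels.copy()
        locked = np.zeros(n, dtype=bool)
        gain = 0.0
        best_gain = 0.0
        best_snapshot = None
        for _ in range(n):
            delta, delta_empty = _move_deltas(A, E0, comm, params)
            sizes_c = np.bincount(comm)
            delta[np.arange(n), comm] = -np.inf  # staying is not a move
            delta[locked] = -np.inf
            delta_empty[locked | (sizes_c[comm] == 1)] = -np.inf
            full = np.column_stack([delta, delta_empty])
            flat = np.argmax(full)
            i, c = divmod(flat, full.shape[1])
            if not np.isfinite(full[i, c]):
                break
            gain += full[i, c]
            comm[i] = int(comm.max()) + 1 if c == delta.shape[1] else c
            # keep labels compact so the delta matrices stay small
            comm = np.unique(comm, return_inverse=True)[1]
            locked[i] = True
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_snapshot = comm.copy()
        if best_snapshot is None:
            return labels
        labels = best_snapshot


def greedy_multiscale_partition(
    W,
    criterion: str = "newman",
    scale: float | None = None,
    seed: int = 0,
) -> tuple[HardPartition, PartitionQuality]:
    """Greedy maximisation of a multi-scale quality criterion.

    Two-phase Louvain scheme (local node moves, then community
    aggregation, repeated until stable) followed by alternating node-level
    sweeps and Kernighan-Lin refinement passes until neither improves.
    The sweep order of local moves is shuffled by ``seed``; with a fixed
    seed the result is deterministic.  Gain ties break toward the lowest
    community id.  The all-in-one and all-singleton partitions are checked
    as baselines, so the returned partition never scores below either.
    """
    cm = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(as_weights(W))
    if not cm.is_connected():
        raise ValueError("community detection expects a connected graph")
    if criterion not in HARD_CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    scale = DEFAULT_SCALES[criterion] if scale is None else float(scale)
    A = cm.weights
    n = A.shape[0]
    two_m = A.sum()
    rng = np.random.default_rng(seed)

    if criterion == "rn":
        params = {"criterion": "rn", "gamma": scale, "two_m": two_m}
    else:
        tau, gamma, rr = {
            "newman": (1.0, 1.0, 0.0),
            "rb": (1.0, scale, 0.0),
            "afg": (1.0, 1.0, 2.0 * scale),
            "stability": (scale, 1.0, 0.0),
        }[criterion]
        params = {"criterion": criterion, "tau": tau, "gamma": gamma,
                  "rr": rr, "M": two_m + n * rr}

    # level-0 state: W diagonal zero, E = ordered adjacent-pair indicators
    level = _Level(A.copy(), (A > 0).astype(float), np.ones(n))
    assignment = np.arange(n)
    while True:
        comm = _local_moves(level, params, rng)
        if np.unique(comm).size == level.k:
            break
        level, inv = _aggregate(level, comm)
        assignment = inv[assignment]
        if level.k == 1:
            break

    # refinement at node level: alternate greedy sweeps and KL passes
    level0 = _Level(A.copy(), (A > 0).astype(float), np.ones(n))
    comm = np.unique(assignment, return_inverse=True)[1]
    value = criterion_value(A, comm + 1, criterion, scale)
    for _ in range(20):
        swept = _local_moves(level0, params, rng, init=comm)
        swept = np.unique(swept, return_inverse=True)[1]
        refined = _kl_refine(A, level0.E, swept, params)
        refined = np.unique(refined, return_inverse=True)[1]
        new_value = criterion_value(A, refined + 1, criterion, scale)
        if new_value <= value + 1e-12:
            break
        comm, value = refined, new_value

    labels = _canonical_labels(comm)
    candidates = [labels, np.ones(n, dtype=int), np.arange(1, n + 1)]
    values = [criterion_value(A, lab, criterion, scale) for lab in candidates]
    labels = candidates[int(np.argmax(values))]
    Q = max(values)
    part = HardPartition(labels.tolist(), algorithm=criterion, scale=scale)
    return part, PartitionQuality(float(Q), criterion, scale)


def _partition_density(edge_labels: np.ndarray, edges: list[tuple[int, int]]) -> float:
    M = len(edges)
    total = 0.0
    for c in np.unique(edge_labels):
        members = [edges[i] for i in np.flatnonzero(edge_labels == c)]
        m_c = len(members)
        nodes = {u for e in members for u in e}
        n_c = len(nodes)
        if n_c > 2:
            total += m_c * (m_c - n_c + 1) / ((n_c - 2) * (n_c - 1) / 2)
    return 2.0 / M * total / 2.0 if M else 0.0


def detect_soft_cover(W, threshold: float | None = None, seed: int = 0) -> SoftCover:
    """Link-community soft cover (see module docstring).

    ``threshold``: optional explicit dendrogram cut height (a distance in
    [0, 1]); by default the cut maximising partition density is used.  The
    ``seed`` argument is accepted for interface uniformity; the construction
    is deterministic.
    """
    cm = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(as_weights(W))
    if not cm.is_connected():
        raise ValueError("soft cover detection expects a connected graph")
    A = cm.weights
    n = A.shape[0]
    iu, ju = np.nonzero(np.triu(A, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    m = len(edges)
    if m < 2:
        return SoftCover(np.ones((n, 1), dtype=int), algorithm="soft_link")

    nbr = [set(np.nonzero(A[i])[0].tolist()) | {i} for i in range(n)]
    D = np.ones((m, m))
    np.fill_diagonal(D, 0.0)
    incident: list[list[int]] = [[] for _ in range(n)]
    for idx, (u, v) in enumerate(edges):
        incident[u].append(idx)
        incident[v].append(idx)
    for node in range(n):
        inc = incident[node]
        for x in range(len(inc)):
            for y in range(x + 1, len(inc)):
                e1, e2 = inc[x], inc[y]
                a = edges[e1][0] if edges[e1][1] == node else edges[e1][1]
                b = edges[e2][0] if edges[e2][1] == node else edges[e2][1]
                jac = len(nbr[a] & nbr[b]) / len(nbr[a] | nbr[b])
                d = 1.0 - jac
                if d < D[e1, e2]:
                    D[e1, e2] = D[e2, e1] = d

    Z = linkage(squareform(D, checks=False), method="single")
    if threshold is not None:
        edge_labels = fcluster(Z, t=threshold, criterion="distance")
    else:
        heights = np.unique(np.concatenate(([0.0], Z[:, 2])))
        best_labels, best_density = None, -np.inf
        for h in heights:
            lab = fcluster(Z, t=h, criterion="distance")
            dens = _partition_density(lab, edges)
            if dens > best_density:
                best_density, best_labels = dens, lab
        edge_labels = best_labels

    comm_ids = {c: i for i, c in enumerate(np.unique(edge_labels))}
    membership = np.zeros((n, len(comm_ids)), dtype=int)
    for idx, (u, v) in enumerate(edges):
        c = comm_ids[edge_labels[idx]]
        membership[u, c] = 1
        membership[v, c] = 1
    return SoftCover(membership, algorithm="soft_link")


def detect_components(W, spec: AlgoSpec, seed: int | None = None) -> HardPartition:
    """Hard detection on a possibly-disconnected graph, per component.

    Thresholded construction schemes can disconnect a sparse graph; each
    connected component is then partitioned separately (isolated nodes get
    their own community) and the labels concatenated.  On a connected graph
    this equals ``detect``.
    """
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import connected_components

    if spec.soft:
        raise ValueError("detect_components handles hard algorithms only")
    cm = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(as_weights(W))
    n_comp, comp = connected_components(csr_array(cm.weights), directed=False)
    if n_comp == 1:
        part, _ = detect(cm, spec, seed=seed)
        return part
    labels = np.zeros(cm.n_nodes, dtype=int)
    offset = 0
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if idx.size == 1:
            labels[idx] = offset + 1
            offset += 1
            continue
        sub = ConnectomeMatrix(cm.weights[np.ix_(idx, idx)])
        part, _ = detect(sub, spec, seed=seed)
        labels[idx] = part.as_array() + offset
        offset = labels.max()
    return HardPartition(labels.tolist(), algorithm=spec.name, scale=spec.effective_scale)


def detect(W, spec: AlgoSpec, seed: int | None = None):
    """Run the algorithm named by ``spec`` on a graph.

    Returns ``(HardPartition, PartitionQuality)`` for hard algorithms and a
    ``SoftCover`` for soft ones.
    """
    seed = spec.seed if seed is None else seed
    if spec.soft:
        return detect_soft_cover(W, seed=seed)
    part, quality = greedy_multiscale_partition(
        W, criterion=spec.criterion, scale=spec.effective_scale, seed=seed
    )
    part.algorithm = spec.name
    return part, quality
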