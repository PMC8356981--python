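"""Synthetic test-retest cohorts of modular weighted graphs.

The real analysis runs on diffusion-MRI connectomes from a test-retest
cohort (each participant scanned twice).  This module emulates the
*statistical* structure that analysis assumes, with known ground truth:

* per-subject weighted planted-partition graphs (dense modules, sparse
  between-module edges, uniform edge weights);
* a nine-metric stack per graph, built as noisy monotone transforms of the
  streamline-count matrix with controllable inter-metric correlation;
* a second "scan session" obtained by perturbing the first with
  multiplicative log-normal weight noise and degree-preserving rewiring.

Nothing here models diffusion physics or anatomy; the generator exists so
that every downstream stage can be exercised against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from ._rewire import double_edge_swap
from .matrices import INVERTED_METRICS, METRIC_NAMES, ConnectomeMatrix, MetricStack

__all__ = [
    "GroundTruthPartition",
    "SessionNoiseSpec",
    "GraphParams",
    "CohortManifest",
    "DEFAULT_SIMILARITY_PROFILE",
    "generate_planted_partition_graph",
    "generate_metric_stack",
    "generate_test_retest_cohort",
]


@dataclass
class GroundTruthPartition:
    """Planted community affiliation: one community id per node (1-based)."""

    labels: list[int]

    def __post_init__(self) -> None:
        labels = [int(x) for x in self.labels]
        uniq = sorted(set(labels))
        if uniq != list(range(1, len(uniq) + 1)):
            raise ValueError("labels must form a contiguous id set starting at 1")
        self.labels = labels

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))


@dataclass(frozen=True)
class SessionNoiseSpec:
    """Between-scan perturbation applied to session-1 graphs.

    ``weight_noise_sd`` is the standard deviation of multiplicative
    log-normal noise on edge weights (0 = identical weights), and
    ``rewire_fraction`` the fraction of edges rewired by degree-preserving
    double-edge swaps (0 = identical topology).
    """

    weight_noise_sd: float = 0.0
    rewire_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be non-negative")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise ValueError("rewire_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GraphParams:
    """Parameters of the planted-partition generator for one subject.

    Defaults give the desk-scale cohort used throughout the test suite:
    40 nodes in 4 equal modules with within/between edge probabilities
    0.8/0.05 and edge weights uniform on [0.5, 1].
    """

    n_nodes: int = 40
    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    p_in: float = 0.8
    p_out: float = 0.05
    weight_low: float = 0.5
    weight_high: float = 1.0


@dataclass
class CohortManifest:
    """In-memory test-retest cohort: (subject, session) -> graph (+ stack)."""

    n_subjects: int
    entries: dict[tuple[int, int], ConnectomeMatrix]
    ground_truth: dict[int, GroundTruthPartition] = field(default_factory=dict)
    stacks: dict[tuple[int, int], MetricStack] = field(default_factory=dict)
    sessions: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        n_nodes = None
        for subject in self.subjects:
            for session in self.sessions:
                if (subject, session) not in self.entries:
                    raise ValueError(f"subject {subject} is missing session {session}")
                m = self.entries[subject, session]
                if n_nodes is None:
                    n_nodes = m.n_nodes
                elif m.n_nodes != n_nodes:
                    raise ValueError("all cohort matrices must share the node count")

    @property
    def subjects(self) -> list[int]:
        return list(range(1, self.n_subjects + 1))

    @property
    def n_nodes(self) -> int:
        return next(iter(self.entries.values())).n_nodes

    def graph(self, subject: int, session: int) -> ConnectomeMatrix:
        return self.entries[subject, session]

    def stack(self, subject: int, session: int) -> MetricStack:
        return self.stacks[subject, session]


def generate_planted_partition_graph(
    n_nodes: int,
    module_sizes: list[int] | tuple[int, ...],
    p_in: float,
    p_out: float,
    weight_low: float = 0.5,
    weight_high: float = 1.0,
    seed: int = 0,
) -> tuple[ConnectomeMatrix, GroundTruthPartition]:
    """Draw a weighted planted-partition graph with known communities.

    Node pairs within a module carry an edge with probability ``p_in``,
    pairs straddling modules with probability ``p_out``; edge weights are
    uniform on [``weight_low``, ``weight_high``].  If the draw is
    disconnected, a minimal set of bridging edges of weight ``weight_low``
    is added (lightest possible repair, so the planted density is disturbed
    as little as possible).
    """
    module_sizes = [int(s) for s in module_sizes]
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module sizes must be positive")
    if sum(module_sizes) != n_nodes:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)}, expected n_nodes={n_nodes}"
        )
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if not (0.0 < weight_low <= weight_high):
        raise ValueError("need 0 < weight_low <= weight_high")

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, len(module_sizes) + 1), module_sizes)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n_nodes, k=1)
    p_edge = np.where(same[iu], p_in, p_out)
    present = rng.random(p_edge.shape) < p_edge
    weights = rng.uniform(weight_low, weight_high, size=p_edge.shape)

    W = np.zeros((n_nodes, n_nodes))
    W[iu] = np.where(present, weights, 0.0)
    W = W + W.T

    # connectedness repair: chain the components together with the lightest
    # admissible edges, joining each component at its smallest node index
    n_comp, comp = connected_components(csr_array(W), directed=False)
    if n_comp > 1:
        reps = [int(np.flatnonzero(comp == c).min()) for c in range(n_comp)]
        reps.sort()
        for u, v in zip(reps[:-1], reps[1:]):
            W[u, v] = W[v, u] = weight_low

    return ConnectomeMatrix(W), GroundTruthPartition(labels.tolist())


#: Target Pearson correlation (in magnitude) between each generated metric
#: and the streamline-count matrix.  Values mimic the empirical pattern that
#: streamline-derived metrics (PS, SLD, TV) track NS closely, microstructural
#: metrics (FA, MD, RD) only moderately, and geometry (TL) weakly; ED is
#: built from node coordinates and takes whatever correlation geometry gives.
DEFAULT_SIMILARITY_PROFILE: dict[str, float] = {
    "FA": 0.6,
    "MD": 0.5,
    "RD": 0.5,
    "PS": 0.9,
    "SLD": 0.8,
    "TV": 0.7,
    "TL": 0.4,
}


def generate_metric_stack(
    base: ConnectomeMatrix,
    similarity_profile: dict[str, float] | None = None,
    seed: int = 0,
) -> MetricStack:
    """Build a nine-metric stack around a base (streamline-count) graph.

    ``NS`` equals the base.  Each metric *m* in the similarity profile is a
    linear mix ``rho * z(base) + sqrt(1 - rho^2) * noise`` over the base's
    edges, mapped affinely to a positive range, so its edge-wise Pearson
    correlation with the base is ``rho`` up to sampling error.  ``MD`` and
    ``RD`` are mixed against the *negated* base (high diffusivity where
    connectivity is weak), so their correlation with NS is ``-rho``.  ``ED``
    is the pairwise Euclidean distance between random 3-D node coordinates,
    restricted to the base's edges.
    """
    profile = dict(DEFAULT_SIMILARITY_PROFILE if similarity_profile is None else similarity_profile)
    needed = [m for m in METRIC_NAMES if m not in ("NS", "ED")]
    missing = [m for m in needed if m not in profile]
    if missing:
        raise ValueError(f"similarity profile is missing metrics {missing}")
    for m in needed:
        if not 0.0 <= profile[m] <= 1.0:
            raise ValueError(f"similarity for {m} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    W = base.weights
    n = base.n_nodes
    iu, ju = np.nonzero(np.triu(W, k=1))
    w = W[iu, ju]
    sd = w.std()
    z = (w - w.mean()) / sd if sd > 0 else np.zeros_like(w)

    def edge_matrix(values: np.ndarray) -> np.ndarray:
        M = np.zeros((n, n))
        M[iu, ju] = values
        return M + M.T

    metrics: dict[str, np.ndarray] = {"NS": W.copy()}
    for name in needed:
        rho = profile[name]
        signal = -z if name in INVERTED_METRICS else z
        eps = rng.standard_normal(w.shape)
        x = rho * signal + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
        # affine map to (0, 1]; Pearson correlation is unchanged
        span = x.max() - x.min()
        x = 0.05 + 0.95 * (x - x.min()) / span if span > 0 else np.full_like(x, 0.5)
        metrics[name] = edge_matrix(x)

    coords = rng.random((n, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    ED = np.where(W > 0, dist, 0.0)
    np.fill_diagonal(ED, 0.0)
    metrics["ED"] = ED

    return MetricStack(metrics, list(base.node_labels))


def _apply_session_noise(
    W: np.ndarray, noise: SessionNoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Rewire a fraction of edges, then jitter weights multiplicatively."""
    out = W.copy()
    n = out.shape[0]
    iu = np.triu_indices(n, k=1)
    n_edges = int(np.count_nonzero(out[iu]))
    if noise.rewire_fraction > 0 and n_edges >= 2:
        # each successful swap rewires two edges (four endpoint changes), so
        # floor keeps the session difference within rewire_fraction
        target_swaps = int(np.floor(noise.rewire_fraction * n_edges / 2))
        out, _ = double_edge_swap(
            out, n_attempts=50 * target_swaps, rng=rng, max_swaps=target_swaps
        )
    if noise.weight_noise_sd > 0:
        factors = np.exp(noise.weight_noise_sd * rng.standard_normal((n, n)))
        factors = np.triu(factors, k=1)
        factors = factors + factors.T
        out = np.where(out > 0, out * factors, 0.0)
    return out


def generate_test_retest_cohort(
    n_subjects: int,
    graph_params: GraphParams | None = None,
    noise: SessionNoiseSpec | None = None,
    seed: int = 0,
    with_stacks: bool = False,
    similarity_profile: dict[str, float] | None = None,
) -> CohortManifest:
    """Generate a cohort of ``n_subjects`` x 2 sessions with ground truth.

    Session 1 is drawn independently per subject from ``graph_params``;
    session 2 is session 1 with ``noise`` applied.  With ``with_stacks``,
    a metric stack is generated for each session; the stack noise seed is
    shared between a subject's two sessions, so zero session noise yields
    byte-identical stacks.  Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    params = graph_params or GraphParams()
    noise = noise or SessionNoiseSpec()

    root = np.random.SeedSequence([int(seed), int(noise.seed)])
    entries: dict[tuple[int, int], ConnectomeMatrix] = {}
    truth: dict[int, GroundTruthPartition] = {}
    stacks: dict[tuple[int, int], MetricStack] = {}
    for subject, child in zip(range(1, n_subjects + 1), root.spawn(n_subjects)):
        graph_seed, noise_seed, stack_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)
        ]
        g1, gt = generate_planted_partition_graph(
            params.n_nodes,
            params.module_sizes,
            params.p_in,
            params.p_out,
            params.weight_low,
            params.weight_high,
            seed=graph_seed,
        )
        w2 = _apply_session_noise(g1.weights, noise, np.random.default_rng(noise_seed))
        g2 = ConnectomeMatrix(w2, list(g1.node_labels))
        entries[subject, 1] = g1
        entries[subject, 2] = g2
        truth[subject] = gt
        if with_stacks:
            stacks[subject, 1] = generate_metric_stack(g1, similarity_profile, seed=stack_seed)
            stacks[subject, 2] = generate_metric_stack(g2, similarity_profile, seed=stack_seed)

    return CohortManifest(n_subjects, entries, truth, stacks)
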