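"""Graph-construction schemes for weighted structural brain networks.

Seven schemes are implemented, named by their edge-weighting and filtering
recipe (symbols A-G):

====  ============  =========================================================
A     NS-OMST       streamline-count graph, OMST topological filter
B     NS+FA-OMST    data-driven integration of NS and FA, then OMST
C     9m-OMST       data-driven integration of all nine metrics, then OMST
D     NS-thr        keep the highest-NS edges at a matched sparsity
E     NS-t/FA-w     D's topology, surviving edges re-weighted with FA
F     NS-t/MD-w     D's topology, surviving edges re-weighted with MD
G     FA-t/NS-w     keep the highest-FA edges, re-weighted with NS
====  ============  =========================================================

The OMST (orthogonal minimal spanning trees) filter repeatedly extracts
edge-disjoint minimum spanning trees on the distance transform d = 1/w and
keeps the union of the first k trees that maximises the global
cost-efficiency J = E_glob - cost, where cost is the fraction of total input
weight retained.  This keeps the graph connected while trading wiring cost
against communication efficiency.

The multi-metric integration combines min-max-rescaled metric matrices in a
linear combination whose coefficients are proportional to each metric's mean
dissimilarity (1 - |Pearson r|) from the other selected metrics, so that
metrics carrying redundant information are down-weighted and complementary
ones up-weighted.  Diffusivity metrics (MD, RD) enter inverted so that
"large value = strong connection" holds for every term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path

from .matrices import INVERTED_METRICS, METRIC_NAMES, ConnectomeMatrix, MetricStack, as_weights

__all__ = [
    "SCHEME_NAMES",
    "OmstResult",
    "global_efficiency",
    "omst_filter",
    "integrate_metrics",
    "threshold_to_sparsity",
    "apply_scheme",
]

#: Scheme symbol -> canonical name (see module docstring).
SCHEME_NAMES: dict[str, str] = {
    "A": "NS-OMST",
    "B": "NS+FA-OMST",
    "C": "9m-OMST",
    "D": "NS-thr",
    "E": "NS-t/FA-w",
    "F": "NS-t/MD-w",
    "G": "FA-t/NS-w",
}
_NAME_TO_SYMBOL = {v: k for k, v in SCHEME_NAMES.items()}


@dataclass
class OmstResult:
    """Outcome of OMST filtering: the filtered graph plus the audit trail."""

    filtered: ConnectomeMatrix
    n_trees_used: int
    cost_efficiency_curve: list[tuple[float, float]]


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """Weight-to-distance transform d = 1/w; absent edges have no distance."""
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, 0.0)
    return D


def global_efficiency(W) -> float:
    """Mean inverse shortest-path length over node pairs (edge length 1/w).

    0 for an edgeless graph, 1 for a complete graph with unit weights.
    """
    W = as_weights(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = shortest_path(csr_array(_distance_matrix(W)), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def omst_filter(W, max_trees: int = 10) -> OmstResult:
    """Topologically filter a connected graph with orthogonal MSTs.

    Round k extracts the minimum spanning tree (on d = 1/w) of the edges not
    used by rounds 1..k-1; rounds stop when the leftover graph no longer
    spans all nodes or ``max_trees`` is reached.  The returned graph is the
    accumulated union with the highest global cost-efficiency
    J = E_glob(union) - sum(union weights)/sum(input weights).
    """
    if max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    cm = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(as_weights(W))
    if not cm.is_connected():
        raise ValueError("OMST filtering requires a connected graph")
    W = cm.weights
    total_weight = W.sum()  # ordered-pair sum; cost is a ratio so convention cancels
    remaining = W.copy()
    accum = np.zeros_like(W)
    curve: list[tuple[float, float]] = []
    best_accum = None
    best_J = -np.inf
    best_k = 0
    for k in range(1, max_trees + 1):
        n_comp, _ = connected_components(csr_array(remaining), directed=False)
        if n_comp > 1:
            break
        tree = minimum_spanning_tree(csr_array(_distance_matrix(remaining))).toarray()
        ti, tj = np.nonzero(tree)
        accum[ti, tj] = W[ti, tj]
        accum[tj, ti] = W[tj, ti]
        remaining[ti, tj] = 0.0
        remaining[tj, ti] = 0.0
        cost = accum.sum() / total_weight
        J = global_efficiency(accum) - cost
        curve.append((float(cost), float(J)))
        if J > best_J:
            best_J = J
            best_accum = accum.copy()
            best_k = k
    filtered = ConnectomeMatrix(best_accum, list(cm.node_labels))
    return OmstResult(filtered, best_k, curve)


def _rescale_unit(M: np.ndarray, invert: bool) -> np.ndarray:
    """Min-max rescale the nonzero entries to [0, 1]; optionally flip them."""
    out = np.zeros_like(M)
    mask = M > 0
    if not mask.any():
        return out
    vals = M[mask]
    lo, hi = vals.min(), vals.max()
    scaled = (vals - lo) / (hi - lo) if hi > lo else np.full_like(vals, 0.5)
    out[mask] = 1.0 - scaled if invert else scaled
    return out


def integrate_metrics(stack: MetricStack, metric_subset: list[str]) -> ConnectomeMatrix:
    """Combine metrics into a single graph, up-weighting complementary ones.

    Each selected metric is min-max rescaled over its edges (MD and RD
    inverted first), then combined as sum_m alpha_m * M_m with alpha_m
    proportional to the mean pairwise dissimilarity 1 - |Pearson r| between
    metric m and the other selected metrics, normalised to sum to 1.
    """
    subset = list(dict.fromkeys(metric_subset))
    if len(subset) < 2:
        raise ValueError("metric integration needs at least 2 metrics")
    unknown = [m for m in subset if m not in METRIC_NAMES]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}")

    rescaled = {m: _rescale_unit(stack[m], m in INVERTED_METRICS) for m in subset}
    support = stack["NS"] > 0
    iu = np.triu_indices(stack.n_nodes, k=1)
    mask = support[iu]
    vectors = {m: rescaled[m][iu][mask] for m in subset}

    k = len(subset)
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = vectors[subset[a]], vectors[subset[b]]
            if va.std() == 0 or vb.std() == 0:
                warnings.warn(
                    f"metric {subset[a] if va.std() == 0 else subset[b]} has zero"
                    " variance over edges; its correlations are taken as 0",
                    stacklevel=2,
                )
                r = 0.0
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            corr[a, b] = corr[b, a] = r
    dissim = 1.0 - np.abs(corr)
    alpha = dissim.sum(axis=1) / (k - 1)  # mean dissimilarity to the others
    alpha = np.ones(k) / k if alpha.sum() == 0 else alpha / alpha.sum()

    combined = np.zeros_like(stack["NS"])
    for weight, m in zip(alpha, subset):
        combined += weight * rescaled[m]
    return ConnectomeMatrix(combined, list(stack.node_labels))


def threshold_to_sparsity(W, target_sparsity: float) -> ConnectomeMatrix:
    """Keep the ceil(target * n(n-1)/2) highest-weight edges.

    Ties at the cutoff are broken by keeping the lexicographically smallest
    (i, j) pairs, so the result is deterministic.
    """
    cm = W if isinstance(W, ConnectomeMatrix) else ConnectomeMatrix(as_weights(W))
    if not 0.0 < target_sparsity <= 1.0:
        raise ValueError("target_sparsity must lie in (0, 1]")
    n = cm.n_nodes
    n_pairs = n * (n - 1) // 2
    n_keep = int(np.ceil(target_sparsity * n_pairs))
    iu, ju = np.triu_indices(n, k=1)
    w = cm.weights[iu, ju]
    nz = np.flatnonzero(w)
    if nz.size < n_keep:
        raise ValueError(
            f"cannot reach sparsity {target_sparsity:g}: need {n_keep} edges"
            f" but only {nz.size} are nonzero (deficit {n_keep - nz.size})"
        )
    order = np.lexsort((ju[nz], iu[nz], -w[nz]))
    keep = nz[order[:n_keep]]
    out = np.zeros_like(cm.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return ConnectomeMatrix(out, list(cm.node_labels))


def _reweight(topology: ConnectomeMatrix, values: np.ndarray) -> np.ndarray:
    return np.where(topology.weights > 0, values, 0.0)


def apply_scheme(scheme: str, stack: MetricStack, reference_sparsity="auto") -> ConnectomeMatrix:
    """Run one of the seven construction schemes on a metric stack.

    ``reference_sparsity`` anchors the thresholded schemes (D-G): a number
    in (0, 1], or ``"auto"`` to match the sparsity of scheme C (the
    nine-metric OMST graph) computed on the same stack.  Outputs are
    max-normalised to 1 with a zero diagonal.
    """
    symbol = scheme if scheme in SCHEME_NAMES else _NAME_TO_SYMBOL.get(scheme)
    if symbol is None:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of "
                         f"{sorted(SCHEME_NAMES) + sorted(_NAME_TO_SYMBOL)}")

    if symbol == "A":
        out = omst_filter(stack.connectome("NS")).filtered
    elif symbol == "B":
        out = omst_filter(integrate_metrics(stack, ["NS", "FA"])).filtered
    elif symbol == "C":
        out = omst_filter(integrate_metrics(stack, list(METRIC_NAMES))).filtered
    else:
        if reference_sparsity == "auto":
            s = apply_scheme("C", stack).sparsity
        else:
            s = float(reference_sparsity)
        if symbol in ("D", "E", "F"):
            topo = threshold_to_sparsity(stack.connectome("NS"), s)
            if symbol == "D":
                out = topo
            else:
                metric = "FA" if symbol == "E" else "MD"
                out = ConnectomeMatrix(_reweight(topo, stack[metric]), list(stack.node_labels))
        else:  # G
            topo = threshold_to_sparsity(ConnectomeMatrix(stack["FA"].copy()), s)
            out = ConnectomeMatrix(_reweight(topo, stack["NS"]), list(stack.node_labels))
    return out.normalized()
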