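"""Degree-preserving double-edge swaps on weighted graphs.

A double-edge swap replaces edges (a, b) and (c, d) by (a, d) and (c, b),
which preserves every node's degree.  Weights travel with their edge, so the
weight multiset is preserved as well.  Swaps that would create multi-edges,
self-loops or disconnect the graph are rejected, keeping the output in the
same graph family as the input (simple, connected, weighted).
"""

from __future__ import annotations

import numpy as np


def _is_connected_adj(adj: list[set[int]]) -> bool:
    n = len(adj)
    seen = bytearray(n)
    stack = [0]
    seen[0] = 1
    count = 1
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if not seen[v]:
                seen[v] = 1
                count += 1
                stack.append(v)
    return count == n


def double_edge_swap(
    W: np.ndarray,
    n_attempts: int,
    rng: np.random.Generator,
    max_swaps: int | None = None,
    keep_connected: bool = True,
) -> tuple[np.ndarray, int]:
    """Apply up to ``max_swaps`` successful swaps within ``n_attempts`` tries.

    Returns the rewired weight matrix and the number of swaps performed.
    """
    W = W.copy()
    n = W.shape[0]
    iu, ju = np.nonzero(np.triu(W, k=1))
    edges = [(int(i), int(j)) for i, j in zip(iu, ju)]
    if len(edges) < 2:
        return W, 0
    adj: list[set[int]] = [set(np.nonzero(W[i])[0].tolist()) for i in range(n)]
    n_swapped = 0
    limit = max_swaps if max_swaps is not None else n_attempts
    for _ in range(int(n_attempts)):
        if n_swapped >= limit:
            break
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.integers(0, 2):
            c, d = d, c
        # proposed: (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        w1, w2 = W[a, b], W[c, d]
        for u, v in ((a, b), (c, d)):
            W[u, v] = W[v, u] = 0.0
            adj[u].discard(v)
            adj[v].discard(u)
        W[a, d] = W[d, a] = w1
        W[c, b] = W[b, c] = w2
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        if keep_connected and not _is_connected_adj(adj):
            # revert
            W[a, d] = W[d, a] = 0.0
            W[c, b] = W[b, c] = 0.0
            adj[a].discard(d); adj[d].discard(a)
            adj[c].discard(b); adj[b].discard(c)
            W[a, b] = W[b, a] = w1
            W[c, d] = W[d, c] = w2
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)
            continue
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        n_swapped += 1
    return W, n_swapped
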