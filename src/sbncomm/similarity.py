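"""Agreement between community structures.

Hard-partition agreement uses normalised mutual information,
NMI = 2 I(X;Y) / (H(X) + H(Y)), computed from the label co-occurrence
contingency table (scikit-learn's arithmetic-mean normalisation).  Covers
are compared with the Lancichinetti-Fortunato-Kertesz normalised mutual
information for overlapping communities, built from best-matching binary
membership vectors.

Significance of an observed between-scan NMI is assessed against a
resampling null that permutes the node-to-label assignment of one
partition: community sizes are preserved while node correspondence is
destroyed.  p-values use the add-one convention p = (1 + b) / (B + 1) so
they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from .detection import SoftCover, _partition_labels

__all__ = [
    "SimilarityResult",
    "nmi_hard",
    "nmi_cover",
    "bootstrap_nmi_pvalue",
    "group_between_scan_agreement",
    "group_agreement_pvalue",
]


@dataclass
class SimilarityResult:
    nmi: float
    p_value: float | None = None
    n_resamples: int | None = None


def nmi_hard(p1, p2, average_method: str = "arithmetic") -> float:
    """NMI between two hard partitions, in [0, 1].

    Symmetric and invariant to community relabelling.  When both partitions
    are a single community (both entropies zero) the partitions carry the
    same (absent) information and the value is defined as 1.
    """
    a = _partition_labels(p1)
    b = _partition_labels(p2)
    if a.shape != b.shape:
        raise ValueError(f"partition lengths differ: {a.shape[0]} vs {b.shape[0]}")
    if np.unique(a).size == 1 and np.unique(b).size == 1:
        return 1.0
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def _h(p: float) -> float:
    return 0.0 if p <= 0.0 else -p * np.log2(p)


def _lfk_conditional(X: np.ndarray, Y: np.ndarray) -> float:
    """Normalised conditional entropy H(X|Y) of cover X given cover Y.

    For each community (column) of X, the best-matching column of Y is the
    one minimising H(x|y), considered only when the joint distribution
    satisfies h(1,1) + h(0,0) >= h(0,1) + h(1,0); otherwise Y carries no
    admissible information about x and H(x) is used.  Each term is
    normalised by H(x) and the mean over X's communities returned.
    """
    n = X.shape[0]
    terms = []
    for k in range(X.shape[1]):
        x = X[:, k]
        px = x.mean()
        Hx = _h(px) + _h(1 - px)
        if Hx == 0.0:
            continue
        best = Hx
        for l in range(Y.shape[1]):
            y = Y[:, l]
            p11 = np.mean(x & y)
            p10 = np.mean(x & ~y)
            p01 = np.mean(~x & y)
            p00 = 1.0 - p11 - p10 - p01
            if _h(p11) + _h(p00) < _h(p01) + _h(p10):
                continue
            py = y.mean()
            Hy = _h(py) + _h(1 - py)
            Hxy = _h(p11) + _h(p10) + _h(p01) + _h(p00)
            best = min(best, Hxy - Hy)
        terms.append(best / Hx)
    return float(np.mean(terms)) if terms else 0.0


def nmi_cover(c1: SoftCover, c2: SoftCover) -> float:
    """Lancichinetti-Fortunato-Kertesz NMI between two covers, in [0, 1].

    1 - [H(C1|C2)_norm + H(C2|C1)_norm] / 2.  Note this normalisation is
    not numerically identical to the contingency-table NMI even when both
    covers are hard partitions, though the two agree closely for similar
    partitions.
    """
    X = np.asarray(c1.membership, dtype=bool)
    Y = np.asarray(c2.membership, dtype=bool)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("covers must share the node count")
    if X.size == 0 or Y.size == 0:
        raise ValueError("empty cover")
    value = 1.0 - 0.5 * (_lfk_conditional(X, Y) + _lfk_conditional(Y, X))
    return float(min(1.0, max(0.0, value)))


def bootstrap_nmi_pvalue(
    p1, p2, n_resamples: int = 999, seed: int = 0
) -> SimilarityResult:
    """Permutation significance of the NMI between two hard partitions.

    The null shuffles the node-to-label assignment of ``p2`` (preserving
    its community-size profile) ``n_resamples`` times;
    p = (1 + #{null NMI >= observed}) / (n_resamples + 1).
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    a = _partition_labels(p1)
    b = _partition_labels(p2)
    observed = nmi_hard(a, b)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_resamples):
        if nmi_hard(a, rng.permutation(b)) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_resamples + 1)
    return SimilarityResult(nmi=observed, p_value=float(p), n_resamples=n_resamples)


def group_between_scan_agreement(cohort_partitions: dict) -> float:
    """Mean over subjects of the NMI between session-1 and session-2 partitions.

    ``cohort_partitions`` maps (subject, session) -> HardPartition with
    sessions labelled 1 and 2.
    """
    subjects = sorted({s for s, _ in cohort_partitions})
    values = []
    for s in subjects:
        if (s, 1) not in cohort_partitions or (s, 2) not in cohort_partitions:
            raise ValueError(f"subject {s} is missing a session")
        values.append(nmi_hard(cohort_partitions[s, 1], cohort_partitions[s, 2]))
    if not values:
        raise ValueError("no subjects supplied")
    return float(np.mean(values))


def group_agreement_pvalue(
    cohort_partitions: dict, n_resamples: int = 999, seed: int = 0
) -> SimilarityResult:
    """Permutation significance of the group-averaged between-scan NMI.

    The null permutes every subject's session-2 node-to-label assignment
    independently and recomputes the group mean.
    """
    if n_resamples < 100:
        raise ValueError("need at least 100 resamples")
    subjects = sorted({s for s, _ in cohort_partitions})
    pairs = [
        (_partition_labels(cohort_partitions[s, 1]), _partition_labels(cohort_partitions[s, 2]))
        for s in subjects
    ]
    observed = float(np.mean([nmi_hard(a, b) for a, b in pairs]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_resamples):
        null = float(np.mean([nmi_hard(a, rng.permutation(b)) for a, b in pairs]))
        if null >= observed:
            exceed += 1
    p = (1 + exceed) / (n_resamples + 1)
    return SimilarityResult(nmi=observed, p_value=float(p), n_resamples=n_resamples)
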