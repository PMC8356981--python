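"""Modular hub cartography: participation coefficient, within-module
z-score, connector/provincial hub roles and their test-retest agreement.

For node i with strength k_i and strength kappa_is towards module s, the
participation coefficient is

    P_i = 1 - sum_s (kappa_is / k_i)^2,

0 when all of a node's strength stays inside its own module and
approaching 1 as the strength spreads evenly over many modules.  The
within-module z-score standardises a node's within-module strength against
the mean and standard deviation of its module.  Both use weighted
(strength-based) quantities, consistent with weighted connectomes.

Hubs are nodes with z >= z_hub; hubs with P above p_connector are
connector hubs, the rest provincial.  The defaults (z_hub = 2.5,
p_connector = 0.30) follow the classic cartographic role taxonomy.

The agreement index of a hub role is, per node, the fraction of subjects
for which the node holds that role in *both* scan sessions; a node is a
consistent hub of the cohort only when the index equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import _partition_labels
from .matrices import as_weights

__all__ = [
    "NodalModularMetrics",
    "HubAssignment",
    "AgreementVector",
    "participation_coefficient",
    "within_module_zscore",
    "nodal_modular_metrics",
    "classify_hubs",
    "agreement_index",
]

HUB_ROLES = ("connector", "provincial", "none")


@dataclass
class NodalModularMetrics:
    """Per-node participation coefficient P and within-module z-score z."""

    P: np.ndarray
    z: np.ndarray


@dataclass
class HubAssignment:
    """Per-node hub role: 'connector', 'provincial' or 'none'."""

    roles: list[str]

    def __post_init__(self) -> None:
        bad = [r for r in self.roles if r not in HUB_ROLES]
        if bad:
            raise ValueError(f"invalid roles {set(bad)}")

    def mask(self, role: str) -> np.ndarray:
        return np.asarray([r == role for r in self.roles])


@dataclass
class AgreementVector:
    values: np.ndarray
    role_assessed: str

    def consistent_nodes(self) -> np.ndarray:
        """Indices of nodes with agreement exactly 1."""
        return np.flatnonzero(self.values >= 1.0)


def participation_coefficient(W, partition) -> np.ndarray:
    """P_i = 1 - sum_s (kappa_is / k_i)^2 on node strengths, in [0, 1].

    Isolated nodes (zero strength) get P = 0 by convention.
    """
    A = as_weights(W)
    labels = _partition_labels(partition)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("partition length does not match the node count")
    strengths = A.sum(axis=1)
    P = np.zeros(A.shape[0])
    nz = strengths > 0
    frac_sq = np.zeros(A.shape[0])
    for c in np.unique(labels):
        kappa = A[:, labels == c].sum(axis=1)
        frac_sq[nz] += (kappa[nz] / strengths[nz]) ** 2
    P[nz] = 1.0 - frac_sq[nz]
    return P


def within_module_zscore(W, partition) -> np.ndarray:
    """z_i = (kappa_i - mean_module) / sd_module on within-module strengths.

    Modules whose within-module strengths have zero standard deviation
    assign z = 0 to all members.
    """
    A = as_weights(W)
    labels = _partition_labels(partition)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("partition length does not match the node count")
    z = np.zeros(A.shape[0])
    for c in np.unique(labels):
        idx = labels == c
        kappa = A[np.ix_(idx, idx)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            z[idx] = (kappa - kappa.mean()) / sd
    return z


def nodal_modular_metrics(W, partition) -> NodalModularMetrics:
    return NodalModularMetrics(
        P=participation_coefficient(W, partition),
        z=within_module_zscore(W, partition),
    )


def classify_hubs(
    metrics: NodalModularMetrics, z_hub: float = 2.5, p_connector: float = 0.30
) -> HubAssignment:
    """Threshold-based hub roles: hub iff z >= z_hub (boundary included);
    among hubs, connector iff P > p_connector, otherwise provincial."""
    roles = []
    for P_i, z_i in zip(metrics.P, metrics.z):
        if z_i >= z_hub:
            roles.append("connector" if P_i > p_connector else "provincial")
        else:
            roles.append("none")
    return HubAssignment(roles)


def agreement_index(assignments: dict, role: str) -> AgreementVector:
    """Cross-cohort agreement of a hub role, per node, on the grid
    {0, 1/n_subjects, ..., 1}.

    ``assignments`` maps (subject, session) -> HubAssignment; a subject
    counts towards a node only when the node holds ``role`` in both of the
    subject's sessions.
    """
    if role not in ("connector", "provincial"):
        raise ValueError("role must be 'connector' or 'provincial'")
    subjects = sorted({s for s, _ in assignments})
    if not subjects:
        raise ValueError("no assignments supplied")
    counts = None
    for s in subjects:
        if (s, 1) not in assignments or (s, 2) not in assignments:
            raise ValueError(f"subject {s} is missing a session")
        both = assignments[s, 1].mask(role) & assignments[s, 2].mask(role)
        counts = both.astype(int) if counts is None else counts + both
    return AgreementVector(counts / len(subjects), role_assessed=role)
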