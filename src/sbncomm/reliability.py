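"""Test-retest reliability statistics and pair ranking.

ICC follows the two-way random-effects, absolute-agreement, single-
measurement model ICC(2,1):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

with n subjects as rows and k = 2 sessions as columns.  The factorial
comparison of graph-construction schemes and community-detection
algorithms uses a standard fixed-effects two-way ANOVA with interaction;
p-values are reported raw and Bonferroni-adjusted across the three
effects.

A (scheme, algorithm) pair is *selected* when its group-averaged
between-scan NMI exceeds 0.9 with a significant resampling p-value and its
partition quality beats the surrogate null (p < .05); selected pairs are
ranked by consensus-individual similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "IccTable",
    "PairEvaluation",
    "AnovaEffect",
    "icc_two_session",
    "icc_table",
    "anova_two_way",
    "rank_pairs",
    "compare_nodal_values",
]


@dataclass
class IccTable:
    """Per-node ICC values for one nodal metric plus their network average."""

    nodal: np.ndarray
    metric: str

    @property
    def network_average(self) -> float:
        return float(np.mean(self.nodal))


@dataclass
class PairEvaluation:
    """Evaluation record for one (scheme, algorithm) pair."""

    scheme: str
    algorithm: str
    between_scan_nmi: float
    nmi_p: float
    quality_p: float
    consensus_similarity: float
    selected: bool = field(init=False)

    def __post_init__(self) -> None:
        self.selected = (
            self.between_scan_nmi > 0.9 and self.nmi_p < 0.05 and self.quality_p < 0.05
        )

    @property
    def pair_name(self) -> str:
        return f"{self.scheme}/{self.algorithm}"


@dataclass
class AnovaEffect:
    F: float
    df: int
    p: float
    p_bonferroni: float


def icc_two_session(values) -> float:
    """ICC(2,1) for an (n_subjects x 2) table of a nodal metric.

    Degenerate tables (no variance anywhere) are defined as 0: with no
    between-subject variance there is no agreement to attribute.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (n_subjects, 2) table")
    n, k = X.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in ICC table")
    grand = X.mean()
    ss_rows = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom <= 0 or np.isclose(denom, 0.0):
        return 0.0
    return float((ms_r - ms_e) / denom)


def icc_table(session1: np.ndarray, session2: np.ndarray, metric: str = "") -> IccTable:
    """Per-node ICC from (n_subjects x n_nodes) session matrices."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("session matrices must share shape")
    nodal = np.array(
        [icc_two_session(np.column_stack([s1[:, j], s2[:, j]])) for j in range(s1.shape[1])]
    )
    return IccTable(nodal, metric=metric)


def anova_two_way(grid: pd.DataFrame, response: str = "response") -> dict[str, AnovaEffect]:
    """Fixed-effects two-way ANOVA with interaction over a scheme x algorithm grid.

    ``grid`` needs columns ``scheme``, ``algorithm`` and the response, with
    one row per cell replicate and every cell populated.  Returns effects
    keyed 'scheme', 'algorithm' and 'interaction'.
    """
    for col in ("scheme", "algorithm", response):
        if col not in grid.columns:
            raise ValueError(f"grid is missing column {col!r}")
    counts = grid.groupby(["scheme", "algorithm"], observed=True).size()
    n_schemes = grid["scheme"].nunique()
    n_algos = grid["algorithm"].nunique()
    if n_schemes < 2 or n_algos < 2:
        raise ValueError("need at least 2 levels per factor")
    if len(counts) != n_schemes * n_algos:
        raise ValueError("unbalanced design: some scheme x algorithm cells are empty")
    if (counts < 2).any():
        raise ValueError("interaction term needs >= 2 replicates per cell")

    df = grid.rename(columns={response: "_y"})
    if np.ptp(df["_y"].to_numpy()) == 0:
        # constant response: no variance to attribute to any effect
        dfs = {
            "scheme": n_schemes - 1,
            "algorithm": n_algos - 1,
            "interaction": (n_schemes - 1) * (n_algos - 1),
        }
        return {k: AnovaEffect(0.0, v, 1.0, 1.0) for k, v in dfs.items()}
    model = ols("_y ~ C(scheme) * C(algorithm)", data=df).fit()
    table = anova_lm(model, typ=2)
    keys = {
        "scheme": "C(scheme)",
        "algorithm": "C(algorithm)",
        "interaction": "C(scheme):C(algorithm)",
    }
    out = {}
    for name, row in keys.items():
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        out[name] = AnovaEffect(F, int(table.loc[row, "df"]), p, min(1.0, 3 * p))
    return out


def rank_pairs(evaluations: list[PairEvaluation]) -> list[PairEvaluation]:
    """Filter pairs by the selection gates, rank the survivors.

    Order: consensus-individual similarity descending, ties by between-scan
    NMI descending, then lexicographic pair name.
    """
    if not evaluations:
        raise ValueError("no evaluations supplied")
    selected = [e for e in evaluations if e.selected]
    return sorted(
        selected,
        key=lambda e: (-e.consensus_similarity, -e.between_scan_nmi, e.pair_name),
    )


def compare_nodal_values(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two sets of nodal values
    (e.g. the per-node ICC vectors of two pairs); returns (statistic, p)."""
    stat, p = ranksums(np.asarray(a), np.asarray(b))
    return float(stat), float(p)
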