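"""Plain-text input/output.

Matrices are square delimited numeric text with an optional ``#``-prefixed
header row of node labels.  Hard partitions are two-column node,community
tables; covers are multi-row node,community tables.  A cohort is a
directory of matrix files indexed by a tab-separated manifest with columns
subject, session, path and (optionally) ground_truth_path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detection import HardPartition, SoftCover
from .matrices import METRIC_NAMES, ConnectomeMatrix, MetricStack
from .synthetic import CohortManifest, GroundTruthPartition

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_partition",
    "load_partition",
    "save_cover",
    "load_cover",
    "save_cohort",
    "load_cohort",
]


def save_matrix(path, matrix: ConnectomeMatrix | np.ndarray, labels=None) -> None:
    path = Path(path)
    if isinstance(matrix, ConnectomeMatrix):
        labels = matrix.node_labels
        matrix = matrix.weights
    header = " ".join(labels) if labels else ""
    np.savetxt(path, np.asarray(matrix), fmt="%.10g", header=header)


def load_matrix(path) -> ConnectomeMatrix:
    path = Path(path)
    labels = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        fields = first[1:].split()
        labels = fields or None
    W = np.loadtxt(path)
    return ConnectomeMatrix(W, labels)


def save_partition(path, partition: HardPartition) -> None:
    df = pd.DataFrame(
        {"node": np.arange(1, partition.n_nodes + 1), "community": partition.labels}
    )
    df.to_csv(path, index=False)


def load_partition(path, algorithm: str = "", scale: float = 1.0) -> HardPartition:
    df = pd.read_csv(path).sort_values("node")
    return HardPartition(df["community"].tolist(), algorithm=algorithm, scale=scale)


def save_cover(path, cover: SoftCover) -> None:
    nodes, comms = np.nonzero(cover.membership)
    pd.DataFrame({"node": nodes + 1, "community": comms + 1}).to_csv(path, index=False)


def load_cover(path, algorithm: str = "") -> SoftCover:
    df = pd.read_csv(path)
    n = int(df["node"].max())
    k = int(df["community"].max())
    M = np.zeros((n, k), dtype=int)
    M[df["node"].to_numpy() - 1, df["community"].to_numpy() - 1] = 1
    return SoftCover(M, algorithm=algorithm)


def save_cohort(directory, cohort: CohortManifest) -> Path:
    """Write a cohort to ``directory``: matrices, ground truth and manifest.

    Metric stacks, when present, are written one file per metric per
    subject-session.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, session), matrix in sorted(cohort.entries.items()):
        name = f"sub{subject:03d}_ses{session}.txt"
        save_matrix(directory / name, matrix)
        gt_name = ""
        if subject in cohort.ground_truth:
            gt_name = f"sub{subject:03d}_truth.txt"
            np.savetxt(
                directory / gt_name,
                np.asarray(cohort.ground_truth[subject].labels, dtype=int),
                fmt="%d",
            )
        rows.append({"subject": subject, "session": session, "path": name,
                     "ground_truth_path": gt_name})
        if (subject, session) in cohort.stacks:
            stack = cohort.stacks[subject, session]
            for metric in METRIC_NAMES:
                save_matrix(
                    directory / f"sub{subject:03d}_ses{session}_{metric}.txt",
                    stack[metric],
                    stack.node_labels,
                )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path) -> CohortManifest:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", keep_default_na=False)
    entries: dict[tuple[int, int], ConnectomeMatrix] = {}
    truth: dict[int, GroundTruthPartition] = {}
    stacks: dict[tuple[int, int], MetricStack] = {}
    for row in df.itertuples():
        subject, session = int(row.subject), int(row.session)
        entries[subject, session] = load_matrix(base / row.path)
        gt = getattr(row, "ground_truth_path", "")
        if gt and subject not in truth:
            labels = np.loadtxt(base / gt, dtype=int, ndmin=1)
            truth[subject] = GroundTruthPartition(labels.tolist())
        stack_files = {
            m: base / f"sub{subject:03d}_ses{session}_{m}.txt" for m in METRIC_NAMES
        }
        if all(p.exists() for p in stack_files.values()):
            stacks[subject, session] = MetricStack(
                {m: load_matrix(p).weights for m, p in stack_files.items()}
            )
    n_subjects = len({s for s, _ in entries})
    return CohortManifest(n_subjects, entries, truth, stacks)
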