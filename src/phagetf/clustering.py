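"""Greedy identity clustering and all-vs-all pairwise identity matrices.

Mirrors the UCLUST greedy centroid scheme: sequences are processed
longest-first and join the first centroid they match at or above the
identity threshold, otherwise found a new cluster.  Identity is global
(Needleman-Wunsch) with gap columns — terminal gaps included — counted
in the denominator, the convention of pairwise sequence demarcation
(SDT-style) identity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import global_identity
from .io_formats import ProteinRecord


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    threshold: float
    clusters: list  # list[Cluster]
    representatives: dict  # cluster index -> protein_id (longest member)

    def cluster_of(self, protein_id: str) -> int:
        for i, c in enumerate(self.clusters):
            if protein_id in c.member_ids:
                return i
        raise KeyError(protein_id)


def greedy_cluster(seqs: list, threshold: float = 0.9) -> ClusterSet:
    """UCLUST-style greedy clustering at an identity threshold.

    Sequences sorted by length descending (ties: id); each joins the
    first centroid with identity >= threshold, else seeds a new cluster.
    The representative of a cluster is its longest member (ties: lowest
    id) — with length-descending input order this is the centroid itself.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(seqs, key=lambda r: (-len(r.sequence), r.protein_id))
    by_id = {r.protein_id: r for r in order}
    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for cl in clusters:
            centroid = by_id[cl.centroid_id]
            if global_identity(rec.sequence, centroid.sequence) >= threshold:
                cl.member_ids.append(rec.protein_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=rec.protein_id,
                                    member_ids=[rec.protein_id]))
    reps = {}
    for i, cl in enumerate(clusters):
        reps[i] = min(
            cl.member_ids, key=lambda pid: (-len(by_id[pid].sequence), pid)
        )
    return ClusterSet(threshold=threshold, clusters=clusters, representatives=reps)


def representatives(seqs: list, cluster_set: ClusterSet) -> list:
    by_id = {r.protein_id: r for r in seqs}
    return [by_id[pid] for pid in cluster_set.representatives.values()]


@dataclass
class IdentityMatrix:
    labels: list
    values: np.ndarray  # symmetric, diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def identity_matrix(
    seqs: list, group_labels: dict | None = None
) -> tuple[IdentityMatrix, pd.DataFrame]:
    """All-vs-all global identities plus per-source-group summaries.

    ``group_labels`` maps protein_id -> group (defaults to each record's
    ``source_group``).  The summary gives, per group, the median and IQR
    of within-group pairwise identities.
    """
    if len(seqs) < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    labels = [r.protein_id for r in seqs]
    groups = group_labels or {r.protein_id: r.source_group for r in seqs}
    n = len(seqs)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = global_identity(
                seqs[i].sequence, seqs[j].sequence
            )
    rows = []
    for grp in sorted(set(groups.values())):
        idx = [i for i, lab in enumerate(labels) if groups[lab] == grp]
        within = [vals[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]]
        if within:
            q1, med, q3 = np.percentile(within, [25, 50, 75])
            rows.append({"group": grp, "n_seqs": len(idx),
                         "n_pairs": len(within), "median_identity": med,
                         "iqr": q3 - q1})
    return IdentityMatrix(labels, vals), pd.DataFrame(rows)


def identity_long_table(matrix: IdentityMatrix, groups: dict) -> pd.DataFrame:
    """Long-format (a, b, identity, group_a, group_b) table for plotting."""
    rows = []
    for i, a in enumerate(matrix.labels):
        for j in range(i + 1, len(matrix.labels)):
            b = matrix.labels[j]
            rows.append({"a": a, "b": b, "identity": matrix.values[i, j],
                         "group_a": groups.get(a), "group_b": groups.get(b)})
    return pd.DataFrame(rows)
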