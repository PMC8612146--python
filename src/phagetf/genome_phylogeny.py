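"""Alignment-free whole-genome phylogeny.

Genomes are summarized as k-mer frequency profiles, compared pairwise
with the Jensen-Shannon divergence (base-2, so JSD lies in [0, 1]), and
the resulting distance matrix is clustered with the Saitou-Nei
neighbor-joining algorithm (Studier-Keppler Q-criterion).

Defaults: k = 6 (4096 features; standard for phage-genome-scale
alignment-free trees), profiles on the given strand only (a
``canonical`` flag folds in reverse complements), and sqrt-JSD as the
distance.  The square root is the form that is a metric; raw JSD grows
~quadratically in small composition differences, which distorts
additivity and makes neighbor joining ladder intermediate groups, so
the metric form is the default (raw JSD available via ``sqrt=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import GenomeRecord, PhyloTree

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_RC = np.array([3, 2, 1, 0])  # A<->T, C<->G on the 0..3 encoding


@dataclass
class KmerProfile:
    genome_id: str
    k: int
    freq: np.ndarray  # length 4**k, sums to 1

    def __post_init__(self) -> None:
        if abs(float(self.freq.sum()) - 1.0) > 1e-9:
            raise ValueError("k-mer frequencies must sum to 1")


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0) or np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distances must be >= 0 with zero diagonal")


def kmer_profile(genome: GenomeRecord, k: int, canonical: bool = False) -> KmerProfile:
    """Normalized k-mer counts over all windows containing only ACGT.

    Windows containing N are skipped.  With ``canonical=True`` each
    window also contributes its reverse complement, making the profile
    strand-symmetric.
    """
    if not 1 <= k <= 10:
        raise ValueError("k must lie in 1..10")
    if genome.length_bp < k:
        raise ValueError(f"genome {genome.genome_id} shorter than k={k}")
    codes = _CODE[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = windows[(windows >= 0).all(axis=1)]
    if valid.size == 0:
        raise ValueError(f"genome {genome.genome_id} has no N-free window of length {k}")
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = valid @ powers
    counts = np.bincount(idx, minlength=4**k).astype(float)
    if canonical:
        rc_idx = _RC[valid[:, ::-1]] @ powers
        counts += np.bincount(rc_idx, minlength=4**k)
    return KmerProfile(genome.genome_id, k, counts / counts.sum())


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd(p: KmerProfile, q: KmerProfile) -> float:
    """Jensen-Shannon divergence in bits: H(M) - (H(P)+H(Q))/2, M=(P+Q)/2.

    Symmetric and bounded to [0, 1] in base 2; its square root is a
    metric.
    """
    if p.k != q.k:
        raise ValueError(f"mismatched k: {p.k} vs {q.k}")
    m = (p.freq + q.freq) / 2.0
    val = _entropy_bits(m) - (_entropy_bits(p.freq) + _entropy_bits(q.freq)) / 2.0
    return float(min(max(val, 0.0), 1.0))


def jsd_matrix(profiles: list, sqrt: bool = True) -> DistanceMatrix:
    """All-pairs JSD distance matrix; sqrt-JSD (the metric form) by default."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    labels = [p.genome_id for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome ids among profiles")
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = jsd(profiles[i], profiles[j])
            d[i, j] = d[j, i] = np.sqrt(v) if sqrt else v
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Exact on additive distance matrices (topology and branch lengths).
    Q-minimization ties break on the lowest (i, j) index pair; negative
    branch lengths are clamped to 0 with the deficit moved to the
    sibling branch, so output lengths are non-negative.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    nodes = [dendropy.Node(taxon=tns[i]) for i in range(n)]
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minimizers, for determinism
        best = np.argwhere(q <= q.min() + 1e-12)
        ai, aj = min((tuple(sorted(p)) for p in best))
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        vj = dij - vi
        vi, vj = clamp_pair(vi, vj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        # distances from the new node to the remaining taxa
        new_idx = i
        for k in active:
            if k not in (i, j):
                D[new_idx, k] = D[k, new_idx] = max(
                    0.0, 0.5 * (D[i, k] + D[j, k] - dij)
                )
        nodes[new_idx] = parent
        active.remove(j)

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = dendropy.Node()
    for node, v in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        root.add_child(node)
        node.edge.length = max(v, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def edge_bipartitions(tree: PhyloTree) -> list:
    """Leaf-label sets on the child side of every edge (pendant + internal)."""
    sides = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        sides.append(leaves)
    return sides


def cluster_concordance(tree: PhyloTree, metadata) -> dict:
    """Per-cluster monophyly of tree leaves, plus the concordant fraction.

    A cluster is concordant when its leaf set is one side of some edge of
    the unrooted tree.  Clusters with fewer than two leaves in the tree
    are skipped; the report maps cluster label -> bool plus the overall
    fraction under key "fraction".
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    by_cluster: dict[str, set] = {}
    meta = metadata.set_index("genome_id")["cluster"]
    for gid, cl in meta.items():
        if gid in leaf_labels and cl not in (None, "singleton") and cl == cl:
            by_cluster.setdefault(str(cl), set()).add(gid)
    sides = edge_bipartitions(tree)
    side_sets = {frozenset(s) for s in sides}
    side_sets |= {frozenset(leaf_labels - s) for s in sides}
    report: dict = {}
    concordant = 0
    scored = 0
    for cl, members in sorted(by_cluster.items()):
        if len(members) < 2:
            continue
        ok = frozenset(members) in side_sets
        report[cl] = ok
        scored += 1
        concordant += ok
    report["fraction"] = concordant / scored if scored else float("nan")
    return report
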