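"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value from first principles, by a
route independent of the implementation it checks: recursive affine-gap
alignment scoring, covered-position interval union, rank-assignment
enumeration for the Wilcoxon test, and edge enumeration for tree
bipartitions.
"""

import itertools
from functools import lru_cache

import numpy as np
from scipy.stats import rankdata

from phagetf.alignment import BLOSUM62, GAP_EXTEND, GAP_OPEN

NEG = float("-inf")


def _sub(a: str, b: str) -> float:
    return float(BLOSUM62[a][b])


def global_score_oracle(a: str, b: str) -> float:
    """Needleman-Wunsch score by explicit recursion over affine states.

    A gap of length L costs GAP_OPEN + L * GAP_EXTEND, terminal gaps
    included.
    """

    @lru_cache(maxsize=None)
    def g(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            prev = max(g(i - 1, j - 1, s) for s in "MXY")
            return prev + _sub(a[i - 1], b[j - 1])
        if state == "X":  # gap in b (consume a[i-1])
            if i == 0:
                return NEG
            return max(
                g(i - 1, j, "M") - GAP_OPEN - GAP_EXTEND,
                g(i - 1, j, "X") - GAP_EXTEND,
                g(i - 1, j, "Y") - GAP_OPEN - GAP_EXTEND,
            )
        if j == 0:
            return NEG
        return max(
            g(i, j - 1, "M") - GAP_OPEN - GAP_EXTEND,
            g(i, j - 1, "Y") - GAP_EXTEND,
            g(i, j - 1, "X") - GAP_OPEN - GAP_EXTEND,
        )

    return max(g(len(a), len(b), s) for s in "MXY")


def local_score_oracle(a: str, b: str) -> float:
    """Smith-Waterman score by recursion with a zero floor on starts."""

    @lru_cache(maxsize=None)
    def h(i: int, j: int, state: str) -> float:
        if i == 0 or j == 0:
            return NEG
        if state == "M":
            prev = max(
                0.0,
                h(i - 1, j - 1, "M"),
                h(i - 1, j - 1, "X"),
                h(i - 1, j - 1, "Y"),
            )
            return prev + _sub(a[i - 1], b[j - 1])
        if state == "X":
            return max(
                h(i - 1, j, "M") - GAP_OPEN - GAP_EXTEND,
                h(i - 1, j, "X") - GAP_EXTEND,
                h(i - 1, j, "Y") - GAP_OPEN - GAP_EXTEND,
            )
        return max(
            h(i, j - 1, "M") - GAP_OPEN - GAP_EXTEND,
            h(i, j - 1, "Y") - GAP_EXTEND,
            h(i, j - 1, "X") - GAP_OPEN - GAP_EXTEND,
        )

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            for s in "MXY":
                best = max(best, h(i, j, s))
    return best


def merge_oracle(intervals):
    """Union of [start, end) intervals via explicit covered positions."""
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    if not covered:
        return []
    runs = []
    pos = sorted(covered)
    start = prev = pos[0]
    for p in pos[1:]:
        if p != prev + 1:
            runs.append((start, prev + 1))
            start = p
        prev = p
    runs.append((start, prev + 1))
    return runs


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating group assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    sums = [sum(ranks[list(c)]) for c in
            itertools.combinations(range(len(pooled)), n_x)]
    sums = np.array(sums)
    eps = 1e-9
    lo = np.mean(sums <= w_obs + eps)
    hi = np.mean(sums >= w_obs - eps)
    return min(1.0, 2 * min(lo, hi))


def bipartition_sides_oracle(tree):
    """All leaf-label sets separated by some edge, both orientations,
    found by deleting each edge in a networkx copy of the tree."""
    import networkx as nx

    g = nx.Graph()
    labels = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            labels[id(node)] = node.taxon.label
        for child in node.child_nodes():
            g.add_edge(id(node), id(child))
    leaves = set(labels.values())
    sides = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(labels[n] for n in comp if n in labels)
        sides.add(side)
        sides.add(frozenset(leaves - side))
        g.add_edge(u, v)
    return sides
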