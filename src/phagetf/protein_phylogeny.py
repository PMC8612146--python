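"""Gene trees for WhiB/Lsr2 representatives and source-group interleaving.

Trees are neighbor-joining on identity-derived distances (p-distance
1 - identity, or the Poisson correction -ln(identity)).  The
"paraphyly index" of a source group (phage / bacteria / plasmid) is the
number of maximal group-pure edge sides of the unrooted tree: 1 means
the group is monophyletic, larger values mean its leaves are scattered
across that many clades.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .clustering import IdentityMatrix, identity_matrix
from .genome_phylogeny import DistanceMatrix, edge_bipartitions, neighbor_joining
from .io_formats import PhyloTree

logger = logging.getLogger(__name__)


def distance_from_identity(
    matrix: IdentityMatrix, correction: str = "poisson", d_max: float = 5.0
) -> DistanceMatrix:
    """Identity -> evolutionary distance.

    ``p``: d = 1 - identity.  ``poisson``: d = -ln(identity), which
    corrects for multiple substitutions; identity 0 is capped at
    ``d_max`` with a warning.
    """
    if correction not in ("p", "poisson"):
        raise ValueError("correction must be 'p' or 'poisson'")
    vals = np.asarray(matrix.values, dtype=float)
    if correction == "p":
        d = 1.0 - vals
    else:
        with np.errstate(divide="ignore"):
            d = -np.log(np.maximum(vals, 0.0))
        if np.isinf(d).any():
            logger.warning("identity 0 capped at distance %.1f", d_max)
        d = np.minimum(d, d_max)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.labels), d)


def build_gene_tree(
    representatives: list, correction: str = "poisson"
) -> PhyloTree:
    """NJ tree over representative proteins; leaves carry group prefixes."""
    if len(representatives) < 4:
        raise ValueError("gene tree needs at least 4 representatives")
    labeled = []
    for rec in representatives:
        labeled.append(
            type(rec)(
                protein_id=f"{rec.source_group}_{rec.protein_id}",
                sequence=rec.sequence,
                source_group=rec.source_group,
            )
        )
    matrix, _ = identity_matrix(labeled)
    return neighbor_joining(distance_from_identity(matrix, correction))


def source_interleaving(tree: PhyloTree, source_groups: dict) -> pd.DataFrame:
    """Monophyly report per source group on an unrooted tree.

    ``source_groups`` maps leaf label -> group.  For each group the
    number of maximal same-group clades (edge sides whose leaves all
    belong to the group, maximal under inclusion) is reported; these
    clades partition the group's leaves.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = leaves - set(source_groups)
    if missing:
        raise ValueError(f"leaves without source group: {sorted(missing)[:5]}")
    sides = set(edge_bipartitions(tree))
    sides |= {frozenset(leaves - s) for s in sides}
    sides |= {frozenset([lf]) for lf in leaves}  # pendant edges both ways
    rows = []
    for grp in sorted(set(source_groups[lf] for lf in leaves)):
        members = frozenset(lf for lf in leaves if source_groups[lf] == grp)
        pure = [s for s in sides if s and s <= members]
        maximal = [s for s in pure if not any(s < t for t in pure)]
        rows.append(
            {
                "group": grp,
                "n_leaves": len(members),
                "n_clades": len(maximal),
                "monophyletic": len(maximal) == 1,
            }
        )
    return pd.DataFrame(rows)
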