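import numpy as np
import pytest

from phagetf import simulate as sim


@pytest.fixture(scope="session")
def small_collection():
    """2 clusters x 3 genomes, WhiB implants in cluster 0 (1 copy, 20% aa)."""
    cfg = sim.SimulationConfig(
        n_clusters=2,
        genomes_per_cluster=3,
        cluster_gc=[0.50, 0.60],
        implant_plan=[sim.ImplantSpec(0, "whiB-like", 1, 0.2)],
        lifestyle_odds=3.0,
        seed=7,
    )
    return sim.simulate_collection(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree with positive branch lengths plus its
    patristic distance matrix; used as the NJ recovery oracle."""
    import dendropy

    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns[i]) for i in range(n_taxa)]
    # leaf-set bookkeeping for patristic distances
    dist = np.zeros((n_taxa, n_taxa))
    depth = {id(nd): {i: 0.0 for i in [k]} for k, nd in enumerate(nodes)}
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[i], pool[j]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length, b.edge.length = la, lb
        da = {k: v + la for k, v in depth[id(a)].items()}
        db = {k: v + lb for k, v in depth[id(b)].items()}
        for ka, va in da.items():
            for kb, vb in db.items():
                dist[ka, kb] = dist[kb, ka] = va + vb
        depth[id(parent)] = {**da, **db}
        pool = [nd for k, nd in enumerate(pool) if k not in (i, j)] + [parent]
    a, b = pool
    if not a.child_nodes():  # root at an internal node
        a, b = b, a
    lb = float(rng.uniform(0.1, 1.0))
    a.add_child(b)
    b.edge.length = lb
    da = depth[id(a)]
    db = {k: v + lb for k, v in depth[id(b)].items()}
    for ka, va in da.items():
        for kb, vb in db.items():
            dist[ka, kb] = dist[kb, ka] = va + vb
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = a
    tree.is_rooted = False
    return tree, labels, dist
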