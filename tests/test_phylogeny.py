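import numpy as np
import pytest

from dwdkit.phylogeny import (
    DistanceMatrix,
    MotifAlignment,
    bootstrap_support,
    cut_tree_groups,
    neighbor_joining,
    p_distance,
    p_distance_matrix,
    random_additive_tree,
    robinson_foulds,
    tree_bipartitions,
    tree_distance_matrix,
)
from dwdkit.synthetic import random_motif


def test_p_distance_examples():
    assert p_distance("AAAA", "AAAA") == 0.0
    assert p_distance("AAAA", "AAAT") == 0.25


def test_p_distance_x_exclusion_and_errors():
    assert p_distance("AXAA", "AAAT") == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        p_distance("XX", "AA")
    with pytest.raises(ValueError):
        p_distance("AA", "AAA")


def test_p_distance_equals_hand_count(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(1000):
        a = "".join(aas[i] for i in rng.integers(0, 20, 16))
        b = "".join(aas[i] for i in rng.integers(0, 20, 16))
        hamming = sum(1 for x, y in zip(a, b) if x != y) / 16
        assert p_distance(a, b) == hamming


def test_p_distance_matrix_metric_properties(rng):
    rows = tuple(random_motif(rng) for _ in range(10))
    aln = MotifAlignment(names=tuple(f"m{i}" for i in range(10)), rows=rows)
    dm = p_distance_matrix(aln)
    v = dm.values
    assert np.allclose(v, v.T)
    assert (np.diag(v) == 0).all()
    assert ((v >= 0) & (v <= 1)).all()
    i, j = 2, 7
    assert v[i, j] == p_distance(rows[i], rows[j])


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(
        labels=("A", "B", "C"),
        values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
    )
    tree = neighbor_joining(dm)
    lengths = {
        l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=("A", "B"), values=np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError):
        DistanceMatrix(labels=("A", "B"), values=np.array([[0, -1], [-1, 0]], float))
    dm = DistanceMatrix(labels=("A", "B"), values=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        neighbor_joining(dm)


def test_nj_four_taxon_topology_oracle(rng):
    """Distances from a known additive quartet recover its topology (the
    alternative quartets are strictly worse)."""
    # quartet ((A,B),(C,D)) with internal edge 2
    #   A,B at 1 from left node; C,D at 1 from right node
    d = {
        ("A", "B"): 2,
        ("C", "D"): 2,
        ("A", "C"): 4,
        ("A", "D"): 4,
        ("B", "C"): 4,
        ("B", "D"): 4,
    }
    labels = ("A", "B", "C", "D")
    v = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                v[i, j] = v[j, i] = d[(x, y)]
    tree = neighbor_joining(DistanceMatrix(labels=labels, values=v))
    assert tree_bipartitions(tree) == {frozenset({"A", "B"})}


def test_nj_additive_recovery_100_trees(rng):
    """On exact path-length matrices of random 8-16 taxon trees NJ recovers
    the generating topology (RF = 0) and reproduces the matrix to 1e-9."""
    for _ in range(100):
        n = int(rng.integers(8, 17))
        gen = random_additive_tree(rng, n)
        dm = tree_distance_matrix(gen)
        rec = neighbor_joining(dm)
        assert robinson_foulds(gen, rec) == 0
        err = np.abs(tree_distance_matrix(rec).values - dm.values).max()
        assert err <= 1e-9


def test_nj_matches_scikit_bio(rng):
    """Independent implementation cross-check on random (noisy, non-additive)
    distance matrices: identical topologies."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    for _ in range(10):
        n = 8
        gen = random_additive_tree(rng, n)
        dm = tree_distance_matrix(gen)
        noisy = dm.values + rng.uniform(0, 0.01, size=dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels=dm.labels, values=noisy))
        theirs = skbio_nj(SkbioDM(noisy, ids=list(dm.labels)))
        their_bips = set()
        leaves = sorted(dm.labels)
        universe, anchor = frozenset(leaves), leaves[0]
        for node in theirs.non_tips():
            s = frozenset(t.name for t in node.tips())
            if 2 <= len(s) <= n - 2:
                their_bips.add(s if anchor in s else universe - s)
        assert tree_bipartitions(ours) == their_bips


def test_nj_leaf_order_invariance(rng):
    gen = random_additive_tree(rng, 10)
    dm = tree_distance_matrix(gen)
    perm = rng.permutation(10)
    permuted = DistanceMatrix(
        labels=tuple(dm.labels[i] for i in perm),
        values=dm.values[np.ix_(perm, perm)],
    )
    t1, t2 = neighbor_joining(dm), neighbor_joining(permuted)
    assert tree_bipartitions(t1) == tree_bipartitions(t2)


def _two_cluster_alignment():
    rows = ["IIAAAADAAIAIWDIR"] * 4 + ["LLTTTTEKKLKLYELK"] * 4
    return MotifAlignment(
        names=tuple(f"x{i}" for i in range(8)), rows=tuple(rows)
    )


def _supports(tree):
    out = {}
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    universe, anchor = frozenset(leaves), leaves[0]
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        s = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 2 <= len(s) <= len(leaves) - 2:
            key = s if anchor in s else universe - s
            out[key] = int(nd.label)
    return out


def test_bootstrap_strong_split_support_100():
    tree = bootstrap_support(_two_cluster_alignment(), n_reps=1000, seed=5)
    sup = _supports(tree)
    assert sup[frozenset({"x0", "x1", "x2", "x3"})] == 100
    assert all(v == 0 for k, v in sup.items() if k != frozenset({"x0", "x1", "x2", "x3"}))


def test_bootstrap_no_signal_support_0():
    aln = MotifAlignment(
        names=tuple(f"x{i}" for i in range(6)),
        rows=tuple(["IIAAAADAAIAIWDIR"] * 6),
    )
    tree = bootstrap_support(aln, n_reps=200, seed=5)
    assert all(v == 0 for v in _supports(tree).values())


def test_bootstrap_deterministic_and_relabel_invariant(rng):
    aln = _two_cluster_alignment()
    s1 = _supports(bootstrap_support(aln, n_reps=200, seed=9))
    s2 = _supports(bootstrap_support(aln, n_reps=200, seed=9))
    assert s1 == s2
    # relabel leaves by a fixed permutation; supports must follow the mapping
    mapping = {f"x{i}": f"y{(i + 3) % 8}" for i in range(8)}
    aln2 = MotifAlignment(
        names=tuple(mapping[n] for n in aln.names), rows=aln.rows
    )
    s3 = _supports(bootstrap_support(aln2, n_reps=200, seed=9))
    # zero-support edges are tie-broken on labels (polytomy resolutions), so
    # only the genuinely supported splits must follow the relabeling
    remapped = {frozenset(mapping[x] for x in k): v for k, v in s1.items() if v > 0}
    universe = frozenset(mapping.values())
    norm = lambda d: {min(k, universe - k, key=sorted): v for k, v in d.items()}
    assert norm(remapped) == norm({k: v for k, v in s3.items() if v > 0})


def test_cut_tree_trivial_ks(rng):
    tree = random_additive_tree(rng, 6)
    one = cut_tree_groups(tree, 1)
    assert set(one.values()) == {"G1"}
    singletons = cut_tree_groups(tree, 6)
    assert len(set(singletons.values())) == 6
    with pytest.raises(ValueError):
        cut_tree_groups(tree, 7)


def test_cut_tree_recovers_planted_families(rng):
    """15 well-separated motif families are recovered exactly at k=15
    (adjusted Rand index 1.0)."""
    from sklearn.metrics import adjusted_rand_score

    names, rows, labels = [], [], []
    made = set()
    for g in range(15):
        while True:
            base = random_motif(rng)
            if base not in made:
                made.add(base)
                break
        for m in range(4):
            names.append(f"g{g:02d}_m{m}")
            rows.append(base)
            labels.append(g)
    aln = MotifAlignment(names=tuple(names), rows=tuple(rows))
    tree = neighbor_joining(p_distance_matrix(aln))
    groups = cut_tree_groups(tree, 15)
    got = [groups[n] for n in names]
    assert adjusted_rand_score(labels, [int(g[1:]) for g in got]) == 1.0
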