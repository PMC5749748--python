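"""Distance-based phylogenetics of DWD motif sequences.

Motifs are fixed 16-mers, so the multiple alignment is the identity mapping
of columns: no gaps, no alignment step.  Evolutionary distances are
p-distances (proportion of differing amino-acid sites; sites with an X in
either sequence are excluded).  Trees are built with the classic Saitou-Nei
neighbor-joining agglomeration, with 1,000-replicate column-bootstrap
supports by default, and can be cut into k groups by removing the k-1
longest internal edges.

Determinism: ties in the Q criterion, in edge selection and in group
labelling are all broken lexicographically on leaf labels; bootstrap
resampling is driven by an explicit seed.  Negative NJ branch lengths are
clamped to zero with the deficit transferred to the sister branch.  An
internal edge of length zero is treated as a polytomy: it contributes no
bipartition to bootstrap replicates, so unresolvable edges get support 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

_TOL = 1e-12


@dataclass(frozen=True)
class MotifAlignment:
    """Positionally aligned fixed-length sequences (no gaps)."""

    names: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("names must be unique")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_codes(self) -> np.ndarray:
        return np.array(
            [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in self.rows]
        )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of p-distances in [0, 1] with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (v < -_TOL).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites; X sites excluded from both numerator
    and denominator.  Zero comparable sites is an error."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    diffs = comparable = 0
    for x, y in zip(a, b):
        if x == "X" or y == "X":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError("no comparable (non-X) sites")
    return diffs / comparable


def p_distance_matrix(
    alignment: MotifAlignment, columns: Optional[np.ndarray] = None
) -> DistanceMatrix:
    """All-pairs p-distances, optionally over a resampled column index array.

    Pairs with zero comparable sites (all-X overlap) get distance 0 with the
    understanding that such rows carry no signal.
    """
    codes = alignment.to_codes()
    if columns is not None:
        codes = codes[:, columns]
    not_x = codes != ord("X")
    comp = (not_x[:, None, :] & not_x[None, :, :]).sum(axis=2)
    diff = (
        (codes[:, None, :] != codes[None, :, :])
        & not_x[:, None, :]
        & not_x[None, :, :]
    ).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comp > 0, diff / np.maximum(comp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=tuple(alignment.names), values=d)


# ---------------------------------------------------------------------------
# Neighbor joining


def _clamp_pair(li: float, lj: float, d_ij: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, transferring the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


class _NJResult:
    """Join history of one NJ run.

    ``joins`` is a list of (node_i, node_j, len_i, len_j, new_node); the last
    three active nodes are resolved onto a central trifurcation with lengths
    from the three-point closed form.  ``leafsets[v]`` is the frozenset of
    leaf labels under node v; ``edge_lengths[v]`` is the length of the edge
    above v.
    """

    def __init__(self, labels):
        self.labels = list(labels)
        self.joins: list = []
        self.final: tuple = ()
        self.leafsets: list = [frozenset([l]) for l in labels]
        self.edge_lengths: dict = {}

    def bipartitions(self, min_length: float = _TOL) -> set:
        """Normalized internal bipartitions with edge length > min_length."""
        n = len(self.labels)
        universe = frozenset(self.labels)
        anchor = min(self.labels)
        out = set()
        for v, length in self.edge_lengths.items():
            s = self.leafsets[v]
            if 2 <= len(s) <= n - 2 and length > min_length:
                out.add(s if anchor in s else universe - s)
        return out


def _nj_core(values: np.ndarray, labels: Sequence[str]) -> _NJResult:
    n = len(labels)
    res = _NJResult(labels)
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = values
    min_label = list(labels)
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q may be asymmetric at the last ulp (left-to-right float sums), so
        # normalize candidate orientation before tie-breaking.
        cand = {(min(i, j), max(i, j)) for i, j in np.argwhere(Q == qmin)}
        best = min(
            (tuple(sorted((min_label[idx[i]], min_label[idx[j]]))), i, j)
            for i, j in cand
        )
        _, i, j = best
        gi, gj = int(idx[i]), int(idx[j])
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj, d_ij)
        u = nxt
        nxt += 1
        new_d = 0.5 * (sub[i, :] + sub[j, :] - d_ij)
        D[u, idx] = new_d
        D[idx, u] = new_d
        D[u, u] = 0.0
        res.leafsets.append(res.leafsets[gi] | res.leafsets[gj])
        min_label.append(min(min_label[gi], min_label[gj]))
        res.edge_lengths[gi] = li
        res.edge_lengths[gj] = lj
        res.joins.append((gi, gj, li, lj, u))
        active.remove(gi)
        active.remove(gj)
        active.append(u)
    # final three-node resolution, closed form
    order = sorted(active, key=lambda v: min_label[v])
    x, y, z = order
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    lx = max(0.0, (dxy + dxz - dyz) / 2)
    ly = max(0.0, (dxy + dyz - dxz) / 2)
    lz = max(0.0, (dxz + dyz - dxy) / 2)
    res.final = ((x, lx), (y, ly), (z, lz))
    for v, l in res.final:
        res.edge_lengths[v] = l
    return res


def _validate_dm(dm: DistanceMatrix) -> None:
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if len(set(dm.labels)) != len(dm.labels):
        raise ValueError("labels must be unique")


def _result_to_tree(res: _NJResult) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(res.labels)
    nodes: dict = {}
    for k, label in enumerate(res.labels):
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes[k] = node
    for gi, gj, li, lj, u in res.joins:
        parent = dendropy.Node()
        parent.add_child(nodes[gi])
        nodes[gi].edge.length = li
        parent.add_child(nodes[gj])
        nodes[gj].edge.length = lj
        nodes[u] = parent
    central = dendropy.Node()
    for v, l in res.final:
        central.add_child(nodes[v])
        nodes[v].edge.length = l
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = central
    tree.is_rooted = False
    return tree


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair (i, j) minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``, with branch
    lengths from the standard NJ formulas, the final three nodes resolved in
    closed form, and Q ties broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf).  The result
    is an unrooted tree with a central trifurcation.
    """
    _validate_dm(dm)
    return _result_to_tree(_nj_core(dm.values, dm.labels))


# ---------------------------------------------------------------------------
# Bootstrap


def tree_bipartitions(tree: dendropy.Tree, min_length: Optional[float] = None) -> set:
    """Normalized non-trivial bipartitions of an (unrooted) tree; with
    ``min_length`` set, only edges longer than it contribute."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    universe = frozenset(leaves)
    anchor = leaves[0]
    n = len(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        if min_length is not None:
            length = node.edge.length or 0.0
            if length <= min_length:
                continue
        s = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(s) <= n - 2:
            out.add(s if anchor in s else universe - s)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted RF distance (symmetric difference of bipartition sets)."""
    b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_support(
    alignment: MotifAlignment, n_reps: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """NJ tree from the full alignment, with internal-edge bootstrap supports.

    Each replicate resamples the alignment columns with replacement,
    recomputes p-distances and the NJ tree; an internal edge's support is the
    percentage of replicates containing the same bipartition (integer,
    attached as the internal ``node.label``).  Zero-length edges count as
    polytomies in the replicates, so edges without signal get support 0.
    Deterministic given the seed.
    """
    if len(alignment.names) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    dm = p_distance_matrix(alignment)
    _validate_dm(dm)
    res = _nj_core(dm.values, dm.labels)
    tree = _result_to_tree(res)

    rng = np.random.default_rng(seed)
    ncols = alignment.n_columns
    counts: dict = {}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_dm = p_distance_matrix(alignment, columns=cols)
        rep = _nj_core(rep_dm.values, rep_dm.labels)
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    leaves = sorted(alignment.names)
    universe = frozenset(leaves)
    anchor = leaves[0]
    n = len(leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        s = frozenset(l.taxon.label for l in node.leaf_iter())
        if not (2 <= len(s) <= n - 2):
            continue
        key = s if anchor in s else universe - s
        support = int(round(100.0 * counts.get(key, 0) / n_reps))
        node.label = str(support)
    return tree


# ---------------------------------------------------------------------------
# Tree cutting into groups


def cut_tree_groups(tree: dendropy.Tree, k: int) -> dict:
    """Cut a tree into k groups by removing the k-1 longest internal edges.

    Ties are broken by higher bootstrap support (internal node label, when
    numeric), then by the lexicographically smallest leaf below the edge.
    When internal edges run out (large k), leaf edges are cut by the same
    priority; any cut that would strand a leafless component is skipped.
    Components become groups G1..Gk, numbered by their smallest leaf label.
    """
    leaves = [l for l in tree.leaf_node_iter()]
    n = len(leaves)
    if k > n:
        raise ValueError(f"k={k} exceeds number of leaves ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")

    nodes = list(tree.preorder_node_iter())
    node_id = {id(nd): i for i, nd in enumerate(nodes)}
    edges = []  # (sort key, child node index, parent node index)
    for nd in nodes:
        if nd.parent_node is None:
            continue
        length = nd.edge.length or 0.0
        try:
            support = float(nd.label) if nd.label is not None else -1.0
        except (TypeError, ValueError):
            support = -1.0
        min_leaf = min(l.taxon.label for l in nd.leaf_iter())
        internal = 0 if not nd.is_leaf() else 1  # prefer internal edges
        edges.append(
            ((internal, -length, -support, min_leaf), node_id[id(nd)], node_id[id(nd.parent_node)])
        )
    edges.sort(key=lambda e: e[0])

    adj = {i: set() for i in range(len(nodes))}
    for _, c, p in edges:
        adj[c].add(p)
        adj[p].add(c)

    def leaf_components():
        seen = set()
        comps = []
        for i, nd in enumerate(nodes):
            if i in seen:
                continue
            stack, comp = [i], []
            seen.add(i)
            while stack:
                v = stack.pop()
                if nodes[v].is_leaf():
                    comp.append(nodes[v].taxon.label)
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if comp:
                comps.append(sorted(comp))
        return comps

    cuts = 0
    for _, c, p in edges:
        if cuts == k - 1:
            break
        adj[c].discard(p)
        adj[p].discard(c)
        if len(leaf_components()) == cuts + 2:
            cuts += 1
        else:  # cut stranded a leafless component; undo
            adj[c].add(p)
            adj[p].add(c)
    comps = leaf_components()
    comps.sort(key=lambda c: c[0])
    out = {}
    for g, comp in enumerate(comps, start=1):
        for leaf in comp:
            out[leaf] = f"G{g}"
    return out


# ---------------------------------------------------------------------------
# Random additive trees (simulation / oracle support)


def random_additive_tree(
    rng: np.random.Generator, n_taxa: int, min_bl: float = 0.1, max_bl: float = 1.0
) -> dendropy.Tree:
    """Random unrooted binary topology (sequential random joins) with branch
    lengths uniform in [min_bl, max_bl]; taxa labelled T01, T02, ..."""
    labels = [f"T{i + 1:02d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    pool = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        pool.append(nd)
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[i], pool[j]
        parent = dendropy.Node()
        parent.add_child(a)
        a.edge.length = float(rng.uniform(min_bl, max_bl))
        parent.add_child(b)
        b.edge.length = float(rng.uniform(min_bl, max_bl))
        pool = [p for p in pool if p is not a and p is not b] + [parent]
    central = dendropy.Node()
    for nd in pool:
        central.add_child(nd)
        nd.edge.length = float(rng.uniform(min_bl, max_bl))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = central
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(labels), values=values)
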