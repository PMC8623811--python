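"""Distance-based phylogenetics: p-distances, Poisson correction,
neighbor-joining, midpoint rooting and monophyly tests.

The tree contract is topology-level: the three CHD paralogue groups must
come out as clades on realistic inputs.  Branch supports and
maximum-likelihood inference are deliberately out of scope; trees are
dendropy :class:`~dendropy.Tree` objects so they interoperate with the
wider ecosystem (Newick I/O, Robinson-Foulds comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .errors import FormatError, ValidationError
from .seqio import GAP, Alignment, newick_string

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled taxa."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise FormatError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise FormatError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise FormatError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise FormatError("distance matrix has negative entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def p_distance_matrix(a: Alignment) -> DistanceMatrix:
    """Pairwise proportion of differing residues over mutually ungapped
    columns.  X never matches anything, including another X."""
    if a.n_rows < 2:
        raise ValidationError("need at least 2 rows")
    codes = np.array([list(s) for s in a.seqs])
    gap = codes == GAP
    isx = codes == "X"
    n = a.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~gap[i] & ~gap[j]
            comp = int(mask.sum())
            if comp == 0:
                raise ValidationError(
                    f"no comparable columns between {a.labels[i]!r} and {a.labels[j]!r}"
                )
            diff = ((codes[i] != codes[j]) | isx[i] | isx[j]) & mask
            d[i, j] = d[j, i] = diff.sum() / comp
    return DistanceMatrix(list(a.labels), d)


def poisson_correct(m: DistanceMatrix) -> DistanceMatrix:
    """Poisson-corrected distances d' = -ln(1 - p)."""
    if np.any(m.d >= 1.0):
        raise ValidationError("cannot Poisson-correct a p-distance >= 1")
    return DistanceMatrix(list(m.labels), -np.log1p(-m.d))


# ---------------------------------------------------------------------------
# Neighbor-joining

def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining; returns an unrooted dendropy tree.

    Ties in the Q criterion are broken by the smallest (i, j) index pair in
    the current working list (new clusters are appended at the end).
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch, preserving the joined pair's path
    length.
    """
    n = len(m.labels)
    if n < 3:
        raise ValidationError("neighbor-joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(m.labels)
    nodes: list[dendropy.Node] = []
    for lab in m.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)
    D = m.d.copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        return parent

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(k):
            for b in range(a + 1, k):
                if best is None or Q[a, b] < best[0] - 1e-12:
                    best = (Q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (k - 2))
        lj = dij - li
        parent = join(i, j, li, lj)
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_d[None, :]])
        D = np.hstack([D, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    i, j, kk = active
    dij, dik, djk = D[i, j], D[i, kk], D[j, kk]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    root = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (kk, lk)):
        nodes[idx].edge.length = max(ln, 0.0)
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting

def _adjacency(tree: dendropy.Tree):
    adj: dict[int, list[tuple[int, float, dendropy.Node]]] = {}
    nodes = {id(nd): nd for nd in tree.preorder_node_iter()}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            w = ch.edge.length or 0.0
            adj.setdefault(id(nd), []).append((id(ch), w, ch))
            adj.setdefault(id(ch), []).append((id(nd), w, ch))
    return adj, nodes


def _paths_from(start: dendropy.Node, adj):
    dist = {id(start): 0.0}
    prev: dict[int, tuple[int, dendropy.Node]] = {}
    stack = [id(start)]
    while stack:
        u = stack.pop()
        for v, w, child in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + w
                prev[v] = (u, child)
                stack.append(v)
    return dist, prev


def midpoint_root(t: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken by the lexicographically
    smallest sorted pair of end-leaf labels.  If every branch length is
    zero the tree is rooted at the first internal node and a warning is
    logged.
    """
    tree = t.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    if len(leaves) < 2:
        return tree
    adj, _ = _adjacency(tree)
    best = None  # (length, (label_u, label_v), u_leaf, v_leaf, prev_map)
    for u in leaves:
        dist, prev = _paths_from(u, adj)
        for v in leaves:
            if v is u:
                continue
            lab = tuple(sorted((u.taxon.label, v.taxon.label)))
            key = (-dist[id(v)], lab)
            if best is None or key < best[0]:
                best = (key, u, v, dist, prev)
    (neg_len, _), u, v, dist, prev = best
    total = -neg_len
    if total <= 0:
        log.warning("all branch lengths zero; rooting at first internal node")
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf():
                tree.reroot_at_node(nd)
                break
        tree.is_rooted = True
        return tree
    # walk from v back to u, collecting the path's edges (child nodes)
    path_edges = []  # (child_node, length) from u towards v
    cur = id(v)
    while cur != id(u):
        parent_id, child = prev[cur]
        path_edges.append((child, child.edge.length or 0.0))
        cur = parent_id
    path_edges.reverse()
    half = total / 2.0
    acc = 0.0
    for child, w in path_edges:
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from the u-side end of this edge
            head, tail = child, child.parent_node
            # the u-side end of the edge is the endpoint nearer u in the BFS
            u_side_is_tail = dist[id(tail)] < dist[id(head)]
            from_tail = offset if u_side_is_tail else w - offset
            eps = 1e-12
            if from_tail <= eps:
                tree.reroot_at_node(tail)
            elif w - from_tail <= eps:
                tree.reroot_at_node(head)
            else:
                tree.reroot_at_edge(child.edge, length1=from_tail,
                                    length2=w - from_tail)
            tree.is_rooted = True
            return tree
        acc += w
    raise RuntimeError("midpoint not located on path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Clade tests

def is_monophyletic(t: dendropy.Tree, labels: set[str] | Sequence[str]) -> bool:
    """True iff some edge bipartition separates exactly ``labels``."""
    want = set(labels)
    all_labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    unknown = want - all_labels
    if unknown:
        raise ValidationError(f"unknown leaf label(s): {sorted(unknown)}")
    if want == all_labels or len(want) == 1:
        return True
    for nd in t.preorder_node_iter():
        under = {lf.taxon.label for lf in nd.leaf_iter()}
        if under == want or all_labels - under == want:
            return True
    return False


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance between two trees."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=newick_string(t1), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    b = dendropy.Tree.get(data=newick_string(t2), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
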