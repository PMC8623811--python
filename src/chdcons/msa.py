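"""Progressive multiple alignment of protein families.

The aligner is a classical deterministic pipeline: global pairwise
alignment with affine gap costs (Gotoh), a UPGMA guide tree on pairwise
p-distances, and profile-profile progressive merging where the score of
pairing two profile columns is the mean substitution-matrix score over all
residue pairs drawn from the two columns (gap cells excluded).

It targets orthologue/paralogue sets in the 50-100% identity range, where
any reasonable global aligner agrees; externally produced alignments can be
substituted at any pipeline boundary via :func:`chdcons.seqio.read_alignment`.

All tie-breaks are fixed (traceback precedence diagonal > up > left; guide
tree joins break distance ties lexicographically) so output is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .errors import ValidationError
from .seqio import GAP, Alignment, ProteinRecord

#: Residue order used to index scoring matrices; X is a first-class code.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

_NEG = -1e30
_TIE_TOL = 1e-9  # traceback equality tolerance; scores are near-integer


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a (21, 21) substitution matrix over :data:`AA_ORDER`."""
    m = substitution_matrices.load(name)
    out = np.empty((21, 21))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    matrix: np.ndarray = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.matrix is None:
            object.__setattr__(self, "matrix", load_matrix(self.matrix_name))
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("substitution matrix must be symmetric")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("gap penalties must be non-positive")
        if self.gap_extend < self.gap_open:
            raise ValidationError("gap_extend must be >= gap_open")


DEFAULT_SCHEME_NAME = "BLOSUM62"


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"illegal residue {exc.args[0]!r}") from None


def _affine_dp(C: np.ndarray, go: float, ge: float):
    """Fill Gotoh matrices for a position-score matrix ``C`` (n x m).

    Returns (M, Ix, Iy) of shape (n+1, m+1).  ``Ix`` consumes rows of C
    ("up" moves, gap in the second sequence); ``Iy`` consumes columns
    ("left" moves, gap in the first).
    """
    n, m = C.shape
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        Ix[1:, 0] = go + ge * np.arange(n)
    if m:
        Iy[0, 1:] = go + ge * np.arange(m)
    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = C[i - 1] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + go, Ix[i - 1, 1:] + ge), Iy[i - 1, 1:] + go
        )
        # horizontal state via max-plus prefix scan:
        # Iy[i,j] = max_{k<j} (max(M,Ix)[i,k] + go + (j-1-k)*ge)
        A = np.maximum(M[i, :-1], Ix[i, :-1]) + go
        Iy[i, 1:] = ge * jj + np.maximum.accumulate(A - ge * np.arange(1, m + 1))
    return M, Ix, Iy


def _traceback(M, Ix, Iy, C, go, ge) -> list[tuple[int | None, int | None]]:
    """Recover one optimal path as (row_index, col_index) pairs, gaps as None.

    Tie-breaks: end state and predecessors are chosen with precedence
    M (diagonal) > Ix (up) > Iy (left).
    """
    n, m = C.shape
    i, j = n, m
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    best = max(finals)
    state = ("M", "Ix", "Iy")[int(np.argmax([f >= best - _TIE_TOL for f in finals]))]
    # argmax on booleans returns the first True -> precedence order
    path: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            target = M[i, j] - C[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])):
                if abs(v - target) <= _TIE_TOL:
                    state = s
                    break
        elif state == "Ix":
            path.append((i - 1, None))
            target = Ix[i, j]
            i -= 1
            for s, v in (("M", M[i, j] + go), ("Ix", Ix[i, j] + ge),
                         ("Iy", Iy[i, j] + go)):
                if abs(v - target) <= _TIE_TOL:
                    state = s
                    break
        else:
            path.append((None, j - 1))
            target = Iy[i, j]
            j -= 1
            for s, v in (("M", M[i, j] + go), ("Ix", Ix[i, j] + go),
                         ("Iy", Iy[i, j] + ge)):
                if abs(v - target) <= _TIE_TOL:
                    state = s
                    break
    path.reverse()
    return path


def pairwise_align(a: str, b: str, scheme: ScoringScheme | None = None,
                   labels: tuple[str, str] = ("a", "b")) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences with affine gap costs."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    ea, eb = encode(a), encode(b)
    C = scheme.matrix[np.ix_(ea, eb)]
    M, Ix, Iy = _affine_dp(C, scheme.gap_open, scheme.gap_extend)
    score = float(max(M[-1, -1], Ix[-1, -1], Iy[-1, -1]))
    path = _traceback(M, Ix, Iy, C, scheme.gap_open, scheme.gap_extend)
    ra = "".join(a[p] if p is not None else GAP for p, _ in path)
    rb = "".join(b[q] if q is not None else GAP for _, q in path)
    return Alignment(list(labels), [ra, rb]), score


def pairwise_p_distance(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """p-distance between two sequences after optimal pairwise alignment.

    Columns where either row is a gap are excluded; X matches nothing.
    """
    aln, _ = pairwise_align(a, b, scheme)
    ra, rb = aln.seqs
    comparable = diffs = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x != y or x == "X":
            diffs += 1
    if comparable == 0:
        raise ValidationError("no comparable columns between sequences")
    return diffs / comparable


# ---------------------------------------------------------------------------
# Guide tree (UPGMA)

def build_guide_tree(records: Sequence[ProteinRecord],
                     scheme: ScoringScheme | None = None,
                     distances: np.ndarray | None = None) -> dendropy.Tree:
    """UPGMA tree on pairwise p-distances.

    Distance ties are broken by joining the lexicographically smallest
    (cluster, cluster) label pair, a cluster being named after its smallest
    member label.  ``distances`` may supply a precomputed matrix in record
    order to skip the pairwise alignments.
    """
    if len(records) < 2:
        raise ValidationError("guide tree needs at least 2 records")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate record ids")
    n = len(records)
    if distances is None:
        distances = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pairwise_p_distance(records[i].sequence, records[j].sequence, scheme)
                distances[i, j] = distances[j, i] = d

    taxa = dendropy.TaxonNamespace(labels)
    nodes: dict[int, dendropy.Node] = {}
    heights: dict[int, float] = {}
    names: dict[int, str] = {}
    sizes: dict[int, int] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[i] = node
        heights[i] = 0.0
        names[i] = lab
        sizes[i] = 1
    D = {frozenset((i, j)): distances[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                x, y = active[ii], active[jj]
                d = D[frozenset((x, y))]
                name_key = tuple(sorted((names[x], names[y])))
                key = (d, name_key)
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _), x, y = best
        h = d / 2.0
        parent = dendropy.Node()
        for child in (x, y):
            nodes[child].edge.length = max(h - heights[child], 0.0)
            parent.add_child(nodes[child])
        nodes[next_id] = parent
        heights[next_id] = h
        names[next_id] = min(names[x], names[y])
        sizes[next_id] = sizes[x] + sizes[y]
        active = [a for a in active if a not in (x, y)]
        for a in active:
            da = D.pop(frozenset((x, a)))
            db = D.pop(frozenset((y, a)))
            D[frozenset((next_id, a))] = (sizes[x] * da + sizes[y] * db) / sizes[next_id]
        D.pop(frozenset((x, y)))
        active.append(next_id)
        next_id += 1
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Progressive profile-profile alignment

def _counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Residue count matrix (21 x width) and per-column residue totals."""
    counts = np.zeros((21, aln.width))
    for s in aln.seqs:
        for c, ch in enumerate(s):
            if ch != GAP:
                counts[_AA_INDEX[ch], c] += 1
    return counts, counts.sum(axis=0)


def _merge(a: Alignment, b: Alignment, scheme: ScoringScheme) -> Alignment:
    ca, na = _counts(a)
    cb, nb = _counts(b)
    denom = np.outer(na, nb)
    C = (ca.T @ scheme.matrix @ cb)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, C / np.where(denom > 0, denom, 1.0), 0.0)
    M, Ix, Iy = _affine_dp(C, scheme.gap_open, scheme.gap_extend)
    path = _traceback(M, Ix, Iy, C, scheme.gap_open, scheme.gap_extend)
    rows_a = [[] for _ in a.seqs]
    rows_b = [[] for _ in b.seqs]
    for p, q in path:
        for r, s in zip(rows_a, a.seqs):
            r.append(s[p] if p is not None else GAP)
        for r, s in zip(rows_b, b.seqs):
            r.append(s[q] if q is not None else GAP)
    return Alignment(a.labels + b.labels,
                     ["".join(r) for r in rows_a + rows_b])


def progressive_align(records: Sequence[ProteinRecord],
                      scheme: ScoringScheme | None = None,
                      guide_tree: dendropy.Tree | None = None) -> Alignment:
    """Multiple alignment by profile-profile merges along a UPGMA guide tree.

    Every output row ungaps to its input sequence; given identical inputs
    and scheme the result is deterministic.
    """
    scheme = scheme or ScoringScheme()
    if len(records) < 2:
        raise ValidationError("progressive alignment needs at least 2 records")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise ValidationError("duplicate record ids")
    if guide_tree is None:
        guide_tree = build_guide_tree(records, scheme)

    def rec_align(node: dendropy.Node) -> Alignment:
        if node.is_leaf():
            rec = by_id[node.taxon.label]
            return Alignment([rec.id], [rec.sequence])
        children = node.child_nodes()
        acc = rec_align(children[0])
        for child in children[1:]:
            acc = _merge(acc, rec_align(child), scheme)
        return acc

    aln = rec_align(guide_tree.seed_node)
    # restore input order
    order = [r.id for r in records]
    idx = {lab: i for i, lab in enumerate(aln.labels)}
    return Alignment(order, [aln.seqs[idx[lab]] for lab in order])
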