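"""Alignment refinement by column reliability, in the style of BMGE.

A column is kept when (a) its matrix-weighted entropy score is at most
``entropy_threshold`` and (b) its gap rate is at most ``gap_rate_cutoff``;
maximal runs of kept columns shorter than ``min_block_size`` are then
discarded, so only contiguous blocks of reliable columns survive.

The entropy score is this module's own formulation (it does not claim
equivalence with BMGE's internals): substitution-matrix similarities are
min-max normalised to [0, 1]; each residue type in a column receives a
dissimilarity weight ``1 - (mean normalised similarity to the other
residues in the column)``; type frequencies are multiplied by these
weights, renormalised, and their Shannon entropy is divided by
``log(min(n, 20))`` — the maximum entropy achievable with *n* non-gap
residues — so the score always spans [0, 1].  A single-residue column
scores 0, an all-gap column 1 (maximally unreliable).  The weighting makes
a column of interchangeable residues (e.g. I/L/V) score lower than a
column of biochemically dissimilar ones at the same multiplicities, and
the capacity normalisation keeps deep alignments usable: a column split
between two clades of a 54-row alignment scores ~0.2, not ~1, so
phylogenetically informative columns survive the default 0.5 threshold
while genuinely scrambled columns do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ChdconsError
from .msa import AA_ORDER, _AA_INDEX, load_matrix
from .seqio import GAP, Alignment


@dataclass(frozen=True)
class TrimParams:
    matrix: str = "BLOSUM62"
    entropy_threshold: float = 0.5
    gap_rate_cutoff: float = 0.5
    min_block_size: int = 5

    def __post_init__(self) -> None:
        for name in ("entropy_threshold", "gap_rate_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ChdconsError(f"{name} must be in [0, 1], got {v}")
        if self.min_block_size < 1:
            raise ChdconsError("min_block_size must be >= 1")


@lru_cache(maxsize=4)
def _normalized_similarity(matrix_name: str) -> np.ndarray:
    m = load_matrix(matrix_name)
    return (m - m.min()) / (m.max() - m.min())


def column_gap_rate(a: Alignment, col: int) -> float:
    """Fraction of rows that are gaps at ``col`` (0-based)."""
    if not 0 <= col < a.width:
        raise IndexError(f"column {col} outside alignment of width {a.width}")
    column = a.column(col)
    return column.count(GAP) / len(column)


def column_entropy_score(a: Alignment, col: int, matrix: str = "BLOSUM62") -> float:
    """Matrix-weighted normalised entropy of a column, in [0, 1]."""
    if not 0 <= col < a.width:
        raise IndexError(f"column {col} outside alignment of width {a.width}")
    residues = [ch for ch in a.column(col) if ch != GAP]
    if not residues:
        return 1.0
    types: dict[str, int] = {}
    for ch in residues:
        types[ch] = types.get(ch, 0) + 1
    if len(types) == 1:
        return 0.0
    S = _normalized_similarity(matrix)
    n = len(residues)
    freqs = []
    for r, c_r in types.items():
        i = _AA_INDEX[r]
        sim = (c_r - 1) * S[i, i]
        for r2, c_r2 in types.items():
            if r2 != r:
                sim += c_r2 * S[i, _AA_INDEX[r2]]
        weight = 1.0 - sim / (n - 1)
        freqs.append(c_r * weight)
    total = sum(freqs)
    if total <= 0:  # degenerate: fall back to plain count frequencies
        freqs = [c for c in types.values()]
        total = float(n)
    entropy = -sum((f / total) * math.log(f / total) for f in freqs if f > 0)
    capacity = math.log(min(n, 20))
    return min(max(entropy / capacity, 0.0), 1.0)


def trim_alignment(a: Alignment, params: TrimParams | None = None
                   ) -> tuple[Alignment, list[int]]:
    """Keep blocks of reliable columns; return the trimmed alignment and the
    original (0-based) indices of the kept columns."""
    params = params or TrimParams()
    keep = [
        column_entropy_score(a, c, params.matrix) <= params.entropy_threshold
        and column_gap_rate(a, c) <= params.gap_rate_cutoff
        for c in range(a.width)
    ]
    kept: list[int] = []
    run: list[int] = []
    for c in range(a.width + 1):
        if c < a.width and keep[c]:
            run.append(c)
        else:
            if len(run) >= params.min_block_size:
                kept.extend(run)
            run = []
    return a.take_columns(kept), kept
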