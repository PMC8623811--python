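"""Independent oracles used by the test-suite and the acceptance script.

These deliberately avoid the package's own dynamic-programming code paths:
the affine-gap optimum is recomputed by plain memoised recursion over
(i, j, last-move) states, and — for very short sequences — by exhaustive
enumeration of every gapped alignment, scored by scanning gap runs.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def affine_optimum_recursive(a: str, b: str, score, go: float, ge: float) -> float:
    """Optimal global affine-gap score by memoised recursion.

    ``score(x, y)`` gives the substitution score; a gap of length L costs
    go + (L - 1) * ge.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # best score of aligning a[:i] with b[:j], ending in `state`
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        options = []
        if state == "M" and i > 0 and j > 0:
            prev = max(best(i - 1, j - 1, s) for s in "MXY")
            options.append(prev + score(a[i - 1], b[j - 1]))
        elif state == "X" and i > 0:  # gap in b
            options.append(best(i - 1, j, "X") + ge)
            options.append(max(best(i - 1, j, "M"), best(i - 1, j, "Y")) + go)
        elif state == "Y" and j > 0:  # gap in a
            options.append(best(i, j - 1, "Y") + ge)
            options.append(max(best(i, j - 1, "M"), best(i, j - 1, "X")) + go)
        return max(options) if options else NEG

    return max(best(len(a), len(b), s) for s in "MXY")


def _score_moves(a: str, b: str, moves: list[str], score, go: float, ge: float) -> float:
    total = 0.0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == "M":
            total += score(a[i], b[j])
            i += 1
            j += 1
        else:
            total += ge if mv == prev else go
            if mv == "X":
                i += 1
            else:
                j += 1
        prev = mv
    return total


def affine_optimum_enumerated(a: str, b: str, score, go: float, ge: float) -> float:
    """Optimum over an explicit enumeration of all gapped alignments.

    Exponential; intended for sequences of length <= 4.
    """
    best = NEG
    n, m = len(a), len(b)
    stack: list[tuple[int, int, list[str]]] = [(0, 0, [])]
    while stack:
        i, j, moves = stack.pop()
        if i == n and j == m:
            best = max(best, _score_moves(a, b, moves, score, go, ge))
            continue
        if i < n and j < m:
            stack.append((i + 1, j + 1, moves + ["M"]))
        if i < n:
            stack.append((i + 1, j, moves + ["X"]))
        if j < m:
            stack.append((i, j + 1, moves + ["Y"]))
    return best


def sum_of_pairs_score(rows: list[str], score, go: float, ge: float) -> float:
    """Sum over row pairs of the induced pairwise affine alignment scores
    (columns gapped in both rows of a pair are dropped)."""
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            prev = None
            for x, y in zip(rows[i], rows[j]):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    mv = "X" if y == "-" else "Y"
                    total += ge if mv == prev else go
                    prev = mv
                else:
                    total += score(x, y)
                    prev = "M"
    return total
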