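"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: a plain Gotoh
dynamic-programming local aligner scored with Biopython's BLOSUM62 (the
package aligns through scikit-bio), a set-merging transitive-closure
clusterer, and a Pascal-triangle binomial table.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, protein: bool = False) -> float:
    """Optimal local alignment score by full Gotoh DP (no heuristics).

    A contiguous gap of length k costs open + ext*k, matching the package's
    scoring convention (BLOSUM62 11/1 for protein, 2/-3 with 5/2 gaps for
    nucleotide).
    """
    if protein:
        sub = lambda x, y: float(_BLOSUM62[x][y])
        go, ge = 11.0, 1.0
    else:
        sub = lambda x, y: 2.0 if x == y else -3.0
        go, ge = 5.0, 2.0
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def transitive_closure_oracle(
    nodes: list[str], edges: list[tuple[str, str]]
) -> set[frozenset[str]]:
    """Clusters by naive repeated set merging (brute-force closure)."""
    clusters: list[set[str]] = [{n} for n in nodes]
    for a, b in edges:
        ca = next(c for c in clusters if a in c)
        cb = next(c for c in clusters if b in c)
        if ca is not cb:
            clusters.remove(cb)
            ca |= cb
    return {frozenset(c) for c in clusters}


def pascal_binomial(n: int, m: int) -> int:
    """C(n, m) from an explicitly built Pascal triangle."""
    row = [1]
    for _ in range(n):
        row = [1] + [row[i] + row[i + 1] for i in range(len(row) - 1)] + [1]
    return row[m]
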