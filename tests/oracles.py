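"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: the aligner is a plain
Python Gotoh DP returning only the optimal local score, and the Markov
clustering oracle is an explicit-loop dense iteration.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal local alignment score, affine gaps costing open + k*extend."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            if a[i - 1] == "X" or b[j - 1] == "X":
                s = 0
            else:
                s = int(_BLOSUM[a[i - 1]][b[j - 1]])
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def mcl_oracle(
    nodes: list[str],
    weighted_edges: list[tuple[str, str, float]],
    inflation: float,
    max_iter: int = 2000,
) -> list[set[str]]:
    """Dense Markov clustering iterated to machine precision.

    Explicit-loop implementation: column-stochastic matrix with max-weight
    self-loops, squaring + elementwise inflation, no pruning (beyond
    numerical zero), attractor-system read-out with overlap merging.
    """
    nodes = sorted(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for a, b, w in weighted_edges:
        i, j = idx[a], idx[b]
        W[i][j] = max(W[i][j], w)
        W[j][i] = max(W[j][i], w)
    for i in range(n):
        loop = max(W[i][j] for j in range(n)) if n else 0.0
        W[i][i] = loop if loop > 0 else 1.0
    M = np.zeros((n, n))
    for j in range(n):
        colsum = sum(W[i][j] for i in range(n))
        for i in range(n):
            M[i][j] = W[i][j] / colsum
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M
        M = np.power(M, inflation)
        for j in range(n):
            colsum = M[:, j].sum()
            if colsum > 0:
                M[:, j] /= colsum
        if np.max(np.abs(M - prev)) < 1e-14:
            break
    clusters: list[set[int]] = []
    for i in range(n):
        if M[i][i] <= 1e-9:
            continue
        members = {j for j in range(n) if M[i][j] > 1e-9} | {i}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters.pop(j)
                    changed = True
                    break
            if changed:
                break
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters]
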