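"""Independently written reference implementations used as test oracles.

These deliberately re-derive results from first principles (textbook
formulas, exhaustive enumeration, loop-based linear algebra) instead of
calling the package code paths they are checking.
"""

import math

import numpy as np


def tajimas_d_oracle(seqs):
    """Tajima's test statistic from a list of equal-length sequences.

    Loop-based: S by column enumeration, mean pairwise differences by
    explicit double loop, constants from the 1989 definitions.
    """
    n = len(seqs)
    L = len(seqs[0])
    S = 0
    for col in range(L):
        bases = {s[col] for s in seqs if s[col] in "ACGT"}
        if len(bases) >= 2:
            S += 1
    if S == 0:
        return None
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
            pairs += 1
    k_hat = total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def mcl_oracle(nodes, edges, inflation=2.0, max_iter=100, prune_eps=1e-6, tol=1e-8):
    """Markov clustering via a row-stochastic transpose formulation.

    Works on the transpose of the column-stochastic walk matrix, so every
    numeric step mirrors the definition through different code; returns a
    frozenset-of-frozensets partition.
    """
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    R = np.eye(n)
    for a, b in edges:
        R[index[a], index[b]] = 1.0
        R[index[b], index[a]] = 1.0
    for i in range(n):
        R[i, :] = R[i, :] / R[i, :].sum()
    for _ in range(max_iter):
        nxt = R @ R
        nxt = nxt**inflation
        nxt[nxt < prune_eps] = 0.0
        for i in range(n):
            s = nxt[i, :].sum()
            if s == 0:
                s = 1.0
            nxt[i, :] = nxt[i, :] / s
        if np.abs(nxt - R).max() < tol:
            R = nxt
            break
        R = nxt
    # union-find over the support
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(R)):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(nodes[i])
    return frozenset(frozenset(g) for g in groups.values())
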