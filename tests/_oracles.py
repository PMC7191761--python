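"""Independent brute-force oracles used to check the implementation paths.

Everything here is deliberately naive (pure-Python DP, exhaustive
enumeration) and shares no code with the package's own algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def nw_align(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0):
    """Affine-gap global alignment (Gotoh) with traceback.

    The first residue of a gap costs ``gap_open``, each further one
    ``gap_extend``.  Returns (score, gapped_a, gapped_b).
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    # traceback from the best terminal state
    states = {"M": M, "X": X, "Y": Y}
    state = max(states, key=lambda k: states[k][n, m])
    score = states[state][n, m]
    ga, gb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            prev = max(("M", "X", "Y"), key=lambda k: states[k][i - 1, j - 1])
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            cand = [
                ("M", M[i - 1, j] - gap_open),
                ("X", X[i - 1, j] - gap_extend),
                ("Y", Y[i - 1, j] - gap_open),
            ]
            prev = max(cand, key=lambda t: t[1])[0]
            ga.append(a[i - 1])
            gb.append("-")
            i -= 1
            state = prev
        else:
            cand = [
                ("M", M[i, j - 1] - gap_open),
                ("Y", Y[i, j - 1] - gap_extend),
                ("X", X[i, j - 1] - gap_open),
            ]
            prev = max(cand, key=lambda t: t[1])[0]
            ga.append("-")
            gb.append(b[j - 1])
            j -= 1
            state = prev
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    return float(score), "".join(reversed(ga)), "".join(reversed(gb))


def nw_identity(a: str, b: str) -> float:
    """Identity from the DP alignment, terminal-gap columns excluded."""
    _, ga, gb = nw_align(a, b)
    start = max(len(ga) - len(ga.lstrip("-")), len(gb) - len(gb.lstrip("-")))
    end = min(len(ga.rstrip("-")), len(gb.rstrip("-"))) - 1
    if end < start:
        return 0.0
    matches = sum(
        1 for i in range(start, end + 1) if ga[i] == gb[i] and ga[i] != "-"
    )
    return matches / (end - start + 1)


def replay_greedy(records, threshold, identity_fn, match_mode="first"):
    """Replay the greedy discipline from a full pairwise identity matrix.

    Returns member tagged-id → centroid tagged-id.
    """
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.tagged_id))
    ident = {}
    for r1 in ordered:
        for r2 in ordered:
            if r1.tagged_id < r2.tagged_id:
                ident[(r1.tagged_id, r2.tagged_id)] = identity_fn(r1.sequence, r2.sequence)

    def lookup(x, y):
        if x == y:
            return 1.0
        key = (x, y) if x < y else (y, x)
        return ident[key]

    centroids = []
    assignment = {}
    for rec in ordered:
        chosen = None
        for c in centroids:
            d = lookup(rec.tagged_id, c)
            if d >= threshold:
                if match_mode == "first":
                    chosen = c
                    break
                if chosen is None or d > lookup(rec.tagged_id, chosen):
                    chosen = c
        if chosen is None:
            centroids.append(rec.tagged_id)
            assignment[rec.tagged_id] = rec.tagged_id
        else:
            assignment[rec.tagged_id] = chosen
    return assignment


def scan_all_windows(query: str, scores: np.ndarray, aa_order: str):
    """Best ungapped window by explicit enumeration (ties: smallest start)."""
    L = scores.shape[0]
    if len(query) < L:
        return float("-inf"), 0, 0
    index = {a: i for i, a in enumerate(aa_order)}
    best, best_start = float("-inf"), 0
    for s in range(len(query) - L + 1):
        total = 0.0
        for k in range(L):
            c = query[s + k]
            total += scores[k, index[c]] if c in index else 0.0
        if total > best:
            best, best_start = total, s
    return best, best_start + 1, best_start + L


def exhaustive_pan_core(presence: np.ndarray, n: int):
    """Mean pan/core size over all genome subsets of size n."""
    N = presence.shape[1]
    pans, cores = [], []
    for idx in combinations(range(N), n):
        sub = presence[:, list(idx)]
        pans.append(sub.any(axis=1).sum())
        cores.append(sub.all(axis=1).sum())
    return float(np.mean(pans)), float(np.mean(cores))


def pair_count_cooccurrence(counts: np.ndarray) -> np.ndarray:
    """Genomes shared per CYP pair by explicit per-genome counting."""
    n = counts.shape[0]
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i, j] = sum(
                1 for g in range(counts.shape[1]) if counts[i, g] > 0 and counts[j, g] > 0
            )
    return out
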