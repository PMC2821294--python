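"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the implementation it checks: exhaustive enumeration for local alignment,
a memoized top-down recursion for affine-gap scoring, dense grid search
for ML distances, path-sum distances on randomly built trees for NJ, and
plain Python tallies for co-occurrence counts.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def enumerate_local_score(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Exhaustive enumeration of every local alignment (tiny inputs only).

    Walks all monotone move sequences from every start cell, charging
    ``gap_open`` for the first residue of a gap run and ``gap_extend``
    for each further one, and keeps the best running score (floored at 0,
    the empty alignment).
    """
    best = 0.0

    def rec(i: int, j: int, state: str, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "m", score + _B62[a[i], b[j]])
        if i < len(a):
            cost = gap_extend if state == "ga" else gap_open
            rec(i + 1, j, "ga", score - cost)
        if j < len(b):
            cost = gap_extend if state == "gb" else gap_open
            rec(i, j + 1, "gb", score - cost)

    for i0 in range(len(a) + 1):
        for j0 in range(len(b) + 1):
            rec(i0, j0, "start", 0.0)
    return best


def gotoh_local_score(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Memoized top-down affine local-alignment score (independent of the
    bottom-up library DP it checks; validated against full enumeration)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def match(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return NEG
        prev = max(0.0, match(i - 1, j - 1), gap_a(i - 1, j - 1), gap_b(i - 1, j - 1))
        return prev + _B62[a[i - 1], b[j - 1]]

    @lru_cache(maxsize=None)
    def gap_a(i: int, j: int) -> float:  # consumes a[i-1], gap in b
        if i == 0:
            return NEG
        return max(
            match(i - 1, j) - gap_open,
            gap_a(i - 1, j) - gap_extend,
            gap_b(i - 1, j) - gap_open,
        )

    @lru_cache(maxsize=None)
    def gap_b(i: int, j: int) -> float:
        if j == 0:
            return NEG
        return max(
            match(i, j - 1) - gap_open,
            gap_b(i, j - 1) - gap_extend,
            gap_a(i, j - 1) - gap_open,
        )

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, match(i, j))
    return best


def grid_jtt_distance(row_a: str, row_b: str, step: float = 1e-4) -> float:
    """Dense grid search of the pairwise JTT likelihood over [1e-6, 10]."""
    from efpmod.phylo import JTT_FREQS, ProteinAlignment, _pair_counts, _transition_batch

    codes = ProteinAlignment(taxa=["a", "b"], rows=[row_a, row_b]).codes()
    counts = _pair_counts(codes[0], codes[1])
    log_prior = np.log(JTT_FREQS)[:, None]
    ts = np.arange(1e-6, 10.0 + step, step)
    best_ll, best_t = -np.inf, None
    for start in range(0, len(ts), 4000):
        chunk = ts[start : start + 4000]
        P = _transition_batch(chunk)
        ll = (np.log(P) + log_prior[None, :, :]).reshape(len(chunk), 400) @ counts
        k = int(np.argmax(ll))
        if ll[k] > best_ll:
            best_ll, best_t = ll[k], chunk[k]
    return float(best_t)


def grid_jtt_distances_batch(
    pairs: list[tuple[str, str]], step: float = 1e-4
) -> np.ndarray:
    """Grid search as above for many pairs at once, sharing the transition
    grid (one pass over t, argmax tracked per pair)."""
    from efpmod.phylo import JTT_FREQS, ProteinAlignment, _pair_counts, _transition_batch

    counts = []
    for a, b in pairs:
        codes = ProteinAlignment(taxa=["a", "b"], rows=[a, b]).codes()
        counts.append(_pair_counts(codes[0], codes[1]))
    counts = np.stack(counts)                       # (P, 400)
    log_prior = np.log(JTT_FREQS)[:, None]
    ts = np.arange(1e-6, 10.0 + step, step)
    best_ll = np.full(len(pairs), -np.inf)
    best_t = np.zeros(len(pairs))
    for start in range(0, len(ts), 4000):
        chunk = ts[start : start + 4000]
        P = _transition_batch(chunk)
        logP = (np.log(P) + log_prior[None, :, :]).reshape(len(chunk), 400)
        ll = logP @ counts.T                        # (T, P)
        k = np.argmax(ll, axis=0)
        vals = ll[k, np.arange(len(pairs))]
        better = vals > best_ll
        best_ll[better] = vals[better]
        best_t[better] = chunk[k[better]]
    return best_t


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Distances realized as path lengths on a random binary tree, built
    and measured without any phylogenetics library."""
    parent: dict[int, tuple[int, float]] = {}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = (next_id, float(rng.uniform(0.05, 1.0)))
        parent[b] = (next_id, float(rng.uniform(0.05, 1.0)))
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    def path_to_root(x: int) -> dict[int, float]:
        out, dist = {x: 0.0}, 0.0
        while x in parent:
            x, bl = parent[x][0], parent[x][1]
            dist += bl
            out[x] = dist
        return out

    D = np.zeros((n, n))
    for i in range(n):
        pi = path_to_root(i)
        for j in range(i + 1, n):
            pj = path_to_root(j)
            shared = [pi[x] + pj[x] for x in pi if x in pj]
            D[i, j] = D[j, i] = min(shared)
    return [f"t{k}" for k in range(n)], D


def tally_cooccurrence(presence: dict[str, dict[str, bool]], fam_a: str, fam_b: str):
    """Loop-based co-occurrence tally over a genome -> family -> bool map."""
    both = only_a = only_b = neither = 0
    for families in presence.values():
        a, b = families[fam_a], families[fam_b]
        if a and b:
            both += 1
        elif a:
            only_a += 1
        elif b:
            only_b += 1
        else:
            neither += 1
    return both, only_a, only_b, neither
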