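"""Independent brute-force oracles used to validate the implementation.

Everything here deliberately avoids the code paths under test: alignment by
full three-matrix Gotoh dynamic programming, suffix arrays by sorting the
suffix strings, substring counting by a sliding window, and chaining by
exhaustive enumeration over all anchor subsets and orderings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 10**9


@njit(cache=True)
def _gotoh_kernel(a, b, x, o, e):
    n, m = a.shape[0], b.shape[0]
    S = np.full((n + 1, m + 1), INF, dtype=np.int64)  # best ending in any state
    E = np.full((n + 1, m + 1), INF, dtype=np.int64)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), INF, dtype=np.int64)  # gap in b (consumes a)
    S[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = o + e * j
        S[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = o + e * i
        S[i, 0] = F[i, 0]
        for j in range(1, m + 1):
            E[i, j] = min(E[i, j - 1] + e, S[i, j - 1] + o + e)
            F[i, j] = min(F[i - 1, j] + e, S[i - 1, j] + o + e)
            sub = S[i - 1, j - 1] + (0 if a[i - 1] == b[j - 1] else x)
            S[i, j] = min(sub, E[i, j], F[i, j])
    return S[n, m]


def gotoh_cost(a: str, b: str, mismatch: int = 2, gap_open: int = 3, gap_extend: int = 1) -> int:
    """Optimal global gap-affine cost by full dynamic programming."""
    if not a and not b:
        return 0
    ac = np.frombuffer(a.encode(), dtype=np.uint8).astype(np.int64)
    bc = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    return int(_gotoh_kernel(ac, bc, mismatch, gap_open, gap_extend))


def naive_count(text: str, pattern: str) -> int:
    """Sliding-window occurrence count (empty pattern: one per position)."""
    if not pattern:
        return len(text)
    return sum(1 for i in range(len(text) - len(pattern) + 1) if text[i : i + len(pattern)] == pattern)


def brute_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def brute_longest_match(center: str, query: str, y: int) -> tuple[int, int] | None:
    """Longest center match starting at query position y; smallest x on ties."""
    best = None
    for w in range(len(query) - y, 0, -1):
        sub = query[y : y + w]
        x = center.find(sub)
        if x != -1:
            return (x, w)
    return best


def brute_best_chain_value(matches) -> int:
    """Exhaustive maximum of the chain objective over all valid orderings.

    A sequence of anchors is valid when each anchor's ends strictly dominate
    its predecessor's in both coordinates; its value is the first anchor's
    length plus, per step, the successor's length minus the overlap.
    """
    def overlap(a, b):
        return max(0, a.x + a.w - b.x, a.y + a.w - b.y)

    best = 0
    n = len(matches)
    for mask in range(1, 1 << n):
        subset = [matches[i] for i in range(n) if mask >> i & 1]
        # any valid ordering is strictly increasing in both ends, so the
        # end-sorted order is the only candidate
        subset.sort(key=lambda m: (m.x + m.w, m.y + m.w))
        ok = all(
            a.x + a.w < b.x + b.w and a.y + a.w < b.y + b.w
            for a, b in zip(subset, subset[1:])
        )
        if not ok:
            continue
        val = subset[0].w + sum(
            b.w - min(overlap(a, b), b.w) for a, b in zip(subset, subset[1:])
        )
        best = max(best, val)
    return best


def random_similar_pair(rng: np.random.Generator, max_len: int = 200) -> tuple[str, str]:
    """A pair of sequences with 50-100% similarity, possibly empty."""
    bases = "ACGT"
    n = int(rng.integers(0, max_len + 1))
    a = "".join(rng.choice(list(bases), size=n)) if n else ""
    sim = rng.uniform(0.5, 1.0)
    out = []
    for ch in a:
        r = rng.random()
        if r < sim:
            out.append(ch)
        elif r < sim + (1 - sim) / 2:
            out.append(bases[int(rng.integers(4))])  # substitution (may be silent)
        # else deletion
        if rng.random() < (1 - sim) / 4:
            out.append(bases[int(rng.integers(4))])  # insertion
    b = "".join(out)
    return a, b
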