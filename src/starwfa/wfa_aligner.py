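"""Exact gap-affine pairwise alignment by the wavefront algorithm (WFA).

WFA explores alignment scores in increasing order.  For each score s it keeps
three *wavefronts* — the furthest-reaching offsets per diagonal for states
ending in a match/mismatch (M), a gap in the second sequence (D, consumes
only the first sequence), and a gap in the first sequence (I, consumes only
the second) — and greedily extends M offsets along runs of equal characters
for free (match cost is 0 by construction).  Runtime is O(n·s) for the
optimal score s, which is what makes it fast on highly similar sequences;
no heuristic pruning is applied, so the returned score is exactly optimal.

A gap of length k costs gap_open + k·gap_extend.  Diagonals are k = i - j
(i along ``a``, j along ``b``); offsets store i.  All wavefronts are retained
for traceback, which yields a run-length-encoded CIGAR over {M, X, I, D}
with I = gap in the ``a`` row (the center row downstream) and D = gap in the
``b`` row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = np.int32(-(2**30))


@dataclass(frozen=True)
class PenaltySet:
    """Gap-affine alignment costs; match must be free for the wavefront model."""

    match: int = 0
    mismatch: int = 2
    gap_open: int = 3
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.match != 0:
            raise ValueError("wavefront formulation requires match cost 0")
        if self.mismatch <= 0 or self.gap_open + self.gap_extend <= 0 or self.gap_extend <= 0:
            raise ValueError("mismatch and gap penalties must be positive")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + self.gap_extend * length if length else 0


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    cigar: str

    def ops(self) -> list[tuple[int, str]]:
        """Decode the run-length CIGAR into (count, op) tuples."""
        return [(int(n), op) for n, op in re.findall(r"(\d+)([MXID])", self.cigar)]


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("latin-1"), dtype=np.uint8).astype(np.int8)


@njit(cache=True)
def _extend(M, lo, a, b):
    """Greedy free extension of M offsets along exact-match runs."""
    n = a.shape[0]
    m = b.shape[0]
    for idx in range(M.shape[0]):
        h = M[idx]
        if h < 0:
            continue
        k = lo + idx
        j = h - k
        while h < n and j < m and a[h] == b[j]:
            h += 1
            j += 1
        M[idx] = h


@njit(cache=True)
def _get(arr, lo, k):
    idx = k - lo
    if 0 <= idx < arr.shape[0]:
        return arr[idx]
    return NEG


@njit(cache=True)
def _next_wave(lo, hi, n, m,
               mx, lo_mx,      # M at score s - mismatch
               moe, lo_moe,    # M at score s - open - extend
               ie, lo_ie,      # I at score s - extend
               de, lo_de,      # D at score s - extend
               newM, newI, newD):
    for idx in range(hi - lo + 1):
        k = lo + idx
        hmax = min(n, m + k)  # offsets beyond either end are unreachable
        # I: gap in a, consume one char of b (from diagonal k+1, same offset)
        iv = max(_get(moe, lo_moe, k + 1), _get(ie, lo_ie, k + 1))
        if iv > hmax or iv - k > m or iv < 0:
            iv = NEG
        newI[idx] = iv
        # D: gap in b, consume one char of a (from diagonal k-1, offset + 1)
        dv = max(_get(moe, lo_moe, k - 1), _get(de, lo_de, k - 1))
        dv = dv + 1 if dv >= 0 else NEG
        if dv > hmax:
            dv = NEG
        newD[idx] = dv
        # M: mismatch step on the same diagonal, or close a gap
        mv = _get(mx, lo_mx, k)
        mv = mv + 1 if mv >= 0 else NEG
        if mv > hmax or (mv >= 0 and mv - k > m):
            mv = NEG
        best = max(mv, iv, dv)
        newM[idx] = best if best >= 0 else NEG


class _Wavefronts:
    """Per-score M/I/D wavefront storage with diagonal bookkeeping."""

    __slots__ = ("M", "I", "D", "lo", "hi")

    def __init__(self):
        self.M: list[np.ndarray | None] = []
        self.I: list[np.ndarray | None] = []
        self.D: list[np.ndarray | None] = []
        self.lo: list[int] = []
        self.hi: list[int] = []

    def push_empty(self):
        self.M.append(None)
        self.I.append(None)
        self.D.append(None)
        self.lo.append(0)
        self.hi.append(-1)

    def get(self, comp: str, s: int, k: int) -> int:
        if s < 0 or s >= len(self.lo):
            return int(NEG)
        arr = getattr(self, comp)[s]
        if arr is None:
            return int(NEG)
        idx = k - self.lo[s]
        if 0 <= idx < arr.shape[0]:
            return int(arr[idx])
        return int(NEG)


_EMPTY = np.empty(0, dtype=np.int32)


def _forward(a: np.ndarray, b: np.ndarray, x: int, o: int, e: int) -> tuple[int, _Wavefronts]:
    n, m = a.shape[0], b.shape[0]
    k_end = n - m
    wf = _Wavefronts()
    M0 = np.zeros(1, dtype=np.int32)
    _extend(M0, 0, a, b)
    wf.M.append(M0)
    wf.I.append(None)
    wf.D.append(None)
    wf.lo.append(0)
    wf.hi.append(0)
    if k_end == 0 and int(M0[0]) >= n:
        return 0, wf
    # any alignment costs at most all-mismatch plus one flanking gap
    s_cap = x * min(n, m) + o + e * abs(n - m) + o + e
    s = 0
    while s < s_cap:
        s += 1
        # diagonal range of score s: one wider than any source wavefront
        bounds = []
        for ps, comp in ((s - x, "M"), (s - o - e, "M"), (s - e, "I"), (s - e, "D")):
            if 0 <= ps < len(wf.lo) and getattr(wf, comp)[ps] is not None:
                bounds.append((wf.lo[ps] - 1, wf.hi[ps] + 1))
        if not bounds:
            wf.push_empty()
            continue
        lo = max(-m, min(lo_ for lo_, _ in bounds))
        hi = min(n, max(hi_ for _, hi_ in bounds))
        if lo > hi:
            wf.push_empty()
            continue
        size = hi - lo + 1
        newM = np.empty(size, dtype=np.int32)
        newI = np.empty(size, dtype=np.int32)
        newD = np.empty(size, dtype=np.int32)

        def comp_of(ps: int, name: str) -> tuple[np.ndarray, int]:
            if 0 <= ps < len(wf.lo):
                arr = getattr(wf, name)[ps]
                if arr is not None:
                    return arr, wf.lo[ps]
            return _EMPTY, 0

        mx, lo_mx = comp_of(s - x, "M")
        moe, lo_moe = comp_of(s - o - e, "M")
        ie, lo_ie = comp_of(s - e, "I")
        de, lo_de = comp_of(s - e, "D")
        _next_wave(lo, hi, n, m, mx, lo_mx, moe, lo_moe, ie, lo_ie, de, lo_de, newM, newI, newD)
        _extend(newM, lo, a, b)
        wf.M.append(newM)
        wf.I.append(newI)
        wf.D.append(newD)
        wf.lo.append(lo)
        wf.hi.append(hi)
        if lo <= k_end <= hi and int(newM[k_end - lo]) >= n:
            return s, wf
    raise RuntimeError("wavefront search exceeded its score cap (internal error)")


def _traceback(wf: _Wavefronts, s: int, n: int, m: int, x: int, o: int, e: int) -> str:
    ops: list[str] = []  # collected right to left
    k = n - m
    comp = "M"
    h = wf.get("M", s, k)
    while True:
        if comp == "M":
            mv = wf.get("M", s - x, k)
            mv = mv + 1 if mv > NEG else int(NEG)
            if mv > min(n, m + k):  # mismatch step past either end
                mv = int(NEG)
            iv = wf.get("I", s, k)
            dv = wf.get("D", s, k)
            if s == 0:
                ops.append("M" * h)
                break
            pre = max(mv, iv, dv)
            run = h - pre
            if run > 0:
                ops.append("M" * run)
            h = pre
            if mv == pre:
                ops.append("X")
                s -= x
                h -= 1
            elif iv == pre:
                comp = "I"
            else:
                comp = "D"
        elif comp == "I":
            ops.append("I")
            from_m = wf.get("M", s - o - e, k + 1)
            if from_m == h:
                comp = "M"
                s -= o + e
            else:
                s -= e
            k += 1
        else:  # D
            ops.append("D")
            pre = h - 1
            from_m = wf.get("M", s - o - e, k - 1)
            if from_m == pre:
                comp = "M"
                s -= o + e
            else:
                s -= e
            k -= 1
            h = pre
    seq = "".join(reversed(ops))
    return _rle(seq)


def _rle(ops: str) -> str:
    if not ops:
        return ""
    out = []
    prev = ops[0]
    count = 1
    for c in ops[1:]:
        if c == prev:
            count += 1
        else:
            out.append(f"{count}{prev}")
            prev, count = c, 1
    out.append(f"{count}{prev}")
    return "".join(out)


def wfa_align(a: str, b: str, penalties: PenaltySet = PenaltySet()) -> AlignmentResult:
    """Optimal global gap-affine alignment of ``a`` vs ``b``.

    Returns the exact optimal cost and a CIGAR realizing it.  ``I`` denotes a
    column with a gap in the ``a`` row, ``D`` a gap in the ``b`` row.
    """
    if not a and not b:
        return AlignmentResult(0, "")
    if not a:
        return AlignmentResult(penalties.gap_cost(len(b)), f"{len(b)}I")
    if not b:
        return AlignmentResult(penalties.gap_cost(len(a)), f"{len(a)}D")
    x, o, e = penalties.mismatch, penalties.gap_open, penalties.gap_extend
    ac, bc = _encode(a), _encode(b)
    score, wf = _forward(ac, bc, x, o, e)
    cigar = _traceback(wf, score, len(a), len(b), x, o, e)
    return AlignmentResult(score, cigar)


def align_or_shortcut(a: str, b: str, penalties: PenaltySet = PenaltySet()) -> AlignmentResult:
    """Cheap dispatch: identical strings and empty sides skip the wavefronts."""
    if a == b:
        return AlignmentResult(0, f"{len(a)}M" if a else "")
    if not a:
        return AlignmentResult(penalties.gap_cost(len(b)), f"{len(b)}I")
    if not b:
        return AlignmentResult(penalties.gap_cost(len(a)), f"{len(a)}D")
    return wfa_align(a, b, penalties)


def cigar_cost(cigar: str, penalties: PenaltySet = PenaltySet()) -> int:
    """Re-derive the alignment cost encoded by a CIGAR string."""
    cost = 0
    for count, op in AlignmentResult(0, cigar).ops():
        if op == "X":
            cost += penalties.mismatch * count
        elif op in "ID":
            cost += penalties.gap_cost(count)
    return cost


def apply_cigar(a: str, b: str, cigar: str) -> tuple[str, str]:
    """Expand a CIGAR into the two gapped alignment rows (a row, b row)."""
    ra: list[str] = []
    rb: list[str] = []
    i = j = 0
    for count, op in AlignmentResult(0, cigar).ops():
        if op in "MX":
            ra.append(a[i : i + count])
            rb.append(b[j : j + count])
            i += count
            j += count
        elif op == "I":  # gap in a
            ra.append("-" * count)
            rb.append(b[j : j + count])
            j += count
        else:  # D: gap in b
            ra.append(a[i : i + count])
            rb.append("-" * count)
            i += count
    if i != len(a) or j != len(b):
        raise ValueError("CIGAR does not consume the full sequences")
    return "".join(ra), "".join(rb)
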