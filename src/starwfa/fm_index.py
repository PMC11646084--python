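"""FM-index over the center sequence: suffix array, BWT, and backward search.

The index supports exact-pattern counting/locating via backward search: a
suffix-array interval is narrowed one character at a time, right to left,
using the per-symbol cumulative counts C and the occurrence (rank) table of
the BWT.  Occurrence ranks are stored as a full prefix-count table, giving
O(1) rank queries at O(sigma * n) memory — the right trade at the scales this
package targets.

The text is terminated by a sentinel character that must be unique and sort
strictly before every other symbol ('$' for nucleotide data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SENTINEL = "$"


def build_suffix_array(text: str, sentinel: str = SENTINEL) -> np.ndarray:
    """Suffix array of ``text`` (which must end in a unique sentinel).

    Prefix-doubling over numpy ``lexsort`` — O(n log^2 n), comfortably fast
    for center sequences in the hundreds of kilobases.
    """
    if not text.endswith(sentinel) or text.count(sentinel) != 1:
        raise ValueError("text must contain the sentinel exactly once, at the end")
    n = len(text)
    codes = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    # initial ranks from single characters
    order = np.argsort(codes, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    sorted_codes = codes[order]
    rank[order] = np.cumsum(np.r_[0, (sorted_codes[1:] != sorted_codes[:-1]).astype(np.int64)])
    k = 1
    sa = order
    while k < n and rank.max() < n - 1:
        # pair ranks (rank[i], rank[i+k]) with -1 past the end
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        pair_first = rank[sa]
        pair_second = second[sa]
        changed = np.r_[
            0,
            ((pair_first[1:] != pair_first[:-1]) | (pair_second[1:] != pair_second[:-1])).astype(np.int64),
        ]
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.cumsum(changed)
        rank = new_rank
        k *= 2
    return sa.astype(np.int64)


def bwt_from_sa(text: str, sa: np.ndarray) -> str:
    """Last column of the sorted rotations, derived from the suffix array."""
    if len(sa) != len(text):
        raise ValueError("suffix array length does not match text")
    idx = (np.asarray(sa) - 1) % len(text)
    codes = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
    return codes[idx].tobytes().decode("latin-1")


def invert_bwt(bwt: str, sentinel: str = SENTINEL) -> str:
    """Reconstruct the original text by the LF-walk from the sentinel row."""
    n = len(bwt)
    codes = np.frombuffer(bwt.encode("latin-1"), dtype=np.uint8)
    order = np.argsort(codes, kind="stable")  # LF: row of bwt[i] in the first column
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(n)
    out = np.empty(n, dtype=np.uint8)
    # row 0 holds the rotation starting with the sentinel; walking LF from it
    # yields the text right to left
    out[n - 1] = ord(sentinel)
    row = 0
    for i in range(n - 2, -1, -1):
        out[i] = codes[row]
        row = int(lf[row])
    return out.tobytes().decode("latin-1")


@dataclass(frozen=True)
class SAInterval:
    """Half-open row range [lo, hi) of the suffix array matching a pattern."""

    lo: int
    hi: int

    def __len__(self) -> int:
        return self.hi - self.lo

    @property
    def empty(self) -> bool:
        return self.hi <= self.lo


class FMIndex:
    """Suffix array + BWT + rank structures over a sentinel-terminated text."""

    def __init__(self, residues: str, sentinel: str = SENTINEL):
        if sentinel in residues:
            raise ValueError("sentinel occurs in the text body")
        self.sentinel = sentinel
        self.text = residues + sentinel
        self.sa = build_suffix_array(self.text, sentinel)
        self.bwt = bwt_from_sa(self.text, self.sa)
        codes = np.frombuffer(self.text.encode("latin-1"), dtype=np.uint8)
        bwt_codes = np.frombuffer(self.bwt.encode("latin-1"), dtype=np.uint8)
        self.alphabet = sorted(set(self.text))
        self._sym_index = {c: i for i, c in enumerate(self.alphabet)}
        sigma = len(self.alphabet)
        alpha_codes = np.array([ord(c) for c in self.alphabet], dtype=np.uint8)
        counts = np.array([(codes == a).sum() for a in alpha_codes], dtype=np.int64)
        #: C[c] = number of text characters strictly smaller than symbol c
        self.count = np.r_[0, np.cumsum(counts)[:-1]]
        # full prefix-count table: occ[i, c] = occurrences of c in bwt[0:i)
        one_hot = bwt_codes[:, None] == alpha_codes[None, :]
        self.occ = np.zeros((len(self.text) + 1, sigma), dtype=np.int64)
        np.cumsum(one_hot, axis=0, out=self.occ[1:])

    def __len__(self) -> int:
        """Length of the indexed text including the sentinel."""
        return len(self.text)

    def full_interval(self) -> SAInterval:
        return SAInterval(0, len(self.text))

    def backward_step(self, interval: SAInterval, c: str) -> SAInterval:
        """Narrow ``interval`` (matching pattern P) to the interval of c·P."""
        j = self._sym_index.get(c)
        if j is None:
            if len(c) != 1:
                raise ValueError("backward_step takes a single symbol")
            if not c.isprintable() or c == self.sentinel:
                raise ValueError(f"symbol {c!r} outside the index alphabet")
            return SAInterval(0, 0)
        lo = int(self.count[j] + self.occ[interval.lo, j])
        hi = int(self.count[j] + self.occ[interval.hi, j])
        return SAInterval(lo, hi)

    def search(self, pattern: str) -> SAInterval:
        """Suffix-array interval of all occurrences of ``pattern``."""
        interval = self.full_interval()
        for c in reversed(pattern):
            interval = self.backward_step(interval, c)
            if interval.empty:
                break
        return interval

    def locate(self, interval: SAInterval) -> np.ndarray:
        """Sorted start positions of the pattern realizing ``interval``."""
        return np.sort(self.sa[interval.lo : interval.hi])


def count_occurrences(index: FMIndex, pattern: str) -> int:
    """Number of occurrences of ``pattern`` in the indexed text (sans sentinel).

    An empty pattern occurs at every text position by convention.
    """
    if not pattern:
        return len(index.text) - 1
    interval = index.search(pattern)
    return len(interval)
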