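"""Exact-match anchor discovery between the center and a query sequence.

For each query position the finder asks: what is the longest substring
starting here that occurs somewhere in the center?  Backward search on an
FM-index consumes a pattern right to left, so the natural way to grow a match
*rightward* from a fixed query position is to index the REVERSED center and
feed it query characters left to right — each backward step then extends the
forward-strand match by one base.  Interval start positions in the reversed
text map back to forward coordinates as x = |center| - r - w.

A match of length w qualifies as an anchor when w > l (strictly) and it is
nearly unique in the center: windows with more than ``max_occurrences``
center hits are discarded as repeats.  After an anchor at query position y of
length w, the scan restarts at y + w - l + 1, so consecutive anchors overlap
by at most l bases.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fm_index import FMIndex

DEFAULT_MIN_MATCH = 15
DEFAULT_MAX_OCCURRENCES = 10


@dataclass(frozen=True)
class PairMatch:
    """Exact common substring: center[x : x+w] == query[y : y+w]."""

    x: int
    y: int
    w: int

    @property
    def end_x(self) -> int:
        return self.x + self.w

    @property
    def end_y(self) -> int:
        return self.y + self.w


def build_reverse_index(center_residues: str) -> FMIndex:
    """FM-index of the reversed center, as used by the per-position scan."""
    return FMIndex(center_residues[::-1])


def _extend_from(rindex: FMIndex, residues: str, y: int) -> tuple[int, int, int]:
    """Longest center match starting at query position y, via the reverse index.

    Returns ``(x, w, n_occurrences)`` with x the smallest center start among
    the occurrences of the maximal-length window; w = 0 when no character
    matches.
    """
    n_center = len(rindex.text) - 1
    interval = rindex.full_interval()
    last = None
    w = 0
    for ch in residues[y:]:
        nxt = rindex.backward_step(interval, ch)
        if nxt.empty:
            break
        interval = nxt
        w += 1
        last = interval
    if w == 0 or last is None:
        return (-1, 0, 0)
    # reverse-text start r of the reversed window -> forward start
    starts = rindex.locate(last)
    x = int(min(n_center - r - w for r in starts))
    return (x, w, len(last))


def longest_match_at(rindex: FMIndex, residues: str, y: int):
    """Longest exact center match starting at query position ``y``.

    ``rindex`` must be the reverse-center index from
    :func:`build_reverse_index`.  Returns ``(x, w)`` with the smallest center
    start x on ties, or None when not even one character matches.
    """
    if not 0 <= y < len(residues):
        raise IndexError("query position out of range")
    x, w, _ = _extend_from(rindex, residues, y)
    return None if w == 0 else (x, w)


def find_candidates(
    rindex: FMIndex,
    residues: str,
    l: int = DEFAULT_MIN_MATCH,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
) -> list[PairMatch]:
    """Scan the query left to right and emit candidate anchors.

    At each position the maximal match is computed; if it is long enough
    (w > l) and occurs at most ``max_occurrences`` times in the center it is
    emitted and the scan jumps to y + w - l + 1, otherwise the scan advances
    one base.  Emitted anchors have strictly increasing y.
    """
    if l < 1:
        raise ValueError("minimum match length l must be >= 1")
    out: list[PairMatch] = []
    y = 0
    n = len(residues)
    while y < n:
        x, w, nocc = _extend_from(rindex, residues, y)
        if w > l and nocc <= max_occurrences:
            out.append(PairMatch(x, y, w))
            y += w - l + 1
        else:
            y += 1
    return out
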