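"""Pairwise center alignment and the center-referenced star merge.

Stage 2 aligns each query against the center: anchor blocks from the chain
are copied verbatim as match columns and only the segments between anchors
(plus the flanks) go through the wavefront aligner.  Stage 3 merges all
pairwise alignments into one MSA.  The merge works entirely in the center's
coordinate system: each pairwise alignment is summarized by a *gap profile*
counting how many gap columns it opens in each center slot (slot s = just
before center base s; slot |center| = after the last base).  The final
profile is the slot-wise maximum over all pairs, the center row is padded
accordingly, and each query row receives extra gap columns where the final
profile exceeds its own — placed before the pair's own slot gaps, a fixed
convention that keeps the merge deterministic and projection-faithful.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .anchor_finder import (
    DEFAULT_MAX_OCCURRENCES,
    DEFAULT_MIN_MATCH,
    build_reverse_index,
    find_candidates,
)
from .chainer import Chain, select_chain
from .sequence_io import GAP, Sequence, SequenceSet
from .wfa_aligner import PenaltySet, align_or_shortcut, apply_cigar


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows; no column is gapped in both."""

    center_row: str
    query_row: str

    def __post_init__(self) -> None:
        if len(self.center_row) != len(self.query_row):
            raise ValueError("alignment rows differ in length")


@dataclass
class MSA:
    """Rectangular gapped matrix; degapping row k reproduces input k."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("MSA is not rectangular")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class AlignParams:
    min_match_length: int = DEFAULT_MIN_MATCH
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES
    penalties: PenaltySet = field(default_factory=PenaltySet)
    workers: int = 1


def align_pair(
    center: Sequence,
    query: Sequence,
    chain: Chain,
    penalties: PenaltySet = PenaltySet(),
) -> PairwiseAlignment:
    """Segment the pair by its anchor chain and align the segments.

    Anchor blocks become match columns verbatim; flanks and inter-anchor
    segments are aligned gap-affine optimally.  An empty chain sends the
    whole pair through one wavefront alignment.
    """
    c, q = center.residues, query.residues
    prev_x = prev_y = 0
    c_parts: list[str] = []
    q_parts: list[str] = []
    for m in chain:
        if m.x < prev_x or m.y < prev_y or m.end_x > len(c) or m.end_y > len(q):
            raise ValueError("chain is inconsistent with the sequences")
        if c[m.x : m.end_x] != q[m.y : m.end_y]:
            raise ValueError("chain anchor is not an exact match")
        seg_c, seg_q = c[prev_x : m.x], q[prev_y : m.y]
        res = align_or_shortcut(seg_c, seg_q, penalties)
        rc, rq = apply_cigar(seg_c, seg_q, res.cigar)
        c_parts += [rc, c[m.x : m.end_x]]
        q_parts += [rq, q[m.y : m.end_y]]
        prev_x, prev_y = m.end_x, m.end_y
    seg_c, seg_q = c[prev_x:], q[prev_y:]
    res = align_or_shortcut(seg_c, seg_q, penalties)
    rc, rq = apply_cigar(seg_c, seg_q, res.cigar)
    c_parts.append(rc)
    q_parts.append(rq)
    return PairwiseAlignment("".join(c_parts), "".join(q_parts))


def gap_profile(pa: PairwiseAlignment, center_length: int) -> np.ndarray:
    """Count center-row gap columns per center slot (length |center| + 1)."""
    gaps = np.zeros(center_length + 1, dtype=np.int64)
    pos = 0  # next ungapped center position
    run = 0
    for ch in pa.center_row:
        if ch == GAP:
            run += 1
        else:
            gaps[pos] += run
            run = 0
            pos += 1
    gaps[pos] += run
    if pos != center_length:
        raise ValueError("degapped center row does not match the center length")
    return gaps


def _pad_query_row(pa: PairwiseAlignment, own: np.ndarray, final: np.ndarray) -> str:
    """Insert extra gap columns where the final profile exceeds this pair's own.

    Extra gaps go at the slot boundary, before the pair's own gap columns.
    """
    extra = final - own
    out: list[str] = []
    i = 0  # cursor in the pairwise columns
    row_c, row_q = pa.center_row, pa.query_row
    width = len(row_c)
    for slot in range(len(final)):
        out.append(GAP * int(extra[slot]))
        # this pair's own gap columns in the slot, then the center base column
        take = int(own[slot])
        out.append(row_q[i : i + take])
        i += take
        if slot < len(final) - 1:
            out.append(row_q[i])
            i += 1
    if i != width:
        raise ValueError("pairwise alignment columns not fully consumed")
    return "".join(out)


def merge_alignments(
    center: Sequence, pairwise: list[PairwiseAlignment], ids: list[str]
) -> MSA:
    """Merge center-referenced pairwise alignments into one rectangular MSA.

    ``ids`` identify the queries, in the order of ``pairwise``.  The merged
    MSA has the padded center as its first row followed by the query rows;
    callers that care about input order reposition the center row.
    """
    L = len(center.residues)
    profiles = []
    for pa in pairwise:
        if pa.center_row.replace(GAP, "") != center.residues:
            raise ValueError("pairwise alignment does not share the given center")
        profiles.append(gap_profile(pa, L))
    final = np.max(profiles, axis=0) if profiles else np.zeros(L + 1, dtype=np.int64)
    center_row = _pad_center_row(center.residues, final)
    rows = [_pad_query_row(pa, own, final) for pa, own in zip(pairwise, profiles)]
    return MSA([center.id] + list(ids), [center_row] + rows)


def _pad_center_row(residues: str, final: np.ndarray) -> str:
    out = []
    for slot in range(len(final)):
        out.append(GAP * int(final[slot]))
        if slot < len(residues):
            out.append(residues[slot])
    return "".join(out)


def _align_one(args) -> PairwiseAlignment:
    center, query, params = args
    rindex = _get_reverse_index(center.residues)
    candidates = find_candidates(
        rindex, query.residues, params.min_match_length, params.max_occurrences
    )
    chain = select_chain(candidates)
    return align_pair(center, query, chain, params.penalties)


_INDEX_CACHE: dict[int, tuple[str, object]] = {}


def _get_reverse_index(center_residues: str):
    """Per-process memo of the reverse-center FM-index (worker-safe)."""
    cached = _INDEX_CACHE.get(0)
    if cached is not None and cached[0] == center_residues:
        return cached[1]
    rindex = build_reverse_index(center_residues)
    _INDEX_CACHE[0] = (center_residues, rindex)
    return rindex


def align_all(seqs: SequenceSet, params: AlignParams = AlignParams()) -> MSA:
    """Full center-star pipeline: index, anchor, chain, align, merge.

    The per-query map is order-deterministic, so the output is byte-identical
    for any worker count.
    """
    center = seqs.center
    others = [s for i, s in enumerate(seqs.sequences) if i != seqs.center_index]
    jobs = [(center, q, params) for q in others]
    if params.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=params.workers) as pool:
            pairwise = list(pool.map(_align_one, jobs, chunksize=max(1, len(jobs) // params.workers)))
    else:
        pairwise = [_align_one(j) for j in jobs]
    other_ids = [s.id for s in others]
    merged = merge_alignments(center, pairwise, other_ids)
    center_row, rows = merged.rows[0], list(merged.rows[1:])
    rows.insert(seqs.center_index, center_row)
    ids = other_ids
    ids.insert(seqs.center_index, center.id)
    return MSA(ids, rows)
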