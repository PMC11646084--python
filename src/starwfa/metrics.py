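"""Alignment quality metrics: SP, scaled SP, Q, and TC.

The sum-of-pairs (SP) score sums, over every column and every unordered row
pair, +1 for a base match, -1 for a base mismatch, -2 when exactly one row is
gapped, and 0 when both are (charging shared gaps would double-count the
indel already paid for).  Scaled SP normalizes by the number of row pairs and
the alignment width,

    scaled_SP = 2 * SP / (n * (n - 1) * L),

so a gap-free, all-identical alignment scores exactly 1.  Q and TC compare a
test alignment to a reference with the same sequences: Q is the fraction of
reference-aligned residue pairs reproduced by the test (the classical
developer score), TC the fraction of reference columns reproduced exactly.
A fully reproduced column reproduces all its pairs, so TC <= Q always.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import GAP
from .star_msa import MSA

_GAP_CODE = 0


def _matrix(msa: MSA) -> np.ndarray:
    """Rows as a uint8 matrix; gaps coded 0, residues by their byte value."""
    if not msa.rows:
        raise ValueError("empty MSA")
    mat = np.frombuffer("".join(msa.rows).encode("latin-1"), dtype=np.uint8).reshape(
        len(msa.rows), msa.width
    )
    return np.where(mat == ord(GAP), _GAP_CODE, mat)


def sp_score(msa: MSA) -> int:
    """Sum-of-pairs score with match +1, mismatch -1, gap -2, gap pair 0."""
    if len(msa) < 2:
        raise ValueError("SP score requires at least two rows")
    mat = _matrix(msa)
    n = mat.shape[0]
    total_pairs = n * (n - 1) // 2
    gap_counts = (mat == _GAP_CODE).sum(axis=0)
    residue_counts = n - gap_counts
    # per column: sum over symbols of C(count, 2) = matching pairs
    match_pairs = np.zeros(mat.shape[1], dtype=np.int64)
    for sym in np.unique(mat):
        if sym == _GAP_CODE:
            continue
        c = (mat == sym).sum(axis=0).astype(np.int64)
        match_pairs += c * (c - 1) // 2
    residue_pairs = residue_counts.astype(np.int64) * (residue_counts - 1) // 2
    mismatch_pairs = residue_pairs - match_pairs
    gap_residue_pairs = gap_counts.astype(np.int64) * residue_counts
    col_scores = match_pairs - mismatch_pairs - 2 * gap_residue_pairs
    return int(col_scores.sum())


def scaled_sp_score(msa: MSA) -> float:
    """SP normalized by row-pair count and alignment width (saturates at 1)."""
    sp = sp_score(msa)
    n = len(msa)
    return 2.0 * sp / (n * (n - 1) * msa.width)


def _residue_indices(msa: MSA) -> np.ndarray:
    """Per cell: 0-based index of the residue within its row, or -1 for gaps."""
    mat = _matrix(msa)
    nongap = mat != _GAP_CODE
    idx = np.cumsum(nongap, axis=1) - 1
    return np.where(nongap, idx, -1)


def _check_comparable(test: MSA, ref: MSA) -> None:
    if test.ids != ref.ids:
        raise ValueError("test and reference MSAs have different record ids")
    for rid, t, r in zip(test.ids, test.rows, ref.rows):
        if t.replace(GAP, "") != r.replace(GAP, ""):
            raise ValueError(f"record {rid!r} differs between test and reference")


def q_score(test: MSA, ref: MSA) -> float:
    """Fraction of reference-aligned residue pairs reproduced by the test."""
    _check_comparable(test, ref)
    ti = _residue_indices(test)
    ri = _residue_indices(ref)
    n = len(ref)
    ref_pairs = 0
    shared = 0
    for i in range(n):
        for j in range(i + 1, n):
            rm = (ri[i] >= 0) & (ri[j] >= 0)
            if not rm.any():
                continue
            # encode an aligned residue pair as a single integer
            width = len(test.rows[j].replace(GAP, "")) + 1
            rp = ri[i][rm].astype(np.int64) * width + ri[j][rm]
            tm = (ti[i] >= 0) & (ti[j] >= 0)
            tp = ti[i][tm].astype(np.int64) * width + ti[j][tm]
            ref_pairs += rp.size
            shared += np.intersect1d(rp, tp, assume_unique=True).size
    if ref_pairs == 0:
        return 1.0
    return shared / ref_pairs


def tc_score(test: MSA, ref: MSA) -> float:
    """Fraction of reference columns reproduced exactly by the test.

    A column is identified by its full tuple of residue indices (gap = -1)
    across rows; all-gap columns are ignored on both sides.
    """
    _check_comparable(test, ref)
    ti = _residue_indices(test)
    ri = _residue_indices(ref)
    ref_cols = _column_keys(ri)
    test_cols = set(_column_keys(ti))
    if not ref_cols:
        return 1.0
    hit = sum(1 for c in ref_cols if c in test_cols)
    return hit / len(ref_cols)


def _column_keys(indices: np.ndarray) -> list[bytes]:
    keys = []
    arr = np.ascontiguousarray(indices.T.astype(np.int32))
    for col in arr:
        if (col < 0).all():
            continue
        keys.append(col.tobytes())
    return keys
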