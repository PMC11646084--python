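"""Synthetic similar-sequence datasets with a known true alignment.

The generator draws a uniform random root sequence and derives each output
sequence independently from it (a star topology — the same assumption the
center-star aligner itself makes), applying per-site substitutions and
geometric-length insertions/deletions.  Because every edit is recorded in
root coordinates, the exact multiple alignment of the derived sequences is
known and emitted alongside them.

The per-site substitution probability p is calibrated so that the *pairwise*
identity between two derived sequences matches the requested target: two
leaves agree at a root site with probability (1-p)^2 + p^2/3 (both untouched,
or both substituted to the same of three alternatives), so p solves

    (4/3) p^2 - 2 p + (1 - t) = 0.

Indel events are added on top at a rate of ``indel_fraction`` relative to
substitutions; insertions at unrelated leaves are left-aligned within the
same root slot in the true MSA, the standard convention for unalignable
insertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import GAP, Sequence
from .star_msa import MSA

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    n: int = 10
    root_length: int = 1000
    target_similarity: float = 0.95
    indel_fraction: float = 0.1
    indel_length_geometric_p: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two sequences")
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        if not 0.0 < self.target_similarity <= 1.0:
            raise ValueError("target_similarity must be in (0, 1]")
        if not 0.0 <= self.indel_fraction < 1.0:
            raise ValueError("indel_fraction must be in [0, 1)")
        if not 0.0 < self.indel_length_geometric_p <= 1.0:
            raise ValueError("indel_length_geometric_p must be in (0, 1]")


@dataclass
class SimResult:
    sequences: list[Sequence]
    true_msa: MSA
    params: SimParams


def substitution_probability(target_similarity: float) -> float:
    """Per-site, per-leaf substitution probability hitting the target identity."""
    t = target_similarity
    if t >= 1.0:
        return 0.0
    # (1-p)^2 + p^2/3 = t  ->  (4/3) p^2 - 2 p + (1 - t) = 0, smaller root
    disc = 4.0 - (16.0 / 3.0) * (1.0 - t)
    return (2.0 - math.sqrt(disc)) * 3.0 / 8.0


def simulate(params: SimParams) -> SimResult:
    """Generate ``n`` sequences from a common root plus their true MSA."""
    rng = np.random.default_rng(params.seed)
    L = params.root_length
    root = _BASES[rng.integers(0, 4, size=L)]
    p_sub = substitution_probability(params.target_similarity)
    f = params.indel_fraction
    p_indel = p_sub * f / (1.0 - f) if f > 0 else 0.0
    geo_p = params.indel_length_geometric_p

    # per leaf: surviving/substituted base per root site (0 = deleted) and
    # inserted residues per slot (slot i = before root site i; slot L = end)
    kept: list[np.ndarray] = []
    inserts: list[list[bytes]] = []
    for _ in range(params.n):
        while True:
            bases = root.copy()
            if p_sub > 0:
                sub_mask = rng.random(L) < p_sub
                n_sub = int(sub_mask.sum())
                if n_sub:
                    # substitute to one of the three other bases, uniformly
                    shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
                    old = bases[sub_mask]
                    old_idx = np.searchsorted(_BASES, old)  # _BASES is sorted
                    bases[sub_mask] = _BASES[(old_idx + shift) % 4]
            ins: list[bytes] = [b""] * (L + 1)
            if p_indel > 0:
                event_mask = rng.random(L) < p_indel
                for site in np.nonzero(event_mask)[0]:
                    length = int(rng.geometric(geo_p))
                    if rng.random() < 0.5:  # deletion of [site, site+length)
                        bases[site : site + length] = 0
                    else:  # insertion before root site
                        ins[site] = _BASES[rng.integers(0, 4, size=length)].tobytes()
            if bases.any() or any(ins):  # redraw the (rare) fully deleted leaf
                break
        kept.append(bases)
        inserts.append(ins)

    slot_width = np.zeros(L + 1, dtype=np.int64)
    for ins in inserts:
        for s, frag in enumerate(ins):
            if len(frag) > slot_width[s]:
                slot_width[s] = len(frag)

    ids = [f"seq{i+1}" for i in range(params.n)]
    rows: list[str] = []
    seqs: list[Sequence] = []
    for leaf in range(params.n):
        parts: list[str] = []
        bases = kept[leaf]
        ins = inserts[leaf]
        for s in range(L + 1):
            frag = ins[s].decode("latin-1")
            parts.append(frag + GAP * int(slot_width[s] - len(frag)))
            if s < L:
                parts.append(chr(bases[s]) if bases[s] else GAP)
        row = "".join(parts)
        rows.append(row)
        seqs.append(Sequence(ids[leaf], row.replace(GAP, "")))
    msa = MSA(ids, rows)
    return SimResult(seqs, msa, params)


def mean_pairwise_identity(msa: MSA) -> float:
    """Mean over row pairs of matches / columns where both rows have a base."""
    mat = np.frombuffer("".join(msa.rows).encode("latin-1"), dtype=np.uint8).reshape(
        len(msa.rows), msa.width
    )
    gap = ord(GAP)
    vals = []
    n = len(msa.rows)
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != gap) & (mat[j] != gap)
            tot = int(both.sum())
            if tot:
                vals.append(float((mat[i][both] == mat[j][both]).sum() / tot))
    return float(np.mean(vals)) if vals else 1.0


def length_series(template_lengths: list[int], base_params: SimParams) -> list[SimResult]:
    """One dataset per requested root length, seeds derived as seed + index."""
    if any(l < 1 for l in template_lengths):
        raise ValueError("lengths must be positive")
    out = []
    for i, L in enumerate(template_lengths):
        p = SimParams(
            n=base_params.n,
            root_length=L,
            target_similarity=base_params.target_similarity,
            indel_fraction=base_params.indel_fraction,
            indel_length_geometric_p=base_params.indel_length_geometric_p,
            seed=base_params.seed + i,
        )
        out.append(simulate(p))
    return out
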