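"""FASTA input/output, sequence preprocessing, and center selection.

Sequences are normalized onto the closed alphabet {A, C, G, T}: lowercase is
uppercased, U (RNA) maps to T, and every IUPAC ambiguity code is resolved to a
random base drawn from the set of bases the code denotes (N draws uniformly
from all four).  Resolution is seeded, so a run is reproducible end to end.

Coordinates everywhere in this package are 0-based with half-open intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

GAP = "-"

#: IUPAC nucleotide ambiguity codes -> the bases each denotes.  Characters
#: outside this table (and outside ACGTU) fall back to the full alphabet.
IUPAC_SETS = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Sequence:
    """An identified nucleotide sequence over {A, C, G, T}."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of preprocessed sequences plus its center.

    The center is a longest sequence of the set (lowest index on ties); no
    member is longer than ``sequences[center_index]``.
    """

    sequences: list[Sequence]
    center_index: int

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("SequenceSet requires at least one sequence")
        if not 0 <= self.center_index < len(self.sequences):
            raise ValueError("center_index out of range")
        cl = len(self.sequences[self.center_index])
        if any(len(s) > cl for s in self.sequences):
            raise ValueError("center must be a longest sequence")

    @property
    def center(self) -> Sequence:
        return self.sequences[self.center_index]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-line) FASTA file into ``(id, residues)`` records.

    Record ids are the header text up to the first whitespace; residue lines
    are concatenated verbatim (no normalization — see :func:`preprocess`).

    Raises
    ------
    ValueError
        If the file contains no sequences, or sequence data precedes the
        first header (with the offending line number).
    """
    if isinstance(path, io.TextIOBase):
        handle = path
        close = False
    else:
        handle = open(path)
        close = True
    records: list[tuple[str, str]] = []
    chunks: list[str] = []
    header: str | None = None
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"malformed FASTA: sequence data before any header at line {lineno}"
                    )
                chunks.append(line.strip())
    finally:
        if close:
            handle.close()
    if header is not None:
        records.append((header, "".join(chunks)))
    if not records:
        raise ValueError("no sequences")
    return records


def preprocess(raw_residues: str, rng_seed: int = 0) -> str:
    """Normalize raw residues onto {A, C, G, T}.

    Uppercases, maps U->T, and replaces each remaining non-ACGT character by a
    base drawn from the seeded generator: IUPAC codes draw from their denoted
    base set, anything else uniformly from the four bases.  The same seed and
    input always produce the same output.
    """
    if not raw_residues:
        raise ValueError("empty sequence")
    s = raw_residues.upper().replace("U", "T")
    if set(s) <= set("ACGT"):
        return s
    rng = np.random.default_rng(rng_seed)
    out = []
    for ch in s:
        if ch in "ACGT":
            out.append(ch)
        else:
            choices = IUPAC_SETS.get(ch, "ACGT")
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def select_center(seqs: list[Sequence]) -> int:
    """Index of the longest sequence (lowest index on length ties)."""
    if not seqs:
        raise ValueError("empty sequence list")
    best = 0
    for i, s in enumerate(seqs):
        if len(s) > len(seqs[best]):
            best = i
    return best


def load_sequence_set(path, seed: int = 0) -> SequenceSet:
    """Read, preprocess (per-record derived seeds) and wrap a FASTA file."""
    records = read_fasta(path)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(records))
    seqs = [
        Sequence(rid, preprocess(raw, int(child.generate_state(1)[0] % (2**31))))
        for (rid, raw), child in zip(records, children)
    ]
    return SequenceSet(seqs, select_center(seqs))


def write_fasta_records(records: Iterable[tuple[str, str]], path, wrap_width: int = 0) -> None:
    """Write ``(id, residues)`` records as FASTA; wrap_width 0 = one line per record."""
    if isinstance(path, io.TextIOBase):
        handle, close = path, False
    else:
        handle, close = open(path, "w"), True
    try:
        for rid, row in records:
            handle.write(f">{rid}\n")
            if wrap_width and wrap_width > 0:
                for i in range(0, len(row), wrap_width):
                    handle.write(row[i : i + wrap_width] + "\n")
            else:
                handle.write(row + "\n")
    finally:
        if close:
            handle.close()


def write_fasta(msa, path, wrap_width: int = 0) -> None:
    """Write an MSA (any object with ``ids`` and ``rows``) as gapped FASTA."""
    write_fasta_records(zip(msa.ids, msa.rows), path, wrap_width)
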