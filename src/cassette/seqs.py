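"""Small shared sequence utilities (DNA alphabet, FASTA IO, identity)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        raise ValueError("sequence length must be positive")
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def translate_dna(seq: str, table: int = 11) -> str:
    """Translate an in-frame coding sequence with the bacterial table."""
    return str(Seq(seq).translate(table=table))


def hamming_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("hamming identity needs equal-length sequences")
    if not a:
        return 1.0
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity(a: str, b: str, mode: str = "global") -> tuple[int, int, float]:
    """Best pairwise alignment of two sequences.

    Returns (matches, alignment_columns, identity) where identity is
    matches over alignment columns (gap columns included).
    """
    if not a and not b:
        return 0, 0, 1.0
    if not a or not b:
        n = max(len(a), len(b))
        return 0, n, 0.0
    aln = make_aligner(mode).align(a, b)[0]
    matches = 0
    cols = 0
    prev_a = prev_b = None
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            cols += max(a0 - prev_a, b0 - prev_b)
        matches += sum(a[i] == b[j] for i, j in zip(range(a0, a1), range(b0, b1)))
        cols += a1 - a0
        prev_a, prev_b = a1, b1
    # unaligned overhangs count as gap columns
    first_a = blocks_a[0][0] if len(blocks_a) else 0
    first_b = blocks_b[0][0] if len(blocks_b) else 0
    cols += max(first_a, first_b)
    cols += max(len(a) - (prev_a or 0), len(b) - (prev_b or 0))
    return matches, cols, (matches / cols if cols else 1.0)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
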