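"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

from typing import Iterator

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and convert RNA alphabet to DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA sequence in the RNA alphabet (T -> U) for reports."""
    return seq.upper().replace("T", "U")


def kmers(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def kmer_set(seqs, k: int, both_strands: bool = True) -> set:
    """All k-mers of every sequence; optionally include the reverse complement."""
    out: set = set()
    for s in seqs:
        out.update(kmers(s, k))
        if both_strands:
            out.update(kmers(revcomp(s), k))
    return out


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
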