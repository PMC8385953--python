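"""Exact-match short-read mapping over small genomes.

A k-mer hash index supports exact lookup of 15-35 nt queries on both strands;
an optional substitution-tolerant mode scans contigs directly (used for small
reference sets only). Coordinates are 0-based half-open; minus-strand hits
mean the reverse complement of the query matches the forward genome interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .util import hamming, normalize, revcomp

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


@dataclass(frozen=True, order=True)
class AlignmentHit:
    seq: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class PresenceFlags:
    """Per-sequence genome presence and structural-RNA flag."""

    seq: str
    in_plant: bool
    in_fungus: bool
    is_structural: bool
    hits: list = field(default_factory=list)


class GenomeIndex:
    """Hash index of all forward-strand k-mers of a genome."""

    def __init__(self, genome: Mapping[str, str], genome_id: str, k: int = 15):
        if not genome:
            raise ValueError("empty genome")
        self.k = k
        self.genome_id = genome_id
        self.contigs: dict = {}
        self._index: dict = {}
        kept = 0
        for contig, seq in genome.items():
            seq = normalize(seq)
            if len(seq) < k:
                logger.warning(
                    "contig %s shorter than k=%d excluded from index", contig, k)
                continue
            self.contigs[contig] = seq
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((contig, i))
            kept += 1
        if kept == 0:
            raise ValueError("no contig of length >= k; cannot build index")

    def _exact_occurrences(self, query: str) -> list:
        """All (contig, start) where query occurs on the forward strand."""
        out = []
        for contig, pos in self._index.get(query[: self.k], ()):
            if self.contigs[contig][pos : pos + len(query)] == query:
                out.append((contig, pos))
        return out

    def map_read(self, seq: str, max_mismatches: int = 0) -> list:
        """All occurrences of ``seq`` on both strands with at most
        ``max_mismatches`` substitutions (no indels), sorted by
        (contig, start, strand)."""
        q = normalize(seq)
        if not _VALID >= set(q) or not q:
            raise ValueError(f"query contains non-ACGT characters: {seq!r}")
        if len(q) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        hits = []
        if max_mismatches == 0:
            for contig, pos in self._exact_occurrences(q):
                hits.append(AlignmentHit(q, self.genome_id, contig,
                                         pos, pos + len(q), "+"))
            for contig, pos in self._exact_occurrences(revcomp(q)):
                hits.append(AlignmentHit(q, self.genome_id, contig,
                                         pos, pos + len(q), "-"))
        else:
            rc = revcomp(q)
            for contig, ref in self.contigs.items():
                for pos in range(len(ref) - len(q) + 1):
                    window = ref[pos : pos + len(q)]
                    if hamming(window, q) <= max_mismatches:
                        hits.append(AlignmentHit(q, self.genome_id, contig,
                                                 pos, pos + len(q), "+"))
                    if hamming(window, rc) <= max_mismatches:
                        hits.append(AlignmentHit(q, self.genome_id, contig,
                                                 pos, pos + len(q), "-"))
        hits.sort(key=lambda h: (h.contig, h.start, h.strand))
        return hits


def build_index(genome: Mapping[str, str], genome_id: str = "genome",
                k: int = 15) -> GenomeIndex:
    return GenomeIndex(genome, genome_id, k)


def map_read(seq: str, index: GenomeIndex, max_mismatches: int = 0) -> list:
    return index.map_read(seq, max_mismatches)


def flag_structural(seq: str, structural_set: Mapping[str, str] | Iterable[str]) -> bool:
    """True iff ``seq`` (either strand) is an exact substring of any
    structural tRNA/rRNA reference sequence."""
    refs = structural_set.values() if isinstance(structural_set, Mapping) else structural_set
    q = normalize(seq)
    rc = revcomp(q)
    return any(q in normalize(r) or rc in normalize(r) for r in refs)


def annotate_presence(reads, plant_index: GenomeIndex, fungal_index: GenomeIndex,
                      structural_set) -> list:
    """One PresenceFlags per unique sequence.

    Structural flagging runs before genome lookup: structural reads never
    enter origin classification and carry no alignment hits.
    """
    flags = []
    for read in reads:
        seq = read.seq if hasattr(read, "seq") else read
        if flag_structural(seq, structural_set):
            flags.append(PresenceFlags(seq, False, False, True, []))
            continue
        plant_hits = plant_index.map_read(seq)
        fungal_hits = fungal_index.map_read(seq)
        flags.append(
            PresenceFlags(seq, bool(plant_hits), bool(fungal_hits), False,
                          plant_hits + fungal_hits)
        )
    return flags
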