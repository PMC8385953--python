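"""Small-RNA locus calling with DicerCall and known-miRNA matching.

Aligned reads are merged into loci by single-linkage clustering of their
genomic intervals (gap <= merge_gap on the same contig). A locus gets a
DicerCall — the modal read length within the Dicer-typical 20-24 nt window —
when reads of those sizes dominate the locus; its predominant sequence is
matched against a mature-miRNA reference by Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .mapper import AlignmentHit
from .util import hamming, normalize


@dataclass
class SrnaLocus:
    contig: str
    start: int
    end: int
    reads: list = field(default_factory=list)     # (AlignmentHit, count)
    predominant_seq: str = ""
    dicer_call: str = "N"
    matched_mirna: str | None = None

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.reads)


def call_loci(hits_with_counts: Iterable[tuple], merge_gap: int = 75,
              min_total_reads: int = 5) -> list:
    """Single-linkage merge of (AlignmentHit, count) pairs into loci.

    Two alignments join the same locus when they sit on the same contig and
    the gap between their intervals is <= merge_gap nt. Loci with fewer than
    ``min_total_reads`` total reads are dropped; output is ordered by
    (contig, start).
    """
    by_contig: dict = {}
    for hit, count in hits_with_counts:
        by_contig.setdefault(hit.contig, []).append((hit, count))
    loci = []
    for contig in sorted(by_contig):
        items = sorted(by_contig[contig], key=lambda hc: (hc[0].start, hc[0].end))
        current: SrnaLocus | None = None
        for hit, count in items:
            if current is not None and hit.start - current.end <= merge_gap:
                current.end = max(current.end, hit.end)
                current.reads.append((hit, count))
            else:
                if current is not None:
                    loci.append(current)
                current = SrnaLocus(contig, hit.start, hit.end, [(hit, count)])
        if current is not None:
            loci.append(current)
    loci = [l for l in loci if l.total_count >= min_total_reads]
    for locus in loci:
        tally: dict = {}
        for hit, count in locus.reads:
            tally[hit.seq] = tally.get(hit.seq, 0) + count
        locus.predominant_seq = min(
            tally, key=lambda s: (-tally[s], s))  # ties -> lexicographic smallest
    return loci


def dicer_call(locus: SrnaLocus, dicer_min: int = 20, dicer_max: int = 24,
               dominance: float = 0.8) -> str:
    """Modal in-window read length when the count-weighted fraction of
    20-24 nt reads reaches ``dominance`` (boundary inclusive); else 'N'."""
    total = locus.total_count
    if total == 0:
        return "N"
    by_len: dict = {}
    for hit, count in locus.reads:
        length = len(hit.seq)
        by_len[length] = by_len.get(length, 0) + count
    in_window = sum(c for length, c in by_len.items()
                    if dicer_min <= length <= dicer_max)
    if in_window / total < dominance:
        return "N"
    modal = min(
        (length for length in by_len if dicer_min <= length <= dicer_max),
        key=lambda length: (-by_len[length], length),
    )
    return str(modal)


def match_mirna(predominant_seq: str, mirna_reference: Mapping[str, str],
                max_mm: int = 1) -> str | None:
    """Best reference mature miRNA within ``max_mm`` substitutions over equal
    length (no indels); ties break by fewest mismatches, then reference
    order. None when nothing qualifies."""
    query = normalize(predominant_seq)
    best_id, best_mm = None, max_mm + 1
    for ref_id, ref_seq in mirna_reference.items():
        ref = normalize(ref_seq)
        if len(ref) != len(query):
            continue
        mm = hamming(query, ref)
        if mm < best_mm:
            best_id, best_mm = ref_id, mm
    return best_id


def annotate_loci(loci: Iterable[SrnaLocus], mirna_reference: Mapping[str, str],
                  max_mm: int = 1, **dicer_kwargs) -> list:
    """Apply DicerCall and miRNA matching to every locus in place."""
    out = []
    for locus in loci:
        locus.dicer_call = dicer_call(locus, **dicer_kwargs)
        locus.matched_mirna = match_mirna(locus.predominant_seq,
                                          mirna_reference, max_mm)
        out.append(locus)
    return out
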