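"""Adapter trimming, size filtering, and collapsing of sRNA reads.

Raw small-RNA reads carry the 3' sequencing adapter; a read without adapter
evidence is rejected (no insert boundary can be located). Trimmed inserts are
kept at 15-35 nt with no ambiguous bases, then collapsed to unique sequences
with per-sample counts — the pipeline's atom.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .util import normalize


@dataclass
class CollapsedRead:
    """A unique sRNA sequence with per-sample raw counts."""

    seq: str
    counts: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_adapter(read_seq: str, adapter: str, min_overlap: int = 8) -> str | None:
    """Remove the 3' adapter; return the insert, or None when no adapter
    evidence is found (REJECT).

    The insert is the prefix preceding the leftmost full adapter occurrence;
    failing that, a terminal read-suffix / adapter-prefix overlap of at least
    ``min_overlap`` nt is accepted (the longest such overlap, i.e. the
    leftmost cut). Empty inserts (adapter dimers) are rejected.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = normalize(read_seq)
    adapter = normalize(adapter)
    if not read:
        return None
    idx = read.find(adapter)
    if idx == -1:
        max_ov = min(len(adapter) - 1, len(read))
        for ov in range(max_ov, min_overlap - 1, -1):
            if read.endswith(adapter[:ov]):
                idx = len(read) - ov
                break
        else:
            return None
    return read[:idx] or None


def filter_reads(trimmed: Iterable[str], min_len: int = 15, max_len: int = 35) -> list:
    """Keep sequences with length in [min_len, max_len] and A/C/G/T only."""
    ok = set("ACGT")
    return [s for s in trimmed if min_len <= len(s) <= max_len and set(s) <= ok]


def collapse(seqs_per_sample: Mapping[str, Iterable[str]]) -> list:
    """Collapse filtered sequences to unique CollapsedReads.

    Counts conserve input totals per sample; output is sorted
    lexicographically by sequence for determinism.
    """
    per_seq: dict = {}
    for sample, seqs in seqs_per_sample.items():
        for seq, n in Counter(seqs).items():
            per_seq.setdefault(seq, {})[sample] = (
                per_seq.get(seq, {}).get(sample, 0) + n
            )
    return [CollapsedRead(seq, per_seq[seq]) for seq in sorted(per_seq)]


def collapse_counts(counts_per_sample: Mapping[str, Mapping[str, int]]) -> list:
    """As :func:`collapse`, but from pre-counted {sample: {seq: count}}."""
    per_seq: dict = {}
    for sample, counts in counts_per_sample.items():
        for seq, n in counts.items():
            if n:
                per_seq.setdefault(seq, {})[sample] = n
    return [CollapsedRead(seq, per_seq[seq]) for seq in sorted(per_seq)]


def prepare_sample(raw_reads: Iterable[str], adapter: str, min_overlap: int = 8,
                   min_len: int = 15, max_len: int = 35) -> list:
    """Trim + filter one sample's raw reads; returns the surviving inserts."""
    trimmed = (trim_adapter(r, adapter, min_overlap) for r in raw_reads)
    return filter_reads((t for t in trimmed if t is not None), min_len, max_len)
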