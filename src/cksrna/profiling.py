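"""Size-distribution and 5'-terminal-nucleotide profiles.

Profiles are computed per (organism x sample x pipeline branch) on either the
total fraction (count-weighted) or the unique fraction (each distinct
sequence once). Lengths run 15-35 nt, the post-filter range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .util import to_rna

LENGTH_RANGE = range(15, 36)
RNA_BASES = ("A", "C", "G", "U")


@dataclass
class SizeProfile:
    weighting: str                                 # 'total' | 'unique'
    counts: dict = field(default_factory=dict)     # length -> count
    sample_class: str | None = None
    organism: str | None = None

    def modes(self, n: int = 2) -> set:
        """The n most frequent lengths (ties by smaller length)."""
        ranked = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return {length for length, c in ranked[:n] if c > 0}


@dataclass
class FivePrimeProfile:
    weighting: str
    fractions: dict = field(default_factory=dict)  # length -> {base: fraction}
    occupied: dict = field(default_factory=dict)   # length -> bool


def _weights(seq_counts: Mapping[str, int], weighting: str):
    if weighting not in ("total", "unique"):
        raise ValueError("weighting must be 'total' or 'unique'")
    for seq, n in seq_counts.items():
        if n > 0:
            yield seq, (n if weighting == "total" else 1)


def size_distribution(seq_counts: Mapping[str, int], weighting: str = "total",
                      sample_class: str | None = None,
                      organism: str | None = None) -> SizeProfile:
    """Length histogram of one read pool ({sequence: raw count})."""
    counts = {length: 0 for length in LENGTH_RANGE}
    for seq, w in _weights(seq_counts, weighting):
        counts[len(seq)] += w
    return SizeProfile(weighting, counts, sample_class, organism)


def five_prime_composition(seq_counts: Mapping[str, int],
                           weighting: str = "total") -> FivePrimeProfile:
    """Per-length first-base fractions, rendered in the RNA alphabet."""
    tallies = {length: {b: 0 for b in RNA_BASES} for length in LENGTH_RANGE}
    for seq, w in _weights(seq_counts, weighting):
        tallies[len(seq)][to_rna(seq[0])] += w
    fractions, occupied = {}, {}
    for length, tally in tallies.items():
        total = sum(tally.values())
        occupied[length] = total > 0
        fractions[length] = (
            {b: tally[b] / total for b in RNA_BASES} if total
            else {b: 0.0 for b in RNA_BASES}
        )
    return FivePrimeProfile(weighting, fractions, occupied)


def profiles_to_frame(profiles: Mapping[str, SizeProfile]) -> pd.DataFrame:
    """Flatten named SizeProfiles into one TSV-ready table."""
    rows = []
    for name, prof in profiles.items():
        for length in LENGTH_RANGE:
            rows.append({
                "profile": name, "sample_class": prof.sample_class,
                "organism": prof.organism, "weighting": prof.weighting,
                "length": length, "count": prof.counts.get(length, 0),
            })
    return pd.DataFrame(rows)
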