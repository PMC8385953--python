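"""Origin classification, RPM normalization, induction selection, and
sample-set comparisons.

Each unique read is assigned one origin per sample: structural RNA first,
then plant-only, fungus-only, ambiguous (both genomes) or unmapped. Reads of
one organism are normalized to reads-per-million over that organism's mapped
total within the sample, and a read is called induced when it is exclusive to
the colonized sample (log2FC rendered as NA) or has positive
log2(colonized/control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .mapper import PresenceFlags

ORIGIN_PLANT = "plant"
ORIGIN_FUNGUS = "fungus"
ORIGIN_AMBIGUOUS = "ambiguous"
ORIGIN_UNMAPPED = "unmapped"
ORIGIN_STRUCTURAL = "structural"
ORIGINS = (ORIGIN_PLANT, ORIGIN_FUNGUS, ORIGIN_AMBIGUOUS,
           ORIGIN_UNMAPPED, ORIGIN_STRUCTURAL)


@dataclass
class OriginCall:
    seq: str
    sample_class: str
    origin: str


@dataclass
class ExpressionRecord:
    """Per-sRNA expression in colonized vs control.

    ``log2fc`` is None (reported NA) iff the read is absent from the control
    but present in the colonized sample.
    """

    seq: str
    organism: str
    rpm_colonized: float
    rpm_control: float
    log2fc: float | None
    induced: bool = False
    high: bool = False


@dataclass
class SetComparison:
    exclusive_a: int
    exclusive_b: int
    shared: int
    pct_exclusive_a: float
    pct_exclusive_b: float
    pct_shared: float


def classify_origin(flags: PresenceFlags, sample_class: str) -> OriginCall:
    """Resolve a read's origin from its presence flags (structural first)."""
    if flags.is_structural:
        origin = ORIGIN_STRUCTURAL
    elif flags.in_plant and flags.in_fungus:
        origin = ORIGIN_AMBIGUOUS
    elif flags.in_plant:
        origin = ORIGIN_PLANT
    elif flags.in_fungus:
        origin = ORIGIN_FUNGUS
    else:
        origin = ORIGIN_UNMAPPED
    return OriginCall(flags.seq, sample_class, origin)


def rpm_normalize(count: int, total_mapped_same_genome: int) -> float:
    """count -> reads per million of the same organism's mapped total."""
    if total_mapped_same_genome <= 0:
        raise ValueError("organism has no mapped reads in this sample")
    if count > total_mapped_same_genome:
        raise ValueError("count exceeds the mapped total")
    return 1e6 * count / total_mapped_same_genome


def compute_log2fc(rpm_colonized: float, rpm_control: float) -> float | None:
    """log2(colonized/control); None (NA) when the read is
    colonized-exclusive. Errors when both are zero."""
    if rpm_colonized == 0 and rpm_control == 0:
        raise ValueError("log2 fold change undefined when both RPM are zero")
    if rpm_control == 0:
        return None
    if rpm_colonized == 0:
        raise ValueError(
            "colonized RPM of zero should be excluded upstream of log2FC")
    return math.log2(rpm_colonized / rpm_control)


def build_expression(colonized_counts: Mapping[str, int],
                     control_counts: Mapping[str, int],
                     origin_of: Mapping[str, str],
                     organism: str) -> list:
    """ExpressionRecords for every read of ``organism`` present in the
    colonized sample. Control-only reads (colonized RPM 0) are excluded —
    they cannot be induced and their fold change is -inf."""
    col_total = sum(n for s, n in colonized_counts.items()
                    if origin_of.get(s) == organism)
    ctrl_total = sum(n for s, n in control_counts.items()
                     if origin_of.get(s) == organism)
    records = []
    for seq, n in colonized_counts.items():
        if origin_of.get(seq) != organism or n == 0:
            continue
        rpm_col = rpm_normalize(n, col_total)
        ctrl_n = control_counts.get(seq, 0)
        rpm_ctrl = rpm_normalize(ctrl_n, ctrl_total) if ctrl_n else 0.0
        records.append(ExpressionRecord(
            seq, organism, rpm_col, rpm_ctrl, compute_log2fc(rpm_col, rpm_ctrl)))
    records.sort(key=lambda r: r.seq)
    return records


def select_induced(records: Iterable[ExpressionRecord],
                   length_filter: int | None = 21) -> list:
    """Retain colonized-exclusive (NA) or positively induced records,
    optionally restricted to one read length; records with log2FC > 1 are
    flagged highly upregulated."""
    out = []
    for rec in records:
        if length_filter is not None and len(rec.seq) != length_filter:
            continue
        if rec.log2fc is None or rec.log2fc > 0:
            rec.induced = True
            rec.high = rec.log2fc is not None and rec.log2fc > 1
            out.append(rec)
    return out


def compare_sets(unique_seqs_a, unique_seqs_b) -> SetComparison:
    """Exclusive/shared unique-sequence counts and percentages of the union
    (one decimal)."""
    a, b = set(unique_seqs_a), set(unique_seqs_b)
    if not a and not b:
        raise ValueError("both sets are empty")
    shared = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    union = only_a + only_b + shared
    return SetComparison(
        only_a, only_b, shared,
        round(100.0 * only_a / union, 1),
        round(100.0 * only_b / union, 1),
        round(100.0 * shared / union, 1),
    )


def classify_sample(presence: Iterable[PresenceFlags],
                    sample_counts: Mapping[str, int],
                    sample_class: str) -> dict:
    """Partition one sample's reads by origin.

    Returns {"origin_of": seq->origin, "unique": origin->n unique,
    "raw": origin->n raw reads} restricted to sequences present in the
    sample. The five origin classes partition both totals exactly.
    """
    origin_of = {}
    unique = {o: 0 for o in ORIGINS}
    raw = {o: 0 for o in ORIGINS}
    for flags in presence:
        n = sample_counts.get(flags.seq, 0)
        if n == 0:
            continue
        call = classify_origin(flags, sample_class)
        origin_of[flags.seq] = call.origin
        unique[call.origin] += 1
        raw[call.origin] += n
    return {"origin_of": origin_of, "unique": unique, "raw": raw}
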