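"""Confirmation of predicted ck-sRNA targets against differential expression.

A predicted (sRNA, transcript) pair is confirmed when the transcript's gene
is significantly downregulated in the partner organism (padj < alpha and
log2FC < 0). Confirmed duplex records join the sRNA's own induction status
(log2FC, or NA when colonized-exclusive) with the target's fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DeRecord:
    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self):
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError("padj must lie in [0, 1]")


@dataclass
class DuplexRecord:
    srna_id: str
    srna_seq: str
    srna_log2fc: float | None      # None rendered as NA (colonized-exclusive)
    transcript_id: str
    gene_id: str
    description: str
    target_log2fc: float
    target_padj: float
    expectation: float


def default_gene_map(transcript_id: str) -> str:
    """Strip a trailing '.N' isoform suffix to get the gene id."""
    stem, _, suffix = transcript_id.rpartition(".")
    return stem if stem and suffix.isdigit() else transcript_id


def _as_de_lookup(de_table) -> dict:
    if isinstance(de_table, pd.DataFrame):
        return {
            str(r.gene_id): DeRecord(str(r.gene_id), float(r.log2FC), float(r.padj))
            for r in de_table.itertuples()
        }
    return {rec.gene_id: rec for rec in de_table}


def confirm_targets(predictions: Iterable, de_table, alpha: float = 0.05,
                    gene_map: Callable[[str], str] | None = None,
                    srna_ids: Mapping[str, str] | None = None,
                    srna_expression: Mapping[str, float | None] | None = None,
                    descriptions: Mapping[str, str] | None = None) -> list:
    """Join target predictions with the partner DE table.

    Keeps pairs whose gene has padj < alpha AND log2FC < 0. Unresolvable
    transcript ids are logged and skipped. Output is sorted by target log2FC
    ascending (strongest downregulation first).
    """
    gene_map = gene_map or default_gene_map
    lookup = _as_de_lookup(de_table)
    srna_ids = srna_ids or {}
    srna_expression = srna_expression or {}
    descriptions = descriptions or {}
    out = []
    for pred in predictions:
        gene = gene_map(pred.transcript_id)
        rec = lookup.get(gene)
        if rec is None:
            logger.warning("transcript %s has no DE record; skipped",
                           pred.transcript_id)
            continue
        if rec.padj < alpha and rec.log2fc < 0:
            out.append(DuplexRecord(
                srna_id=srna_ids.get(pred.srna_seq, pred.srna_seq),
                srna_seq=pred.srna_seq,
                srna_log2fc=srna_expression.get(pred.srna_seq),
                transcript_id=pred.transcript_id,
                gene_id=gene,
                description=descriptions.get(pred.transcript_id, ""),
                target_log2fc=rec.log2fc,
                target_padj=rec.padj,
                expectation=pred.expectation,
            ))
    out.sort(key=lambda d: (d.target_log2fc, d.transcript_id, d.srna_seq))
    return out


def summarize_coverage(n_confirmed_unique_targets: int, n_total_degs: int,
                       decimals: int = 1) -> float:
    """Confirmed unique targets as a percentage of all DEGs (half-up
    rounding at ``decimals``)."""
    if n_total_degs <= 0:
        raise ValueError("n_total_degs must be positive")
    if n_confirmed_unique_targets > n_total_degs:
        raise ValueError("confirmed targets cannot exceed total DEGs")
    pct = Decimal(100 * n_confirmed_unique_targets) / Decimal(n_total_degs)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def duplex_table(records: Iterable[DuplexRecord]) -> pd.DataFrame:
    """Confirmed duplexes as a report table (NA for exclusive sRNAs)."""
    return pd.DataFrame([
        {
            "srna_id": r.srna_id,
            "srna_expression": "NA" if r.srna_log2fc is None
            else round(r.srna_log2fc, 2),
            "target_transcript": r.transcript_id,
            "description": r.description,
            "target_log2fc": round(r.target_log2fc, 2),
            "expectation": r.expectation,
        }
        for r in records
    ])
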