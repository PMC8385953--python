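"""End-to-end orchestration: simulate -> prep -> map -> classify -> profile
-> loci -> targets -> integrate."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, integrate, locus, profiling, readprep, targets
from .config import SimulationConfig
from .mapper import annotate_presence, build_index
from .simulate import (BD_C, BD_SI, FUNGUS, PLANT, SAMPLE_CLASSES, SI_AX,
                       SyntheticDataset, simulate_dataset)


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    sample_counts: dict                  # sample -> {insert seq: raw count}
    collapsed: list                      # CollapsedRead, all samples
    presence: list                       # PresenceFlags per unique seq
    origin_of: dict                      # seq -> origin (sample-independent)
    partitions: dict                     # sample -> classify_sample() output
    expression: dict                     # organism -> [ExpressionRecord]
    induced: dict                        # organism -> induced subset
    predictions: dict                    # organism -> [DuplexScore]
    confirmed: dict                      # organism -> [DuplexRecord]
    coverage_percent: dict               # organism -> % of partner DEGs hit
    loci: list                           # annotated plant SrnaLoci (Bd-Si)
    size_profiles: dict = field(default_factory=dict)
    five_prime: dict = field(default_factory=dict)


def _srna_ids(induced_records, prefix):
    return {rec.seq: f"{prefix}sRNA {i + 1}"
            for i, rec in enumerate(induced_records)}


def run_pipeline(cfg: SimulationConfig | None = None,
                 dataset: SyntheticDataset | None = None,
                 expectation_cutoff: float = 5.0,
                 merge_gap: int = 75, min_total_reads: int = 5) -> PipelineResult:
    """Run the full discovery pipeline on a synthetic dataset.

    Either a configuration (a dataset is simulated) or a ready dataset may be
    given. Induced ck-sRNA candidates of each organism are screened against
    the partner transcriptome and confirmed against the partner DE table.
    """
    if dataset is None:
        if cfg is None:
            raise ValueError("provide a SimulationConfig or a SyntheticDataset")
        dataset = simulate_dataset(cfg)
    cfg = dataset.config

    # read prep: trim, filter, collapse
    sample_counts = {}
    for sample in SAMPLE_CLASSES:
        inserts = readprep.prepare_sample(
            (seq for _, seq in dataset.reads[sample]), cfg.adapter_seq)
        sample_counts[sample] = dict(Counter(inserts))
    collapsed = readprep.collapse_counts(sample_counts)

    # mapping and presence flags
    plant_index = build_index(dataset.plant_genome, PLANT, k=cfg.uniqueness_k)
    fungal_index = build_index(dataset.fungal_genome, FUNGUS, k=cfg.uniqueness_k)
    presence = annotate_presence(collapsed, plant_index, fungal_index,
                                 dataset.structural)
    flags_of = {f.seq: f for f in presence}

    partitions = {
        sample: classify.classify_sample(presence, sample_counts[sample], sample)
        for sample in SAMPLE_CLASSES
    }
    origin_of = {f.seq: classify.classify_origin(f, BD_SI).origin
                 for f in presence}

    # expression and induction, per organism against its control sample
    expression = {
        PLANT: classify.build_expression(
            sample_counts[BD_SI], sample_counts[BD_C], origin_of, PLANT),
        FUNGUS: classify.build_expression(
            sample_counts[BD_SI], sample_counts[SI_AX], origin_of, FUNGUS),
    }
    induced = {org: classify.select_induced(expression[org], cfg.ck_len)
               for org in (PLANT, FUNGUS)}

    # ck branch: induced sRNAs vs the partner transcriptome, then DE check
    partner_tx = {PLANT: dataset.fungal_transcriptome,
                  FUNGUS: dataset.plant_transcriptome}
    partner_de = {PLANT: dataset.de_fungal, FUNGUS: dataset.de_plant}
    predictions, confirmed, coverage = {}, {}, {}
    for org in (PLANT, FUNGUS):
        preds = []
        for rec in induced[org]:
            preds.extend(targets.predict_targets(
                rec.seq, partner_tx[org], cutoff=expectation_cutoff))
        predictions[org] = preds
        ids = _srna_ids(induced[org], "Si" if org == FUNGUS else "Bd")
        expr = {rec.seq: rec.log2fc for rec in induced[org]}
        confirmed[org] = integrate.confirm_targets(
            preds, partner_de[org], alpha=cfg.de_alpha, srna_ids=ids,
            srna_expression=expr, descriptions=dataset.descriptions)
        de = partner_de[org]
        n_degs = int((de["padj"] < cfg.de_alpha).sum())
        n_conf = len({d.transcript_id for d in confirmed[org]})
        coverage[org] = (integrate.summarize_coverage(n_conf, n_degs)
                         if n_degs else 0.0)

    # endogenous branch: plant sRNA loci in the colonized sample
    hits_with_counts = []
    for seq, n in sample_counts[BD_SI].items():
        if origin_of.get(seq) == PLANT:
            for hit in flags_of[seq].hits:
                if hit.genome_id == PLANT:
                    hits_with_counts.append((hit, n))
    plant_loci = locus.call_loci(hits_with_counts, merge_gap=merge_gap,
                                 min_total_reads=min_total_reads)
    locus.annotate_loci(plant_loci, dataset.mirna_reference)

    # profiles per organism x sample
    size_profiles, five_prime = {}, {}
    for sample in SAMPLE_CLASSES:
        for org in (PLANT, FUNGUS):
            pool = {s: n for s, n in sample_counts[sample].items()
                    if origin_of.get(s) == org}
            if not pool:
                continue
            for weighting in ("total", "unique"):
                key = (sample, org, weighting)
                size_profiles[key] = profiling.size_distribution(
                    pool, weighting, sample, org)
                five_prime[key] = profiling.five_prime_composition(pool, weighting)

    return PipelineResult(
        dataset=dataset, sample_counts=sample_counts, collapsed=collapsed,
        presence=presence, origin_of=origin_of, partitions=partitions,
        expression=expression, induced=induced, predictions=predictions,
        confirmed=confirmed, coverage_percent=coverage, loci=plant_loci,
        size_profiles=size_profiles, five_prime=five_prime,
    )


def recovery_metrics(result: PipelineResult) -> dict:
    """Precision/recall of confirmed duplexes against the planted truth.

    Pairs are (sRNA sequence, target transcript id); the truth set is the
    planted ck ledger of both directions.
    """
    truth_pairs = {(ck.srna_seq, ck.target_transcript_id)
                   for ck in result.dataset.truth.planted_ck
                   if ck.target_transcript_id}
    found_pairs = {(d.srna_seq, d.transcript_id)
                   for org in result.confirmed
                   for d in result.confirmed[org]}
    tp = len(found_pairs & truth_pairs)
    precision = tp / len(found_pairs) if found_pairs else 0.0
    recall = tp / len(truth_pairs) if truth_pairs else 0.0
    return {"true_positive": tp, "n_found": len(found_pairs),
            "n_planted": len(truth_pairs),
            "precision": precision, "recall": recall}


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write the pipeline's tabular outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for org in (PLANT, FUNGUS):
        rows = [{
            "seq": r.seq, "origin": r.organism,
            "rpm_colonized": r.rpm_colonized, "rpm_control": r.rpm_control,
            "log2fc": "NA" if r.log2fc is None else r.log2fc,
            "induced": r.induced, "high": r.high,
        } for r in result.expression[org]]
        pd.DataFrame(rows).to_csv(outdir / f"expression_{org}.tsv",
                                  sep="\t", index=False)
        integrate.duplex_table(result.confirmed[org]).to_csv(
            outdir / f"confirmed_duplexes_{org}_origin.tsv", sep="\t", index=False)
    profiling.profiles_to_frame(
        {f"{s}|{o}|{w}": p for (s, o, w), p in result.size_profiles.items()}
    ).to_csv(outdir / "size_profiles.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "locus": f"{l.contig}:{l.start}-{l.end}",
        "predominant_srna": l.predominant_seq.replace("T", "U"),
        "dicer_call": l.dicer_call,
        "known_mirna": l.matched_mirna or "",
        "total_reads": l.total_count,
    } for l in result.loci]).to_csv(outdir / "srna_loci.tsv", sep="\t",
                                    index=False)
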