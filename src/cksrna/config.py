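"""Simulation configuration.

The defaults define the study conditions the synthetic data emulates: a plant
root colonized by a fungal endophyte, with plant small RNAs peaking at 21 and
24 nt (5'-A biased at 24 nt), fungal small RNAs peaking at 26 and 29-30 nt,
and 21-nt cross-kingdom sRNAs induced in the colonized sample with perfectly
complementary sites planted in the partner transcriptome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    All randomness derives from ``seed``; identical configurations produce
    byte-identical outputs.
    """

    seed: int = 0

    # genomes
    plant_genome_len: int = 50_000
    fungal_genome_len: int = 25_000
    n_plant_contigs: int = 2
    n_fungal_contigs: int = 2
    n_decoy_segments: int = 0          # segments planted verbatim in both genomes
    decoy_len: int = 40
    uniqueness_k: int = 15             # no cross-genome shared k-mer at this k

    # small-RNA generating loci
    n_plant_mirna_loci: int = 8        # 21-nt hairpin loci
    n_plant_sirna24_loci: int = 8      # 24-nt siRNA clusters, 5'-A biased
    n_fungal_loci_26: int = 6
    n_fungal_loci_29_30: int = 6
    a_bias_24: float = 0.7             # P(first base = A) for 24-nt reads

    # cross-kingdom sRNAs
    n_ck_srnas_per_direction: int = 20
    ck_len: int = 21
    induction_factor: float = 4.0      # colonized/control raw-count ratio

    # sequencing
    depth_per_sample: int = 10_000     # approximate reads per sample class
    noise_read_fraction: float = 0.02  # reads matching neither genome
    adapter_seq: str = "TGGAATTCTCGGGTGCCAAGG"

    # transcriptomes / differential expression
    n_plant_genes: int = 200
    n_fungal_genes: int = 150
    transcript_len: int = 500
    de_effect_log2fc: float = -1.5     # planted downregulated targets
    de_alpha: float = 0.05

    # structural RNA decoys (tRNA/rRNA stand-ins)
    n_structural_seqs: int = 5
    structural_seq_len: int = 150

    def validate(self) -> None:
        counts = [
            self.plant_genome_len, self.fungal_genome_len,
            self.n_plant_contigs, self.n_fungal_contigs,
            self.n_decoy_segments, self.n_plant_mirna_loci,
            self.n_plant_sirna24_loci, self.n_fungal_loci_26,
            self.n_fungal_loci_29_30, self.n_ck_srnas_per_direction,
            self.depth_per_sample, self.n_plant_genes, self.n_fungal_genes,
            self.n_structural_seqs,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.noise_read_fraction <= 1.0:
            raise ValueError("noise_read_fraction must be in [0, 1]")
        if not 15 <= self.ck_len <= 35:
            raise ValueError("ck_len must lie in [15, 35]")
        if not 0.0 <= self.a_bias_24 <= 1.0:
            raise ValueError("a_bias_24 must be in [0, 1]")
        if self.induction_factor < 1.0:
            raise ValueError("induction_factor must be >= 1")
        if not set(self.adapter_seq) <= set("ACGT") or not self.adapter_seq:
            raise ValueError("adapter_seq must be a non-empty ACGT string")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
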