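"""Synthetic dataset generator with a ground-truth ledger.

Emulates small-RNA sequencing of three sample classes from a plant root /
fungal endophyte system:

* ``Bd-C``  — mock-treated plant root (plant reads only),
* ``Bd-Si`` — colonized root (plant + fungal reads, induced ck-sRNAs),
* ``Si-ax`` — axenic fungal culture (fungal reads only).

Plant small RNAs come from 21-nt hairpin (miRNA) loci and 24-nt siRNA
clusters with a configurable 5'-A bias; fungal small RNAs from 26-nt and
29/30-nt clusters. Cross-kingdom (ck) sRNAs are planted genome substrings
whose perfect complements are embedded in the partner transcriptome and
whose raw counts are induced in the colonized sample. The two genomes share
no 15-mer on either strand (outside explicitly requested decoy segments), so
read-origin classification has an exact ground truth.

Read counts are deterministic expected counts rather than multinomial draws,
which makes planted-truth recovery exact on noise-free runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .seqio import write_fasta, write_fastq, write_gff3
from .util import kmer_set, random_seq, revcomp, to_rna

BD_C = "Bd-C"
BD_SI = "Bd-Si"
SI_AX = "Si-ax"
SAMPLE_CLASSES = (BD_C, BD_SI, SI_AX)

PLANT = "plant"
FUNGUS = "fungus"

# Mature sequence of a conserved plant MIR156-family miRNA (DNA alphabet);
# planted verbatim as the first synthetic miRNA locus.
MIR156E_MATURE = "TGACAGAAGAGAGTGAGCAC"
MIR156E_ID = "bdi-MIR156e"

_MIRNA_WIN = 120
_SIRNA_WIN = 200
_FUNGAL_WIN = 150


@dataclass
class LocusTruth:
    organism: str
    contig: str
    start: int
    end: int
    dominant_len: int
    locus_class: str                       # mirna21 | sirna24 | sirna26 | sirna29_30
    mature_seq: str | None = None
    mirna_id: str | None = None
    read_offsets: tuple = ()


@dataclass
class CkTruth:
    origin_organism: str
    srna_seq: str
    target_transcript_id: str = ""
    planted_mismatches: int = 0
    site_region: str = "full"
    exclusive: bool = False
    control_count: int = 0
    colonized_count: int = 0
    site_start: int = -1


@dataclass
class DeTruth:
    organism: str
    gene_id: str
    true_log2fc: float
    is_target: bool


@dataclass
class DecoyTruth:
    seq: str
    plant_contig: str
    plant_start: int
    fungal_contig: str
    fungal_start: int


@dataclass
class GroundTruth:
    planted_loci: list = field(default_factory=list)
    planted_ck: list = field(default_factory=list)
    planted_de: list = field(default_factory=list)
    decoys: list = field(default_factory=list)


class _Allocator:
    """Round-robin placement of non-overlapping feature windows on contigs."""

    def __init__(self, contig_lens: dict, rng: np.random.Generator, margin: int = 60):
        self.cursors = {c: margin for c in contig_lens}
        self.lens = dict(contig_lens)
        self.names = list(contig_lens)
        self.rng = rng
        self.margin = margin
        self._next = 0

    def take(self, length: int) -> tuple:
        for _ in range(len(self.names)):
            contig = self.names[self._next % len(self.names)]
            self._next += 1
            pos = self.cursors[contig]
            if pos + length <= self.lens[contig] - self.margin:
                # inter-feature gaps stay above typical locus merge distances
                self.cursors[contig] = pos + length + int(self.rng.integers(100, 220))
                return contig, pos
        raise ValueError("genome too small for the requested feature layout")


def _contig_lengths(total: int, n: int, prefix: str) -> dict:
    base = total // n
    lens = {f"{prefix}{i + 1}": base for i in range(n)}
    lens[f"{prefix}{n}"] += total - base * n
    return lens


def generate_genomes(cfg: SimulationConfig):
    """Build the plant and fungal genomes plus a ground-truth stub.

    The fungal genome is sampled base by base, rejecting any trailing k-mer
    (either strand) present in the finished plant genome, so no >= k substring
    is shared between the genomes except planted decoy segments.

    Returns ``(plant_genome, fungal_genome, truth)`` with genomes as ordered
    ``{contig: sequence}`` dicts.
    """
    cfg.validate()
    rng = np.random.default_rng([1, cfg.seed])
    truth = GroundTruth()
    k = cfg.uniqueness_k

    # --- plant genome with edited-in loci ---------------------------------
    plant_lens = _contig_lengths(cfg.plant_genome_len, cfg.n_plant_contigs, "BdChr")
    plant = {c: list(random_seq(rng, n)) for c, n in plant_lens.items()}
    alloc = _Allocator(plant_lens, rng)

    for i in range(cfg.n_plant_mirna_loci):
        contig, start = alloc.take(_MIRNA_WIN)
        mature = MIR156E_MATURE if i == 0 else random_seq(rng, 21)
        mir_id = MIR156E_ID if i == 0 else f"bdi-MIRsyn{i:02d}"
        plant[contig][start + 10 : start + 10 + len(mature)] = list(mature)
        star = revcomp(mature)
        plant[contig][start + 75 : start + 75 + len(star)] = list(star)
        truth.planted_loci.append(
            LocusTruth(PLANT, contig, start, start + _MIRNA_WIN, len(mature),
                       "mirna21", mature_seq=mature, mirna_id=mir_id,
                       read_offsets=(10,))
        )

    for _ in range(cfg.n_plant_sirna24_loci):
        contig, start = alloc.take(_SIRNA_WIN)
        offsets = tuple(sorted(rng.choice(_SIRNA_WIN - 24, size=40, replace=False)))
        for o in offsets:
            if rng.random() < cfg.a_bias_24:
                plant[contig][start + o] = "A"
            else:
                plant[contig][start + o] = "CGT"[rng.integers(0, 3)]
        truth.planted_loci.append(
            LocusTruth(PLANT, contig, start, start + _SIRNA_WIN, 24,
                       "sirna24", read_offsets=offsets)
        )

    plant_ck_pos = [alloc.take(cfg.ck_len) for _ in range(cfg.n_ck_srnas_per_direction)]
    decoy_src = [alloc.take(cfg.decoy_len) for _ in range(cfg.n_decoy_segments)]

    plant_genome = {c: "".join(s) for c, s in plant.items()}
    plant_kmers = kmer_set(plant_genome.values(), k, both_strands=True)

    # --- fungal genome avoiding every plant k-mer -------------------------
    fungal_lens = _contig_lengths(cfg.fungal_genome_len, cfg.n_fungal_contigs, "SiCtg")
    fungal = {}
    bases = "ACGT"
    for contig, length in fungal_lens.items():
        seq: list = []
        for i in range(length):
            for attempt in range(20):
                b = bases[rng.integers(0, 4)]
                if i < k - 1:
                    seq.append(b)
                    break
                tail = "".join(seq[i - k + 1 :]) + b
                if tail not in plant_kmers:
                    seq.append(b)
                    break
            else:
                raise ValueError(
                    "rejection sampling failed: genomes too small for the "
                    f"requested cross-genome uniqueness at k={k}"
                )
        fungal[contig] = seq

    falloc = _Allocator(fungal_lens, rng)
    for i in range(cfg.n_fungal_loci_26):
        contig, start = falloc.take(_FUNGAL_WIN)
        offsets = tuple(sorted(rng.choice(_FUNGAL_WIN - 30, size=10, replace=False)))
        truth.planted_loci.append(
            LocusTruth(FUNGUS, contig, start, start + _FUNGAL_WIN, 26,
                       "sirna26", read_offsets=offsets)
        )
    for i in range(cfg.n_fungal_loci_29_30):
        contig, start = falloc.take(_FUNGAL_WIN)
        offsets = tuple(sorted(rng.choice(_FUNGAL_WIN - 31, size=10, replace=False)))
        truth.planted_loci.append(
            LocusTruth(FUNGUS, contig, start, start + _FUNGAL_WIN, 29,
                       "sirna29_30", read_offsets=offsets)
        )

    fungal_ck_pos = [falloc.take(cfg.ck_len) for _ in range(cfg.n_ck_srnas_per_direction)]

    # decoy segments: verbatim plant substrings spliced into the fungal genome
    for (p_contig, p_start) in decoy_src:
        f_contig, f_start = falloc.take(cfg.decoy_len)
        seg = plant_genome[p_contig][p_start : p_start + cfg.decoy_len]
        fungal[f_contig][f_start : f_start + cfg.decoy_len] = list(seg)
        truth.decoys.append(DecoyTruth(seg, p_contig, p_start, f_contig, f_start))

    fungal_genome = {c: "".join(s) for c, s in fungal.items()}

    # ck-sRNA sequences are plain genome substrings of the origin organism
    for i, (contig, start) in enumerate(plant_ck_pos):
        seq = plant_genome[contig][start : start + cfg.ck_len]
        truth.planted_ck.append(CkTruth(PLANT, seq, exclusive=(i % 2 == 0)))
    for i, (contig, start) in enumerate(fungal_ck_pos):
        seq = fungal_genome[contig][start : start + cfg.ck_len]
        truth.planted_ck.append(CkTruth(FUNGUS, seq, exclusive=(i % 2 == 0)))

    seqs = [ck.srna_seq for ck in truth.planted_ck]
    if len(set(seqs)) != len(seqs):
        raise ValueError("planted ck-sRNA sequences collide; change the seed")
    return plant_genome, fungal_genome, truth


def _endogenous_counts(cfg: SimulationConfig, plant_genome, fungal_genome,
                       truth: GroundTruth, unit: int):
    """Deterministic per-sequence counts of locus-derived reads, per organism."""
    plant_counts: Counter = Counter()
    fungal_counts: Counter = Counter()
    for locus in truth.planted_loci:
        genome = plant_genome if locus.organism == PLANT else fungal_genome
        seq = genome[locus.contig]
        if locus.locus_class == "mirna21":
            m = locus.mature_seq
            s = locus.start + 10
            plant_counts[m] += 27 * unit
            plant_counts[seq[s - 1 : s - 1 + len(m)]] += 2 * unit
            plant_counts[seq[s + 1 : s + 1 + len(m)]] += 1 * unit
        elif locus.locus_class == "sirna24":
            for o in locus.read_offsets:
                plant_counts[seq[locus.start + o : locus.start + o + 24]] += unit
        elif locus.locus_class == "sirna26":
            for o in locus.read_offsets:
                fungal_counts[seq[locus.start + o : locus.start + o + 26]] += 3 * unit
        elif locus.locus_class == "sirna29_30":
            for j, o in enumerate(locus.read_offsets):
                length = 29 if j % 2 == 0 else 30
                fungal_counts[seq[locus.start + o : locus.start + o + length]] += 3 * unit
    return plant_counts, fungal_counts


def plant_loci_and_reads(cfg: SimulationConfig, plant_genome, fungal_genome,
                         truth: GroundTruth, structural=None):
    """Emit per-sample read pools (sequence -> raw count, adapters excluded).

    Endogenous locus reads get identical counts in colonized and control
    samples; planted ck-sRNAs are exclusive to the colonized sample or
    induced by ``cfg.induction_factor`` over their control count. Noise reads
    match neither genome. Returns ``{sample_class: Counter}``.
    """
    rng = np.random.default_rng([2, cfg.seed])
    unit = max(1, cfg.depth_per_sample // 1000)
    pools = {s: Counter() for s in SAMPLE_CLASSES}

    plant_endo, fungal_endo = _endogenous_counts(
        cfg, plant_genome, fungal_genome, truth, unit)
    pools[BD_C].update(plant_endo)
    pools[BD_SI].update(plant_endo)
    pools[BD_SI].update(fungal_endo)
    pools[SI_AX].update(fungal_endo)

    base = 2 * unit
    for ck in truth.planted_ck:
        control_sample = BD_C if ck.origin_organism == PLANT else SI_AX
        ck.colonized_count = int(round(base * cfg.induction_factor))
        ck.control_count = 0 if ck.exclusive else base
        pools[BD_SI][ck.srna_seq] += ck.colonized_count
        if ck.control_count:
            pools[control_sample][ck.srna_seq] += ck.control_count

    for decoy in truth.decoys:
        mid = (len(decoy.seq) - 21) // 2
        pools[BD_SI][decoy.seq[mid : mid + 21]] += unit

    if structural:
        for s in structural.values():
            for length in (22, 28):
                o = int(rng.integers(0, len(s) - length))
                read = s[o : o + length]
                for sample in SAMPLE_CLASSES:
                    pools[sample][read] += 2 * unit

    if cfg.noise_read_fraction > 0:
        avoid = kmer_set(plant_genome.values(), cfg.uniqueness_k) | kmer_set(
            fungal_genome.values(), cfg.uniqueness_k)
        for sample in SAMPLE_CLASSES:
            total = sum(pools[sample].values())
            n_noise = int(round(cfg.noise_read_fraction * total
                                / (1 - cfg.noise_read_fraction)))
            made = 0
            while made < n_noise:
                cand = random_seq(rng, int(rng.integers(18, 31)))
                if any(cand[i : i + cfg.uniqueness_k] in avoid
                       for i in range(len(cand) - cfg.uniqueness_k + 1)):
                    continue
                pools[sample][cand] += 1
                made += 1
    return pools


def reads_to_fastq(cfg: SimulationConfig, pools, rng=None):
    """Expand read pools into shuffled FASTQ records with adapters appended."""
    rng = rng if rng is not None else np.random.default_rng([3, cfg.seed])
    out = {}
    for sample, pool in pools.items():
        reads = []
        for seq in sorted(pool):
            reads.extend([seq] * pool[seq])
        order = rng.permutation(len(reads))
        out[sample] = [
            (f"{sample}_{i}", reads[j] + cfg.adapter_seq)
            for i, j in enumerate(order)
        ]
    return out


def generate_structural(cfg: SimulationConfig, plant_genome, fungal_genome):
    """tRNA/rRNA stand-in sequences sharing no k-mer with either genome."""
    rng = np.random.default_rng([4, cfg.seed])
    avoid = kmer_set(plant_genome.values(), cfg.uniqueness_k) | kmer_set(
        fungal_genome.values(), cfg.uniqueness_k)
    out = {}
    i = 0
    while len(out) < cfg.n_structural_seqs:
        cand = random_seq(rng, cfg.structural_seq_len)
        if any(cand[j : j + cfg.uniqueness_k] in avoid
               for j in range(len(cand) - cfg.uniqueness_k + 1)):
            continue
        out[f"structRNA{i + 1:02d}"] = cand
        i += 1
    return out


def generate_transcriptomes(cfg: SimulationConfig, truth: GroundTruth):
    """Random transcript pools with perfectly complementary ck target sites.

    Each planted ck-sRNA is assigned one distinct partner-organism gene; the
    reverse complement of the sRNA is written into that gene's transcript.
    """
    rng = np.random.default_rng([5, cfg.seed])
    plant_ids = [f"BdSynG{i:04d}" for i in range(cfg.n_plant_genes)]
    fungal_ids = [f"SiSynG{i:04d}" for i in range(cfg.n_fungal_genes)]
    plant_tx = {f"{g}.1": random_seq(rng, cfg.transcript_len) for g in plant_ids}
    fungal_tx = {f"{g}.1": random_seq(rng, cfg.transcript_len) for g in fungal_ids}

    fungal_ck = [ck for ck in truth.planted_ck if ck.origin_organism == FUNGUS]
    plant_ck = [ck for ck in truth.planted_ck if ck.origin_organism == PLANT]
    plant_targets = rng.choice(cfg.n_plant_genes, size=len(fungal_ck), replace=False)
    fungal_targets = rng.choice(cfg.n_fungal_genes, size=len(plant_ck), replace=False)

    for ck, gi in zip(fungal_ck, plant_targets):
        tx_id = f"{plant_ids[gi]}.1"
        site = revcomp(ck.srna_seq)
        pos = int(rng.integers(0, cfg.transcript_len - len(site)))
        s = plant_tx[tx_id]
        plant_tx[tx_id] = s[:pos] + site + s[pos + len(site):]
        ck.target_transcript_id = tx_id
        ck.site_start = pos
    for ck, gi in zip(plant_ck, fungal_targets):
        tx_id = f"{fungal_ids[gi]}.1"
        site = revcomp(ck.srna_seq)
        pos = int(rng.integers(0, cfg.transcript_len - len(site)))
        s = fungal_tx[tx_id]
        fungal_tx[tx_id] = s[:pos] + site + s[pos + len(site):]
        ck.target_transcript_id = tx_id
        ck.site_start = pos

    descriptions = {tx: f"synthetic transcript {tx.rsplit('.', 1)[0]}"
                    for tx in list(plant_tx) + list(fungal_tx)}
    return plant_tx, fungal_tx, descriptions


def generate_de_tables(cfg: SimulationConfig, truth: GroundTruth):
    """Differential-expression tables (gene_id, log2FC, padj) per organism.

    Planted ck target genes get ``log2FC = cfg.de_effect_log2fc`` and
    ``padj < cfg.de_alpha``; all other genes draw log2FC symmetric around 0
    and padj uniform on (0, 1).
    """
    rng = np.random.default_rng([6, cfg.seed])
    truth.planted_de = []
    target_by_org = {
        PLANT: {ck.target_transcript_id.rsplit(".", 1)[0]
                for ck in truth.planted_ck
                if ck.origin_organism == FUNGUS and ck.target_transcript_id},
        FUNGUS: {ck.target_transcript_id.rsplit(".", 1)[0]
                 for ck in truth.planted_ck
                 if ck.origin_organism == PLANT and ck.target_transcript_id},
    }
    tables = {}
    for organism, n_genes, prefix in (
        (PLANT, cfg.n_plant_genes, "BdSynG"),
        (FUNGUS, cfg.n_fungal_genes, "SiSynG"),
    ):
        rows = []
        for i in range(n_genes):
            gene = f"{prefix}{i:04d}"
            is_target = gene in target_by_org[organism]
            if is_target:
                lfc = cfg.de_effect_log2fc
                padj = float(rng.uniform(1e-6, cfg.de_alpha * 0.2))
            else:
                lfc = float(rng.normal(0.0, 0.8))
                padj = float(rng.uniform(0.0, 1.0))
            rows.append({"gene_id": gene, "log2FC": lfc, "padj": padj})
            truth.planted_de.append(DeTruth(organism, gene, lfc, is_target))
        tables[organism] = pd.DataFrame(rows)
    return tables[PLANT], tables[FUNGUS]


def generate_phenotypes(seed: int, n_per_group: int, control_mean: float,
                        treatment_mean: float, sd: float,
                        trait: str = "filled_grains",
                        n_replicates: int = 3) -> pd.DataFrame:
    """Two-group replicated trait table with normal noise.

    Columns: trait, group (control/Si), replicate (rep1..repN), value.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng([7, seed])
    rows = []
    for rep in range(1, n_replicates + 1):
        for group, mean in (("control", control_mean), ("Si", treatment_mean)):
            vals = mean + sd * rng.standard_normal(n_per_group)
            rows.extend(
                {"trait": trait, "group": group, "replicate": f"rep{rep}",
                 "value": float(v)} for v in vals
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    plant_genome: dict
    fungal_genome: dict
    plant_transcriptome: dict
    fungal_transcriptome: dict
    descriptions: dict
    structural: dict
    mirna_reference: dict        # RNA alphabet, as a mature-miRNA reference set
    reads: dict                  # sample class -> [(read_id, seq_with_adapter)]
    pools: dict                  # sample class -> Counter(insert seq -> count)
    de_plant: pd.DataFrame
    de_fungal: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "plant_genome.fasta", self.plant_genome)
        write_fasta(outdir / "fungal_genome.fasta", self.fungal_genome)
        write_fasta(outdir / "plant_transcriptome.fasta", self.plant_transcriptome)
        write_fasta(outdir / "fungal_transcriptome.fasta", self.fungal_transcriptome)
        write_fasta(outdir / "structural_rna.fasta", self.structural)
        write_fasta(outdir / "mirna_reference.fasta", self.mirna_reference)
        for sample, reads in self.reads.items():
            write_fastq(outdir / f"reads_{sample}.fastq", reads)
        self.de_plant.to_csv(outdir / "de_plant.tsv", sep="\t", index=False)
        self.de_fungal.to_csv(outdir / "de_fungal.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"organism": l.organism, "contig": l.contig, "start": l.start,
              "end": l.end, "dominant_len": l.dominant_len,
              "locus_class": l.locus_class, "mirna_id": l.mirna_id or ""}
             for l in self.truth.planted_loci]
        ).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"origin_organism": c.origin_organism, "srna_seq": c.srna_seq,
              "target_transcript_id": c.target_transcript_id,
              "exclusive": c.exclusive, "control_count": c.control_count,
              "colonized_count": c.colonized_count}
             for c in self.truth.planted_ck]
        ).to_csv(outdir / "truth_ck.tsv", sep="\t", index=False)
        write_gff3(
            outdir / "truth_loci.gff3",
            [{"contig": l.contig, "start": l.start, "end": l.end,
              "attributes": {"ID": f"locus{idx}", "organism": l.organism,
                             "locus_class": l.locus_class}}
             for idx, l in enumerate(self.truth.planted_loci)],
        )


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage and assemble the full synthetic dataset."""
    plant_genome, fungal_genome, truth = generate_genomes(cfg)
    structural = generate_structural(cfg, plant_genome, fungal_genome)
    pools = plant_loci_and_reads(cfg, plant_genome, fungal_genome, truth, structural)
    reads = reads_to_fastq(cfg, pools)
    plant_tx, fungal_tx, descriptions = generate_transcriptomes(cfg, truth)
    de_plant, de_fungal = generate_de_tables(cfg, truth)
    mirna_ref = {
        l.mirna_id: to_rna(l.mature_seq)
        for l in truth.planted_loci if l.locus_class == "mirna21"
    }
    # decoy reference entries keep known-miRNA matching non-trivial
    rng = np.random.default_rng([8, cfg.seed])
    for i in range(5):
        mirna_ref[f"xxx-MIRdecoy{i + 1:02d}"] = to_rna(random_seq(rng, 21))
    return SyntheticDataset(
        config=cfg, plant_genome=plant_genome, fungal_genome=fungal_genome,
        plant_transcriptome=plant_tx, fungal_transcriptome=fungal_tx,
        descriptions=descriptions, structural=structural,
        mirna_reference=mirna_ref, reads=reads, pools=pools,
        de_plant=de_plant, de_fungal=de_fungal, truth=truth,
    )
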