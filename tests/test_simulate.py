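"""Synthetic dataset generator: determinism, planted structure, truth
consistency."""

import pytest

from cksrna import SimulationConfig, generate_genomes, simulate_dataset
from cksrna.simulate import (BD_C, BD_SI, MIR156E_MATURE, SI_AX,
                             generate_phenotypes, plant_loci_and_reads)
from cksrna.util import kmer_set, revcomp


def shared_kmers_outside_decoys(plant, fungal, truth, k=15):
    """Naive oracle: cross-genome shared k-mers not overlapping a decoy."""
    decoy_spans = {}
    for d in truth.decoys:
        decoy_spans.setdefault(d.plant_contig, []).append(
            ("plant", d.plant_start, d.plant_start + len(d.seq)))
        decoy_spans.setdefault(d.fungal_contig, []).append(
            ("fungal", d.fungal_start, d.fungal_start + len(d.seq)))

    def covered(contig, i):
        return any(s - k < i < e for _, s, e in decoy_spans.get(contig, []))

    plant_kmers = kmer_set(plant.values(), k, both_strands=True)
    shared = []
    for contig, seq in fungal.items():
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in plant_kmers and not covered(contig, i):
                shared.append((contig, i))
    return shared


class TestGenerateGenomes:
    def test_no_cross_shared_15mer_outside_decoys(self, small_cfg):
        plant, fungal, truth = generate_genomes(small_cfg)
        assert shared_kmers_outside_decoys(plant, fungal, truth) == []

    def test_decoy_segments_present_in_both_genomes(self, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, n_decoy_segments=3)
        plant, fungal, truth = generate_genomes(cfg)
        assert len(truth.decoys) == 3
        for d in truth.decoys:
            # naive substring oracle in both genomes
            assert any(d.seq in s for s in plant.values())
            assert any(d.seq in s for s in fungal.values())

    def test_byte_identical_outputs_across_runs(self, small_cfg):
        a = simulate_dataset(small_cfg)
        b = simulate_dataset(small_cfg)
        assert a.plant_genome == b.plant_genome
        assert a.fungal_genome == b.fungal_genome
        assert a.reads == b.reads
        assert a.de_plant.equals(b.de_plant)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_read_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(ck_len=40).validate()

    def test_reference_mature_planted(self, small_dataset):
        plant = small_dataset.plant_genome
        assert any(MIR156E_MATURE in s for s in plant.values())
        assert small_dataset.mirna_reference["bdi-MIR156e"] == \
            MIR156E_MATURE.replace("T", "U")


class TestTruthConsistency:
    def test_ck_srnas_are_origin_genome_substrings_only(self, small_dataset):
        ds = small_dataset
        for ck in ds.truth.planted_ck:
            own = ds.plant_genome if ck.origin_organism == "plant" else ds.fungal_genome
            other = ds.fungal_genome if ck.origin_organism == "plant" else ds.plant_genome
            assert any(ck.srna_seq in s for s in own.values())
            assert not any(ck.srna_seq in s or revcomp(ck.srna_seq) in s
                           for s in other.values())

    def test_target_sites_are_transcript_substrings(self, small_dataset):
        ds = small_dataset
        for ck in ds.truth.planted_ck:
            tx_pool = (ds.plant_transcriptome if ck.origin_organism == "fungus"
                       else ds.fungal_transcriptome)
            tx = tx_pool[ck.target_transcript_id]
            site = revcomp(ck.srna_seq)
            assert tx[ck.site_start : ck.site_start + len(site)] == site

    def test_locus_reads_substrings_of_origin_genome(self, small_dataset):
        ds = small_dataset
        for locus in ds.truth.planted_loci:
            genome = (ds.plant_genome if locus.organism == "plant"
                      else ds.fungal_genome)
            window = genome[locus.contig][locus.start : locus.end]
            if locus.mature_seq:
                assert locus.mature_seq in window


class TestReadPools:
    def test_induced_ck_counts_at_least_factor_over_control(self, small_dataset):
        cfg = small_dataset.config
        pools = small_dataset.pools
        for ck in small_dataset.truth.planted_ck:
            control = BD_C if ck.origin_organism == "plant" else SI_AX
            col = pools[BD_SI][ck.srna_seq]
            ctrl = pools[control][ck.srna_seq]
            if ck.exclusive:
                assert ctrl == 0 and col > 0
            else:
                assert col >= cfg.induction_factor * ctrl

    def test_noise_free_reads_all_map_to_origin(self, dataset):
        """With noise 0, every emitted insert is a substring of a genome or
        a structural sequence."""
        haystacks = (list(dataset.plant_genome.values())
                     + list(dataset.fungal_genome.values())
                     + list(dataset.structural.values()))
        for sample, pool in dataset.pools.items():
            for seq in pool:
                assert any(seq in h or revcomp(seq) in h for h in haystacks), \
                    f"orphan read in {sample}"

    def test_noise_reads_match_neither_genome(self, small_dataset):
        ds = small_dataset
        genome_kmers = kmer_set(
            list(ds.plant_genome.values()) + list(ds.fungal_genome.values()), 15)
        structural = list(ds.structural.values())
        n_noise = 0
        for seq in ds.pools[BD_SI]:
            in_genome = any(seq[i : i + 15] in genome_kmers
                            for i in range(len(seq) - 14))
            in_struct = any(seq in s or revcomp(seq) in s for s in structural)
            if not in_genome and not in_struct:
                n_noise += 1
        expected = round(ds.config.noise_read_fraction
                         / (1 - ds.config.noise_read_fraction)
                         * (sum(ds.pools[BD_SI].values()) - n_noise))
        assert n_noise == expected

    def test_fastq_reads_carry_adapter(self, small_dataset):
        adapter = small_dataset.config.adapter_seq
        for _, seq in small_dataset.reads[BD_C][:50]:
            assert seq.endswith(adapter)

    def test_plant_length_modes_in_control(self, dataset):
        from collections import Counter
        hist = Counter()
        for seq, n in dataset.pools[BD_C].items():
            hist[len(seq)] += n
        top2 = {length for length, _ in hist.most_common(2)}
        assert top2 == {21, 24}


class TestDeTables:
    def test_planted_targets_significant_and_down(self, small_dataset):
        ds = small_dataset
        targets = {ck.target_transcript_id.rsplit(".", 1)[0]
                   for ck in ds.truth.planted_ck
                   if ck.origin_organism == "fungus"}
        sub = ds.de_plant[ds.de_plant["gene_id"].isin(targets)]
        assert len(sub) == len(targets)
        assert (sub["padj"] < 0.05).all()
        assert (sub["log2FC"] < 0).all()

    def test_exact_planted_count_among_down_significant(self, dataset):
        ds = dataset
        targets = {ck.target_transcript_id.rsplit(".", 1)[0]
                   for ck in ds.truth.planted_ck
                   if ck.origin_organism == "fungus"}
        down = ds.de_plant[(ds.de_plant["log2FC"] < 0)
                           & (ds.de_plant["padj"] < 0.05)]
        planted_down = down[down["gene_id"].isin(targets)]
        assert len(planted_down) == len(targets) == 20


def test_generate_phenotypes_sd_zero_exact_means():
    table = generate_phenotypes(seed=1, n_per_group=5, control_mean=10,
                                treatment_mean=15, sd=0)
    means = table.groupby("group")["value"].mean()
    assert means["control"] == 10.0
    assert means["Si"] == 15.0
    assert set(table["replicate"]) == {"rep1", "rep2", "rep3"}


def test_dataset_write_roundtrip(tmp_path, small_dataset):
    small_dataset.write(tmp_path)
    from cksrna.seqio import read_fasta, read_fastq_seqs
    plant = read_fasta(tmp_path / "plant_genome.fasta")
    assert plant == small_dataset.plant_genome
    reads = read_fastq_seqs(tmp_path / f"reads_{BD_C}.fastq")
    assert reads == [seq for _, seq in small_dataset.reads[BD_C]]
    gff = (tmp_path / "truth_loci.gff3").read_text().splitlines()
    assert gff[0] == "##gff-version 3"
    first = small_dataset.truth.planted_loci[0]
    assert any(str(first.start + 1) in line.split("\t") for line in gff[1:])
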