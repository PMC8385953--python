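"""FASTA/FASTQ/GFF3 reading and writing (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict:
    """FASTA file -> ordered {id: sequence} (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq_seqs(path: str | Path) -> list:
    """FASTQ file -> list of read sequences (uppercase strings)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple], qual_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as 4-line FASTQ with a constant quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_gff3(path: str | Path, features: Iterable[dict]) -> None:
    """Write features as GFF3. Feature dicts carry 0-based half-open
    ``start``/``end``; the file is 1-based inclusive per the standard."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        f["contig"],
                        f.get("source", "cksrna"),
                        f.get("type", "sRNA_locus"),
                        str(f["start"] + 1),
                        str(f["end"]),
                        str(f.get("score", ".")),
                        f.get("strand", "."),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )
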