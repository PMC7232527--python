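"""Reading and writing the standard flat formats used by the pipeline.

FASTA via Biopython; GFF3 with 1-based inclusive coordinates (internal
coordinates are 0-based half-open); FASTQ with constant Phred+33 qualities
written with a fast plain writer and parsed with Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Gene, ParentalPair

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_fastq",
    "read_fastq",
    "write_pair",
    "write_counts",
    "read_counts",
]


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    """GFF3 gene lines; converts 0-based half-open to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\thybridase\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};species={g.species}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene features as a DataFrame with 0-based half-open start/end."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "gene_id": fields.get("ID", ""),
                    "species": fields.get("species", ""),
                }
            )
    return pd.DataFrame(rows)


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.description, str(rec.seq).upper()


def write_pair(pair: ParentalPair, out_dir: str | Path) -> None:
    """Write a ParentalPair as per-species FASTA + GFF3 + marker FASTA."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in sorted(pair.chromosomes):
        write_fasta(pair.chromosomes[sp], out / f"{sp}.genome.fa")
        write_gff3(pair.genes[sp], out / f"{sp}.genes.gff3")
        write_fasta(pair.markers[sp], out / f"{sp}.markers.fa")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
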