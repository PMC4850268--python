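"""Readers and writers for the plain-text interchange formats.

FASTA via Biopython; GFF3 (1-based inclusive, strand in column 7) and BED6
(0-based half-open) as flat tables.  Gene annotations travel as a pandas
DataFrame with columns ``gene_id, start, end, strand, product`` sorted by
start — the contract consumed by :mod:`regulomap.annotate`.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GENE_COLUMNS",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_sites_bed",
]

GENE_COLUMNS = ["gene_id", "start", "end", "strand", "product"]


def write_fasta(sequence: str, path, seq_id: str = "chr_sim", description: str = "") -> None:
    record = SeqRecord(Seq(sequence), id=seq_id, description=description)
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    """Return (id, sequence) of the first record."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_gff3(genes: pd.DataFrame, path, seq_id: str = "chr_sim") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};product={row.product}"
            fh.write(
                f"{seq_id}\tregulomap\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def _gff_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return ""


def read_gff3(path) -> pd.DataFrame:
    """Read gene features into the annotation DataFrame contract."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line[:60]}")
            if f[2] not in ("gene", "CDS"):
                continue
            gene_id = _gff_attr(f[8], "ID") or _gff_attr(f[8], "locus_tag")
            rows.append(
                {
                    "gene_id": gene_id,
                    "start": int(f[3]),
                    "end": int(f[4]),
                    "strand": f[6],
                    "product": _gff_attr(f[8], "product"),
                }
            )
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return df.sort_values("start", ignore_index=True)


def write_sites_bed(sites, path, chrom: str = "chr_sim") -> None:
    """Truth sites as BED6: name = target gene or 'artifact', score = enrichment."""
    with open(path, "w") as fh:
        for s in sites:
            name = "artifact" if s.artifact else (s.target_gene or ".")
            fh.write(
                f"{chrom}\t{s.pos - 1}\t{s.pos}\t{name}\t{s.enrichment:.3f}\t+\n"
            )
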