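"""Reading and writing of the flat-file formats used across the package.

FASTA/FASTQ go through Biopython, GFF3 reading through gffutils. GFF3 is
written with gene/exon features, 1-based inclusive coordinates; FASTA is
wrapped at 80 columns. TSV tables are tab-separated with a header row.
"""

from __future__ import annotations

import os
import tempfile
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WRAP = 80


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, records: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(recs)


def write_gff3(path: str, models: Iterable) -> None:
    """Write GeneModel-like objects (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            end = len(m.genomic_seq)
            fh.write(
                f"{m.gene_id}\torthosplice\tgene\t1\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons):
                fh.write(
                    f"{m.gene_id}\torthosplice\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def read_gene_models(gff3_path: str, genome_fasta_path: str) -> list:
    """Load gene models from GFF3 + genomic FASTA (one region per gene)."""
    from .simulate import GeneModel  # local import to avoid a cycle

    seqs = read_fasta(genome_fasta_path)
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(
            gff3_path, dbpath, force=True, keep_order=True, merge_strategy="error"
        )
        models = []
        for gene in db.features_of_type("gene", order_by="start"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
            )
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    genomic_seq=seqs[gene.seqid],
                    exons=[(int(s), int(e)) for s, e in exons],
                    strand=gene.strand if gene.strand in "+-" else "+",
                )
            )
        return models
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)


def write_tsv(path: str, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
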