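"""Readers and writers for the formats the pipeline touches.

Protein and nucleotide FASTA go through Bio.SeqIO; the pairwise similarity
table is the 12-column BLAST ``outfmt 6`` dialect.  No science lives here:
parsing preserves record order and only normalizes case and identifiers.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._types import NT_ALPHABET, GeneRecord, SimilarityHit

#: column order of the tabular similarity dialect (BLAST outfmt 6)
SIMILARITY_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
)


def read_protein_fasta(path: str | os.PathLike, strain_id: str) -> list[GeneRecord]:
    """Read an annotated proteome.

    The first whitespace-delimited header token is the gene id; the remainder
    is the free-text product annotation.  Order is preserved and duplicate
    gene ids within one file are an error.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        product = rec.description[len(rec.id):].strip()
        records.append(
            GeneRecord(
                gene_id=gene_id,
                strain_id=strain_id,
                product=product,
                sequence=str(rec.seq).upper(),
            )
        )
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_protein_fasta(records: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.product)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_similarity_table(path: str | os.PathLike) -> list[SimilarityHit]:
    """Read a 12-column tab-separated similarity table.

    Columns 1, 2, 3, 4, 11, 12 map to the SimilarityHit fields; the rest are
    ignored.  Lines starting with ``#`` are comments.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path: str | os.PathLike) -> None:
    """Write hits in the 12-column dialect (unknown coordinates written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.align_length}\t0\t0\t0\t0\t0\t0\t{h.e_value:.3g}\t"
                f"{h.bit_score:.1f}\n"
            )


def read_nucleotide_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a genome as an ordered list of ``(contig_id, sequence)``.

    Sequences are uppercased; the alphabet is ACGTN.
    """
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: contig {rec.id!r} has illegal characters {sorted(bad)}"
            )
        contigs.append((rec.id, seq))
    if not contigs:
        raise ValueError(f"{path}: no records")
    return contigs


def write_nucleotide_fasta(
    contigs: Iterable[tuple[str, str]], path: str | os.PathLike
) -> None:
    seq_records = [SeqRecord(Seq(s), id=cid, description="") for cid, s in contigs]
    SeqIO.write(seq_records, str(path), "fasta")


def genome_length(contigs: list[tuple[str, str]]) -> int:
    """Total genome length in bp: sum of contig lengths."""
    return sum(len(s) for _, s in contigs)
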