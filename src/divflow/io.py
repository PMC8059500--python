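"""Small IO helpers for FASTA, GFF3 and BED shared across modules."""

from __future__ import annotations

__all__ = ["read_fasta", "write_fasta", "write_gff3", "write_bed"]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into ``{name: sequence}`` (uppercased)."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    seqio_write(records, str(path), "fasta")


def write_gff3(features, path) -> None:
    """Write GFF3 rows given as 9-tuples
    (chrom, source, type, start, end, score, strand, phase, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bed(intervals, path) -> None:
    """Write (chrom, start0, end[, name...]) rows as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
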