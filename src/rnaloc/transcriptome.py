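"""Dual spliced + unspliced transcriptome construction.

For every annotated transcript two sequences are produced: the mature
form (exons concatenated 5'->3') and the precursor form (the genomic span
from transcript start to end, introns retained). Quantifying reads
competitively against both lets pre-mRNA abundance proxy for nuclear
transcripts. Record ids are suffixed ``::spliced`` / ``::unspliced``.

GFF3 uses 1-based closed intervals; conversion to Python slices is
localized here.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._exceptions import InputError

#: GFF3 feature types treated as transcripts.
TRANSCRIPT_TYPES = ("mRNA", "transcript")


def _load_genome(genome: str | Path | dict) -> dict:
    if isinstance(genome, dict):
        return {k: str(v) for k, v in genome.items()}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def build_dual_transcriptome(
    genome: str | Path | dict,
    annotation: str | Path,
) -> list[SeqRecord]:
    """Build spliced and unspliced sequences for every annotated transcript.

    Parameters
    ----------
    genome
        FASTA path or mapping contig id -> sequence string.
    annotation
        GFF3 path with transcript features (``mRNA``/``transcript``) and
        ``exon`` children.

    Returns records in deterministic order (sorted by transcript id, the
    spliced member first). Minus-strand transcripts are
    reverse-complemented, so both members read 5'->3'.
    """
    contigs = _load_genome(genome)
    db = gffutils.create_db(
        str(annotation),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[SeqRecord] = []
    transcripts = [
        feature
        for t in TRANSCRIPT_TYPES
        for feature in db.features_of_type(t)
    ]
    for tx in sorted(transcripts, key=lambda f: f.id):
        if tx.seqid not in contigs:
            raise InputError(f"transcript {tx.id}: unknown contig {tx.seqid!r}")
        contig = contigs[tx.seqid]
        if tx.strand not in {"+", "-"}:
            raise InputError(f"transcript {tx.id}: unknown strand symbol {tx.strand!r}")
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda e: e.start)
        if not exons:
            raise InputError(f"transcript {tx.id}: no exons")
        for ex in exons:
            if ex.start < 1 or ex.end > len(contig):
                raise InputError(
                    f"transcript {tx.id}: exon [{ex.start}, {ex.end}] outside contig "
                    f"{tx.seqid!r} (length {len(contig)})"
                )
        spliced = "".join(contig[ex.start - 1 : ex.end] for ex in exons)
        unspliced = contig[tx.start - 1 : tx.end]
        if tx.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
            unspliced = str(Seq(unspliced).reverse_complement())
        for cls, seq in (("spliced", spliced), ("unspliced", unspliced)):
            records.append(
                SeqRecord(Seq(seq), id=f"{tx.id}::{cls}", description=f"gene={tx.id}")
            )
    return records
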