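"""Readers and writers for the formats the pipeline touches.

GFF3 parsing is delegated to :mod:`gffutils` (in-memory database), FASTA to
:mod:`Bio.SeqIO`; both are normalised into the internal annotation model.
GFF3's 1-based inclusive coordinates are kept as-is.
"""

from __future__ import annotations

import io
import logging
import os
from typing import IO, Iterable, TextIO

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AnnotationSet, ExonChain, GeneRecord, Strand

log = logging.getLogger(__name__)

GENE_TSV_COLUMNS = (
    "species",
    "seq_id",
    "gene_id",
    "symbol",
    "start",
    "end",
    "strand",
    "biotype",
    "source",
)


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input; names the offending line number."""


def _as_text(stream: "str | os.PathLike | IO") -> str:
    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "rt") as fh:
            return fh.read()
    data = stream.read()
    if isinstance(data, bytes):
        data = data.decode()
    return data


def _validate_gff3_lines(text: str) -> None:
    """Column-count sanity check so errors can name a line number.

    gffutils reports malformed features with little positional context;
    this pre-pass rejects lines that are not comments, directives or
    9-column feature records.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("##FASTA"):
            break
        if not line.strip() or line.startswith("#"):
            continue
        n = len(line.split("\t"))
        if n != 9:
            raise Gff3ParseError(
                f"malformed GFF3 line {lineno}: expected 9 tab-separated "
                f"columns, found {n}"
            )


def read_gff3(
    stream: "str | os.PathLike | IO",
    source_label: str = "other",
    species: str = "unknown",
    assembly: str = "",
) -> AnnotationSet:
    """Parse GFF3 into an :class:`AnnotationSet`.

    Gene features with an undefined strand (``.``) are rejected with a
    logged warning; exon/mRNA features that do not resolve to a kept gene
    are skipped likewise.  An input with no gene features is an error.
    """
    text = _as_text(stream)
    _validate_gff3_lines(text)
    if not any(
        ln.strip() and not ln.startswith("#") for ln in text.splitlines()
    ):
        raise Gff3ParseError("GFF3 input contains no gene features (empty set)")
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises several internal types
        raise Gff3ParseError(f"GFF3 parse failure: {exc}") from exc

    ann = AnnotationSet(species=species, assembly=assembly)
    genes = list(db.features_of_type("gene"))
    if not genes:
        raise Gff3ParseError("GFF3 input contains no gene features")

    for feat in genes:
        if feat.strand not in ("+", "-"):
            log.warning(
                "gene %s on %s has undefined strand %r; record rejected",
                feat.id, feat.seqid, feat.strand,
            )
            continue
        symbol = feat.attributes.get("Name", [feat.id])[0]
        biotype = feat.attributes.get(
            "biotype", feat.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        ann.add_gene(
            GeneRecord(
                gene_id=feat.id,
                symbol=symbol,
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=Strand.parse(feat.strand),
                biotype=biotype,
                source=source_label,
            )
        )

    for feat in genes:
        if feat.id not in ann:
            continue
        mrnas = list(db.children(feat, featuretype=("mRNA", "transcript")))
        if mrnas:
            for mrna in mrnas:
                exons = [(e.start, e.end) for e in db.children(mrna, featuretype="exon")]
                if exons:
                    ann.add_transcript(
                        ExonChain(
                            transcript_id=mrna.id,
                            gene_id=feat.id,
                            exons=tuple(exons),
                            strand=Strand.parse(feat.strand),
                            seq_id=feat.seqid,
                        )
                    )
        else:
            exons = [(e.start, e.end) for e in db.children(feat, featuretype="exon")]
            if exons:
                ann.add_transcript(
                    ExonChain(
                        transcript_id=f"{feat.id}.t1",
                        gene_id=feat.id,
                        exons=tuple(exons),
                        strand=Strand.parse(feat.strand),
                        seq_id=feat.seqid,
                    )
                )

    n_orphans = sum(
        1
        for f in db.features_of_type(("mRNA", "transcript", "exon"))
        if not any(p.featuretype == "gene" for p in db.parents(f))
        and not any(
            gp.featuretype == "gene" for p in db.parents(f) for gp in db.parents(p)
        )
    )
    if n_orphans:
        log.warning("skipped %d feature(s) without a gene parent", n_orphans)
    return ann


def write_gff3(annotation: AnnotationSet, stream: "str | os.PathLike | TextIO") -> None:
    """Serialise an AnnotationSet as GFF3 (genes, mRNAs, exons)."""

    def _emit(out: TextIO) -> None:
        out.write("##gff-version 3\n")
        for seq_id in annotation.seq_ids:
            for gene in annotation.ordered_genes(seq_id):
                attrs = (
                    f"ID={gene.gene_id};Name={gene.symbol};"
                    f"biotype={gene.biotype}"
                )
                out.write(
                    "\t".join(
                        [
                            gene.seq_id,
                            gene.source,
                            "gene",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand.value,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
                for chain in annotation.transcripts_of(gene.gene_id):
                    out.write(
                        "\t".join(
                            [
                                gene.seq_id,
                                gene.source,
                                "mRNA",
                                str(chain.exons[0][0]),
                                str(chain.exons[-1][1]),
                                ".",
                                chain.strand.value,
                                ".",
                                f"ID={chain.transcript_id};Parent={gene.gene_id}",
                            ]
                        )
                        + "\n"
                    )
                    for i, (s, e) in enumerate(chain.exons, start=1):
                        out.write(
                            "\t".join(
                                [
                                    gene.seq_id,
                                    gene.source,
                                    "exon",
                                    str(s),
                                    str(e),
                                    ".",
                                    chain.strand.value,
                                    ".",
                                    f"ID={chain.transcript_id}.e{i};"
                                    f"Parent={chain.transcript_id}",
                                ]
                            )
                            + "\n"
                        )

    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "wt") as fh:
            _emit(fh)
    else:
        _emit(stream)


def read_fasta(stream: "str | os.PathLike | IO") -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence mapping.

    Duplicate identifiers are an error.  Non-ACGT characters are preserved
    but flagged with a warning so downstream operations can state their own
    handling.
    """
    if isinstance(stream, (str, os.PathLike)):
        handle: IO = open(stream, "rt")
        close = True
    else:
        handle = stream
        close = False
    try:
        records: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
            seq = str(rec.seq).upper()
            non_acgt = sum(1 for c in seq if c not in "ACGT")
            if non_acgt:
                log.warning(
                    "sequence %s contains %d non-ACGT character(s)", rec.id, non_acgt
                )
            records[rec.id] = seq
        return records
    finally:
        if close:
            handle.close()


def write_fasta(
    collection: dict[str, str], stream: "str | os.PathLike | TextIO", width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in collection.items()
    ]
    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "wt") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, stream, "fasta")


def ordered_genes(annotation: AnnotationSet, seq_id: str) -> list[GeneRecord]:
    """Genes on ``seq_id`` sorted by (start, end, gene_id)."""
    return annotation.ordered_genes(seq_id)


def write_gene_tsv(
    annotations: "AnnotationSet | Iterable[AnnotationSet]",
    stream: "str | os.PathLike | TextIO",
) -> None:
    """Dump GeneRecords of one or more annotation sets as TSV."""
    if isinstance(annotations, AnnotationSet):
        annotations = [annotations]

    def _emit(out: TextIO) -> None:
        out.write("\t".join(GENE_TSV_COLUMNS) + "\n")
        for ann in annotations:
            for seq_id in ann.seq_ids:
                for g in ann.ordered_genes(seq_id):
                    out.write(
                        "\t".join(
                            [
                                ann.species,
                                g.seq_id,
                                g.gene_id,
                                g.symbol,
                                str(g.start),
                                str(g.end),
                                g.strand.value,
                                g.biotype,
                                g.source,
                            ]
                        )
                        + "\n"
                    )

    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "wt") as fh:
            _emit(fh)
    else:
        _emit(stream)


def read_gene_tsv(stream: "str | os.PathLike | IO") -> list[AnnotationSet]:
    """Inverse of :func:`write_gene_tsv`; one AnnotationSet per species."""
    text = _as_text(stream)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = tuple(lines[0].split("\t"))
    if header != GENE_TSV_COLUMNS:
        raise ValueError(f"unexpected TSV header {header!r}")
    sets: dict[str, AnnotationSet] = {}
    for ln in lines[1:]:
        species, seq_id, gene_id, symbol, start, end, strand, biotype, source = (
            ln.split("\t")
        )
        ann = sets.setdefault(species, AnnotationSet(species=species))
        ann.add_gene(
            GeneRecord(
                gene_id=gene_id,
                symbol=symbol,
                seq_id=seq_id,
                start=int(start),
                end=int(end),
                strand=Strand.parse(strand),
                biotype=biotype,
                source=source,
            )
        )
    return list(sets.values())
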