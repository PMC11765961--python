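"""Core annotation data model.

Gene models are held as ordered, stranded intervals on scaffolds, one
:class:`AnnotationSet` per species/assembly.  Coordinates are 1-based
inclusive throughout (GFF3 convention); any half-open representation is
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class Strand(str, Enum):
    """Orientation of a gene model on its scaffold."""

    FORWARD = "+"
    REVERSE = "-"

    @classmethod
    def parse(cls, value: "str | Strand") -> "Strand":
        if isinstance(value, Strand):
            return value
        if value in ("+", "forward", "1"):
            return cls.FORWARD
        if value in ("-", "reverse", "-1"):
            return cls.REVERSE
        raise ValueError(f"not a valid strand: {value!r}")

    def flipped(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD


@dataclass(frozen=True)
class GeneRecord:
    """A single gene model on a scaffold.

    ``symbol`` may be a placeholder identifier such as ``LOC110258194`` or an
    Ensembl stable ID; placeholders are kept verbatim because a misannotated
    target gene is often only findable under one.
    """

    gene_id: str
    symbol: str
    seq_id: str
    start: int
    end: int
    strand: Strand
    biotype: str = "protein_coding"
    source: str = "other"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 1 <= start <= end, "
                f"got start={self.start}, end={self.end}"
            )
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand.parse(self.strand))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExonChain:
    """Exon structure of one transcript in genomic coordinates.

    ``exons`` are stored sorted ascending by genomic start and must be
    pairwise non-overlapping.  Exon numbering reported to users is 5'->3' on
    the transcript strand, i.e. the reverse of genomic order for
    reverse-strand transcripts.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]
    strand: Strand
    seq_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand.parse(self.strand))
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise ValueError(f"transcript {self.transcript_id}: exon {s}>{e}")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_5p_to_3p(self) -> tuple[tuple[int, int], ...]:
        """Exons ordered 5'->3' on the transcript strand."""
        if self.strand is Strand.REVERSE:
            return tuple(reversed(self.exons))
        return self.exons


class AnnotationSet:
    """All gene models of one species/assembly, indexed for synteny queries."""

    def __init__(self, species: str = "unknown", assembly: str = "") -> None:
        self.species = species
        self.assembly = assembly
        self._genes: dict[str, GeneRecord] = {}
        self._by_seq: dict[str, list[str]] = {}
        self._by_symbol: dict[str, list[str]] = {}
        self.transcripts: dict[str, ExonChain] = {}

    def add_gene(self, gene: GeneRecord) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene
        self._by_seq.setdefault(gene.seq_id, []).append(gene.gene_id)
        self._by_symbol.setdefault(gene.symbol.upper(), []).append(gene.gene_id)

    def add_transcript(self, chain: ExonChain) -> None:
        if chain.gene_id not in self._genes:
            raise ValueError(
                f"transcript {chain.transcript_id}: unknown gene_id {chain.gene_id!r}"
            )
        self.transcripts[chain.transcript_id] = chain

    def remove_gene(self, gene_id: str) -> None:
        gene = self._genes.pop(gene_id)
        self._by_seq[gene.seq_id].remove(gene_id)
        self._by_symbol[gene.symbol.upper()].remove(gene_id)
        for tid in [t for t, c in self.transcripts.items() if c.gene_id == gene_id]:
            del self.transcripts[tid]

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def get(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    @property
    def seq_ids(self) -> list[str]:
        return sorted(self._by_seq)

    def genes_by_symbol(self, symbol: str) -> list[GeneRecord]:
        """All genes carrying ``symbol`` (case-insensitive match)."""
        return [self._genes[g] for g in self._by_symbol.get(symbol.upper(), [])]

    def has_symbol(self, symbol: str) -> bool:
        return bool(self._by_symbol.get(symbol.upper()))

    def ordered_genes(
        self, seq_id: str, biotypes: Iterable[str] | None = None
    ) -> list[GeneRecord]:
        """Genes on ``seq_id`` in coordinate order.

        Stable sort key is (start, end, gene_id).  ``biotypes`` optionally
        restricts the list (e.g. to protein-coding genes) before ordering, so
        neighbour ranks downstream are computed on the filtered list.
        """
        if seq_id not in self._by_seq:
            raise KeyError(f"unknown seq_id {seq_id!r} in {self.species}")
        genes = [self._genes[g] for g in self._by_seq[seq_id]]
        if biotypes is not None:
            allowed = set(biotypes)
            genes = [g for g in genes if g.biotype in allowed]
        return sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))

    def transcripts_of(self, gene_id: str) -> list[ExonChain]:
        return [c for c in self.transcripts.values() if c.gene_id == gene_id]
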