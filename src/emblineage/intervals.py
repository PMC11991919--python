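"""Genomic interval and transcript-model containers.

Internal coordinates are 0-based half-open throughout the package; the GTF
reader/writer (:mod:`emblineage.gtf`) is the only place the 1-based shift
happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

STRANDS = {"+", "-", "."}


class InvalidInputError(ValueError):
    """Raised when a structural invariant of an input object is violated."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on one strand of a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InvalidInputError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise InvalidInputError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise InvalidInputError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _validate_exon_chain(exons: tuple[GenomicInterval, ...], owner: str) -> None:
    if not exons:
        raise InvalidInputError(f"{owner}: empty exon chain")
    chroms = {e.chrom for e in exons}
    strands = {e.strand for e in exons}
    if len(chroms) != 1 or len(strands) != 1:
        raise InvalidInputError(f"{owner}: exons span multiple chroms/strands")
    for a, b in zip(exons, exons[1:]):
        if b.start <= a.end:
            # also forbids touching exons: introns must have positive length
            raise InvalidInputError(
                f"{owner}: exons not sorted/disjoint ({a.start}-{a.end} then {b.start}-{b.end})"
            )


def _introns(exons: tuple[GenomicInterval, ...]) -> tuple[tuple[int, int], ...]:
    return tuple((a.end, b.start) for a, b in zip(exons, exons[1:]))


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain belonging to a gene."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _validate_exon_chain(self.exons, f"transcript {self.transcript_id}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """(start, end) pairs of the gaps between consecutive exons."""
        return _introns(self.exons)


@dataclass(frozen=True)
class Transfrag:
    """An assembled transcript fragment awaiting classification.

    Strand '.' (unstranded) is allowed only for single-exon transfrags, the
    assembler convention for exons without splice evidence.
    """

    transfrag_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _validate_exon_chain(self.exons, f"transfrag {self.transfrag_id}")
        if self.strand == "." and len(self.exons) > 1:
            raise InvalidInputError(
                f"transfrag {self.transfrag_id}: strand '.' only allowed for single exons"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return _introns(self.exons)


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def locus(self) -> GenomicInterval:
        """Span covering all transcripts of the gene."""
        start = min(t.start for t in self.transcripts)
        end = max(t.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class AnnotationSet:
    """Genes -> transcripts -> exon chains; both reference input and
    reconciled output use this container."""

    def __init__(self, genes: dict[str, Gene] | None = None):
        self.genes: dict[str, Gene] = dict(genes or {})
        self._check()

    def _check(self) -> None:
        seen: set[str] = set()
        for gid, gene in self.genes.items():
            if gene.gene_id != gid:
                raise InvalidInputError(f"gene map key {gid} != gene_id {gene.gene_id}")
            for t in gene.transcripts:
                if t.gene_id != gid:
                    raise InvalidInputError(
                        f"transcript {t.transcript_id} gene_id {t.gene_id} != {gid}"
                    )
                if t.transcript_id in seen:
                    raise InvalidInputError(
                        f"duplicate transcript_id {t.transcript_id}"
                    )
                seen.add(t.transcript_id)

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise InvalidInputError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def transcript_ids(self) -> set[str]:
        return {t.transcript_id for g in self.genes.values() for t in g.transcripts}

    def transcripts(self) -> Iterator[tuple[Gene, TranscriptModel]]:
        for gene in self.genes.values():
            for t in gene.transcripts:
                yield gene, t

    def transcripts_on(self, chrom: str) -> list[tuple[Gene, TranscriptModel]]:
        return [(g, t) for g, t in self.transcripts() if t.chrom == chrom]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(
            {
                gid: Gene(g.gene_id, g.gene_name, list(g.transcripts))
                for gid, g in self.genes.items()
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            o = other.genes[gid]
            if g.gene_name != o.gene_name:
                return False
            mine = sorted(g.transcripts, key=lambda t: t.transcript_id)
            theirs = sorted(o.transcripts, key=lambda t: t.transcript_id)
            if mine != theirs:
                return False
        return True

    def __len__(self) -> int:
        return len(self.genes)
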