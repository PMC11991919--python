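"""GTF and tabular alignment-hit I/O.

GTF is 1-based inclusive on disk; everything in memory is 0-based half-open.
The converters in this module are the only place the shift happens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils

from .intervals import AnnotationSet, Gene, GenomicInterval, InvalidInputError, Transfrag, TranscriptModel


def _attr(feature, key: str, default: str | None = None) -> str | None:
    vals = feature.attributes.get(key)
    if vals:
        return vals[0]
    return default


def _collect_exons(path: str) -> dict[str, dict]:
    """Group exon features by transcript_id, keeping attributes of interest."""
    records: dict[str, dict] = {}
    for feature in gffutils.DataIterator(path):
        if feature.featuretype != "exon":
            continue
        tid = _attr(feature, "transcript_id")
        if tid is None:
            raise InvalidInputError(f"{path}: exon without transcript_id")
        rec = records.setdefault(
            tid,
            {
                "gene_id": _attr(feature, "gene_id"),
                "gene_name": _attr(feature, "gene_name"),
                "biotype": _attr(feature, "biotype") or _attr(feature, "gene_biotype"),
                "exons": [],
            },
        )
        rec["exons"].append(
            GenomicInterval(feature.seqid, feature.start - 1, feature.end, feature.strand)
        )
    for rec in records.values():
        rec["exons"].sort(key=lambda e: e.start)
    return records


def read_annotation(path: str) -> AnnotationSet:
    """Read a GTF into an AnnotationSet (exon features only are required)."""
    genes: dict[str, Gene] = {}
    for tid, rec in _collect_exons(path).items():
        gid = rec["gene_id"] or tid
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"] or "protein_coding",
        )
        gene = genes.setdefault(gid, Gene(gid, rec["gene_name"] or gid))
        gene.transcripts.append(t)
    for gene in genes.values():
        gene.transcripts.sort(key=lambda t: t.transcript_id)
    return AnnotationSet(genes)


def read_transfrags(path: str) -> list[Transfrag]:
    """Read assembler output (GTF) as a list of transfrags."""
    out = [
        Transfrag(tid, tuple(rec["exons"]))
        for tid, rec in _collect_exons(path).items()
    ]
    out.sort(key=lambda t: t.transfrag_id)
    return out


def write_annotation(aset: AnnotationSet, path: str, source: str = "emblineage") -> None:
    """Write an AnnotationSet as GTF (transcript + exon features)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for gid in sorted(aset.genes):
            gene = aset.genes[gid]
            for t in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_name "{gene.gene_name}"; biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "transcript",
                            str(t.start + 1),
                            str(t.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                source,
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


@dataclass(frozen=True)
class AlignmentHit:
    """Best sequence-similarity hit of a transfrag against another species'
    transcriptome (tabular outfmt-6 style, one HSP / one target per query)."""

    query_id: str
    subject_transcript_id: str
    subject_gene_name: str
    subject_species: str
    evalue: float
    bitscore: float
    pct_identity: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise InvalidInputError("evalue must be >= 0")


def read_blast_hits(
    hits_path: str, subject_genes_path: str, species: str = "human"
) -> dict[str, AlignmentHit]:
    """Read outfmt-6 TSV plus a sidecar subject->gene-name TSV.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  If a query has several rows the best one is kept
    (max bitscore, then min evalue, then lexicographic subject id).
    """
    name_map: dict[str, str] = {}
    with open(subject_genes_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sid, gname = line.rstrip("\n").split("\t")[:2]
            name_map[sid] = gname

    best: dict[str, AlignmentHit] = {}
    with open(hits_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            hit = AlignmentHit(
                query_id=f[0],
                subject_transcript_id=f[1],
                subject_gene_name=name_map.get(f[1], f[1]),
                subject_species=species,
                evalue=float(f[10]),
                bitscore=float(f[11]),
                pct_identity=float(f[2]),
            )
            prev = best.get(hit.query_id)
            if prev is None or (-hit.bitscore, hit.evalue, hit.subject_transcript_id) < (
                -prev.bitscore,
                prev.evalue,
                prev.subject_transcript_id,
            ):
                best[hit.query_id] = hit
    return best
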