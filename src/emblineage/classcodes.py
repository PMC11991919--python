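"""Structural classification of transfrags against a reference annotation.

Each transfrag receives a one-character class code describing its relation to
the closest reference transcript (exact intron-chain match, containment,
junction sharing, intron retention, intronic, intergenic, ...), in the style
of transcriptome-assembly comparison tools.  The dialect implemented here is
fully specified so it can be checked against an independent per-base oracle:

=  multi-exon: identical intron chain; single-exon vs single-exon: same
   strand and reciprocal exonic overlap >= 80%
c  transfrag contained in the reference: its intron chain is a contiguous
   sub-chain of the reference's and both transfrag ends lie inside reference
   exons (single-exon transfrag: inside one reference exon)
k  reverse containment (reference contained in the transfrag)
m  every reference intron either exactly matched or fully retained inside a
   transfrag exon, with exonic overlap
n  at least one reference intron retained, but not all matched-or-retained
j  at least one shared splice junction (exact intron match), same strand
e  single-exon transfrag overlapping a reference exon and extending >= 10 bp
   into an intron
o  other same-strand exonic overlap
s  a transfrag intron exactly matches a reference intron on the opposite
   strand (likely mapping artifact)
x  opposite-strand exonic overlap
i  transfrag entirely within one reference intron, same strand
y  a reference transcript entirely within one transfrag intron, same strand
p  no overlap, same strand, within 2,000 bp downstream of a reference gene
u  intergenic / none of the above

Codes are ranked; a transfrag is labelled with the highest-priority code over
all reference transcripts on its chromosome.  Unstranded ('.') single-exon
transfrags are compared against both strands with the opposite-strand codes
(s, x) suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import (
    AnnotationSet,
    Gene,
    GenomicInterval,
    Transfrag,
    TranscriptModel,
)

#: Strict priority order, best first.
CODE_PRIORITY = "=ckmnjeosxiypu"

#: Maximum downstream gap (bp) for the run-on code 'p'.
POLYMERASE_RUNON_BP = 2000

#: Minimum intrusion into an intron (bp) for the pre-mRNA code 'e'.
EXON_INTRON_OVERHANG_BP = 10

#: Reciprocal-overlap fraction for single-exon '='.
SINGLE_EXON_MATCH_FRAC = 0.8

_RANK = {c: i for i, c in enumerate(CODE_PRIORITY)}


def code_rank(code: str) -> int:
    """Rank of a class code; smaller is higher priority."""
    return _RANK[code]


@dataclass(frozen=True)
class ClassificationResult:
    transfrag_id: str
    code: str
    ref_transcript_id: str | None
    ref_gene_id: str | None
    n_overlapping_genes: int


def _exonic_overlap(a: tuple[GenomicInterval, ...], b: tuple[GenomicInterval, ...]) -> int:
    total = 0
    for ea in a:
        for eb in b:
            total += ea.overlap(eb)
    return total


def _is_contiguous_subchain(
    sub: tuple[tuple[int, int], ...], chain: tuple[tuple[int, int], ...]
) -> bool:
    """True if `sub` (non-empty) appears as consecutive elements of `chain`."""
    if not sub or len(sub) > len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if chain[i : i + len(sub)] == sub:
            return True
    return False


def _ends_in_exons(start: int, end: int, exons: tuple[GenomicInterval, ...]) -> bool:
    in_start = any(e.start <= start < e.end for e in exons)
    in_end = any(e.start < end <= e.end for e in exons)
    return in_start and in_end


def _contained(
    q_exons: tuple[GenomicInterval, ...],
    q_introns: tuple[tuple[int, int], ...],
    r_exons: tuple[GenomicInterval, ...],
    r_introns: tuple[tuple[int, int], ...],
) -> bool:
    """Containment test shared by codes 'c' and 'k' (roles swapped)."""
    if len(q_exons) == 1:
        q = q_exons[0]
        return any(e.start <= q.start and q.end <= e.end for e in r_exons)
    return _is_contiguous_subchain(q_introns, r_introns) and _ends_in_exons(
        q_exons[0].start, q_exons[-1].end, r_exons
    )


def _intron_retained(intron: tuple[int, int], exons: tuple[GenomicInterval, ...]) -> bool:
    s, e = intron
    return any(ex.start <= s and e <= ex.end for ex in exons)


def _code_vs_transcript(t: Transfrag, r: TranscriptModel) -> str | None:
    """Class code of transfrag `t` against one reference transcript, or None
    when the pair is structurally unrelated (codes p/u are decided later at
    the gene level)."""
    if t.chrom != r.chrom:
        return None
    same_strand = t.strand == r.strand or t.strand == "."
    te, re_ = t.exons, r.exons
    ti, ri = t.introns, r.introns
    ov = _exonic_overlap(te, re_)

    if same_strand:
        if len(te) > 1 and len(re_) > 1 and ti == ri:
            return "="
        if len(te) == 1 and len(re_) == 1:
            if ov >= SINGLE_EXON_MATCH_FRAC * t.length and ov >= SINGLE_EXON_MATCH_FRAC * r.length:
                return "="
        if _contained(te, ti, re_, ri):
            return "c"
        if _contained(re_, ri, te, ti):
            return "k"
        if len(ri) > 0 and ov > 0:
            matched = [x in ti for x in ri]
            retained = [_intron_retained(x, te) for x in ri]
            if all(m or k for m, k in zip(matched, retained)):
                return "m"
            if any(retained):
                return "n"
        if len(ti) > 0 and len(ri) > 0 and set(ti) & set(ri):
            return "j"
        if len(te) == 1 and ov > 0:
            intruded = sum(
                max(0, min(te[0].end, ie) - max(te[0].start, is_))
                for is_, ie in ri
            )
            if intruded >= EXON_INTRON_OVERHANG_BP:
                return "e"
        if ov > 0:
            return "o"
        if any(is_ <= t.start and t.end <= ie for is_, ie in ri):
            return "i"
        if any(ts <= r.start and r.end <= te_ for ts, te_ in ti):
            return "y"
        return None

    # concrete opposite strands
    if set(ti) & set(ri):
        return "s"
    if ov > 0:
        return "x"
    return None


def _runon_gene(t: Transfrag, refs: AnnotationSet) -> Gene | None:
    """Reference gene for which `t` is a downstream run-on candidate ('p'):
    same strand, transfrag entirely 3' of the gene locus, gap <= 2 kb.
    Nearest gap wins; ties broken by gene_id."""
    best: tuple[int, str, Gene] | None = None
    for gene in refs.genes_on(t.chrom):
        if t.strand != "." and t.strand != gene.strand:
            continue
        locus = gene.locus
        if gene.strand == "+":
            gap = t.start - locus.end
        else:
            gap = locus.start - t.end
        if 0 <= gap <= POLYMERASE_RUNON_BP:
            key = (gap, gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (gap, gene.gene_id, gene)
    return best[2] if best else None


def classify_transfrag(t: Transfrag, refs: AnnotationSet) -> ClassificationResult:
    """Classify one transfrag against a reference annotation.

    Returns the highest-priority code over all reference transcripts on the
    transfrag's chromosome.  Among references yielding the same top code the
    one with the largest exonic overlap wins, remaining ties by lexicographic
    transcript_id.  ``n_overlapping_genes`` counts distinct reference genes
    with same-strand exonic overlap (any strand for unstranded transfrags).
    """
    candidates: list[tuple[int, int, str, Gene, TranscriptModel]] = []
    overlapping_genes: set[str] = set()
    for gene, r in refs.transcripts_on(t.chrom):
        code = _code_vs_transcript(t, r)
        ov = _exonic_overlap(t.exons, r.exons)
        if ov > 0 and (t.strand == "." or t.strand == r.strand):
            overlapping_genes.add(gene.gene_id)
        if code is not None:
            candidates.append((code_rank(code), -ov, code, gene, r))

    if candidates:
        candidates.sort(key=lambda c: (c[0], c[1], c[4].transcript_id))
        _, _, code, gene, r = candidates[0]
        return ClassificationResult(
            transfrag_id=t.transfrag_id,
            code=code,
            ref_transcript_id=r.transcript_id,
            ref_gene_id=gene.gene_id,
            n_overlapping_genes=len(overlapping_genes),
        )

    gene = _runon_gene(t, refs)
    if gene is not None:
        return ClassificationResult(
            transfrag_id=t.transfrag_id,
            code="p",
            ref_transcript_id=None,
            ref_gene_id=gene.gene_id,
            n_overlapping_genes=0,
        )
    return ClassificationResult(
        transfrag_id=t.transfrag_id,
        code="u",
        ref_transcript_id=None,
        ref_gene_id=None,
        n_overlapping_genes=0,
    )
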