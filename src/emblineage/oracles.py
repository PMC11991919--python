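"""Brute-force reference implementations used only for validation.

These deliberately avoid the interval arithmetic of the production code:
the class-code oracle materialises per-base occupancy as Python sets and
compares explicit junction sets; the neighbour oracle is a plain O(n^2)
double loop.  They exist so the fast implementations can be checked against
an independent computation path, never as the implementations themselves.
"""

from __future__ import annotations

import math

import numpy as np

from .classcodes import (
    CODE_PRIORITY,
    EXON_INTRON_OVERHANG_BP,
    POLYMERASE_RUNON_BP,
    SINGLE_EXON_MATCH_FRAC,
)
from .intervals import AnnotationSet, Transfrag, TranscriptModel


def _exon_bases(exons) -> set[int]:
    bases: set[int] = set()
    for e in exons:
        bases.update(range(e.start, e.end))
    return bases


def _intron_bases(introns) -> set[int]:
    bases: set[int] = set()
    for s, e in introns:
        bases.update(range(s, e))
    return bases


def _contiguous(sub: set, chain: tuple) -> bool:
    """sub (a set of introns) appears as consecutive run inside chain."""
    if not sub:
        return False
    idx = sorted(chain.index(x) for x in sub if x in chain)
    if len(idx) != len(sub):
        return False
    return idx == list(range(idx[0], idx[0] + len(idx)))


def _oracle_code_pair(t: Transfrag, r: TranscriptModel) -> str | None:
    if t.chrom != r.chrom:
        return None
    tb, rb = _exon_bases(t.exons), _exon_bases(r.exons)
    tj, rj = set(t.introns), set(r.introns)
    rib = _intron_bases(r.introns)
    same = t.strand == r.strand or t.strand == "."
    ov = len(tb & rb)

    if not same:
        if tj & rj:
            return "s"
        if ov:
            return "x"
        return None

    # '='
    if len(t.exons) > 1 and len(r.exons) > 1 and tj == rj:
        return "="
    if len(t.exons) == 1 and len(r.exons) == 1:
        if ov >= SINGLE_EXON_MATCH_FRAC * len(tb) and ov >= SINGLE_EXON_MATCH_FRAC * len(rb):
            return "="
    # 'c': contained in reference
    if len(t.exons) == 1:
        if any(set(range(e.start, e.end)) >= tb for e in r.exons):
            return "c"
    elif _contiguous(tj, r.introns) and min(tb) in rb and max(tb) in rb:
        return "c"
    # 'k': reference contained in transfrag
    if len(r.exons) == 1:
        if any(set(range(e.start, e.end)) >= rb for e in t.exons):
            return "k"
    elif _contiguous(rj, t.introns) and min(rb) in tb and max(rb) in tb:
        return "k"
    # 'm'/'n': intron retention
    if rj and ov:
        status = []
        for intron in r.introns:
            bases = set(range(intron[0], intron[1]))
            status.append("match" if intron in tj else ("ret" if bases <= tb else "no"))
        if all(s != "no" for s in status):
            return "m"
        if any(s == "ret" for s in status):
            return "n"
    # 'j'
    if tj and rj and tj & rj:
        return "j"
    # 'e'
    if len(t.exons) == 1 and ov and len(tb & rib) >= EXON_INTRON_OVERHANG_BP:
        return "e"
    # 'o'
    if ov:
        return "o"
    # 'i'
    if t.exons and any(
        tb <= set(range(s, e)) for s, e in r.introns
    ):
        return "i"
    # 'y'
    if any(rb | rib <= set(range(s, e)) for s, e in t.introns):
        return "y"
    return None


def oracle_classify(t: Transfrag, refs: AnnotationSet) -> str:
    """Class code of `t` by exhaustive per-base comparison; the independent
    check for :func:`emblineage.classcodes.classify_transfrag`."""
    codes = []
    for _, r in refs.transcripts_on(t.chrom):
        c = _oracle_code_pair(t, r)
        if c is not None:
            codes.append(c)
    if codes:
        return min(codes, key=CODE_PRIORITY.index)
    # distance scan for 'p': walk bases downstream of each same-strand gene
    tb_min, tb_max = t.start, t.end
    for gene in refs.genes_on(t.chrom):
        if t.strand != "." and t.strand != gene.strand:
            continue
        locus = gene.locus
        if gene.strand == "+":
            ok = tb_min >= locus.end and tb_min - locus.end <= POLYMERASE_RUNON_BP
        else:
            ok = tb_max <= locus.start and locus.start - tb_max <= POLYMERASE_RUNON_BP
        if ok:
            return "p"
    return "u"


def oracle_knn_pairs(a: np.ndarray, b: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Mutual nearest neighbours of columns of a and b by plain double loops."""
    na, nb = a.shape[1], b.shape[1]

    def dist(i: int, j: int) -> float:
        return math.sqrt(sum((a[f, i] - b[f, j]) ** 2 for f in range(a.shape[0])))

    ab = {}
    for i in range(na):
        order = sorted(range(nb), key=lambda j: (dist(i, j), j))
        ab[i] = set(order[: min(k, nb)])
    ba = {}
    for j in range(nb):
        order = sorted(range(na), key=lambda i: (dist(i, j), i))
        ba[j] = set(order[: min(k, na)])
    return {(i, j) for i in range(na) for j in ab[i] if i in ba[j]}
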