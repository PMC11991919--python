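"""Synthetic fixtures with known ground truth.

Two families of generators:

* toy reference annotations plus transfrags *constructed* (not rejection
  sampled) to realise each requested class code, with optional planted
  similarity hits — the substrate for testing classification and
  reconciliation;
* multi-species gene x cell count matrices with lineage-structured
  negative-binomial expression: planted markers, conserved / divergent
  ortholog programmes, stage-specific programmes shared across species,
  mitochondrial and stress-granule fractions, and cells designed to fail
  exactly one QC criterion each.

Every generator is deterministic per seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classcodes import CODE_PRIORITY
from .gtf import AlignmentHit
from .intervals import AnnotationSet, Gene, GenomicInterval, Transfrag, TranscriptModel
from .qc import CORE_LINEAGES, CountMatrix, GeneSets, QCThresholds, compute_qc_metrics
from .xspecies import OrthologTable

# ---------------------------------------------------------------------------
# annotation fixtures

_EXON_LEN = 200
_GENE_SPACING = 10_000


@dataclass(frozen=True)
class AnnotationFixtureSpec:
    """Request for a toy annotation + transfrag fixture.

    ``planted_codes`` lists the class codes to realise, one transfrag each.
    ``u_hit_genes`` aligns with the 'u' entries of ``planted_codes``: each
    entry is a subject gene name to plant a similarity hit for, or None.
    """

    planted_codes: tuple[str, ...] = tuple(CODE_PRIORITY)
    n_genes: int | None = None
    exons_per_transcript: tuple[int, int] = (4, 6)
    intron_length: tuple[int, int] = (250, 400)
    u_hit_genes: tuple[str | None, ...] = ()
    seed: int = 0


def _gene_at(base: int, gid: str, n_exons: int, intron_lens: list[int],
             strand: str = "+", chrom: str = "chrS",
             biotype: str = "protein_coding") -> Gene:
    exons = []
    pos = base
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + _EXON_LEN, strand))
        if i < n_exons - 1:
            pos += _EXON_LEN + intron_lens[i]
    t = TranscriptModel(f"{gid}.t1", gid, tuple(exons), biotype=biotype)
    return Gene(gid, gid, [t])


def _construct_transfrag(code: str, gene: Gene, tf_id: str) -> Transfrag:
    """Build a transfrag guaranteed to classify as `code` against `gene`
    (an isolated multi-exon reference gene on the '+' strand)."""
    r = gene.transcripts[0]
    ex = r.exons
    chrom = r.chrom
    i1 = (ex[0].end, ex[1].start)
    i2 = (ex[1].end, ex[2].start)

    def iv(s, e, strand="+"):
        return GenomicInterval(chrom, s, e, strand)

    if code == "=":
        exons = tuple(ex)
    elif code == "c":
        exons = (iv(ex[1].start + 20, ex[1].end), iv(ex[2].start, ex[2].start + 180))
    elif code == "k":
        exons = (
            (iv(ex[0].start - 100, ex[0].end),)
            + tuple(ex[1:-1])
            + (iv(ex[-1].start, ex[-1].end + 100), iv(ex[-1].end + 400, ex[-1].end + 600))
        )
    elif code == "m":
        exons = (iv(ex[0].start, ex[-1].end),)
    elif code == "n":
        exons = (iv(ex[0].start, ex[1].end + (i2[1] - i2[0]) // 2),)
    elif code == "j":
        exons = (iv(ex[0].start + 20, ex[0].end), iv(ex[1].start, ex[1].end + 50))
    elif code == "e":
        exons = (iv(ex[1].start + 50, ex[1].end + 60),)
    elif code == "o":
        a0 = i1[0] + (i1[1] - i1[0]) // 2
        b0 = ex[1].end + (i2[1] - i2[0]) // 3
        exons = (iv(a0, ex[1].start + 100), iv(b0, b0 + 100))
    elif code == "s":
        exons = (iv(ex[0].end - 100, ex[0].end, "-"), iv(ex[1].start, ex[1].start + 100, "-"))
    elif code == "x":
        exons = (iv(ex[1].start + 30, ex[1].end + 40, "-"),)
    elif code == "i":
        exons = (iv(ex[0].end + 25, ex[0].end + 225),)
    elif code == "y":
        exons = (iv(r.start - 400, r.start - 200), iv(r.end + 200, r.end + 400))
    elif code == "p":
        exons = (iv(r.end + 1500, r.end + 1700),)
    elif code == "u":
        exons = (iv(r.end + 2500, r.end + 2700),)
    else:
        raise ValueError(f"unrealizable class code {code!r}")
    return Transfrag(tf_id, exons)


def make_annotation_fixture(spec: AnnotationFixtureSpec):
    """Toy (AnnotationSet, transfrags, hits, manifest) realising every
    requested class code by construction."""
    rng = np.random.default_rng(spec.seed)
    for code in spec.planted_codes:
        if code not in CODE_PRIORITY:
            raise ValueError(f"unrealizable class code {code!r}")
    lo, hi = spec.exons_per_transcript
    lo = max(lo, 4)
    hi = max(hi, lo)

    genes: dict[str, Gene] = {}
    transfrags: list[Transfrag] = []
    expected: dict[str, str] = {}
    hits: dict[str, AlignmentHit] = {}
    u_hits = list(spec.u_hit_genes)

    base = 5_000
    for i, code in enumerate(spec.planted_codes):
        gid = f"G{i + 1:04d}"
        n_ex = int(rng.integers(lo, hi + 1))
        intron_lens = [int(rng.integers(*spec.intron_length)) for _ in range(n_ex - 1)]
        gene = _gene_at(base, gid, n_ex, intron_lens)
        genes[gid] = gene
        tf_id = f"TF{i + 1:04d}"
        t = _construct_transfrag(code, gene, tf_id)
        transfrags.append(t)
        expected[tf_id] = code
        if code == "u" and u_hits:
            subject = u_hits.pop(0)
            if subject is not None:
                hits[tf_id] = AlignmentHit(
                    query_id=tf_id,
                    subject_transcript_id=f"{subject}-201",
                    subject_gene_name=subject,
                    subject_species="human",
                    evalue=1e-50,
                    bitscore=500.0,
                    pct_identity=92.0,
                )
        base += _GENE_SPACING

    n_extra = 0 if spec.n_genes is None else max(0, spec.n_genes - len(genes))
    for j in range(n_extra):
        gid = f"GX{j + 1:04d}"
        n_ex = int(rng.integers(lo, hi + 1))
        intron_lens = [int(rng.integers(*spec.intron_length)) for _ in range(n_ex - 1)]
        genes[gid] = _gene_at(base, gid, n_ex, intron_lens)
        base += _GENE_SPACING

    manifest = {"expected_codes": expected, "planted_hits": sorted(hits)}
    return AnnotationSet(genes), transfrags, hits, manifest


def random_toy_instance(rng: np.random.Generator):
    """A random (refs, transfrag) pair for oracle-agreement testing.

    Transfrags are usually perturbations of a reference transcript (exon
    drops, boundary shifts, intron removal, offsets, strand flips, intronic
    or intergenic slices) so all relation classes are exercised.
    """
    chrom = "chrR"

    def random_chain(start: int, strand: str, n_exons: int):
        exons = []
        pos = start
        for i in range(n_exons):
            ln = int(rng.integers(80, 301))
            exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
            pos += ln + int(rng.integers(60, 401))
        return tuple(exons)

    genes = {}
    for gi in range(int(rng.integers(1, 3))):
        gid = f"R{gi}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1_000, 4_000)) + gi * 6_000
        gene = Gene(gid, gid, [])
        for ti in range(int(rng.integers(1, 3))):
            n_ex = int(rng.integers(1, 5))
            gene.transcripts.append(
                TranscriptModel(f"{gid}.t{ti}", gid, random_chain(start + int(rng.integers(0, 200)), strand, n_ex))
            )
        genes[gid] = gene
    refs = AnnotationSet(genes)

    _, r = refs.transcripts_on(chrom)[int(rng.integers(0, len(refs.transcripts_on(chrom))))]
    mode = rng.random()
    if mode < 0.55:
        # perturb the reference chain
        exons = list(r.exons)
        if len(exons) > 1 and rng.random() < 0.4:
            a = int(rng.integers(0, 2))
            b = int(rng.integers(0, 2))
            if a + b < len(exons):
                exons = exons[a : len(exons) - b]
        if len(exons) > 1 and rng.random() < 0.3:
            drop = int(rng.integers(0, len(exons) - 1))  # remove an intron
            merged = GenomicInterval(chrom, exons[drop].start, exons[drop + 1].end, exons[drop].strand)
            exons = exons[:drop] + [merged] + exons[drop + 2 :]
        shift = int(rng.integers(-150, 151))
        first = exons[0]
        new_start = max(0, min(first.start + shift, first.end - 20))
        exons[0] = GenomicInterval(chrom, new_start, first.end, first.strand)
        last = exons[-1]
        shift = int(rng.integers(-150, 151))
        new_end = max(last.start + 20, last.end + shift)
        exons[-1] = GenomicInterval(chrom, last.start, new_end, last.strand)
        offset = int(rng.choice([0, 0, 0, rng.integers(-3000, 3001)]))
        strand = r.strand if rng.random() < 0.7 else ("-" if r.strand == "+" else "+")
        fixed = []
        pos = -1
        for e in exons:
            s, en = e.start + offset, e.end + offset
            if s <= pos:
                s = pos + 1
            if en <= s + 10:
                en = s + 10 + int(rng.integers(0, 50))
            fixed.append(GenomicInterval(chrom, max(0, s), max(0, s) + (en - s), strand))
            pos = en
        exons = fixed
    elif mode < 0.75:
        # single-exon slice near (often inside an intron of) the reference
        if r.introns and rng.random() < 0.4:
            s, e = r.introns[int(rng.integers(0, len(r.introns)))]
            ln = max(10, min(int(rng.integers(20, 200)), e - s - 2))
            center = int(rng.integers(s, max(s + 1, e - ln)))
        else:
            center = int(rng.integers(max(0, r.start - 2_500), r.end + 2_500))
            ln = int(rng.integers(60, 400))
        strand = rng.choice([r.strand, "+", "-", "."])
        exons = [GenomicInterval(chrom, center, center + ln, str(strand))]
    elif mode < 0.85:
        # envelop the reference: two distant exons flanking the whole gene
        margin = int(rng.integers(50, 600))
        strand = r.strand if rng.random() < 0.7 else ("-" if r.strand == "+" else "+")
        left = max(0, r.start - margin - 200)
        exons = [
            GenomicInterval(chrom, left, left + 200, strand),
            GenomicInterval(chrom, r.end + margin, r.end + margin + 200, strand),
        ]
    else:
        # random chain, possibly far away
        strand = "+" if rng.random() < 0.5 else "-"
        exons = list(random_chain(int(rng.integers(0, 20_000)), strand, int(rng.integers(1, 4))))
    return refs, Transfrag("T0", tuple(exons))


def reconciliation_fixture():
    """Hand-built fixture whose ten transfrags cover all eight dispositions.

    Returns (refs, transfrags, hits, nonassembled, ortholog_names, manifest).
    """
    chrom = "chr1"

    def iv(s, e, strand="+"):
        return GenomicInterval(chrom, s, e, strand)

    def gene(gid, base, biotype="protein_coding"):
        return _gene_at(base, gid, 4, [300, 300, 300], "+", chrom, biotype)

    ga = gene("GA", 5_000)       # assigned '=' and 'j'
    gb = gene("GB", 20_000)      # short + x
    gc = gene("GC", 35_000)      # merge target (hit FOXA2)
    gd = gene("GD", 50_000)      # host of the 'i' transfrag
    ge = gene("GE", 65_000)      # far ortholog of TBX3 (outside ±3 kb)
    gm1 = gene("GM1", 80_000)    # multigene pair
    gm2 = gene("GM2", 82_500)
    gp_ = gene("GP", 95_000)     # run-on 'p' target
    refs = AnnotationSet({g.gene_id: g for g in (ga, gb, gc, gd, ge, gm1, gm2, gp_)})

    ra = ga.transcripts[0]
    rb = gb.transcripts[0]
    rd = gd.transcripts[0]

    transfrags = [
        Transfrag("TQ01", tuple(ra.exons)),                                    # '='
        Transfrag("TQ02", (iv(ra.exons[0].start + 20, ra.exons[0].end),
                           iv(ra.exons[1].start, ra.exons[1].end + 50))),      # 'j'
        Transfrag("TQ03", (iv(rb.exons[0].start + 10, rb.exons[0].start + 160),)),  # 150 bp -> short
        Transfrag("TQ04", (iv(rb.exons[1].start + 30, rb.exons[1].end + 40, "-"),)),  # 'x'
        Transfrag("TQ05", (iv(gm1.transcripts[0].end - 120, gm2.transcripts[0].start + 120),)),  # 2 genes
        Transfrag("TQ06", (iv(120_000, 120_400),)),            # 'u' + SOX2 hit -> new gene
        Transfrag("TQ07", (iv(gc.locus.start - 1_200, gc.locus.start - 1_000),)),  # 'u' upstream, merge
        Transfrag("TQ08", (iv(130_000, 130_350),)),            # 'u', no hit -> retained
        Transfrag("TQ09", (iv(rd.exons[0].end + 25, rd.exons[0].end + 245),)),  # 'i' + far hit -> retained
        Transfrag("TQ10", (iv(gp_.locus.end + 1_500, gp_.locus.end + 1_700),)),  # 'p' -> assigned
    ]

    def hit(q, subject):
        return AlignmentHit(q, f"{subject}-201", subject, "human", 1e-60, 700.0, 95.0)

    hits = {"TQ06": hit("TQ06", "SOX2"), "TQ07": hit("TQ07", "FOXA2"),
            "TQ09": hit("TQ09", "TBX3")}
    ortholog_names = {"FOXA2": "GC", "TBX3": "GE"}

    nonassembled = AnnotationSet(
        {
            "MIR100": _gene_at(200_000, "MIR100", 4, [300, 300, 300], "+", chrom, "miRNA"),
            "SNORA1": _gene_at(220_000, "SNORA1", 4, [300, 300, 300], "+", chrom, "snRNA"),
        }
    )

    manifest = {
        "dispositions": {
            "TQ01": "assigned_to_reference_gene",
            "TQ02": "assigned_to_reference_gene",
            "TQ03": "dropped_short",
            "TQ04": "dropped_class_esx",
            "TQ05": "dropped_multigene",
            "TQ06": "novel_named_new_gene",
            "TQ07": "novel_merged_within_3kb",
            "TQ08": "novel_retained_unnamed",
            "TQ09": "novel_retained_unnamed",
            "TQ10": "assigned_to_reference_gene",
        },
        "counts": {
            "dropped_short": 1,
            "dropped_class_esx": 1,
            "dropped_multigene": 1,
            "assigned_to_reference_gene": 3,
            "novel_named_new_gene": 1,
            "novel_merged_within_3kb": 1,
            "novel_retained_unnamed": 2,
            "nonassembled_biotypes_merged": 2,
        },
    }
    return refs, transfrags, hits, nonassembled, ortholog_names, manifest


# ---------------------------------------------------------------------------
# expression designs

_SPECIES_PREFIX = {"gp": "GP", "human": "HS", "mouse": "MM"}

_DEFAULT_STAGE_OF_LINEAGE = {
    "gp": {"prelineage": "8C", "ICM": "EB", "EPI": "MB", "PE": "MB", "TE": "LB"},
    "human": {"prelineage": "E3", "ICM": "E5", "EPI": "E6", "PE": "E6", "TE": "E7"},
    "mouse": {"prelineage": "8C", "ICM": "EB", "EPI": "MB", "PE": "MB", "TE": "LB"},
}


@dataclass(frozen=True)
class PlantedMarker:
    gene: str           # regular-gene key, e.g. "G0003"
    lineage: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("planted marker fold_change must exceed 1")


@dataclass(frozen=True)
class ExpressionDesign:
    """Study conditions for the count simulator.

    Counts are negative binomial with per-(gene, lineage, species) means and
    a fixed dispersion (NB size); per-cell depth multipliers are
    log-normal(0, depth_sd).  ``n_genes`` counts the flat background genes;
    ortholog programme genes (conserved/stage maps), mitochondrial and
    stress-granule genes come on top.  Designated QC-fail cells violate
    exactly one filter criterion each.
    """

    species: tuple[str, ...] = ("gp",)
    cell_groups: tuple[tuple[str, str, int], ...] = (
        ("prelineage", "8C", 14),
        ("ICM", "EB", 14),
        ("EPI", "MB", 14),
        ("PE", "MB", 14),
        ("TE", "LB", 14),
    )
    n_genes: int = 4000
    baseline_mean: float = 3.0
    dispersion: float = 2.0
    depth_sd: float = 0.3
    planted_markers: tuple[PlantedMarker, ...] = ()
    conserved_map: tuple[tuple[str, tuple[tuple[str, str | None], ...]], ...] = ()
    conserved_fold: float = 6.0
    conserved_baseline: float = 0.3
    stage_markers: tuple[tuple[str, int], ...] = ()   # (ortholog key, stage-pair idx)
    stage_pairs: tuple[tuple[str, ...], ...] = ()     # per idx: stage per species
    stage_fold: float = 8.0
    n_mito: int = 10
    mito_fraction_target: float = 0.02
    n_stress: int = 20
    stress_fraction_target: float = 0.04
    n_fail_qc: int = 10
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mito_fraction_target + self.stress_fraction_target > 0.5:
            raise ValueError("infeasible mito/stress fraction targets (> 0.5 combined)")
        for _, _, n in self.cell_groups:
            if n < 2:
                raise ValueError("every lineage needs at least 2 cells")

    # ---- presets -----------------------------------------------------

    @classmethod
    def qc_default(cls, n_fail_qc: int = 10, seed: int = 0) -> "ExpressionDesign":
        return cls(n_fail_qc=n_fail_qc, seed=seed)

    @classmethod
    def marker_recovery(cls, seed: int = 0) -> "ExpressionDesign":
        lineages = ("EPI", "PE", "TE")
        markers = tuple(
            PlantedMarker(f"G{i:04d}", lineages[i % 3], 8.0) for i in range(50)
        )
        return cls(
            species=("gp",),
            cell_groups=(("EPI", "MB", 30), ("PE", "MB", 30), ("TE", "LB", 30)),
            n_genes=1000,
            baseline_mean=1.0,
            planted_markers=markers,
            n_fail_qc=0,
            seed=seed,
        )

    @classmethod
    def null_markers(cls, seed: int = 0) -> "ExpressionDesign":
        return replace(cls.marker_recovery(seed=seed), planted_markers=())

    @classmethod
    def conservation(cls, noiseless: bool = False, seed: int = 0) -> "ExpressionDesign":
        lineages = CORE_LINEAGES
        entries: list[tuple[str, tuple[tuple[str, str | None], ...]]] = []
        i = 0

        def key() -> str:
            nonlocal i
            i += 1
            return f"OG{i:04d}"

        def lin(j: int) -> str:
            return lineages[j % len(lineages)]

        for j in range(60):       # conserved in all three
            l = lin(j)
            entries.append((key(), (("human", l), ("mouse", l), ("gp", l))))
        for j in range(50):       # human + guinea pig, mouse divergent/absent
            l = lin(j)
            other = lin(j + 1) if j % 2 == 0 else None
            entries.append((key(), (("human", l), ("mouse", other), ("gp", l))))
        for j in range(40):       # mouse + guinea pig
            l = lin(j)
            other = lin(j + 2) if j % 2 == 0 else None
            entries.append((key(), (("human", other), ("mouse", l), ("gp", l))))
        for j in range(45):       # human + mouse
            l = lin(j)
            other = lin(j + 3) if j % 2 == 0 else None
            entries.append((key(), (("human", l), ("mouse", l), ("gp", other))))
        for j in range(105):      # no agreement
            if j % 3 == 0:
                entries.append((key(), (("human", lin(j)), ("mouse", lin(j + 1)), ("gp", lin(j + 2)))))
            elif j % 3 == 1:
                entries.append((key(), (("human", lin(j)), ("mouse", None), ("gp", None))))
            else:
                entries.append((key(), (("human", None), ("mouse", lin(j)), ("gp", None))))
        groups = tuple((l, _DEFAULT_STAGE_OF_LINEAGE["gp"][l], 20) for l in lineages)
        return cls(
            species=("human", "mouse", "gp"),
            cell_groups=groups,
            n_genes=0,
            baseline_mean=1.0,
            conserved_map=tuple(entries),
            noiseless=noiseless,
            n_fail_qc=0,
            seed=seed,
        )

    @classmethod
    def stage_alignment(cls, seed: int = 0) -> "ExpressionDesign":
        gp_stages = ("8C", "16C", "EB", "MB", "LB")
        hs_stages = ("E3", "E4", "E5", "E6", "E7")
        lineage_of = {"8C": "prelineage", "16C": "prelineage", "EB": "ICM",
                      "MB": "EPI", "LB": "EPI"}
        pairs = tuple((g, h) for g, h in zip(gp_stages, hs_stages))
        # stage programmes span most of the shared transcriptome, as real
        # preimplantation stages do: 40 programme genes per stage over a
        # 100-gene flat background
        markers = tuple(
            (f"SK{idx:02d}_{j:02d}", idx) for idx in range(5) for j in range(40)
        )
        return cls(
            species=("gp", "human"),
            cell_groups=tuple((lineage_of[s], s, 20) for s in gp_stages),
            n_genes=100,
            baseline_mean=2.0,
            stage_markers=markers,
            stage_pairs=pairs,
            n_fail_qc=0,
            seed=seed,
        )


@dataclass
class SpeciesData:
    counts: CountMatrix
    meta: pd.DataFrame
    gene_sets: GeneSets


@dataclass
class SimulatedStudy:
    species: dict[str, SpeciesData]
    orthologs: dict[tuple[str, str], OrthologTable]
    manifest: dict


def _species_stage(design: ExpressionDesign, sp: str, lineage: str, gp_stage: str) -> str:
    if sp == "gp" or not design.stage_pairs:
        mapped = _DEFAULT_STAGE_OF_LINEAGE.get(sp, {}).get(lineage)
        return gp_stage if sp == "gp" else (mapped or gp_stage)
    for pair in design.stage_pairs:
        if pair[0] == gp_stage:
            return pair[design.species.index(sp)]
    return gp_stage


def _build_means(design: ExpressionDesign, sp: str, gene_ids: list[str],
                 kinds: dict[str, str], groups: list[tuple[str, str]]):
    """Gene x group mean matrix for one species (groups are (lineage, stage))."""
    n_g, n_grp = len(gene_ids), len(groups)
    means = np.zeros((n_g, n_grp))
    conserved = dict((k, dict(v)) for k, v in design.conserved_map)
    stage_idx = dict(design.stage_markers)
    for gi, gid in enumerate(gene_ids):
        kind = kinds[gid]
        key = gid.split("_", 1)[1] if "_" in gid else gid
        for ci, (lineage, stage) in enumerate(groups):
            if kind == "regular":
                m = design.baseline_mean
                for pm in design.planted_markers:
                    if pm.gene == key and pm.lineage == lineage:
                        m *= pm.fold_change
            elif kind == "ortholog":
                if key in conserved:
                    target = conserved[key].get(sp)
                    if target is None:
                        m = 0.0
                    else:
                        m = design.conserved_baseline * (
                            design.conserved_fold if lineage == target else 1.0
                        )
                else:  # stage-programme gene
                    idx = stage_idx[key]
                    target = design.stage_pairs[idx][design.species.index(sp)]
                    m = design.baseline_mean * (
                        design.stage_fold if stage == target else 1.0
                    )
            else:
                m = 0.0  # mito/stress set afterwards from the base totals
            means[gi, ci] = m
    # size mito/stress means so expected count fractions hit their targets
    base_total = means.sum(axis=0).mean()
    fm, fs = design.mito_fraction_target, design.stress_fraction_target
    denom = 1.0 - fm - fs
    mito_ids = [i for i, g in enumerate(gene_ids) if kinds[g] == "mito"]
    stress_ids = [i for i, g in enumerate(gene_ids) if kinds[g] == "stress"]
    if mito_ids:
        means[mito_ids, :] = fm / denom * base_total / len(mito_ids)
    if stress_ids:
        means[stress_ids, :] = fs / denom * base_total / len(stress_ids)
    return means


_FAIL_MODES = ("low_genes", "mito", "stress")


def _enforce_qc_design(counts: np.ndarray, kinds_arr: np.ndarray,
                       statuses: list[str], th: QCThresholds) -> None:
    """Deterministically adjust counts so each cell's designated QC outcome
    holds with margin, each failing cell violating exactly one criterion."""
    regular = np.flatnonzero(kinds_arr == "regular")
    mito = np.flatnonzero(kinds_arr == "mito")
    stress = np.flatnonzero(kinds_arr == "stress")
    ballast = regular[0] if regular.size else 0
    for c, status in enumerate(statuses):
        col = counts[:, c]
        if status == "low_genes":
            budget = th.min_genes - 400
            nz = np.flatnonzero(col)
            keep = set(mito.tolist()) | set(stress.tolist())
            for g in nz:
                if len(keep) >= budget:
                    break
                keep.add(int(g))
            for g in nz:
                if int(g) not in keep:
                    col[g] = 0
        else:
            need = (th.min_genes + 50) - int((col > 0).sum())
            if need > 0:
                zeros = [g for g in regular if col[g] == 0]
                col[zeros[:need]] = 1
        # dilute off-target fractions below a safe margin via a ballast gene
        total = col.sum()
        m_sum, s_sum = col[mito].sum(), col[stress].sum()
        want_m = 0.8 * th.max_mito_frac if status != "mito" else 1.0
        want_s = 0.8 * th.max_stress_frac if status != "stress" else 1.0
        extra = max(
            0.0,
            m_sum / want_m - total if want_m < 1 else 0.0,
            s_sum / want_s - total if want_s < 1 else 0.0,
        )
        if extra > 0:
            col[ballast] += int(np.ceil(extra))
        if status == "mito":
            non_m = col.sum() - col[mito].sum()
            per = int(np.ceil(0.10 * non_m / (0.90 * max(1, mito.size))))
            col[mito] = per
        elif status == "stress":
            non_s = col.sum() - col[stress].sum()
            per = int(np.ceil(0.12 * non_s / (0.88 * max(1, stress.size))))
            col[stress] = per


def simulate_counts(design: ExpressionDesign) -> SimulatedStudy:
    """Simulate per-species count matrices with full ground-truth manifest."""
    rng = np.random.default_rng(design.seed)
    th = QCThresholds()

    conserved = dict((k, dict(v)) for k, v in design.conserved_map)
    ortho_keys = sorted(conserved) + sorted(k for k, _ in design.stage_markers)

    study_species: dict[str, SpeciesData] = {}
    manifest: dict = {
        "design": {"seed": design.seed, "noiseless": design.noiseless},
        "qc": {},
        "markers": {},
        "conservation": {},
        "stage_pairs": [list(p) for p in design.stage_pairs],
    }

    # planted marker truth (same for every species)
    marker_truth: dict[str, list[str]] = {}
    gene_ids_by_species: dict[str, list[str]] = {}

    for sp in design.species:
        prefix = _SPECIES_PREFIX.get(sp, sp.upper())
        gene_ids: list[str] = []
        kinds: dict[str, str] = {}
        for key in ortho_keys:
            gid = f"{prefix}_{key}"
            gene_ids.append(gid)
            kinds[gid] = "ortholog"
        for i in range(design.n_genes):
            gid = f"{prefix}_G{i:04d}"
            gene_ids.append(gid)
            kinds[gid] = "regular"
        for i in range(design.n_mito):
            gid = f"{prefix}_MT{i:02d}"
            gene_ids.append(gid)
            kinds[gid] = "mito"
        for i in range(design.n_stress):
            gid = f"{prefix}_SG{i:02d}"
            gene_ids.append(gid)
            kinds[gid] = "stress"
        gene_ids_by_species[sp] = gene_ids

        groups = [(lineage, _species_stage(design, sp, lineage, stage))
                  for lineage, stage, _ in design.cell_groups]
        means = _build_means(design, sp, gene_ids, kinds, groups)

        cell_ids: list[str] = []
        meta_rows = []
        cols = []
        statuses: list[str] = []
        cell_no = 0
        n_cells_total = sum(n for _, _, n in design.cell_groups)
        fail_of: dict[int, str] = {
            n_cells_total - design.n_fail_qc + i: _FAIL_MODES[i % len(_FAIL_MODES)]
            for i in range(design.n_fail_qc)
        } if sp == design.species[0] else {}

        for gi, (lineage, stage, n) in enumerate(design.cell_groups):
            mean_col = means[:, gi]
            for j in range(n):
                cid = f"{sp}_c{cell_no:04d}"
                cell_ids.append(cid)
                meta_rows.append(
                    {
                        "cell_id": cid,
                        "embryo_id": f"{sp}_e{gi:02d}_{j // 5}",
                        "stage": _species_stage(design, sp, lineage, stage)
                        if sp != "gp" else stage,
                        "lineage": lineage,
                        "species": sp,
                    }
                )
                if design.noiseless:
                    col = np.floor(mean_col + 0.5).astype(np.int64)
                else:
                    depth = float(np.exp(rng.normal(0.0, design.depth_sd)))
                    mu = np.clip(mean_col * depth, 0.0, None)
                    p = design.dispersion / (design.dispersion + mu)
                    col = rng.negative_binomial(design.dispersion, p)
                cols.append(col)
                statuses.append(fail_of.get(cell_no, "pass"))
                cell_no += 1

        counts = np.column_stack(cols).astype(np.int64)
        kinds_arr = np.array([kinds[g] for g in gene_ids])
        if design.n_fail_qc > 0 and sp == design.species[0]:
            _enforce_qc_design(counts, kinds_arr, statuses, th)

        cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=cell_ids))
        gs = GeneSets(
            mito_genes={g for g in gene_ids if kinds[g] == "mito"},
            stress_genes={g for g in gene_ids if kinds[g] == "stress"},
        )
        meta = pd.DataFrame(meta_rows).set_index("cell_id")
        study_species[sp] = SpeciesData(cm, meta, gs)

        if design.n_fail_qc > 0 and sp == design.species[0]:
            metrics = compute_qc_metrics(cm, gs)
            passes = (
                (metrics["n_genes"] > th.min_genes)
                & (metrics["mito_frac"] < th.max_mito_frac)
                & (metrics["stress_frac"] < th.max_stress_frac)
            )
            for cid, status in zip(cell_ids, statuses):
                expected = status == "pass"
                if bool(passes[cid]) != expected:  # pragma: no cover - guard
                    raise AssertionError(f"QC enforcement failed for {cid} ({status})")
        manifest["qc"][sp] = {
            cid: status for cid, status in zip(cell_ids, statuses)
        }

    for pm in design.planted_markers:
        marker_truth.setdefault(pm.lineage, []).append(pm.gene)
    manifest["markers"] = {k: sorted(v) for k, v in marker_truth.items()}

    if conserved:
        from .xspecies import conservation_category

        per_key = {}
        for key, lineage_of in conserved.items():
            lin = {
                sp: (lineage_of.get(sp) or "unexpressed")
                for sp in ("human", "mouse", "gp")
            }
            per_key[key] = {
                **lin,
                "category": conservation_category(lin["human"], lin["mouse"], lin["gp"]),
            }
        counts_by_cat: dict[str, int] = {}
        for v in per_key.values():
            counts_by_cat[v["category"]] = counts_by_cat.get(v["category"], 0) + 1
        manifest["conservation"] = {"per_key": per_key, "counts": counts_by_cat}

    orthologs: dict[tuple[str, str], OrthologTable] = {}
    shared_keys = ortho_keys + [f"G{i:04d}" for i in range(design.n_genes)]
    for i, a in enumerate(design.species):
        for b in design.species[i + 1 :]:
            pa, pb = _SPECIES_PREFIX.get(a, a.upper()), _SPECIES_PREFIX.get(b, b.upper())
            rows = [
                {"gene_a": f"{pa}_{k}", "gene_b": f"{pb}_{k}",
                 "homology_type": "ortholog_one2one"}
                for k in shared_keys
            ]
            # decoy one2many records must never enter alignments
            for k in shared_keys[:2]:
                rows.append(
                    {"gene_a": f"{pa}_{k}", "gene_b": f"{pb}_{k}_DUP",
                     "homology_type": "ortholog_one2many"}
                )
            orthologs[(a, b)] = OrthologTable(pd.DataFrame(rows))

    return SimulatedStudy(study_species, orthologs, manifest)


def write_annotation_fixture(spec: AnnotationFixtureSpec, outdir: str) -> None:
    """Write a toy annotation fixture as GTF + hit TSV + manifest JSON."""
    from .gtf import write_annotation
    from .intervals import AnnotationSet, Gene, TranscriptModel

    os.makedirs(outdir, exist_ok=True)
    refs, tfs, hits, manifest = make_annotation_fixture(spec)
    write_annotation(refs, os.path.join(outdir, "reference.gtf"))
    tf_genes = {
        t.transfrag_id: Gene(
            t.transfrag_id,
            t.transfrag_id,
            [TranscriptModel(t.transfrag_id, t.transfrag_id, t.exons)],
        )
        for t in tfs
        if t.strand != "."
    }
    write_annotation(AnnotationSet(tf_genes), os.path.join(outdir, "transfrags.gtf"))
    with open(os.path.join(outdir, "hits.tsv"), "w") as fh:
        for h in sorted(hits.values(), key=lambda h: h.query_id):
            fh.write(
                f"{h.query_id}\t{h.subject_transcript_id}\t{h.pct_identity}\t400\t5\t1"
                f"\t1\t400\t1\t400\t{h.evalue}\t{h.bitscore}\n"
            )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def write_study(study: SimulatedStudy, outdir: str) -> None:
    """Write a simulated study as plain-text TSV/JSON files."""
    os.makedirs(outdir, exist_ok=True)
    for sp, data in study.species.items():
        data.counts.data.to_csv(os.path.join(outdir, f"{sp}_counts.tsv"), sep="\t")
        data.meta.to_csv(os.path.join(outdir, f"{sp}_meta.tsv"), sep="\t")
        with open(os.path.join(outdir, f"{sp}_gene_sets.tsv"), "w") as fh:
            for g in sorted(data.gene_sets.mito_genes):
                fh.write(f"{g}\tmito\n")
            for g in sorted(data.gene_sets.stress_genes):
                fh.write(f"{g}\tstress\n")
    for (a, b), ot in study.orthologs.items():
        ot.data.to_csv(os.path.join(outdir, f"orthologs_{a}_{b}.tsv"),
                       sep="\t", index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(study.manifest, fh, indent=1, sort_keys=True)
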