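# Methods

## Annotation repair

### Coordinates and containers

GTF is 1-based inclusive on disk; everything in memory is 0-based half-open,
and the reader/writer pair in `emblineage.gtf` is the only place the shift
happens. Exon chains must be sorted, strictly disjoint and separated by
introns of positive length; unstranded (`.`) transfrags are permitted only as
single exons, following assembler convention for exons without splice
evidence. A gene's locus is the span of its transcripts and grows as
transcripts are merged in.

### Class-code dialect

The structural relation between a transfrag and a reference transcript is
summarised with the one-character codes familiar from assembly-comparison
tools. Because tool behaviour differs in corner cases, the dialect here is
fully specified (priority order `= c k m n j e o s x i y p u`, best first):

- `=` — multi-exon: identical intron chain. Single-exon against single-exon:
  same strand and reciprocal exonic overlap ≥ 80%.
- `c` / `k` — containment / reverse containment: the contained chain's
  introns form a contiguous sub-chain of the container's and both its ends
  lie inside container exons; a single-exon containee must sit inside one
  exon.
- `m` — every reference intron exactly matched or wholly retained inside a
  transfrag exon (with exonic overlap); `n` — at least one intron retained
  but not all matched-or-retained. Both require exonic overlap, so a
  transfrag exactly tiling an intron does not count as retention.
- `j` — at least one exactly shared intron, same strand, none of the above.
- `e` — single-exon transfrag overlapping an exon and intruding ≥ 10 bp into
  intronic sequence (pre-mRNA leakage).
- `o` — any other same-strand exonic overlap.
- `s` / `x` — an exactly matching intron / exonic overlap on the opposite
  strand. Suppressed for unstranded transfrags, which are compared in sense
  orientation against both strands.
- `i` / `y` — transfrag wholly inside one reference intron / reference
  transcript wholly inside one transfrag intron, same strand (the strand
  requirement on `y` is a choice of this dialect).
- `p` — no code against any transcript, but the transfrag lies entirely
  3′ of a same-strand gene locus with a gap ≤ 2,000 bp (polymerase run-on).
- `u` — intergenic otherwise.

The winning reference is the one yielding the highest-priority code, ties
broken by largest exonic overlap then lexicographic transcript id, making the
classification invariant to reference ordering. `n_overlapping_genes` counts
distinct genes with same-strand exonic overlap and drives the multi-gene
exclusion (opposite-strand overlap is already removed via `x`/`s`).

Every predicate is implemented twice: with interval arithmetic in
`classcodes.py`, and with literal per-base occupancy sets and junction sets
in `oracles.py`. The two implementations are held to 100% agreement on
randomized instances; this is the main guard against silent dialect drift.

### Dispositions

Kept transfrags with codes `= c k m n j o p y` become additional transcripts
of their reference gene. The containment code `c` is included although rule
lists for this procedure usually omit it — merge-stage assembler output
rarely contains fully redundant fragments, and when it does the reference
gene is unambiguous. Novel transfrags (`u`, `i`) follow their best
cross-species similarity hit (required E ≤ 1e-20; a weaker hit supplied
explicitly is an error): no hit → retained as an unnamed novel gene; hit to a
subject gene with no local entry → a new gene named after the subject; hit
resolving to an existing gene → merged if the transfrag falls within the
locus ± 3 kb, otherwise retained unnamed (the outside-window branch is a
documented choice; guessing a gene at a distance seemed worse than keeping
the transfrag discoverable). Transcript-id collisions are renamed with a
numeric suffix and logged. The report tallies every input transfrag exactly
once across the eight dispositions.

## Quality control and normalization

Cells must express more than 3,000 genes and keep mitochondrial and
stress-granule count fractions below 5% and 8.5%; all three comparisons are
strict, and fractions are computed on raw counts before any gene filtering.
An all-zero cell is given fraction 1 so it fails deterministically. Genes
must be detected in at least 3 cells. Normalization is
`log1p(count / cell_total × 10⁴)`; the scale factor follows the convention of
the standard single-cell toolchains. The gene-set inputs (mitochondrial,
stress-granule) are user-supplied identifiers — for genomes without a named
MT contig there is no robust way to derive them automatically.

Variable genes are ranked by variance-stabilised standardized variance: a
local-regression trend (span 0.3) of log₁₀ variance on log₁₀ mean of the raw
counts, counts standardized by the trend-expected s.d., clipped at √n_cells,
and the clipped variance reported. The trend is only identifiable when gene
means span a range; degenerate duplicate-mean fits fall back to the gene's
own variance (score ≈ 1, neutral). Scaling optionally regresses a per-cell
covariate (typically the number of expressed genes) out of each gene by OLS,
then centres to mean 0 / unit variance (population s.d.) and clips at ±10;
rows constant up to floating-point noise come out all-zero rather than as
amplified noise.

## Rank-sum testing and marker calling

`wilcoxon_test` is exact for pooled sample sizes ≤ 12: all C(N, n₁) rank
splits are enumerated and the two-sided p counts splits whose rank-sum
deviates from the null mean at least as much as observed (so identical
samples give p = 1). Beyond that, the asymptotic path uses a normal
approximation with continuity correction whose first four moments are the
*exact* finite-population moments of the midrank sum under permutation —
ties are therefore handled without ad-hoc corrections (the classical
tie-corrected variance is the second-moment special case) — plus Edgeworth
skew/kurtosis terms. The correction matters: the plain tie-corrected normal
approximation has an irreducible error of ≈ 0.017 against exact enumeration
at group sizes 5–6, while the moment-corrected form stays within 0.003 on
continuous data and is calibrated at the far tail (verified against the
exactly computed 30-vs-60 null: P(p ≤ α)/α = 1.00 at α = 10⁻⁴, where the
plain normal gives 0.57). With heavy ties (very few distinct values among
≤ 12 observations) the exact distribution is too lumpy for any smooth
approximation; the exact path covers those sizes anyway, so the approximation
is assessed on continuous data.

Markers: per group one-vs-rest (positive markers only) or a signed pairwise
contrast. Genes enter testing when detected in > 10% of cells of either group
and when the log₂ fold change of de-logged group means (pseudocount 1)
exceeds 0.25; p-values are Bonferroni-multiplied by the number of genes in
the matrix (the toolchain default, and the reading that keeps the adjustment
monotone in the gene universe). Records are kept at p_adj < 0.05 and sorted
by (p, gene id). Because the test is calibrated, scattered single false
positives at the nominal Bonferroni rate (~0.05 per contrast) are expected
and observed in large simulation batches; this is a property of the
thresholds, not of the implementation.

Pseudo-bulk expression is the per-group mean of `expm1(normalized value)`,
with deterministically ordered group columns.

## Cross-species comparison

Gene axes are matched through `ortholog_one2one` records only; any gene still
appearing twice after filtering is removed entirely so the mapping is a
bijection. A gene's lineage is the argmax of its pseudo-bulk means over
lineages, provided it is detected in more than 10% of that lineage's cells;
exact ties are flagged and resolved by the fixed order prelineage < ICM <
EPI < PE < TE; all-zero genes are "unexpressed". Conservation categories:
`all_three` iff all three species agree on a non-unexpressed lineage;
a pairwise category iff that pair agrees (non-unexpressed) and the third
species differs or is unexpressed; `none` otherwise. The categories
partition the ortholog universe.

MNN pairs are mutual k-nearest neighbours (Euclidean, default k = 20, capped
at the dataset size with a warning) between the cells of two scaled matrices
on shared ortholog features, with distance ties broken by cell order so the
output is deterministic and invariant to column permutation. The Pearson
correlation attached to each pair is computed on the scaled shared-feature
vectors — a stated substitute for correlations on a jointly integrated
embedding, which is out of scope here. Stage (or lineage) correspondence is
the contingency table of metadata labels over the pairs.

## Synthetic data

The annotation generator lays isolated multi-exon genes (exon length 200 bp,
intron lengths drawn from the requested range, 10 kb spacing) and builds one
transfrag per requested class code by construction, so realised codes match
requested codes with probability 1. Similarity hits can be planted on
designated `u` transfrags. A separate randomized generator perturbs reference
transcripts (exon drops, boundary shifts, intron removal, offsets, strand
flips, intronic/intergenic slices) to exercise the classifier against the
per-base oracle across all fourteen codes.

Counts are negative binomial, parameterised by (mean, size θ) with per-cell
depth multipliers log-normal(0, 0.3) — enough structure to exercise the
depth-invariance of normalization. Defaults: θ = 2 (typical full-length
scRNA-seq overdispersion); QC design 4,000 background genes at mean 3 so
passing cells clear the 3,000-gene threshold, with 10 mitochondrial and 20
stress-granule genes sized to expected fractions 0.02 and 0.04. Designated
QC-fail cells are adjusted deterministically after sampling so each violates
exactly one criterion with margin (low-gene cells are thinned to ~2,600
detected genes; mito/stress failures are set to fractions 0.10/0.12; a
ballast gene dilutes off-target fractions), which is why the planted
pass-count is recovered exactly for every seed. Marker-recovery design: 3
lineages × 30 cells, 1,000 genes at baseline mean 1, 50 planted markers at
fold 8. Conservation design: three species × five lineages × 20 cells, 300
ortholog genes with planted per-species lineage programmes (fold 6 over
baseline 0.3; "unexpressed" means mean 0), category counts 60/50/40/45/105;
a noiseless mode writes rounded expected counts for exact manifest recovery.
Stage-alignment design: two species with five matched stages × 20 cells;
stage programmes cover 200 of 300 ortholog genes at fold 8 over a 100-gene
flat background — deliberately broad, since real preimplantation stage
transitions shift much of the transcriptome, and a thin programme would not
reproduce the stage-distinct geometry the design is meant to emulate.

What the generator does **not** emulate: batch/embryo effects, ambient RNA,
doublets, gene-length and GC biases, dropout beyond NB zeros, or annotation
errors in the count matrices themselves. Passing the planted-truth suites
therefore demonstrates correctness of the rules and statistics under the
stated model, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The validation suites run at deliberately modest sizes — 1,000 random
classifier instances, 20-seed batches for QC/marker/conservation checks,
50 × 50 matrices against the O(n²) neighbour oracle — chosen so the whole
suite completes in seconds while every oracle comparison remains exhaustive.
Floating-point policy: exact-tie detection in lineage assignment uses strict
equality (the noiseless generator produces exact ties by construction);
constant-row detection in scaling uses a relative 1e-10 tolerance; the
enumeration path compares rank-sum deviations with a 1e-9 slack to absorb
midrank rounding.

## Known limitations

- The class-code dialect approximates published tool semantics; exact
  coordinate matching is assumed for junctions (no fuzz window), and fusion /
  chimeric transfrags are out of scope.
- Bulk headline numbers from the motivating study (cell counts, DEG counts,
  conservation counts) derive from deposited datasets and a custom genome
  annotation; they are not recomputable at desk scale and are not targets of
  the validation suite.
- The pairwise-DEG detection filter is applied to either group (one-group
  interpretation); requiring it of both groups would be stricter.
- Ortholog matching is by table only; gene-symbol fallback is deliberately
  not used to avoid annotation-drift irreproducibility.
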