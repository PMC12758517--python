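# Methods

`gonadnet` re-implements, as a tested pipeline, a computational workflow for
inferring sex-specific transcriptional regulatory networks from joint
single-nucleus RNA + ATAC (multiome) data of differentiating gonads: per-cell
QC and chromosomal sex verification, differential expression and
accessibility between Sertoli (XY) and pregranulosa (XX) supporting cells
across developmental stages, peak–gene linkage, categorization of
differential genes by their linked chromatin, histone-mark profiling of
differential peaks, and motif-based TF→target network assembly.  Because real
multiome data is not bundled, every stage is exercised end-to-end on a
synthetic multiome generator with complete ground truth, and the test suite
is organized around exact oracles, null calibration and planted-structure
recovery.

## Quality control and sex verification

Cells must satisfy, with strict inequalities, `1000 < nCount_RNA < 25,000`
and `percent.mt < 25` (RNA side) and `1000 < nCount_ATAC < 100,000`,
`nucleosome_signal < 2`, `TSS.enrichment > 1` (ATAC side).
`nucleosome_signal` and `TSS.enrichment` are consumed as precomputed per-cell
metrics; computing them from raw fragments is out of scope.  Peaks are
union-reduced, then gated to widths strictly between 20 bp and 10,000 bp,
with blacklist overlap (≥1 bp) and non-standard chromosomes removed.

The sex filter scores each cell for a Y-linked signature (*Kdm5d*, *Eif2s3y*,
*Uty*, *Ddx3y*) with a rank-based module score: genes are ranked per cell by
descending expression (average ranks on ties), ranks capped at `r_max`
(default 1500), and

    U' = Σ_{g∈S} min(rank_g, r_max) − |S|(|S|+1)/2
    score = 1 − U' / (|S|·r_max)

which is bounded in [0, 1] and invariant under any monotone transform of a
cell's expression vector, hence under the choice of normalization.  Cutoffs
come from the reference stage (E13.5, where lineage identity is clearest):
`cutoff_XY = mean − k·SD` of XY reference scores and `cutoff_XX = mean + k·SD`
of XX reference scores, `k = 1` by default.  Earlier-stage cells are removed
from XY datasets when chrY peak-region fragments are exactly 0 AND the score
is strictly below `cutoff_XY`, and from XX datasets when chrY fragments are
> 0 OR the score is strictly above `cutoff_XX`.  Ties at a cutoff keep the
cell (removal rules are strict).  Reference-stage cells define the cutoffs
and are kept unfiltered; this is one possible reading of the procedure and is
flagged as such rather than established fact.

## Normalization

Counts are depth-scaled to the median library size (linear scale); a
`log2(x+1)` transform of the scaled counts is applied where a variance-
stabilized scale is wanted (linkage correlations, LR regression input).
Fold changes and detection fractions are always computed on the linear scale
with a pseudocount of 1: `log2FC = log2((mean₁+1)/(mean₂+1))`.  A regularized
variance-stabilizing normalization of the SCTransform kind is deliberately
not re-implemented: the module score is rank-based and the differential tests
below are either rank-based or invariant to affine covariate transforms, so a
deterministic, dependency-free scaling suffices.

## Differential testing

**DEGs** use the two-sided Wilcoxon rank-sum test with `min.pct = 0.25` and
`logfc.threshold = 0.25`.  Features are pre-filtered on
`max(pct₁, pct₂) ≥ min.pct` and `|log2FC| ≥ threshold`; the Bonferroni
denominator is the *total* feature count of the matrix, not the post-filter
count.  P-values are exact — tie-aware enumeration over all C(n₁+n₂, n₁)
group assignments of the pooled mid-ranks — whenever that count is ≤ 2×10⁵
(which covers every group size where exactness is practically
distinguishable), and otherwise use the tie-corrected normal approximation
with continuity correction.

**DAPs** use a likelihood-ratio test: per peak, logistic regression of group
membership on normalized accessibility (full: intercept + accessibility;
null: intercept only), fitted by Newton–Raphson on the standardized
covariate; the statistic `2(ℓ_full − ℓ_null)` is referred to χ²₁.  Complete
separation is detected (diverging slope or likelihood at its supremum), the
full log-likelihood capped at 0 — bounding the statistic by the null
deviance — and flagged.  Between-sex DAP calls use `min.pct = 0.01`,
`logfc.threshold = 0.1`; within-cluster calls use `0.05 / 0.25`.  Bonferroni
is used for both differential tests (the upstream tooling's default); BH is
reserved for motif enrichment.  The multiple-testing method for DEG/DAP calls
is a documented package decision, not sourced fact.

## Peak–gene linkage

Candidate pairs are (gene, peak) with peak midpoint within ±500 kb of the
gene's TSS (window-edge ties included).  Across the *entire* cell set (all
types pooled — linkage is sensitive to dataset composition and the pooled
analysis recovers the most links), the Pearson correlation r between
depth-scaled peak counts and log-normalized expression is compared with the
correlations of `n_background = 200` peaks matched to the focal peak by
nearest neighbors in standardized (GC fraction, mean accessibility, width)
space, excluding peaks inside the gene's window; `z = (r − mean)/SD` of the
background correlations gives a two-sided normal p.  Links with `p < 0.05`
(uncorrected, by design) are retained with their sign.  Zero-variance peaks
or genes are skipped with a reason; an undersized background pool is used in
full with a warning.

**Categorization.**  Each DEG is exactly one of: `linked_DAP` (≥1
significantly linked peak is a DAP for the same contrast), `linked_nonDAP`
(links exist, none differential), `no_linked_peak`.  DAPs get the mirror
classification by linked DEGs.  Stage-to-stage transition records cover the
union of DEGs (with `absent` for genes not called at a stage); flow counts
conserve per-category totals.  The "newly formed linked-DAP" peak set at the
later stage is the deduplicated union of DAPs linked to genes whose later
category is `linked_DAP` and whose earlier category is anything else —
including genes with no links or absent earlier, a reading that keeps the
stricter "conversion only" subset recoverable from the transition table.

## Chromatin profiles

Peaks are annotated on their midpoint with precedence promoter (TSS ± 3 kb,
the conventional annotation default — unstated upstream) > exon > first
intron > other intron > downstream (≤3 kb past the 3′ end) > distal
intergenic.  Region accessibility is the per-cell sum of counts over matrix
peaks overlapping the region set (≥1 bp), compared between groups with the
same Wilcoxon core as the DEG test.  Histone-mark positivity of a DAP is ≥1 bp
overlap with a ChIP track (the overlap predicate is parameterized; fractional
coverage criteria are not used), and bivalent peaks overlap both H3K4me3 and
H3K27me3 tracks.

## Motifs, deviations and the network

PFMs (JASPAR 2022 text format) become log2-odds PWMs with
`p_b = (count_b + 4·pc·bg_b)/(colsum + 4·pc)`, pseudocount `pc = 0.8` split
by background frequency, uniform background by default.  The scan threshold
at hit-level `p = 10⁻⁴` is the smallest grid score whose exact null tail mass
(0-order background, dynamic programming over per-column scores floored to a
10⁻³ grid) is ≤ p; scanning scores windows on the same grid on both strands,
and windows containing N are excluded.  A degenerate all-uniform PWM scores
every k-mer 0, so its tail mass is 1 everywhere and nothing passes until
p = 1 — the threshold definition, not a special case.

Enrichment compares motif-bearing peaks (counted once per motif) between the
target set — DAPs supporting the focal `linked_DAP` genes, per the workflow's
"DAPs derived from DEG with linked DAP"; a flag allows all focal DAPs — and a
GC/accessibility-matched background drawn from the remaining peaks, via the
hypergeometric upper tail, BH-adjusted; a motif passes iff adjusted p < 0.05
AND fold enrichment > 1.25.

Per-cell motif activity follows the chromVAR recipe: for motif peak set M and
cell i with depth dᵢ, `Eᵢ = total_M · dᵢ / total_all`,
`rawᵢ = (Xᵢ − Eᵢ)/Eᵢ`, z-scored against 50 background sets in which each
member peak is replaced by one of its 50 nearest neighbors in
(GC, accessibility) space.  Cells with Eᵢ = 0 are masked.

Network edges run from each passing motif whose TF gene is itself a focal DEG
to every gene significantly linked to a focal DAP carrying a hit of that
motif; the edge sign is the link sign.  Rows are one per (TF, target, sign) —
a TF can reach the same gene through peaks of opposite link sign, and
positively/negatively linked target sets are reported separately — with
mediating peaks listed in descending link strength.  The co-occurrence matrix
counts, for each TF pair, distinct target genes reached by both (gene-level
scope by default; same-peak scope available via a flag, since "incidence"
admits both readings).

## The synthetic multiome generator

The generator emulates the study design: populations over
(sex ∈ {XX, XY}) × (stage ∈ {E11.5, E12.5, E13.5}) × cell type
{epithelial, presupporting, Sertoli, pregranulosa}, with Sertoli restricted
to XY and pregranulosa to XX, 110 cells per group (~2,000 cells), 500 genes
and 2,000 peaks on three 20 Mb chromosomes (the last is chrY).  The 20 Mb
scale gives a peak density, and hence ~50 linkage candidates per gene, of the
order seen in real mouse snATAC peak sets; smaller toy genomes make every
gene spuriously linked to some DAP at p < 0.05.

RNA counts are negative binomial (dispersion 0.1, the typical magnitude
estimated for expressed genes in UMI data) with lognormal per-cell size
factors (σ = 0.3) and per-group expected library 5,000.  ATAC counts are
Poisson with rate = size factor × peak propensity × group multiplier ×
exp(loading × latent factor), expected library 10,000.  Planted structure:

* **DEGs** — 10% of genes differ between Sertoli and pregranulosa by
  log2FC = 1 (split up/down).  Differential programs are placed on expressed
  genes: planted DEG/TF genes have their baseline floored at the 60th
  percentile of the lognormal draw, so that detection-fraction gates measure
  signal rather than dropout.  TF driver genes carry an extra 2× lineage
  restriction, mirroring the strongly lineage-specific expression of
  Sox9/Dmrt1/Lef1-class factors.  Marker genes (×8 in their own type) support
  cell-type annotation.
* **DAPs** — 10% of peaks, accessibility up in one lineage and down in the
  other (multiplier 2^±1), mixing gained and lost accessibility.
* **Links** — half of the DAPs are placed within ±500 kb of a planted DEG's
  TSS and share a per-cell N(0,1) latent factor with it; the peak loading is
  ±0.35 (20% negative), the gene loading +0.35.  This yields peak–gene
  correlations of roughly 0.3–0.45, the magnitude typical of reported
  single-cell peak–gene links, and keeps coupling noise subdominant to the
  planted expression effect.
* **Stage dynamics** — 30% of linked target genes are "late": all their
  linked DAPs only become differential from E12.5 on, so those genes convert
  from `linked_nonDAP` to `linked_DAP` between stages, which is exactly the
  transition structure the Sankey/newly-formed analyses consume.
* **Motifs** — three sharp synthetic 8-bp motifs (SOX9-, DMRT1- and
  LEF1-like, each named for its TF gene) are substituted as consensus
  sequences into 80% of their host linked-DAP sets at a uniform offset and
  strand; truth tables record every site and implied TF→target edge.
* **Y signal** — *Kdm5d*, *Eif2s3y*, *Uty*, *Ddx3y* live on chrY and are
  expressed only in XY cells; five chrY peaks have nonzero rates only in XY
  cells, so XX cells have exactly zero chrY fragments.
* **Histone tracks** — per mark (H3K4me3, H3K27me3, H3K27ac) and cell state,
  a BED track covering a configured fraction (default 0.40) of each DAP set,
  plus unrelated background intervals.

All randomness flows from one seed through named substreams (CRC32 of the
stream name as spawn key), so identical configs are byte-identical and
components can be regenerated in isolation.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: doublets and ambient RNA (assumed removed upstream),
batch effects, trajectory/pseudotime structure, fragment-level ATAC,
realistic motif information content and co-occurring motif grammar, mappability
and GC biases of a real genome, and the scale of a real experiment (tens of
thousands of nuclei, >100k peaks).  Recovery rates on synthetic data are
statements about the implementation's correctness under the stated model, not
about biological sensitivity.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; widths are `end − start`;
  overlap is ≥1 bp on half-open intervals; a − strand gene's TSS is the larger
  coordinate of its span unless given explicitly.
* Wilcoxon exactness switches to the normal approximation when the assignment
  count exceeds 2×10⁵; the boundary is a tractability choice and both regimes
  are tie-aware.
* The LR fit standardizes the covariate (the statistic is invariant);
  non-convergence and separation are flagged in the output rather than erased.
* Background matching uses seeded tie-breaking jitter; linkage backgrounds
  subsample the 1.5×n nearest eligible neighbors without replacement with a
  fixed seed.
* Degenerate inputs: empty gene sets, empty DAP sets and undefined SDs raise;
  zero-variance features are skipped or reported with p = 1 as documented per
  operation; empty annotation falls back to `distal_intergenic` with a
  warning.
* Problem sizes in the test suite and acceptance script (~2,000 cells for
  recovery, 200 × 400 for null calibration, ~200 peaks for determinism
  replays) were chosen as the smallest sizes at which the measured properties
  are statistically meaningful.

## Known limitations

The LR test uses accessibility as the sole covariate (no latent-count or
batch covariates).  Linkage significance is per-pair and uncorrected by
design, so the links table has a controlled 5% false-positive floor that
propagates visible (and realistic) noise into DEG categories and network
targets.  The sex filter's treatment of reference-stage cells is a documented
reading of an underdetermined procedure.  Peak calling, doublet removal,
ambient correction, embedding/clustering and genome liftover are out of
scope; cluster labels and peak sets are inputs.
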