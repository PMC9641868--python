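# Methods

This note documents the models and procedures `pseudopipe` implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinate model

All internal coordinates are 0-based half-open intervals on named
chromosomes, the BED convention; GFF3 (1-based closed) is converted at the
I/O boundary. Exons are stored merged, so "gene length" always means the
non-redundant exonic length (union of exons). Gene bodies — used when
excluding intergenic shuffle windows — are full exon-to-exon spans,
introns included, which is the natural reading of "known gene regions".

The TSS is strand-aware by default: the smallest exon start on the + strand,
the largest exon end on the − strand. Because "the starting coordinate of
the first exon" is ambiguous on the − strand, the naive strand-blind reading
is also available (`tss_mode="naive_start"`), and neither is asserted to be
the historically used one. Promoters run from 2 kb upstream to 1 kb
downstream of the TSS, oriented by strand and clipped at chromosome ends;
a promoter always contains its TSS.

Overlap calls default to ≥ 1 shared base. The one exception is chromHMM
state annotation, where the rule "more than 1 base pair" is honoured
literally as ≥ 2 bp; both thresholds are explicit parameters.

## Origin dating

A pseudogene is dated from where its exons still align in a ladder of
successively older outgroups of the focal species. Evidence is
reciprocal-best whole-genome-alignment blocks (8-column TSV, one file per
species); non-reciprocal blocks are never evidence. An exon is *present* in
a species when reciprocal-best blocks cover at least `min_cov` of its
length. `min_cov` defaults to 0.5 — tolerant of partial alignment while
excluding spurious micro-hits — and is exposed because no canonical value
exists for this threshold.

Presence/absence across species is resolved under Dollo parsimony: a locus
arises once and may be lost many times, so the origin branch is the
internode immediately older than the most distant species with presence,
and absences in younger species are losses or alignment failures. An exon
with no presence anywhere dates to the youngest, focal-lineage-specific
branch. A gene takes the branch of its most ancient exon. The age reported
is the branch midpoint in myr; the open-ended oldest branch is capped at
1.5× the oldest divergence time (configurable) so that a midpoint exists.
Only ladder trees are representable — the branch table rejects duplicate
divergence depths — because the per-species presence vector cannot encode a
non-ladder topology.

Before dating, pseudogenes on the Y chromosome are excluded (the Y is
saturated with transposable elements and its alignments are unreliable), as
are pseudogenes with strictly more than 70% of their merged exonic bases
covered by repeats. Genes with zero aligned bases in every species are
dated to the youngest branch by default — under Dollo parsimony universal
absence is a legitimate lineage-specific call — but can instead be excluded
(`exclude_unmappable=True`) when universal absence is suspected to reflect
assembly gaps.

## Expression and specificity

Counts are taken as uniquely mapped, assigned reads per gene; the library
size used for normalization is the per-sample counted-read total carried in
the sample metadata, not a column sum recomputed from whatever gene subset
happens to be in the matrix. FPKM divides by merged exonic length in kb and
library size in millions; CPM by library size only.

Specificity uses the tau index over n conditions,
`tau = Σ(1 − x_i/max x) / (n − 1)`, 0 for uniform and 1 for
single-condition expression. Tissue tau is computed over per-tissue
aggregates with stages, sexes and replicates pooled; stage tau over
per-stage aggregates within one tissue. The aggregate is the mean by
default with the median available, since the pooling statistic is not
canonically fixed. "Expressed" defaults to FPKM ≥ 1 in at least one sample;
every report states its cutoff, and the expressed-proportion sweep makes
the cutoff dependence explicit. Ties for the maximum-expression tissue
break lexicographically and are flagged.

## Developmentally dynamic pseudogenes

Per tissue, each gene's expression is regressed by ordinary least squares
on {1, ln t, (ln t)², (ln t)³} where t is time after conception in days;
replicates enter as separate observations at their shared time, preserving
error degrees of freedom. A gene is dynamic in a tissue when R² strictly
exceeds 0.3, and a DDP when dynamic in at least one tissue. A constant
response defines R² = 0. The response is log1p(CPM) by default — log
transformation stabilizes the variance of negative-binomial counts — with
raw CPM available; for the raw response R² is exactly invariant to common
rescaling of the matrix. This is deliberately the stated computation only
(polynomial-in-log-time OLS plus an R² threshold), not a reimplementation
of the stepwise-significance machinery of time-course packages such as
maSigPro.

Under a pure-noise response, R² for k predictors on n samples follows
Beta(k/2, (n−k−1)/2) with mean k/(n−1); `null_r2_reference` draws from this
null empirically and is the calibration reference for the 0.3 threshold.

DDPs whose expression correlates with their parent coding gene at signed
Pearson R ≥ 0.6 are flagged for exclusion as potential mis-mapping;
anti-correlated profiles are retained, and a missing parent leaves the gene
retained with R reported missing.

The co-expression network scores every pseudogene × coding-gene pair by
Pearson R across samples, with testis samples excluded first (testis
transcription is globally permissive and would dominate the correlation
structure). P-values use the exact t-transform with df = n − 2; an edge
needs |R| > 0.90 and two-sided p < 0.01, with no multiple-testing
correction, matching the raw thresholds the analysis is defined by.
Zero-variance genes are skipped with an explicit reason.

## Traffic, cancer specificity, translation

Traffic analysis compares observed pseudogene generation (parent location)
and insertion (pseudogene location) per chromosome with proportional nulls:
generation proportional to protein-coding gene counts, insertion to
chromosome length. X-versus-autosome departures are tested with the
two-sided Fisher exact test, computed by hypergeometric tail summation
(probabilities of all tables with the observed margins that are no more
probable than the observed table); the reported odds ratio is the
conditional MLE, with the sample ad/bc alongside. A zero margin yields
p = 1 and an undefined odds ratio. Type-I calibration simulates the
proportional null as two independent binomials with a common X probability.

Cancer-type specificity works on per-type expression shares, each type's
mean tumor expression divided by the sum over all types. Type-specific:
focal share > 15% and every other share < 5%. Ubiquitous: maximum share
< 30% and each of the top-5 shares > 5%. All inequalities strict; anything
else is "other", and all-zero genes are "other" with a flag. The
"ubiquitous" maximum-share wording in the source description is garbled
("more than less than 30%"); it is resolved here as *less than* 30%, the
only reading consistent with ubiquity, and the threshold is a parameter.
Per-type summary is the mean over tumor samples (the statistic is not
canonically fixed; configurable). Types enter differential analyses only
with strictly more than 5 normal and more than 5 tumor samples.
Tumor/normal differential expression itself is out of scope (DESeq2
territory); DE tables are consumed, not produced.

A pseudogene is a translated candidate when two independent sequence-based
coding predictors both flag it, its maximum ribosome-profiling FPKM over
samples is ≥ 1 (inclusive), and it harbors at least one actively translated
ORF. Predictor flags and ORF counts are inputs; the predictors themselves
are not reimplemented.

## Regulatory metrics

TF diversity is the number of distinct TF names with qualifying overlap of
a region; chromHMM state counts use the ≥ 2 bp rule; SNPs are single-base
features and densities are counts per kb of merged region length; distances
from TSS anchors to m6A sites are measured to interval edges (0 inside a
site), with anchors on site-free chromosomes reported missing. Class
comparisons (DDP vs non-dynamic vs shuffled-intergenic controls) report
per-class medians and two-sided Wilcoxon rank-sum p-values — exact
enumeration when both groups have ≤ 20 untied observations, the
tie-corrected normal approximation otherwise. Intergenic control windows
are drawn uniformly from gaps between gene spans, with exact requested
length, pairwise disjointness, a capacity check that fails loudly, and full
reproducibility under a seed.

## Synthetic scenario generator

The generator produces every input the pipeline consumes plus ground-truth
tables, from a single seeded `numpy` generator, so all stages are testable
without downloads and byte-identically reproducible. Defaults define the
study conditions and are deliberately small so the whole pipeline runs in
minutes on one CPU: 500 pseudogenes and 200 coding genes on 4 autosomes
plus X and Y; an 8-outgroup ladder spanning 6.7–435 myr; 5 tissues × 8
stages (10.5–90 days post conception) × 2 sexes × 2 replicates; a 33-type
cancer matrix over 200 genes.

* **Orthology**: a pseudogene planted on branch b gets reciprocal-best
  blocks, covering a uniform 0.8–1.0 fraction of each exon, in exactly the
  species that diverged after b's older bound. Dropout (default 0) removes
  each (exon, species) block independently and never adds presence;
  species older than the origin may receive non-reciprocal decoy blocks
  that must not influence dating. Because a gene takes its most ancient
  exon, multi-exon genes tolerate single-block dropout, which is why branch
  recovery stays well above 90% at dropout 0.1.
* **Expression**: negative-binomial counts with variance μ + αμ², α = 0.1;
  baseline means log-normal (median 30 counts, log-sd 1). A 20% dynamic
  subset gets a random centered cubic-in-ln-t log-mean profile with SD 1.0
  log-unit across stages — roughly an e²-fold swing, comfortably more than
  twice the NB log-noise SD at these means — planted in one random tissue;
  dynamic genes have their baseline floored at 20 counts, since a trend
  planted on a never-expressed gene is biologically meaningless and
  undetectable by construction. A disjoint 20% subset is strictly
  tissue-specific (zero mean elsewhere); a random quarter of the remaining
  pseudogenes gets a 5× testis boost, mimicking testis-dominant expression
  qualitatively. Library sizes are the column totals plus a fixed 300,000
  background reads representing the bulk transcriptome outside the
  simulated gene set — without this, the toy library would be so small
  that planted trends in a few genes would push a compositional trend into
  every flat gene's CPM, which real libraries (tens of millions of reads
  dominated by coding genes) do not do.
* **Tracks**: uniform background TF sites (20 subtypes), single-base SNPs
  and m6A peaks, plus planted enrichments — 2× TF-site density at
  dynamic-pseudogene promoters, 2.5× SNP density at all promoters, and one
  m6A peak within 200 bp of each dynamic TSS — and a full random chromHMM
  tiling.
* **Cancer**: planted type-specific genes (one dominant type, flat low
  background) and ubiquitous genes (six co-dominant types, each share
  ~12%, satisfying the <30%/top-5>5% definition). The matrix is
  deterministic rounded means by default (`cancer_noise_sd=0`), so planted
  labels are recoverable exactly; log-normal noise can be switched on.

What the generator does **not** emulate: mapping ambiguity between
pseudogenes and parents (counts are uniquely assigned by construction),
alignment-block fragmentation and synteny breaks, GC/length biases,
batch effects, sex-specific expression, or correlated noise across genes.
Passing tests therefore demonstrate the correctness and calibration of the
computations under the stated generative model — not robustness to the
mapping and alignment artefacts of real data.

## Numerical choices

* Trend fits share one QR factorization per tissue across all genes;
  agreement with per-gene statsmodels OLS is verified in tests. R² is
  clipped to [0, 1] against floating-point excursions.
* Fisher tail summation compares probabilities with a 1e-7 relative slack
  so exact ties (symmetric tables) are counted despite float rounding.
* Pearson edge p-values use the t-transform; |R| = 1 maps to p = 0.
* All-tied rank-sum data returns p = 1 with a warning path rather than an
  error.
* Degenerate trend designs (fewer distinct times than degree+1) raise an
  error naming the gene and tissue; all-zero tau vectors return NaN with a
  warning.

## Limitations

Branch dating inherits the ladder restriction and reports midpoint ages,
which compress all within-branch information to one number; the oldest
branch's age depends on the root cap. The DDP rule is a pure
goodness-of-fit threshold and will flag any smooth time profile, including
monotone drift; it makes no claim of statistical significance. Cancer
labels depend on the share thresholds, which are sharp cliffs: genes near
a boundary flip labels under small perturbations. The co-expression
network is correlation, not interaction.
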