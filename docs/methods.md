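# Methods

This note documents the models, rules and numerical choices behind
`scexhaust`, and what the synthetic cohorts do and do not establish about
real data.

## The analysis pipeline

**QC.** A cell is retained iff it has *more than* 200 detected genes and
*less than* 30% mitochondrial counts — both strict inequalities, so
boundary cells fail. Mitochondrial genes are identified by the "MT-"/"mt-"
symbol prefix (the mito gene set is never hard-coded). Zero-count cells
fail the gene rule before any mito division is taken. `qc_filter` is
idempotent.

**Normalization.** Library-size log-normalization,
`x = ln(1 + 10^4 · k/K)`. The scale factor 10,000 is the field's
conventional default and is configurable. Zeros map to zeros, and the
transform is invariant to rescaling a cell's counts, so downstream scores
never depend on sequencing depth through the normalized route except via
sampling noise. Z-scaling is deliberately *not* used for scoring: a summed
z-score can be negative and sign-ambiguous; scaling is applied only inside
the clustering delegate.

**Exhaustion scores.** Two per-cell statistics over the 14-gene signature:
the sum of log-normalized expression (`score_norm ≥ 0`) and the signature
transcript fraction (`score_frac ∈ [0,1]`). Signature genes absent from a
matrix contribute zero and are logged, not fatal — gene annotations vary
across references. Both scores are invariant to gene-column order and to
adding non-signature genes.

**Highly exhausted calling.** "Upper outlier" is formalized as the Tukey
boxplot fence: score > Q3 + k·IQR with k = 1.5 and linear-interpolation
quantiles (both configurable). Fences are computed over the non-malignant
compartment pooled across patients — the compartment the association is
about; per-patient fencing is available (`fence_scope="per_patient"`).

*Combination rule.* The source description of the procedure — outlier
status "in the two distributions" — does not fix whether a cell must be an
outlier in **both** scores or in **either**. Both readings are
implemented. The default is **union** (either score): the two scores are
two operationalizations of one biological quantity, and requiring
consensus (intersection) turns out to gate the call on the
normalized-sum score alone, whose upper tail is structurally thin — the
log transform compresses large counts and the score saturates in the
number of co-expressed signature genes — so the intersection flags so few
cells (~0.2–1%) that the downstream chi-squared test operates on expected
counts of 2–6 and becomes so discrete/conservative that its null
rejection rate collapses well below nominal. Under the union rule the
flagged fraction sits at 3–4%, the test operates in its calibrated
regime (measured null rejection 0.033 over 150 null cohorts), and
detection power for the default spiked effect is 0.99. Intersection
remains one config switch away (`combine_mode="intersection"`) for users
who prefer the conservative reading.

**Association test.** Pearson's chi-squared with Yates' continuity
correction on the 2×2 flag × MRD-group table over non-malignant,
non-omitted cells, in the closed 2×2 form with the correction clamped at
zero; p from the upper tail of χ²(1). The test refuses degenerate tables
(a zero margin implies a zero expected count). Cells are the test's units,
as in the original pooled analysis; with a handful of patients this
pseudoreplicates patient-level effects, so a patient-label permutation
test on the flagged fraction (`permutation_p_per_patient`) is exposed as a
sensitivity check, but is not the default.

**Clustering and malignancy reconciliation.** Clustering is a pluggable
delegate behind `cluster_cells`: the default mirrors the standard
single-cell stack (per-gene scaling → PCA with 35 components →
shared-nearest-neighbor graph → Leiden), with a PCA+KMeans delegate for
small, well-separated problems; both are seed-deterministic. The original
reconciliation of flow-sort labels with clusters was done visually on a
UMAP; the reproducible equivalent used here is a purity rule: clusters
whose leukemic-sorted fraction is ≥ τ = 0.90 are leukemia clusters;
nonleukemic-sorted cells inside them are relabeled leukemic, and
leukemic-sorted cells stranded in immune clusters are omitted from every
downstream statistic. Clusters below 10 cells are left untouched (logged).
A leukemic-sorted cell is never relabeled to non-leukemic.

**Cell typing and composition.** Each cluster is assigned the cell type
whose marker list has the highest mean normalized expression over the
cluster (deterministic tie-break by type name; missing markers dropped
with a warning). The marker map is user configuration — the original
subset markers are not published — and the synthetic cohort ships its own
truth marker map so the operation is testable. Composition is reported
as percentages of non-malignant cells per MRD group *and* per patient;
patients are the exchangeable units, so any between-group composition
test should run on the per-patient table (the choice of test is left to
the caller).

## Panel statistics

- **Welch's t-test** is the reading of "t test" used throughout
  (unpooled variances; robust default when group variances differ); the
  degenerate all-constant case returns t = 0, p = 1. Cytokine
  concentrations are tested on the log scale by default (lognormal assay
  convention), with a flag for raw.
- **Mann–Whitney U** uses midranks for ties; the two-sided p is exact (full
  permutation null) when both groups have n ≤ 8 and the pooled sample is
  tie-free, else the tie-corrected normal approximation.
- **BKY two-stage FDR**: linear step-up at q′ = q/(1+q); if it rejects r₁
  of m hypotheses with 0 < r₁ < m, a second step-up at q′·m/(m−r₁) gives
  the final rejection set. The original procedure defines rejections, not
  adjusted values; the reported q-values are the smallest nominal q at
  which each hypothesis is rejected, computed by bisection (the rejection
  set is monotone in q), which is the monotone-consistent extension.
- **BH adjustment** is used for the volcano/threshold workflow (the
  two-stage procedure is specific to the cytokine panel).
- **"Reliably detected"** is formalized as above the detection floor in
  ≥ 50% of samples (configurable); below-floor values are stored at the
  floor with a flag, never dropped, so the filter stays a downstream
  decision.
- **Median-relative display**: log2(value / analyte median) with the
  median taken on the log scale (geometric interpolation at even sample
  counts), so each displayed row has median exactly 0; below-floor values
  are floored first. Rows are ordered by the supplied group ordering —
  supervised display, no dendrogram.
- **Fold changes** are ratios of linear-scale group means; when a mean is
  zero a pseudocount ε = 0.5 is added to both means so log10 fold change
  is always defined. Threshold gene lists apply fold ≥ f (up) or ≤ 1/f
  (down) with p (or q) below the cutoff, ordered by |log10 FC|.

## The synthetic cohort generator

The generator produces the study design the analysis assumes: 7 patients
(4 MRD+, 3 MRD−), 500 cells each by default, a blast-dominated mixture
(52% leukemic blasts; the sorted non-leukemic compartment is T/NK-rich)
over 8 cell types, and 2,000 genes.

**Counts.** Per-gene negative binomial (mean μ, size r, variance
μ + μ²/r) via a gamma–Poisson draw; per-gene baseline means are lognormal
(meanlog −0.5, sdlog 1.0), genome-wide size r = 2. A per-cell lognormal
library-size factor (sd 0.45) reproduces the capture-depth spread of
droplet data and exercises the detected-genes QC rule.

**Cell identity.** Each type boosts its canonical markers 6-fold; markers
get a solid baseline (mean 1 count/cell, mild spread), since canonical
markers are well-expressed genes. Each type additionally carries a diffuse
30-gene program at 3-fold — real cell types differ transcriptome-wide,
and without this breadth no clustering method can separate them at these
cell numbers (with it, cluster malignancy purity is ≥ 0.93 for the default
delegates).

**Mitochondrial content.** Per cell, a Beta(2, 13) target fraction; mito
gene means are scaled so the expected mito fraction equals the draw.
Beta(2, 13) puts ~5% of cells above the 0.30 QC cutoff, so the filter is
exercised.

**The exhaustion/checkpoint program.** Signature genes are lowly expressed
at baseline (mean 1.8 counts/cell over 14 genes, size r = 5). The program
is *continuous*: every cell carries a lognormal program intensity
(sd 0.25), and a 7% subpopulation of transiently activated cells carries a
further lognormal boost (median 1.5×, sd 0.35) — checkpoint genes
(PD-1, CTLA-4, ICOS, ...) are activation-induced, and a null population
with such a tail is precisely the setting in which upper-outlier calling
is meaningful. This correlated structure is deliberate: with strictly
independent signature genes the pooled score distributions have no genuine
upper tail, the fences sit in a regime of 2–6 flagged cells, and the
association test cannot be calibrated — the generator would then be
simulating data that violates the analysis's own premise. Cells labeled
*exhausted* (20% of cytotoxic cells in MRD+ patients, 2% in MRD−, by
default) multiply the signature means by λ = 3 on top of their program
intensity. Truth columns record type, malignancy and exhaustion per cell.

**Flow sorting.** Sort labels follow true malignancy with a 2% error rate,
giving the relabeling stage realistic work to do.

These generator constants were calibrated once, jointly, against the two
operating-characteristic requirements the pipeline is specified to meet —
null rejection 5% ± 2·SE over ≥200 replicate cohorts, and p < 0.001 in
≥90% of spiked cohorts — and then frozen; the acceptance script re-measures
both from scratch on every run.

**Cytokine panel.** 35 analytes named after a representative human 35-plex
Luminex panel; per-analyte lognormal concentrations (meanlog 3.0,
sdlog 0.5) for 12 + 12 samples, one true effect by default (IL-7 3.5×
higher in MRD−, matching the reported direction), detection floor
1 pg/mL with below-floor values stored at the floor and flagged.

**What the synthetic cohorts do not show.** No doublets, ambient RNA,
batch effects, patient-level expression heterogeneity beyond the group
effect, or gene–gene correlation beyond the type programs and the
signature program intensity. Passing tests therefore demonstrate that the
implementation is correct and that the procedure is calibrated and
powered *under its own model assumptions* — not that those assumptions
hold in any particular real cohort; in particular the pooled chi-squared
inherits the pseudoreplication caveat above on real patients.

## Numerical choices and degenerate inputs

- Quantiles everywhere use numpy's default linear interpolation.
- A constant score vector has IQR 0 and flags nothing.
- `flag_upper_outliers` requires ≥ 4 finite scores; `log_normalize`
  refuses zero-total cells and points the caller at `qc_filter`.
- Ties in HVG dispersion and in cell-type assignment break
  deterministically (gene symbol / type name order).
- Duplicate gene symbols are disambiguated by suffixing ".1", ".2" in
  file order, reversible via the features file.
- All randomness in a simulation flows from one integer seed through a
  single `numpy.random.default_rng` stream; identical config + seed gives
  bit-identical matrices, annotations and panels.
- Problem sizes used by the test-suite and acceptance runs (cohorts of
  3,500 cells × 2,000 genes; 200 null and 50 spiked replicates; 1,000
  random instances per statistical-procedure oracle) were chosen as the
  smallest at which the measured operating characteristics are stable
  against their Monte-Carlo error.

## Known limitations

- The two association scores share the same counts; their fences are not
  independent pieces of evidence, which is why the combination rule is a
  reading choice rather than a statistical one.
- The BKY q-values are defined through the procedure's rejection
  threshold; unlike BH-adjusted p-values they are not themselves adjusted
  p-values and should be read as "smallest q at which this analyte is
  called".
- `group_composition` reports percentages; it deliberately does not pick
  a between-group test, because the correct unit (patients) leaves very
  few degrees of freedom in cohorts of this size.
- The accession-based check on the deposited patient cohort requires the
  public download to be placed under `data/gse198519/`; it cannot run on
  synthetic data.
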