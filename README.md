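# scexhaust

Single-cell T/NK **exhaustion scoring** and its association with
**measurable residual disease (MRD)** in pediatric B-cell acute
lymphoblastic leukemia (B-ALL), packaged as a tested, reusable pipeline —
together with the accompanying plasma **cytokine-panel** and **targeted
expression-panel** statistics and a seeded **synthetic-cohort generator**
that makes every stage verifiable at desk scale.

It is written for computational immunologists and leukemia researchers who
want to apply (or stress-test) the outlier-based "highly exhausted cell"
analysis on their own droplet scRNA-seq cohorts, and for methodologists who
want a calibrated sandbox for that analysis.

## The method

Cells passing QC (more than 200 detected genes and less than 30%
mitochondrial counts) are log-normalized,
`x(c,g) = ln(1 + s * k(c,g) / K(c))` with scale factor `s = 10^4`, where
`k(c,g)` are raw counts and `K(c)` the cell total. Each cell is scored over
a fixed 14-gene exhaustion signature
(*PDCD1, CTLA4, HAVCR2, TIGIT, TOX, LAG3, NFATC1, NFATC2, NR4A1, TOX2,
TCF7, CD244, CD160, ICOS*) in two ways:

- **normalized sum** — `S1(c) = Σ_{g∈sig} x(c,g)`;
- **count fraction** — `S2(c) = Σ_{g∈sig} k(c,g) / K(c)`.

A cell is **highly exhausted** when it exceeds the Tukey upper fence
`Q3 + 1.5·IQR` of either score distribution (the combination rule is
configurable; see `docs/methods.md`). The 2×2 table of flag × MRD group
over non-malignant cells is tested with Pearson's chi-squared with Yates'
continuity correction,

```
X² = N (|ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)),   df = 1,
```

with the correction clamped at zero. Flow-sort labels are reconciled with
expression clusters first: clusters ≥90% leukemic-sorted are leukemia
clusters, stray sorted labels inside/outside them are relabeled or omitted.

Panel statistics include Welch's t-test, the exact/midrank Mann–Whitney U
test, Benjamini–Hochberg FDR and the Benjamini–Krieger–Yekutieli two-stage
adaptive step-up FDR, detection-floor filtering, analyte ratios,
median-relative display matrices, and fold-change/threshold gene lists.

## Worked example

```python
import scexhaust as sx

cohort = sx.simulate_cohort(sx.CohortConfig(seed=1))      # 7 patients, 3,500 cells
counts, report = sx.qc_filter(cohort.counts)              # QC: >200 genes, <30% mito
ann = (cohort.annotation[cohort.annotation["barcode"].isin(set(counts.barcodes))]
       .set_index("barcode").loc[counts.barcodes].reset_index())
norm = sx.log_normalize(counts)
result, table, test = sx.run_exhaustion_association(counts, norm, ann)
print(table.to_array())
print(test.statistic, test.p)
```

prints

```
[[ 80  22]
 [815 656]]
19.695... 9.08e-06   # chi² and p for the cohort drawn above
```

— 102 of 1,573 non-malignant cells are flagged highly exhausted, and they
sit disproportionately in the MRD+ column (80 vs 22 against group totals
895 vs 678), which the Yates-corrected chi-squared calls strongly
significant. On a null cohort (exhaustion effect switched off) the same
pipeline rejects at the nominal ~5% rate.

The `examples/` directory holds one short narrative script per capability
(cohort simulation, exhaustion association, cytokine panel, clustering and
relabeling, targeted-panel fold changes); each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same library calls for file-based runs:

```bash
scexhaust --config config.yaml simulate --out-dir sim/
scexhaust --config config.yaml qc --counts-dir sim/ --annotation sim/annotation.csv --out-dir qc/
scexhaust --config config.yaml associate --counts-dir qc/ --annotation qc/annotation.csv --out-dir out/
```

Every subcommand writes a manifest (config hash, seed, input checksums)
next to its outputs.

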