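# Methods

This note documents the statistical procedures implemented in `metaniche`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic cohorts do and do not emulate, and the numerical conventions that
matter for reproducing results.

## Data model and normalization

Counts are a sparse genes × cells matrix of non-negative integers with
companion cell and gene tables; on disk, the standard MatrixMarket triplet
bundle. Gene identity is matched on symbol throughout (duplicate symbols
resolve to the row with the larger total, with a logged warning), and gene
coordinates are 1-based; only the ordering of genes along a chromosome — not
physical distance — is consumed downstream.

Normalization is library-size scaling to a fixed total (default 10,000
counts per cell) followed by log1p. The downstream literature for this kind
of toolchain does not always state whether signature scores average log or
linear normalized values; both are supported (`log_transform` flag), log
being the default. A cell with zero counts cannot be normalized and is an
explicit error naming the cell, rather than a silent drop.

## Quality control and composition

Cells with fewer than 600 total UMIs or a doublet score above 0.4 are
removed; both thresholds are strict in the stated direction (exactly 600 or
exactly 0.4 is retained). The doublet score is an input — typically from a
dedicated doublet detector — and a missing score is an error, never treated
as a pass.

Composition compares per-sample cell-type proportions (denominator: all
retained cells of the sample) between two condition arms with a two-sided
Wilcoxon rank-sum test per cell type. With 6–8 samples per arm the normal
approximation is unreliable, so the exact null distribution is used whenever
both arms have at most 10 samples and the proportions are tie-free; the
tie- and continuity-corrected normal approximation otherwise. Samples with
fewer than 40 cells in the analyzed subset are dropped before testing.

## Marker detection (per-cell route)

For one cluster against all remaining cells, each gene gets a two-sided
rank-sum p and a signed Z:

    Z = sgn(mean rank in − mean rank out) · Φ⁻¹(1 − p/2)

computed directly as the signed, continuity- and tie-corrected standardized
U statistic, so |Z| and p are exactly consistent and Z remains finite even
when p underflows. Tiny clusters (both groups ≤ 10 cells, no ties) use the
exact distribution, which the vectorized path hands off to per-gene exact
tests. Genes constant across both groups are flagged with Z = 0, p = 1.
Markers are genes with Z above the cutoff (default 3). BH correction is
applied over genes. The marker log2 fold change is computed on de-logged
mean normalized expression with a 1e-9 pseudocount for stability at zero.

## Mini-bulk differential expression (per-sample route)

Per-sample, per-cell-type summed ("mini-bulk"/pseudobulk) counts put the
replication unit at the sample, where it belongs for condition contrasts.
Samples contributing fewer than 10 cells of the type are excluded.

The test is a simplified NB Wald pipeline in the style of bulk RNA-seq DE:

1. **Size factors** — median-of-ratios against the geometric-mean reference
   sample, over genes with positive counts everywhere.
2. **Dispersion** — gene-wise method of moments with shrinkage toward a
   fitted mean-dispersion trend α(μ) = a₀ + a₁/μ. Two details matter for
   calibration. First, the Poisson part of the variance of normalized
   counts is μ·mean(1/sⱼ), not μ, so the moment estimator uses the excess
   v − μ·mean(1/s). Second, the trend is fit to binned ratio estimates
   Σ excess / Σ μ² — an estimator that stays unbiased because it never
   conditions on the sign of the noisy per-gene moments (fitting only to
   genes with positive moment estimates, a tempting shortcut, biases the
   trend upward and makes the test conservative). The final per-gene
   dispersion is the log-space midpoint of the trend and the gene-wise
   value clipped to within 5× of the trend.
3. **Wald test** — per-gene NB GLM `count ~ group` with log size-factor
   offset (fit via statsmodels); two-sided normal p on the group
   coefficient; BH over tested genes. The coefficient sign convention is
   log-FC of the first group over the second. Genes with zero counts in
   every sample are reported untested; non-convergent fits give NaN p.

No independent filtering or outlier (Cook's distance) handling is done;
acceptance is by simulation recovery and null calibration, not bit-parity
with any particular bulk DE package. Under the no-effect cohort the
fraction of genes with raw p < 0.05 sits inside the binomial 95% band of
0.05 for both routes (measured on 2,000 genes, 15 samples).

## Signature scoring

A signature score is the unweighted mean of normalized expression over the
set members present in the matrix, per cell or aggregated per sample (mean
of cell scores). Missing members reduce `n_members_used` and are logged;
they never produce NaN. No background-gene (control-pool) correction is
applied — the score is a plain average by design. Group comparisons use the
same rank-sum machinery as composition, BH-corrected across the family of
comparisons when more than one is run. Cell-level and sample-level units
give different effective sample sizes; the unit is an explicit argument
because the right choice depends on the claim being made.

## CNV profiles

Malignancy evidence is read from expression along chromosomes: per gene,
center by the mean over a caller-supplied reference population (e.g. all
immune cells), clip at ±3 reference SDs to tame outliers (genes with zero
reference variance are thereby nulled, which is the desired behavior for
genes the reference never expresses), smooth with a 101-gene centered
moving average within each chromosome (windows shorten symmetrically at
chromosome ends and never span two chromosomes), then median-center each
cell's profile. Window length and clip bound are flags; 101 and 3 mirror
the documented defaults of the standard tool for this inference.
Chromosomes with fewer than 3 genes are excluded with a warning.

Because the per-cell median shift is not identically zero, a
reference-only profile is flat but not exactly zero; the operative
invariant is that the reference cells' mean profile stays within ±0.05 of
zero in every window (measured ≈ 0.01 at default scale). Segment calls in
validation use a 2-SD rule: a cell carries a gain (loss) if its mean
profile over the segment's windows exceeds (falls below) the reference
mean ± 2 reference SDs of the same quantity.

## Metastatic signature and stratification

The signature is the intersection of two Z-filtered marker comparisons at
the same cutoff (default 10): metastatic tumor cells vs primary tumor
cells, and metastatic tumor cells vs all non-malignant cells. The second
comparison operationalizes "exclusively expressed in tumor cells"; an
optional stricter filter (expressed fraction in non-malignant cells below
10%) exists but is off by default. An empty intersection is a valid result
with a warning, not an error.

Bulk cohorts are stratified by per-patient signature score: bottom
⌊q·n⌋ patients are "low", top ⌊q·n⌋ "high" (default q = 0.25), the middle
mass excluded. Ties at a boundary break by stable patient-id order with the
boundary patient staying in its stratum — deterministic and monotone
(raising a patient's score never demotes them). An all-equal score vector
is flagged degenerate but still stratified by the same rule.

## Survival

Kaplan–Meier from the product-limit definition, with the standard
convention that events precede censoring at tied times (a patient censored
at t is still at risk for events at t). The log-rank statistic accumulates
observed minus hypergeometric-expected events in one stratum over distinct
event times, with variance d·(n₁/n)(1 − n₁/n)(n − d)/(n − 1), referred to
χ² with 1 df. Zero events overall, or zero total variance, are explicit
errors. Only the plain two-group test is provided — no stratified or trend
variants, no Cox regression. Both estimators agree with an independent
survival library to floating-point precision on random fixtures.

## Ligand–receptor interactions

A channel (pair, sender type, receiver type) passes the screen when the
ligand is expressed (> 0 normalized) in ≥ 10% of sender cells and the
receptor in ≥ 10% of receiver cells. Its score is the product of the mean
normalized ligand expression over sender cells and mean receptor
expression over receiver cells (log-normalized values by default, matching
the signature module).

Significance: each permutation round shuffles the cell-type label vector
globally — one shuffle shared by all channels, which preserves type counts
exactly and retains the between-channel correlation of the null — and the
empirical p uses the add-one convention p = (1 + #{null ≥ obs})/(1 + N)
with ties counted against significance. The literal count/N formula can
return p = 0, which misrepresents a finite-draw null; the add-one form is
the documented deviation and is recorded in the output metadata
(`n_perm`). An exhaustive mode enumerates every distinct label arrangement
for tiny inputs, where the add-one closed form is exact. Tumor-exclusive
ligands are flagged by their tumor-marker Z exceeding the marker cutoff.

## Synthetic cohorts

The single-cell generator emulates the study design: 7 nonmetastatic + 8
metastatic bone-marrow samples plus 3 primary-tumor samples of 150–250
cells each; five cell types (tumor, T, myeloid, B, NK) with 10 marker genes
each at fold 5; per-sample composition Dirichlet-distributed with a
multiplicative concentration shift in the metastatic arm (T ×0.7, myeloid
×1.6, NK ×0.8); tumor fractions 0.35 (metastatic), 0.6 (primary), 0
(nonmetastatic); 30 tumor-exclusive genes upregulated at fold 4 only in
metastatic tumor cells; one full-chromosome gain (ratio 2) and one loss
(ratio 0.5) acting multiplicatively on tumor-cell expression; 2,000 genes
on 10 equal chromosomes; NB counts with shared dispersion 0.3 and
log-normal library sizes (median ≈ 2,000 UMIs); 5% doublets built by
binomial-thinning the summed counts of two same-sample cells, with doublet
scores drawn high (0.55–0.95) versus low (0–0.25) for singlets. One
`numpy` Generator seeded once drives every draw, so cohorts are
bit-reproducible. Composition shifts and tumor fractions are free
parameters of the generator, chosen as plausible magnitudes — they are not
estimates of any particular cohort.

Marker and signature gene baselines are drawn from the expressed range
(log-normal mean 1.0, sd 0.5, versus mean 0 for the transcriptome): a
curated marker or signature gene is by construction one the assay detects,
and planting effects on never-expressed genes would make the planted truth
unrecoverable in principle rather than test the pipeline.

The bulk generator gives each patient a latent burden b ~ N(0,1);
signature genes read μ_g + b + noise, background genes carry no signal;
event times are exponential with hazard 0.08·HRᵇ and censoring uniform on
(0, 12). The `null()` constructor produces the matching no-effect cohort
(all folds 1, no CNV, optionally label-only tumor cells) used for
calibration checks.

Not emulated: ambient RNA, batch effects, UMI saturation, realistic
co-expression structure, cell-cycle or lineage continua. Passing tests
therefore demonstrate correctness of the statistics under a clean
generative model, not robustness to those artifacts.

## Problem sizes and numerical conventions

Validation runs at the generator's default scale: ~3,500–3,700 cells ×
2,000 genes per cohort, 15 bone-marrow samples, 200-patient bulk cohorts,
100 Monte-Carlo survival replicates, 400–1,000 permutations for
ligand-receptor nulls, 200 random fixtures for the exact-test oracle. The
whole validation suite computes in a few minutes on one CPU.

Conventions worth restating: exact rank-sum only without ties and with
both groups ≤ 10; continuity correction of 0.5 in the asymptotic rank-sum;
BH capped at 1; quantile strata use ⌊q·n⌋ per tail; dispersion floors at
1e-8 and ceilings at 10; permutation p never reaches 0 by construction.

## Known limitations

- The NB Wald route is a simplified re-implementation: no independent
  filtering, no outlier refitting, no LFC shrinkage. Its guarantees are
  the measured calibration and recovery, not equivalence to any reference
  implementation.
- Clustering/annotation is out of scope: cell-type labels are inputs.
  Errors in annotation propagate directly into every per-type statistic.
- The CNV profile is a smoothing heuristic for visual/threshold evidence
  of large segments; it performs no HMM segmentation and cannot call
  focal events near the window scale.
- Multi-subunit ligand/receptor complexes are not modeled; each pair is a
  single gene on each side.
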