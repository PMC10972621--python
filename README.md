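# metaniche

Comparative single-cell analysis of tumor bone-marrow metastasis, built as a
tested, reusable pipeline. The package re-creates the analytic core of a
two-arm scRNA-seq cohort study — bone-marrow samples from metastatic versus
nonmetastatic neuroblastoma patients, plus primary-tumor references — and
ships a synthetic cohort generator with planted ground truth so that every
stage can be validated end-to-end without any external download.

It is aimed at computational biologists who want the individual statistical
stages of such a study as importable, unit-tested functions rather than a
one-off analysis script.

## What it computes

| Stage | Method |
|---|---|
| Cell QC | keep cells with total UMIs ≥ 600 and doublet score ≤ 0.4 |
| Composition | per-sample cell-type proportions; two-sided Wilcoxon rank-sum per type (exact for ≤ 10 samples per arm) |
| Markers | per-gene rank-sum with signed Z = sgn(Δ mean rank) · Φ⁻¹(1 − p/2); markers at Z > 3; BH-adjusted |
| Mini-bulk DE | per-sample, per-type summed counts (samples with < 10 cells dropped); median-of-ratios size factors; NB GLM `count ~ group` with trend-shrunken dispersion; Wald test |
| Signature scores | unweighted mean normalized expression over a gene set, per cell or per sample |
| CNV profile | reference-centered, ±3 SD clipped, 101-gene moving average along chromosome-ordered genes, per-cell median centered |
| Metastatic signature | genes with Z > 10 both vs primary tumor cells and vs non-malignant cells (intersection) |
| Survival | Kaplan–Meier product limit S(t) = Π(1 − dᵢ/nᵢ); two-group log-rank (ΣO − ΣE)²/ΣV ~ χ²₁; patients stratified by top/bottom 25% of signature score |
| Ligand–receptor | screen at ≥ 10% expressed fraction; score = mean ligand (sender) × mean receptor (receiver); empirical p from 1,000 global shuffles of cell identities, p = (1 + #{null ≥ obs})/(1 + N) |

The synthetic generator plants every effect these stages are supposed to
find: condition-shifted composition, tumor cells exclusive to metastatic
samples, tumor-exclusive upregulated genes, chromosomal gain/loss segments,
doublets, and a bulk cohort whose hazard follows a signature burden
(hazard ∝ HRᵇ, b ~ N(0,1)).

## Worked example

```python
import metaniche as mn

counts, cells, genes, truth = mn.generate_sc_cohort(mn.SimConfig(seed=0))
fcounts, fcells, audit = mn.filter_cells(counts, cells)
norm = mn.normalize(fcounts, genes, fcells)

comp = mn.composition_test(fcells, "metastatic", "nonmetastatic")
der = mn.derive_signature(norm, fcells, z_cutoff=10.0)

bulk, surv, _ = mn.generate_bulk_cohort(200, der.signature, 3.0, seed=1)
score = bulk.loc[list(der.signature.genes)].mean(axis=0)
score.index.name = "patient_id"
strat = mn.stratify_by_score(score, 0.25)
m = surv.merge(strat[["patient_id", "stratum"]], on="patient_id")
stat, p = mn.logrank_test(m[m.stratum.isin(["high", "low"])], "high", "low")
```

Output of the script version of this example:

```
cohort: 2000 genes x 3549 cells, 18 samples
QC retained 3371/3549 cells (1 low-UMI, 177 doublet)
tumor composition: median 0.349 vs 0.000, two-sided p = 7.95e-04
derived metastatic signature: 30 genes
log-rank chi-square = 43.40, p = 4.46e-11; S(5) high = 0.26, low = 0.93
```

Reading this: tumor cells make up ~35% of metastatic samples and are absent
from nonmetastatic ones (with only 8 vs 7 samples a rank-sum p cannot go
much below 10⁻³, however complete the separation — the tie-corrected
approximation is used here because the nonmetastatic proportions are all
exactly zero); the Z > 10 double
filter recovers exactly the 30 planted tumor-exclusive genes; and the
high-signature quartile of the bulk cohort dies much faster than the low
quartile (survival at t = 5 of 0.26 vs 0.93), as planted.

The same stages are available from the shell:

```sh
metaniche simulate --seed 0 --out cohort/
metaniche qc --bundle cohort/ --out qc/
metaniche composition --bundle qc/ --out composition.tsv
metaniche run --seed 0 --out full_run/   # all stages + manifest
```

## Layout

- `src/metaniche/core.py` — matrices, tables, MTX/GMT I/O, normalization
- `src/metaniche/simulate.py` — synthetic single-cell and bulk cohorts
- `src/metaniche/qc.py` — cell filtering, composition tests
- `src/metaniche/rank_stats.py` — rank-sum markers, BH, mini-bulk NB DE
- `src/metaniche/signatures.py` — gene-set scoring and comparisons
- `src/metaniche/cnv.py` — moving-average CNV profiles
- `src/metaniche/metastatic.py` — signature derivation, stratification
- `src/metaniche/survival.py` — Kaplan–Meier, log-rank
- `src/metaniche/interactions.py` — ligand-receptor permutation test
- `src/metaniche/pipeline.py`, `cli.py` — orchestration and `metaniche` CLI

See `docs/methods.md` for the statistical details and design decisions.
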