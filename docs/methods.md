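# Methods

This note documents the models, statistics and numerical conventions behind
`sclc_tme`, the choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Cohort and measurement model

The package targets cohorts shaped like a limited-stage SCLC TMA study:
each patient contributes a primary tumor (two 1-mm cores, two sections
counted per core) and a matched lymph-node (LN) metastasis (one core, two
sections); five immune markers (CD68 pan-macrophage, CD163 M2-macrophage,
CD33 myeloid/MDSC, CD45 pan-leukocyte, CD3 T-cell) are counted separately
in the stroma and tumor-nest compartments of every section over manually
measured areas; and a 2560-gene targeted oncology panel provides log2-scale
expression per sample.  Samples carry neuroendocrine subtype labels
(NE-high ≈ ASCL1/NEUROD1-driven, NE-low ≈ YAP1/POU2F3) from expression
clustering, treated here as given.

### Density conversion and replicate averaging

Densities are `count / (area_um2 × 10⁻⁶)` cells/mm².  Averaging is
two-stage and unweighted: section densities are averaged within a core,
core means within a sample.  Unweighted core averaging is an assumption
(core areas could be used as weights); it matches the replicate handling
described for such studies and keeps the estimator unbiased when a core's
tissue composition, not its size, differs.  A compartment absent from a
core is *missing*, never a zero — zeros would drag cohort cutoffs down.

CD33 is scored ordinally per core compartment (0: 0 cells, 1: 1–10,
2: 11–20, 3: ≥21, so exactly 21 scores 3 and the bins partition the
integers); section counts are averaged and rounded before binning, and a
sample takes the maximum score across its cores.

### Composition

Marker shares of the CD45⁺ pool are reported per group and compartment.
Default aggregation is ratio-of-sums (group-summed marker density over
group-summed CD45 density), which is robust to samples with tiny CD45
denominators; mean-of-ratios is available where per-sample shares are the
estimand.  Markers overlap biologically (CD163⁺ ⊂ CD68⁺ cells), so shares
are per-marker and need not sum to 1.

## Dichotomization and phenotype rules

Continuous biomarkers are split at `median + c·MAD` with the raw
(unscaled) MAD; `c` defaults to 0 because no multiplier is canonical —
the split point, not the scale factor, carries the assumption.  Values
exactly at the threshold are LOW (deterministic, and consistent with
ordinal HIGH being strictly the upper bins).  Cutoffs may be computed on a
sample subset (e.g. primary tumors only) while calls are made for all
samples.

The immune-phenotype rule is evaluated literally:

* oasis ⇔ (CD45s = HIGH ∨ CD45t = HIGH) ∧ (CD3s = HIGH ∨ CD3t = HIGH)
* desert ⇔ (CD3s = LOW ∧ CD3t = LOW) ∧ (CD45s = LOW ∨ CD45t = LOW)

The two rules cannot both fire (oasis needs a CD3 HIGH, desert forbids
it), but they do not cover all 16 combinations: samples that are, e.g.,
CD45-high/CD3-low are reported as a third *ambiguous* category rather than
forced into either class, and missing required calls are ambiguous with a
reason code.  The macrophage-high/-low grouping — used in the literature
but never formally defined — defaults to "HIGH in ≥ half of the available
macrophage-related parameters (CD68s/t, CD163s/t, CD33s, MHCII)" and is
fully configurable.

## Rank statistics

Spearman (midrank ties) and Kendall tau-b coefficients and two-sided
p-values come from scipy; missing values are removed pairwise because TMA
dropout is compartment-specific.  Mann–Whitney U uses the exact
permutation distribution when both groups have ≤ 8 observations and no
ties, otherwise the tie-corrected normal approximation; both are exposed.
The replicate-core check is the Wilcoxon matched-pairs signed-rank test
with zero differences dropped; the reported statistic is W⁺ (rank sum of
positive differences).  Correlation strength labels (<0.4 weak, 0.4–0.7
moderate, >0.7 strong) are reporting conventions, configurable and never
used for inference.

## Preranked GSEA

The enrichment statistic is authored here rather than wrapped, because it
is the analytical core of the pipeline.

**Ranking.** Default metric is signal-to-noise
`(μ_A − μ_B) / (σ_A + σ_B)` with each group sd floored at
`max(0.2·|μ|, 0.2)` — the convention that keeps low-variance genes from
dominating targeted panels, where many features are near-constant.  Welch
t and plain log2 fold change are switches; the metric used is recorded in
output metadata.  Ties are broken by gene identifier so rankings are fully
deterministic.

**Running sum.** With weight exponent p ≥ 0 (default 1), a hit at gene i
adds `|sᵢ|ᵖ / Σ_hits |s|ᵖ`, a miss subtracts `1/(N − N_h)`; the sum ends at
0 by construction (asserted to 1e-9 in tests).  ES is the running-sum
value of maximal absolute deviation; an exact tie between the positive and
negative extreme resolves to the positive one.  With p = 0 the statistic
is the classical two-sample KS statistic, verified against a brute-force
oracle.  Permutation nulls use an O(|S|) evaluation at hit positions only;
its agreement with the full walk is itself under test.

**Null and NES.** The null resamples |S| gene labels uniformly without
replacement (the preranked null — phenotype permutation is out of scope
for a preranked interface).  NES = ES / mean(|null ES| of the same sign);
nominal p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign),
so p ∈ (0, 1] and is never exactly zero.  If no same-sign null exists the
result is flagged unstable and normalized against the unsigned null mean.
Benjamini–Hochberg adjustment is applied across pathways within a run.
Uniformity of the nominal p under the null is a tested property (1000
decoy sets, KS test).

**Heat-map matrix.** Pathway × group NES profiles keep pathways whose
maximal |NES| exceeds 1 and are z-scored per pathway with the population
(n) denominator — this is display scaling, not inference, and a constant
row z-scores to 0 rather than NaN.

## Differential expression, volcano, networks

Per-gene tests are Welch's t on the log2 values with a 1e-12 variance
floor (a gene constant in both groups with equal means reports p = 1; with
different means the evidence is treated as overwhelming).  A light
empirical-Bayes option shrinks gene variances halfway to the across-gene
mean; the full hierarchical moderated-t is deliberately not reimplemented,
since downstream consumers are thresholded target lists and the Welch
calls converge to the same lists at these effect sizes.  The choice is
logged in output metadata.  Bonferroni adjustment is over the number of
tested genes; volcano categories apply by default to the *adjusted* p
(adjustment precedes plotting), with strict boundaries: |log2FC| exactly 2
is dark blue, exactly 1.5 is light blue.

Target genes (p < 0.05 and log2FC > 1.5, both strict, directional) induce
a subgraph of the user-supplied interaction table (STRING-export-like TSV;
no live database calls).  Edges need score ≥ 0.4; isolated selected nodes
stay in the graph.  `edges/node` is the literal ratio E/N — mean degree
2E/N is a switch, and the interpretation used is recorded in output.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is validated.

**Densities.** Per-sample true log densities follow a one-factor model
`x_v = μ_{v,subtype} + λ_v f + σ_v ε` with a single latent "infiltration"
factor f per sample (primary and LN factors correlate at 0.6; the LN
reuses the patient's NE label with flip probability 0.1).  Subtype means
are calibrated to published group means for CD68/CD163; CD45 and CD3 means
are derived from the published composition fractions (CD68 = 64%/71% of
CD45 in tumor nests for NE-low/NE-high, CD3 = 38%/18%); CD33 stromal means
are set so expected core counts land in the ordinal score bins.  Observed
counts are negative-binomial (size 20) with mean = density × area, areas
log-normally jittered around 0.30 mm² (stroma) and 0.45 mm² (tumor nest) —
so density estimates carry realistic integer sampling noise.

**Correlation targets.** Requested pairwise Spearman targets are honored
on the *measured* densities: the generator subtracts the correlation the
NE-subtype mean shifts already induce, inflates for the attenuation
expected from counting noise (delta-method `1/m + 1/k` per section,
divided by the replicate count), and solves for factor loadings by
log-space least squares.  Targets that would need loadings above the
within-subtype spread, or a non-PSD latent correlation matrix, are
rejected with a diagnostic rather than silently approximated — a
one-factor model cannot represent every printed correlation triangle, so
the default targets are a feasible subset (CD68–CD163 in both
compartments, CD163–CD33 in stroma) and the remaining published
correlations emerge from the shared factor plus the subtype mixture.
Realized Spearman at n = 5000 is within ±0.05 of each target (tested).

**Expression.** Gene baselines are N(6, 1.5²) log2 units; samples share a
patient-level effect (sd 0.4) so matched primary/LN profiles correlate;
immune-module genes shift +effect_size (default 2.0 log2 units) in NE-low
samples plus 0.3 per unit of the infiltration factor; proliferation and
neuroendocrine modules shift +effect_size in NE-high samples.  Four
immune genes (CSF1, VEGFC, IL4R, CXCR2) are calibrated to published
NE-low/NE-high group means and SDs, exact at the reference effect size 2.0
and scaling proportionally with effect_size so the effect_size = 0 null is
a true null.  Gene sets are the module memberships plus random decoy sets;
interaction edges are sampled with a 25× within-module probability boost
and uniform (0.4, 1] scores.

**What the generator does not emulate** — and hence what green tests do
not establish about real cohorts: spatial structure within a core
(necrosis, tissue heterogeneity) beyond an area jitter; inter-observer
counting variation; marginal distributions beyond
lognormal-with-NB-counts; batch or assay effects in the panel;
co-expression structure within modules beyond the shared shifts; and any
survival or outcome process.  Passing tests show the *pipeline* recovers
the structure it is pointed at, not that a particular biological claim
holds.

## Problem sizes and runtime choices

Unit and property tests run on scaled inputs (panels of 150–300 genes,
cohorts of 10–60 patients, 150–300 permutations); the calibration-critical
checks use the sizes they need (fraction recovery at n = 10 000, Spearman
targets at n = 5000, permutation-uniformity at 1000 decoy sets).  The
acceptance script reports correlations at n = 5000 patients, composition
at n = 3000 and calibrated gene means at n = 1000 so reported values
reflect generator conditions rather than seed noise, while phenotype
counts, NES and network statistics use the study-sized 32-patient default.
All randomness flows from explicit seeds; rerunning any entry point with
the same configuration is byte-identical.

## Known limitations

* The MAD multiplier c and the cutoff cohort (primary-only vs pooled) are
  exposed but no value is claimed to reproduce any published cutoff table.
* The exact ranking metric and permutation count behind published NES
  values are unknown; no default here claims numerical reproduction of a
  published enrichment figure — only of its qualitative structure.
* With ~30 patients, MAD cutoffs and permutation p-values are themselves
  noisy; the pipeline reports them deterministically but the scientific
  uncertainty is larger than the numerical one.
* `edges/node` = E/N equals mean degree / 2; both readings circulate, so
  cross-study comparisons must check which one a number uses.
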