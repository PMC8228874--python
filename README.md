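# sclc-tme

Compartment-resolved analysis of the tumor immune microenvironment in small
cell lung cancer (SCLC) cohorts: from per-compartment immune-cell counts on
tissue-microarray (TMA) cores and a targeted expression panel to rule-based
immune-phenotype calls, pathway enrichment profiles, differential-expression
target lists, and interaction-network connectivity.

It is written for translational researchers who quantify
immunohistochemistry manually (cell counts over measured areas, stroma vs
tumor nest) and profile the same samples with a targeted RNA panel, and who
want every step of the downstream analysis — dichotomization, phenotype
rules, enrichment statistics, target selection — explicit, configurable and
testable.  A synthetic-cohort generator reproduces the statistical structure
such studies assume, so the full pipeline can be exercised and validated
without access to patient data.

## What it computes

**Morphometry.** Counts *N* over measured areas *A* (µm²) become densities
*D = N / (A·10⁻⁶)* cells/mm²; section densities are averaged within a core
and core means within a sample.  Sparse CD33⁺ myeloid cells are scored
ordinally: 0 (0 cells), 1 (1–10), 2 (11–20), 3 (≥21).  Immune composition is
reported per compartment as each marker's share of the CD45⁺ density.

**Phenotyping.** Each biomarker *x* is dichotomized at
*t = median(x) + c·MAD(x)*, MAD = median|xᵢ − median(x)| (default *c* = 0,
a median split; ordinal scores are HIGH for 2–3).  Samples are then
classified: **immune-oasis** iff (CD45 stroma HIGH or CD45 tumor HIGH) and
(CD3 stroma HIGH or CD3 tumor HIGH); **immune-desert** iff (CD3 LOW in both
compartments) and (CD45 LOW in at least one); anything else is ambiguous.
A configurable majority rule over CD68/CD163/CD33/MHCII calls yields
macrophage-high vs macrophage-low groups.

**Association.** Spearman's r_s and Kendall's tau-b over the marker ×
compartment grid, Mann–Whitney U for unpaired contrasts (exact for small
groups), Wilcoxon matched-pairs signed-rank for replicate-core agreement.

**Enrichment.** Preranked GSEA implemented from first principles: genes are
ranked by signal-to-noise (or Welch t, or log2 FC) between two groups; a
weighted Kolmogorov–Smirnov running sum scores each gene set
(hits add |sᵢ|ᵖ/Σ_hits|s|ᵖ, misses subtract 1/(N−N_h)); ES is the maximal
deviation from zero.  A gene-label permutation null gives
NES = ES / mean(|null ES| of the same sign) and a nominal p with a +1
pseudocount.  Pathway × group NES profiles are z-scored per pathway
(population denominator) for heat-map summaries.

**Differential expression & networks.** Per-gene Welch t with Bonferroni
adjustment; volcano categories (red: adj. p < 0.05 and |log2FC| > 2; dark
blue: 1.5 < |log2FC| ≤ 2; light blue: significant with smaller fold change).
Genes with p < 0.05 and log2FC > 1.5 form the target set whose induced
interaction subgraph (edges kept at score ≥ 0.4) is summarised as
edges/node = E/N and total connection score = Σ edge scores.

## Worked example

```python
from sclc_tme import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1))
print(bundle["phenotypes"]["phenotype"].value_counts())
```

```
oasis        36
desert       15
ambiguous    13
```

Of the 64 synthetic samples (32 patients, primary + matched lymph-node
metastasis), 36 are immune-oasis — every NE-low sample plus the infiltrated
minority of NE-high samples — 15 are immune-desert (all NE-high), and 13
match neither rule.  The enrichment table from the same bundle, restricted
to the module gene sets for the NE-low group:

```
        pathway  group     es    nes     p  padj
IMMUNE_RESPONSE NE-low  0.999  3.056 0.001 0.025
 NEUROENDOCRINE NE-low -0.987 -2.831 0.003 0.025
  PROLIFERATION NE-low -0.992 -3.477 0.003 0.025
```

Immune-response genes concentrate at the NE-low end of the ranking
(NES ≈ +3), proliferation and neuroendocrine programs at the NE-high end —
the separation the cohort was generated with, recovered end to end.  None of
the 20 random decoy sets reaches nominal p < 0.05.

The same stages are available as shell subcommands:

```
sclc-tme simulate --seed 1 --out-dir results
sclc-tme all --seed 1 --out-dir results
```

Short narrative scripts under `examples/` walk through each capability
(cohort simulation, phenotyping, enrichment, targets and networks, full
pipeline).

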