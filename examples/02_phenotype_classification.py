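"""Dichotomize biomarkers and call immune-oasis / immune-desert phenotypes.

Median(+c*MAD) cutoffs turn each compartment-resolved density into a
HIGH/LOW call; the rule-based classifier then labels each sample:
oasis = any CD45 HIGH and any CD3 HIGH; desert = both CD3 LOW and any CD45
LOW; everything else is ambiguous.
"""

import pandas as pd

from sclc_tme import (
    CohortSpec,
    annotate,
    average_replicates,
    classify_phenotypes,
    generate_cohort,
    score_cd33_cores,
)

samples, counts = generate_cohort(CohortSpec(seed=1))
densities = average_replicates(counts)

# continuous markers get cohort MAD cutoffs; CD33 uses the ordinal 0-3 score
continuous = densities[densities["marker"] != "CD33"]
cd33 = score_cd33_cores(counts).rename(columns={"score": "density"})
annotation, cutoffs = annotate(
    pd.concat([continuous, cd33], ignore_index=True), c=0.0
)

print("Cutoffs (median split, c = 0):")
for cut in cutoffs[:4]:
    print(f"  {cut.marker}_{cut.compartment}: threshold {cut.threshold:.1f} "
          f"cells/mm^2 (median {cut.median:.1f}, MAD {cut.mad:.1f})")

phenotypes = classify_phenotypes(annotation)
print("\nPhenotype counts:")
print(phenotypes["phenotype"].value_counts().to_string())

merged = phenotypes.merge(
    samples[["sample_id", "ne_subtype"]], on="sample_id"
)
print("\nPhenotype by NE subtype (oasis tracks NE-low infiltration):")
print(merged.groupby(["ne_subtype", "phenotype"]).size().unstack(fill_value=0))
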