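import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from sclc_tme import (
    CohortSpec,
    PanelSpec,
    average_replicates,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    generate_interactions,
)
from sclc_tme.simulate import NE_HIGH, NE_LOW, fit_factor_loadings


class TestCohortSpec:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            CohortSpec(ne_high_fraction=1.2)

    def test_negative_mean_rejected(self):
        means = dict(CohortSpec().density_means)
        means[("CD68", "stroma", NE_LOW)] = -1.0
        with pytest.raises(ValueError, match="negative"):
            CohortSpec(density_means=means)

    def test_correlation_target_range(self):
        with pytest.raises(ValueError, match="correlation"):
            CohortSpec(
                target_correlations={
                    (("CD68", "stroma"), ("CD163", "stroma")): 1.5
                }
            )

    def test_unsatisfiable_target_rejected_with_diagnostic(self):
        # CD33 counts are tiny; a near-perfect correlation through that much
        # counting noise is impossible and must be rejected, not silently
        # approximated
        spec = CohortSpec(
            target_correlations={
                (("CD33", "tumor_nest"), ("CD3", "tumor_nest")): 0.95
            }
        )
        with pytest.raises(ValueError, match="unattainable|unsatisfiable|PSD"):
            fit_factor_loadings(spec)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_patients=10, seed=42)
        s1, c1 = generate_cohort(spec)
        s2, c2 = generate_cohort(CohortSpec(n_patients=10, seed=42))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(c1, c2)
        s3, _ = generate_cohort(CohortSpec(n_patients=10, seed=43))
        assert not s3["infiltration"].equals(s1["infiltration"])

    def test_replicate_structure(self, small_cohort):
        samples, counts = small_cohort
        merged = counts.merge(samples[["sample_id", "site"]], on="sample_id")
        primary = merged[merged["site"] == "primary"]
        ln = merged[merged["site"] == "ln"]
        assert set(primary["core_id"]) == {"A", "B"}
        assert set(ln["core_id"]) == {"A"}
        per = primary.groupby(["sample_id", "marker", "compartment"]).size()
        assert (per == 4).all()  # 2 cores x 2 sections
        per_ln = ln.groupby(["sample_id", "marker", "compartment"]).size()
        assert (per_ln == 2).all()

    def test_counts_and_areas_valid(self, small_cohort):
        _, counts = small_cohort
        assert (counts["area_um2"] > 0).all()
        assert (counts["cell_count"] >= 0).all()
        assert counts["cell_count"].dtype.kind == "i"

    def test_ne_fraction_recovered(self):
        spec = CohortSpec(n_patients=10_000, ne_high_fraction=0.65, seed=3)
        samples, _ = generate_cohort(spec)
        frac = (
            samples.loc[samples["site"] == "primary", "ne_subtype"] == NE_HIGH
        ).mean()
        assert abs(frac - 0.65) <= 0.02

    def test_ln_labels_mostly_concordant(self):
        spec = CohortSpec(n_patients=2_000, seed=5)
        samples, _ = generate_cohort(spec)
        wide = samples.pivot(index="patient_id", columns="site", values="ne_subtype")
        flip_rate = (wide["primary"] != wide["ln"]).mean()
        assert abs(flip_rate - spec.ln_flip_prob) < 0.03

    def test_realized_spearman_honors_target(self):
        spec = CohortSpec(n_patients=5_000, seed=7)
        _, counts = generate_cohort(spec)
        dens = average_replicates(counts)
        wide = dens.pivot_table(
            index="sample_id", columns=["marker", "compartment"], values="density"
        )
        r = spearmanr(
            wide[("CD68", "tumor_nest")], wide[("CD163", "tumor_nest")]
        ).statistic
        assert abs(r - 0.76) <= 0.05


class TestPanelSpec:
    def test_default_panel_size(self):
        panel = PanelSpec()
        assert len(panel.genes) == 2560
        assert len(set(panel.genes)) == 2560

    def test_assignments_partition(self, small_panel):
        genes = small_panel.genes
        modules = small_panel.module_assignments
        assert set(modules).issubset(set(genes))
        sizes = {m: len(small_panel.module_genes(m)) for m in
                 ("immune", "proliferation", "neuroendocrine")}
        assert sizes == {"immune": 20, "proliferation": 20, "neuroendocrine": 10}

    def test_too_many_assignments_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            PanelSpec(n_genes=10, module_sizes={"immune": 20})

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="unknown modules"):
            PanelSpec(module_assignments={"g1": "stemness"})


class TestGenerateExpression:
    def _module_log2fc(self, expr, panel, module):
        lab = expr.label_series("ne_subtype")
        low = expr.values.loc[:, (lab == NE_LOW).to_numpy()]
        high = expr.values.loc[:, (lab == NE_HIGH).to_numpy()]
        genes = panel.module_genes(module)
        return (low.loc[genes].mean(axis=1) - high.loc[genes].mean(axis=1)).mean()

    def test_deterministic(self, small_cohort, small_panel):
        samples, _ = small_cohort
        e1 = generate_expression(samples, small_panel, seed=9)
        e2 = generate_expression(samples, small_panel, seed=9)
        pd.testing.assert_frame_equal(e1.values, e2.values)

    def test_null_effect_size(self, small_cohort):
        samples, _ = small_cohort
        panel = PanelSpec(
            n_genes=200,
            module_sizes={"immune": 20, "proliferation": 20, "neuroendocrine": 10},
            effect_size=0.0,
        )
        expr = generate_expression(samples, panel, seed=11)
        n_low = (samples["ne_subtype"] == NE_LOW).sum()
        n_high = len(samples) - n_low
        for module in ("immune", "proliferation"):
            n_genes = len(panel.module_genes(module))
            # SE of a module-mean difference of independent unit-ish values
            se = panel.noise_sd * np.sqrt(
                (1 / n_low + 1 / n_high) / n_genes
            ) + panel.patient_sd
            diff = self._module_log2fc(expr, panel, module)
            assert abs(diff) < 3 * se

    def test_immune_shift_recovered(self):
        spec = CohortSpec(n_patients=30, seed=21)
        samples, _ = generate_cohort(spec)
        panel = PanelSpec(
            n_genes=300,
            module_sizes={"immune": 30, "proliferation": 30, "neuroendocrine": 10},
            effect_size=2.0,
            noise_sd=0.5,
        )
        expr = generate_expression(samples, panel, seed=22)
        diff = self._module_log2fc(expr, panel, "immune")
        assert abs(diff - 2.0) <= 0.3

    def test_proliferation_up_in_ne_high(self, small_cohort, small_panel):
        samples, _ = small_cohort
        expr = generate_expression(samples, small_panel, seed=23)
        assert self._module_log2fc(expr, small_panel, "proliferation") < -1.0

    def test_matched_pairs_correlate(self):
        spec = CohortSpec(n_patients=40, seed=31)
        samples, _ = generate_cohort(spec)
        panel = PanelSpec(n_genes=150, module_sizes={"immune": 15,
                          "proliferation": 15, "neuroendocrine": 10})
        expr = generate_expression(samples, panel, seed=32)
        sample_means = expr.values.mean(axis=0)
        meta = samples.set_index("sample_id")
        pri = sample_means[meta["site"] == "primary"].to_numpy()
        ln = sample_means[meta["site"] == "ln"].to_numpy()
        paired = np.corrcoef(pri, ln)[0, 1]
        rng = np.random.default_rng(0)
        shuffled = np.corrcoef(pri, rng.permutation(ln))[0, 1]
        assert paired > shuffled

    def test_missing_labels_rejected(self, small_panel):
        cohort = pd.DataFrame({"sample_id": ["s1"], "patient_id": ["p1"]})
        with pytest.raises(ValueError, match="ne_subtype"):
            generate_expression(cohort, small_panel, seed=1)


class TestGeneSetsAndInteractions:
    def test_sets_subset_of_panel(self, small_panel):
        sets = generate_gene_sets(small_panel, seed=2)
        universe = set(small_panel.genes)
        for members in sets.values():
            assert set(members) <= universe
        assert set(sets["IMMUNE_RESPONSE"]) == set(
            small_panel.module_genes("immune")
        )

    def test_decoys_from_background(self, small_panel):
        sets = generate_gene_sets(small_panel, n_decoys=5, seed=3)
        assigned = set(small_panel.module_assignments)
        for name, members in sets.items():
            if name.startswith("DECOY"):
                assert not (set(members) & assigned)

    def test_zero_density_empty(self, small_panel):
        edges = generate_interactions(small_panel, density=0.0, seed=1)
        assert len(edges) == 0

    def test_scores_in_range(self, small_panel):
        edges = generate_interactions(small_panel, density=0.01, seed=4)
        assert ((edges["score"] > 0.4) & (edges["score"] <= 1.0)).all()
        assert (edges["gene_a"] != edges["gene_b"]).all()

    def test_within_module_fraction_higher(self, small_panel):
        modules = small_panel.module_assignments
        for seed in range(5):
            edges = generate_interactions(small_panel, density=0.01, seed=seed)
            mod_a = edges["gene_a"].map(modules)
            mod_b = edges["gene_b"].map(modules)
            within = (mod_a == mod_b) & mod_a.notna()
            n_members = {m: len(small_panel.module_genes(m)) for m in
                         ("immune", "proliferation", "neuroendocrine")}
            n_within_pairs = sum(k * (k - 1) // 2 for k in n_members.values())
            n_total = len(small_panel.genes) * (len(small_panel.genes) - 1) // 2
            frac_within = within.sum() / n_within_pairs
            frac_across = (~within).sum() / (n_total - n_within_pairs)
            assert frac_within > frac_across
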