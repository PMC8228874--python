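import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sclc_tme import (
    enrichment_score,
    gsea_preranked,
    nes_heatmap_matrix,
    normalize_es,
    rank_genes,
)
from sclc_tme.enrichment import _es_from_hits


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return pd.Series(scores, index=genes, dtype=float)


def _brute_force_es(scores, hit_mask, p):
    """Independent oracle: literal walk of the ranked list."""
    scores = np.abs(np.asarray(scores, dtype=float)) ** p
    n = len(scores)
    n_h = int(np.sum(hit_mask))
    denom_hit = scores[hit_mask].sum()
    if denom_hit == 0:
        denom_hit = float(n_h)
        scores = np.ones(n)
    running = []
    s = 0.0
    for i in range(n):
        if hit_mask[i]:
            s += scores[i] / denom_hit
        else:
            s -= 1.0 / (n - n_h)
        running.append(s)
    running = np.asarray(running)
    # maximal absolute deviation; exact ties broken toward the positive
    # deviation (the package's documented convention)
    hi, lo = float(np.max(running)), float(np.min(running))
    return (hi if hi >= -lo else lo), running


class TestRankGenes:
    def _expr(self, rows):
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))],
            columns=["a1", "a2", "b1", "b2"],
        )

    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_equal_means_score_zero(self):
        expr = self._expr([[1.0, 3.0, 2.0, 2.0]])
        ranked = rank_genes(expr, self.labels, "A", "B")
        assert ranked.iloc[0] == pytest.approx(0.0)

    def test_zero_variance_floored_finite(self):
        expr = self._expr([[2.0, 2.0, 0.0, 0.0]])
        ranked = rank_genes(expr, self.labels, "A", "B")
        # sd floor 0.2*|mean| per group: (2-0)/(0.4 + 0.2) with abs floor 0.2
        assert np.isfinite(ranked.iloc[0])
        assert ranked.iloc[0] == pytest.approx(2.0 / 0.6)

    def test_log2fc_metric(self):
        expr = self._expr([[3.0, 5.0, 1.0, 1.0]])
        ranked = rank_genes(expr, self.labels, "A", "B", metric="log2fc")
        assert ranked.iloc[0] == pytest.approx(3.0)

    def test_tie_break_lexicographic_descending(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0], [5.0, 5.0, 0.0, 0.0]],
            index=["zz", "aa", "mm"],
            columns=["a1", "a2", "b1", "b2"],
        )
        ranked = rank_genes(expr, self.labels, "A", "B", metric="log2fc")
        assert list(ranked.index) == ["mm", "aa", "zz"]

    def test_small_group_rejected(self):
        expr = self._expr([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="2 samples"):
            rank_genes(expr, {"a1": "A", "a2": "B", "b1": "B", "b2": "B"}, "A", "B")

    def test_unknown_metric_rejected(self):
        expr = self._expr([[1.0, 2.0, 3.0, 4.0]])
        with pytest.raises(ValueError, match="metric"):
            rank_genes(expr, self.labels, "A", "B", metric="median_diff")


class TestEnrichmentScore:
    def test_top_gene_unweighted(self):
        ranked = _ranked([4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(ranked, ["g0"], p=0).es == pytest.approx(1.0)

    def test_bottom_gene_unweighted(self):
        ranked = _ranked([4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(ranked, ["g3"], p=0).es == pytest.approx(-1.0)

    def test_five_step_weighted_example(self):
        # scores [5,4,3,2,1], hits at ranks 1 and 3 (p=1):
        # +5/8, -1/3, +3/8, -1/3, -1/3 -> running max 2/3
        ranked = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        res = enrichment_score(ranked, ["g0", "g2"], p=1)
        expected = [5 / 8, 5 / 8 - 1 / 3, 5 / 8 - 1 / 3 + 3 / 8, 1 / 3, 0.0]
        assert res.running_sum == pytest.approx(expected)
        assert res.es == pytest.approx(2 / 3)
        assert res.leading_edge == ["g0", "g2"]

    @pytest.mark.parametrize("p", [0.0, 1.0, 2.0])
    def test_running_sum_returns_to_zero(self, p):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            hits = rng.choice(n, size=k, replace=False)
            ranked = _ranked(scores)
            res = enrichment_score(ranked, [f"g{i}" for i in hits], p=p)
            assert abs(res.running_sum[-1]) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.exponential(size=30))[::-1]
        hits = [f"g{i}" for i in rng.choice(30, size=6, replace=False)]
        for p in (0.0, 1.0, 1.5):
            es1 = enrichment_score(_ranked(scores), hits, p=p).es
            es2 = enrichment_score(_ranked(scores * 7.3), hits, p=p).es
            assert es1 == pytest.approx(es2)

    def test_unweighted_matches_ks_oracle(self):
        # classical KS statistic on 200 random instances, N <= 50
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            hit_idx = np.sort(rng.choice(n, size=k, replace=False))
            hit_mask = np.zeros(n, dtype=bool)
            hit_mask[hit_idx] = True
            expected, _ = _brute_force_es(scores, hit_mask, p=0)
            got = enrichment_score(
                _ranked(scores), [f"g{i}" for i in hit_idx], p=0
            ).es
            assert got == pytest.approx(expected)

    def test_fast_path_matches_full_walk(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            hit_idx = np.sort(rng.choice(n, size=k, replace=False))
            w = np.abs(scores)[hit_idx]
            full_mask = np.zeros(n, dtype=bool)
            full_mask[hit_idx] = True
            expected, _ = _brute_force_es(scores, full_mask, p=1)
            got = _es_from_hits(hit_idx, w, n, k)
            assert got == pytest.approx(expected)

    def test_degenerate_sets_rejected(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="disjoint"):
            enrichment_score(ranked, ["nope"])
        with pytest.raises(ValueError, match="universe"):
            enrichment_score(ranked, ["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="p must be"):
            enrichment_score(ranked, ["g0"], p=-1)


class TestNormalizeES:
    def test_sign_consistency_and_determinism(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(size=100))[::-1]
        ranked = _ranked(scores)
        for hits in (range(0, 10), range(90, 100)):
            members = [f"g{i}" for i in hits]
            r1 = normalize_es(ranked, members, n_perm=200, seed=9)
            r2 = normalize_es(ranked, members, n_perm=200, seed=9)
            assert r1 == r2
            assert np.sign(r1["nes"]) == np.sign(r1["es"])
            assert 0 < r1["p"] <= 1

    def test_enriched_set_detected(self):
        rng = np.random.default_rng(6)
        scores = np.sort(rng.normal(size=200))[::-1]
        ranked = _ranked(scores)
        top = [f"g{i}" for i in range(15)]
        res = normalize_es(ranked, top, n_perm=300, seed=1)
        assert res["nes"] > 1
        assert res["p"] < 0.05

    def test_min_permutations_enforced(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5])
        with pytest.raises(ValueError, match="n_perm"):
            normalize_es(ranked, ["g0"], n_perm=10)

    def test_null_p_values_uniform(self):
        # decoy sets on exchangeable scores: nominal p ~ U(0,1)
        rng = np.random.default_rng(31)
        scores = np.sort(rng.normal(size=300))[::-1]
        ranked = _ranked(scores)
        pvals = []
        for _ in range(1000):
            members = [f"g{i}" for i in rng.choice(300, size=20, replace=False)]
            pvals.append(
                normalize_es(ranked, members, n_perm=200, seed=rng)["p"]
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestHeatmapMatrix:
    def test_two_group_z_population_sd(self):
        res = pd.DataFrame(
            {
                "pathway": ["p1", "p1"],
                "group": ["A", "B"],
                "nes": [2.0, -2.0],
            }
        )
        z = nes_heatmap_matrix(res)
        assert z.loc["p1", "A"] == pytest.approx(1.0)
        assert z.loc["p1", "B"] == pytest.approx(-1.0)

    def test_constant_row_zeroed(self):
        res = pd.DataFrame(
            {
                "pathway": ["p1"] * 3,
                "group": ["A", "B", "C"],
                "nes": [1.5, 1.5, 1.5],
            }
        )
        z = nes_heatmap_matrix(res)
        assert (z.loc["p1"] == 0).all()

    def test_threshold_filter(self):
        res = pd.DataFrame(
            {
                "pathway": ["weak", "weak", "strong", "strong"],
                "group": ["A", "B", "A", "B"],
                "nes": [0.5, -0.3, 2.2, -1.9],
            }
        )
        z = nes_heatmap_matrix(res, nes_threshold=1.0)
        assert list(z.index) == ["strong"]

    def test_single_group_rejected(self):
        res = pd.DataFrame({"pathway": ["p1"], "group": ["A"], "nes": [2.0]})
        with pytest.raises(ValueError, match="2 groups"):
            nes_heatmap_matrix(res)


class TestGseaPreranked:
    def test_collection_run(self, small_expression):
        expr = small_expression
        labels = expr.label_series("ne_subtype").to_dict()
        ranked = rank_genes(expr.values, labels, "NE-low", "NE-high")
        sets = {
            "top": list(ranked.index[:10]),
            "tiny": list(ranked.index[:1]),  # dropped: below min_size
            "mid": list(ranked.index[50:80]),
        }
        res = gsea_preranked(ranked, sets, n_perm=150, seed=3)
        assert set(res["pathway"]) == {"top", "mid"}
        assert ((res["padj"] >= res["p"] - 1e-12)).all()
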