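"""Preranked gene-set enrichment analysis (weighted KS running-sum statistic).

Implements the classical GSEA statistic from first principles: genes are
ranked by a differential metric between two sample groups, a weighted
Kolmogorov-Smirnov running sum walks the ranked list, and the enrichment
score (ES) is normalized against a gene-label permutation null to give an
NES and nominal p-value.  Pathway-by-group NES profiles are then z-scored
per pathway for heat-map style summaries.

Running-sum definition (weight exponent ``p >= 0``): at a gene in the set
("hit") the sum increases by ``|score|**p / sum_hits |score|**p``; at a gene
outside the set ("miss") it decreases by ``1 / (N - N_h)``.  The ES is the
running-sum value of maximal absolute deviation from zero; the sum always
returns to zero at the end of the list.  ``p = 0`` recovers the unweighted
(classical KS) statistic.

The permutation null resamples ``|S|`` gene labels uniformly without
replacement, matching the null used by preranked fgsea-style tools rather
than a phenotype-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

RANK_METRICS = ("signal_to_noise", "t_stat", "log2fc")


def rank_genes(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    metric: str = "signal_to_noise",
) -> pd.Series:
    """Per-gene ranking scores for group_a vs group_b, sorted descending.

    Positive scores mean higher expression in ``group_a``.  Ties are broken
    by gene identifier (lexicographic), so the ordering is fully
    deterministic.

    Parameters
    ----------
    expr :
        genes x samples log-scale expression DataFrame.
    labels :
        sample -> group assignment.
    metric :
        ``signal_to_noise`` (difference of means over the sum of standard
        deviations, each sd floored at ``0.2 * |group mean|`` with an absolute
        floor of 0.2, the GSEA convention), ``t_stat`` (Welch t), or
        ``log2fc`` (difference of means of the log-scale values).
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    a_cols = [s for s in expr.columns if labels.get(s) == group_a]
    b_cols = [s for s in expr.columns if labels.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(a_cols)} vs {len(b_cols)})"
        )
    a = expr[a_cols].to_numpy(dtype=float)
    b = expr[b_cols].to_numpy(dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    if metric == "log2fc":
        score = ma - mb
    else:
        sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
        if metric == "signal_to_noise":
            sa = np.maximum(sa, np.maximum(0.2 * np.abs(ma), 0.2))
            sb = np.maximum(sb, np.maximum(0.2 * np.abs(mb), 0.2))
            score = (ma - mb) / (sa + sb)
        else:  # Welch t with a small variance floor for degenerate genes
            se = np.sqrt(
                np.maximum(sa**2, 1e-12) / len(a_cols)
                + np.maximum(sb**2, 1e-12) / len(b_cols)
            )
            score = (ma - mb) / se
    out = pd.Series(score, index=expr.index, name=metric)
    # descending by score, gene id as deterministic tie-break
    order = sorted(out.index, key=lambda g: (-out[g], str(g)))
    return out.loc[order]


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list = field(default_factory=list)


def _hit_increments(abs_scores: np.ndarray, hit_mask: np.ndarray, p: float):
    w = abs_scores[hit_mask] ** p
    total = w.sum()
    if total == 0:
        # every hit has score 0: fall back to equal weights
        w = np.ones_like(w)
        total = w.sum()
    return w / total


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], p: float = 1.0
) -> ESResult:
    """Weighted KS enrichment score with the full running sum.

    ``ranked`` is a descending-ordered Series of ranking scores indexed by
    gene.  Raises if the set is disjoint from the ranked universe or covers
    it entirely (the miss decrement would be undefined).
    """
    if p < 0:
        raise ValueError("weight exponent p must be >= 0")
    genes = ranked.index
    n = len(genes)
    hit_mask = np.asarray(genes.isin(set(gene_set)))
    n_h = int(hit_mask.sum())
    if n_h == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    if n_h == n:
        raise ValueError("gene set covers the whole universe; ES undefined")
    abs_scores = np.abs(ranked.to_numpy(dtype=float))
    steps = np.full(n, -1.0 / (n - n_h))
    steps[hit_mask] = _hit_increments(abs_scores, hit_mask, p)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        le = [g for g, h in zip(genes[: i_max + 1], hit_mask[: i_max + 1]) if h]
    else:
        es = float(running[i_min])
        le = [g for g, h in zip(genes[i_min:], hit_mask[i_min:]) if h]
    return ESResult(es=es, running_sum=running, leading_edge=le)


def _es_from_hits(
    hit_idx: np.ndarray, weights: np.ndarray, n: int, n_h: int
) -> float:
    """ES from sorted hit positions only (O(n_h)); used for permutations.

    ``weights`` are the (unnormalized) hit increments in hit order.  The
    running sum is piecewise linear and decreasing between hits, so its
    extrema occur right after a hit (candidate maxima) or right before one
    (candidate minima).
    """
    total = weights.sum()
    if total == 0:
        weights = np.ones_like(weights)
        total = weights.sum()
    cum_w = np.cumsum(weights) / total
    miss = 1.0 / (n - n_h)
    # number of misses strictly before hit t: hit_idx[t] - t
    misses_before = (hit_idx - np.arange(n_h)) * miss
    after_hit = cum_w - misses_before  # value right after each hit
    before_hit = after_hit - weights / total  # value right before each hit
    hi = after_hit.max()
    lo = min(before_hit.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def normalize_es(
    ranked: pd.Series,
    gene_set: Sequence[str],
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Gene-label permutation NES and nominal p for one set.

    ``n_perm`` random same-size gene sets are drawn without replacement from
    the universe; NES = ES / mean(|null ES| of the same sign); nominal
    p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}).
    When the null produces no same-sign ES the result is flagged unstable and
    normalized against the unsigned null mean instead.

    Returns a dict with keys ``es, nes, p, leading_edge, n_hits, unstable``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    res = enrichment_score(ranked, gene_set, p=p)
    es = res.es
    n = len(ranked)
    hit_mask = np.asarray(ranked.index.isin(set(gene_set)))
    n_h = int(hit_mask.sum())
    abs_scores = np.abs(ranked.to_numpy(dtype=float)) ** p
    # draw all permutation index sets at once (uniform without replacement)
    u = rng.random((n_perm, n))
    idx_mat = np.argpartition(u, n_h - 1, axis=1)[:, :n_h]
    idx_mat.sort(axis=1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = idx_mat[i]
        null[i] = _es_from_hits(idx, abs_scores[idx], n, n_h)
    if es == 0:
        return {
            "es": 0.0,
            "nes": 0.0,
            "p": 1.0,
            "leading_edge": res.leading_edge,
            "n_hits": n_h,
            "unstable": False,
        }
    same = null[np.sign(null) == np.sign(es)]
    unstable = len(same) == 0
    denom = np.abs(same).mean() if not unstable else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    if unstable:
        pval = 1.0 / (n_perm + 1)
    else:
        pval = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
    return {
        "es": es,
        "nes": float(nes),
        "p": float(pval),
        "leading_edge": res.leading_edge,
        "n_hits": n_h,
        "unstable": unstable,
    }


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Run preranked GSEA over a gene-set collection.

    Sets are first intersected with the ranked universe; those smaller than
    ``min_size`` (or covering the whole universe) are dropped.  Adjusted
    p-values are Benjamini-Hochberg across the retained pathways.

    Returns a DataFrame ``pathway, es, nes, p, padj, n_hits, leading_edge_size``.
    """
    rng = np.random.default_rng(seed)
    universe = set(ranked.index)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        if len(members) < min_size or len(members) >= len(universe):
            continue
        r = normalize_es(ranked, members, p=p, n_perm=n_perm, seed=rng)
        rows.append(
            {
                "pathway": name,
                "es": r["es"],
                "nes": r["nes"],
                "p": r["p"],
                "n_hits": r["n_hits"],
                "leading_edge_size": len(r["leading_edge"]),
                "unstable": r["unstable"],
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["padj"] = []
    return out


def nes_heatmap_matrix(
    results: pd.DataFrame, nes_threshold: float = 1.0
) -> pd.DataFrame:
    """Pathway x group matrix of z-scored NES values.

    ``results`` is a long table with columns ``pathway, group, nes``.
    Pathways whose maximal |NES| across groups does not exceed the threshold
    are dropped; each retained pathway's NES profile is z-scored across
    groups with the population (n) denominator.  A pathway with identical
    NES in every group gets a zero row.
    """
    for col in ("pathway", "group", "nes"):
        if col not in results.columns:
            raise ValueError(f"results must have a {col!r} column")
    wide = results.pivot_table(index="pathway", columns="group", values="nes")
    if wide.shape[1] < 2:
        raise ValueError("need >= 2 groups to z-score pathways")
    keep = wide.abs().max(axis=1) > nes_threshold
    wide = wide.loc[keep]
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=0)
    z = wide.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z
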