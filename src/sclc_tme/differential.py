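"""Per-gene differential expression, volcano categorization, set overlaps.

Each gene of the log2-scale panel is tested between two sample groups with
Welch's t-test (optionally with a simple empirical-Bayes shrinkage of the
gene-level variances toward their cohort mean), p-values are Bonferroni
adjusted over the number of tested genes, and genes are categorized with the
volcano color rules:

* ``red`` - significant and |log2FC| > 2
* ``darkblue`` - significant and 1.5 < |log2FC| <= 2
* ``lightblue`` - significant and |log2FC| <= 1.5
* ``ns`` - not significant

"Significant" means the (by default Bonferroni-adjusted) p is below 0.05.
Boundary values are read literally from the strict inequalities: |log2FC|
exactly 2 is darkblue, exactly 1.5 is lightblue.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("red", "darkblue", "lightblue", "ns")

#: variance floor so zero-variance genes give finite statistics
VAR_FLOOR = 1e-12


def de_test(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    group_a: str,
    group_b: str,
    shrink_var: bool = False,
    p_threshold: float = 0.05,
    fc_low: float = 1.5,
    fc_high: float = 2.0,
    use_adjusted_p: bool = True,
) -> pd.DataFrame:
    """Welch two-sample test per gene; log2fc = mean(group_a) - mean(group_b).

    Parameters
    ----------
    expr :
        genes x samples log2-scale expression.
    shrink_var :
        If True, gene variances are shrunk halfway toward the across-gene
        mean variance before forming the t statistic (a light-weight
        moderated-t; the full hierarchical fit is deliberately not
        reimplemented).
    use_adjusted_p :
        Categorize on the Bonferroni-adjusted p (default) or the raw p.

    Returns
    -------
    DataFrame indexed by gene with columns
    ``log2fc, t, p_raw, p_adj, category``.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    a_cols = [s for s in expr.columns if labels.get(s) == group_a]
    b_cols = [s for s in expr.columns if labels.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(a_cols)} vs {len(b_cols)})"
        )
    a = expr[a_cols].to_numpy(dtype=float)
    b = expr[b_cols].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if shrink_var:
        va = 0.5 * va + 0.5 * va.mean()
        vb = 0.5 * vb + 0.5 * vb.mean()
    va = np.maximum(va, VAR_FLOOR)
    vb = np.maximum(vb, VAR_FLOOR)
    lfc = ma - mb
    se2 = va / na + vb / nb
    t = lfc / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p_raw = 2 * stats.t.sf(np.abs(t), df)
    # genes with no variance and no mean difference carry no evidence
    degenerate = (se2 <= 2 * VAR_FLOOR) & (lfc == 0)
    p_raw = np.where(degenerate, 1.0, p_raw)
    m = len(expr)
    p_adj = np.minimum(1.0, m * p_raw)
    out = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p_raw": p_raw, "p_adj": p_adj}, index=expr.index
    )
    p_for_cat = out["p_adj"] if use_adjusted_p else out["p_raw"]
    out["category"] = [
        volcano_classify(l, p, p_threshold, fc_low, fc_high)
        for l, p in zip(out["log2fc"], p_for_cat)
    ]
    return out


def volcano_classify(
    log2fc: float,
    p: float,
    p_threshold: float = 0.05,
    fc_low: float = 1.5,
    fc_high: float = 2.0,
) -> str:
    """Volcano color category for one gene.

    Strict inequalities on |log2FC|: above ``fc_high`` is red, strictly
    between the bounds is darkblue, otherwise (significant) lightblue.
    """
    if not (np.isfinite(log2fc) and np.isfinite(p)):
        return "ns"
    if p >= p_threshold:
        return "ns"
    alfc = abs(log2fc)
    if alfc > fc_high:
        return "red"
    if alfc > fc_low:
        return "darkblue"
    return "lightblue"


def target_overlap(
    set_a: Sequence[str], set_b: Sequence[str]
) -> tuple[set, set, set]:
    """Three-way partition (a_only, shared, b_only) of two target gene sets."""
    sa, sb = set(set_a), set(set_b)
    return sa - sb, sa & sb, sb - sa


def overlap_report(sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise overlap table for a family of named target sets."""
    names = sorted(sets)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            a_only, shared, b_only = target_overlap(sets[na], sets[nb])
            rows.append(
                {
                    "set_a": na,
                    "set_b": nb,
                    "a_only": len(a_only),
                    "shared": len(shared),
                    "b_only": len(b_only),
                    "shared_genes": ",".join(sorted(shared)),
                }
            )
    return pd.DataFrame(rows)
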