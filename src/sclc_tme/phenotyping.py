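"""MAD-based biomarker dichotomization and immune-phenotype classification.

Continuous biomarkers (compartment-resolved cell densities) are dichotomized
at ``median + c * MAD`` of the cohort distribution; ordinal scores (CD33,
MHCII) are HIGH for scores 2-3 and LOW for 0-1.  Per-sample HIGH/LOW calls
over CD45 and CD3 in stroma and tumor nests then classify samples as
immune-oasis, immune-desert, or ambiguous, and macrophage-related calls
(CD68, CD163, CD33, MHCII) classify macrophage-high vs -low tumors.

The oasis/desert rule:

* **oasis** - HIGH for stromal *or* intratumoral CD45, and HIGH for stromal
  *or* intratumoral CD3;
* **desert** - LOW for *both* stromal and intratumoral CD3, and LOW for
  stromal *or* intratumoral CD45;
* anything else (including missing required calls) is **ambiguous**.

The two rules are mutually exclusive by construction: oasis requires some
CD3 HIGH, desert requires no CD3 HIGH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HIGH = "HIGH"
LOW = "LOW"
MISSING = "missing"

OASIS = "oasis"
DESERT = "desert"
AMBIGUOUS = "ambiguous"

#: biomarkers the default macrophage rule inspects (marker, compartment)
MACROPHAGE_PARAMS = (
    ("CD68", "stroma"),
    ("CD68", "tumor_nest"),
    ("CD163", "stroma"),
    ("CD163", "tumor_nest"),
    ("CD33", "stroma"),
    ("MHCII", "tumor_nest"),
)


@dataclass(frozen=True)
class Cutoff:
    """Dichotomization threshold for one (marker, compartment) biomarker."""

    marker: str
    compartment: str
    threshold: float
    c: float = 0.0
    mad: float = float("nan")
    median: float = float("nan")


def mad_cutoff(
    values: Iterable[float],
    c: float = 0.0,
    marker: str = "",
    compartment: str = "",
) -> Cutoff:
    """Threshold at ``median(values) + c * MAD(values)``.

    MAD is the raw median absolute deviation ``median(|x - median(x)|)``
    (no normal-consistency scaling).  The default ``c = 0`` is a median
    split; ``c`` is exposed because the multiplier used for the published
    cutoffs is not stated.

    NaNs are dropped; at least two finite values are required.  If all values
    are identical a warning is emitted (the dichotomization is degenerate:
    every value ties with the threshold and is called LOW).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("mad_cutoff needs at least 2 finite values")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    if np.ptp(arr) == 0:
        warnings.warn(
            "all values identical; threshold is degenerate and every sample "
            "will be called LOW",
            stacklevel=2,
        )
    return Cutoff(
        marker=marker,
        compartment=compartment,
        threshold=med + c * mad,
        c=c,
        mad=mad,
        median=med,
    )


def dichotomize(value, cutoff: Cutoff | float | None = None, *, ordinal: bool = False):
    """HIGH/LOW call for one value.

    Continuous values are HIGH iff strictly above the threshold (a value
    exactly at the threshold is LOW).  Ordinal 0-3 scores ignore the cutoff:
    HIGH iff the score is 2 or 3.  Missing values (None/NaN) stay missing.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if ordinal:
        return HIGH if value >= 2 else LOW
    thr = cutoff.threshold if isinstance(cutoff, Cutoff) else float(cutoff)
    return HIGH if value > thr else LOW


def annotate(
    densities: pd.DataFrame,
    c: float = 0.0,
    ordinal_markers: Sequence[str] = ("CD33", "MHCII"),
    cutoff_samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[Cutoff]]:
    """Per-sample HIGH/LOW annotation table from a long density/score table.

    Parameters
    ----------
    densities :
        Long table ``sample_id, marker, compartment, density`` (ordinal
        markers may carry their score in the same column).
    c :
        MAD multiplier for the continuous cutoffs.
    ordinal_markers :
        Markers dichotomized by the fixed score >= 2 rule instead of a
        cohort cutoff.
    cutoff_samples :
        Optional subset of sample_ids on which cutoffs are computed (e.g.
        primary tumors only); calls are still made for every sample.

    Returns
    -------
    (annotation, cutoffs)
        ``annotation`` is a wide DataFrame indexed by sample_id with one
        ``marker_compartment`` column per biomarker, entries HIGH/LOW/missing.
    """
    cutoffs: list[Cutoff] = []
    wide = densities.pivot_table(
        index="sample_id",
        columns=["marker", "compartment"],
        values=densities.columns[-1] if "density" not in densities else "density",
        aggfunc="first",
    )
    calls = {}
    for marker, compartment in wide.columns:
        col = wide[(marker, compartment)]
        name = f"{marker}_{compartment}"
        if marker in ordinal_markers:
            calls[name] = col.map(lambda v: dichotomize(v, ordinal=True))
        else:
            basis = col
            if cutoff_samples is not None:
                basis = col.loc[col.index.intersection(list(cutoff_samples))]
            cut = mad_cutoff(
                basis.dropna(), c=c, marker=marker, compartment=compartment
            )
            cutoffs.append(cut)
            calls[name] = col.map(lambda v, _cut=cut: dichotomize(v, _cut))
    ann = pd.DataFrame(calls, index=wide.index)
    ann.index.name = "sample_id"
    return ann.fillna(MISSING), cutoffs


def _is_high(call) -> bool:
    return call == HIGH


def _is_low(call) -> bool:
    return call == LOW


def classify_immune_phenotype(calls: Mapping[str, str]) -> tuple[str, str]:
    """Immune-oasis / immune-desert / ambiguous phenotype for one sample.

    ``calls`` maps biomarker names (``CD45_stroma``, ``CD45_tumor_nest``,
    ``CD3_stroma``, ``CD3_tumor_nest``) to HIGH/LOW/missing.

    Returns ``(phenotype, reason)`` where reason explains ambiguous calls.
    """
    required = ("CD45_stroma", "CD45_tumor_nest", "CD3_stroma", "CD3_tumor_nest")
    got = {k: calls.get(k, MISSING) for k in required}
    absent = [k for k, v in got.items() if v == MISSING]
    if absent:
        return AMBIGUOUS, f"missing calls: {','.join(absent)}"
    cd45_any_high = _is_high(got["CD45_stroma"]) or _is_high(got["CD45_tumor_nest"])
    cd45_any_low = _is_low(got["CD45_stroma"]) or _is_low(got["CD45_tumor_nest"])
    cd3_any_high = _is_high(got["CD3_stroma"]) or _is_high(got["CD3_tumor_nest"])
    cd3_both_low = _is_low(got["CD3_stroma"]) and _is_low(got["CD3_tumor_nest"])
    if cd45_any_high and cd3_any_high:
        return OASIS, ""
    if cd3_both_low and cd45_any_low:
        return DESERT, ""
    return AMBIGUOUS, "matches neither rule"


def classify_phenotypes(annotation: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify_immune_phenotype` to every row of an annotation
    table; returns ``sample_id, phenotype, reason``."""
    rows = []
    for sample_id, row in annotation.iterrows():
        pheno, reason = classify_immune_phenotype(row.to_dict())
        rows.append({"sample_id": sample_id, "phenotype": pheno, "reason": reason})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MacrophageRule:
    """Configurable rule for the macrophage-high/-low grouping.

    ``macrophage_high`` iff the number of HIGH calls among the available
    (non-missing) parameters is at least ``min_fraction`` of them.
    """

    params: tuple = MACROPHAGE_PARAMS
    min_fraction: float = 0.5

    @property
    def param_names(self) -> list[str]:
        return [f"{m}_{c}" for m, c in self.params]


def macrophage_class(
    calls: Mapping[str, str], rule: MacrophageRule | None = None
) -> str:
    """``macrophage_high`` / ``macrophage_low`` for one sample.

    Counts HIGH calls among the rule's available macrophage-related
    parameters; raises if every parameter is missing.
    """
    rule = rule or MacrophageRule()
    available = [
        calls[name]
        for name in rule.param_names
        if calls.get(name, MISSING) != MISSING
    ]
    if not available:
        raise ValueError("no macrophage-related calls available")
    n_high = sum(1 for v in available if v == HIGH)
    frac = n_high / len(available)
    return "macrophage_high" if frac >= rule.min_fraction else "macrophage_low"
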