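"""Compartment-resolved cell-count morphometry.

Converts manual cell counts on TMA core sections into cell densities
(cells/mm**2), averages technical replicates in two stages (sections within a
core, then cores within a sample), assigns the semi-quantitative 0-3 CD33
score, and summarises the immune-cell composition of a compartment relative
to the pan-leukocyte CD45 density.

Input tables are tidy pandas DataFrames with one row per counted section::

    sample_id  core_id  section_id  marker  compartment  cell_count  area_um2

``compartment`` is one of ``stroma`` / ``tumor_nest``.  A compartment absent
from a core (e.g. a punch with no stromal tissue) is simply absent from the
table; it must never be encoded as a zero count over a fabricated area.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

COMPARTMENTS = ("stroma", "tumor_nest")

#: square micrometers per square millimeter
UM2_PER_MM2 = 1e6

COUNT_COLUMNS = [
    "sample_id",
    "core_id",
    "section_id",
    "marker",
    "compartment",
    "cell_count",
    "area_um2",
]


def cell_density(cell_count, area_um2):
    """Cell density in cells/mm**2 from a count over a measured area in um**2.

    Parameters
    ----------
    cell_count : int or array-like
        Non-negative number of positive cells counted in the compartment.
    area_um2 : float or array-like
        Measured compartment area in square micrometers; must be > 0.

    Returns
    -------
    float or ndarray
        ``cell_count / (area_um2 * 1e-6)``.
    """
    count = np.asarray(cell_count, dtype=float)
    area = np.asarray(area_um2, dtype=float)
    if np.any(count < 0):
        raise ValueError("cell_count must be non-negative")
    if np.any(~(area > 0)):
        raise ValueError(
            "area_um2 must be strictly positive; a zero or negative area "
            "indicates an invalid compartment annotation"
        )
    dens = count / (area / UM2_PER_MM2)
    if dens.ndim == 0:
        return float(dens)
    return dens


def validate_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a compartment-count table and return it with typed columns."""
    missing = [c for c in COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    out = records.copy()
    out["cell_count"] = pd.to_numeric(out["cell_count"])
    out["area_um2"] = pd.to_numeric(out["area_um2"])
    if (out["cell_count"] < 0).any():
        bad = out.index[out["cell_count"] < 0].tolist()[:5]
        raise ValueError(f"negative cell_count at rows {bad}")
    if (out["area_um2"] <= 0).any():
        bad = out.index[out["area_um2"] <= 0].tolist()[:5]
        raise ValueError(f"non-positive area_um2 at rows {bad}")
    bad_comp = set(out["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartments: {sorted(bad_comp)}")
    return out


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Two-stage replicate averaging of section counts into sample densities.

    Section-level densities are averaged within each core, and core means are
    then averaged (unweighted) within each sample, yielding one density per
    (sample_id, marker, compartment).  Combinations absent from the input stay
    absent from the output rather than appearing as zero.

    Returns
    -------
    DataFrame
        Columns ``sample_id, marker, compartment, density`` (cells/mm**2).
    """
    rec = validate_counts(records)
    rec = rec.assign(density=cell_density(rec["cell_count"], rec["area_um2"]))
    keys = ["sample_id", "marker", "compartment"]
    core_means = (
        rec.groupby(keys + ["core_id"], sort=True)["density"].mean().reset_index()
    )
    sample_means = core_means.groupby(keys, sort=True)["density"].mean().reset_index()
    return sample_means


# CD33 score bins: 0 cells -> 0, 1-10 -> 1, 11-20 -> 2, 21 or more -> 3.
_CD33_EDGES = (0, 10, 20)


def cd33_score(cell_count):
    """Semi-quantitative 0-3 CD33 score from a raw cell count.

    The bins partition the non-negative integers: 0 -> 0, 1-10 -> 1,
    11-20 -> 2, >= 21 -> 3 (a count of exactly 21 scores 3).
    """
    count = np.asarray(cell_count)
    if np.any(count < 0):
        raise ValueError("cell_count must be non-negative")
    score = np.searchsorted(_CD33_EDGES, count, side="left")
    if score.ndim == 0:
        return int(score)
    return score.astype(int)


def score_cd33_cores(records: pd.DataFrame, marker: str = "CD33") -> pd.DataFrame:
    """Score CD33 counts per core compartment, then take the per-sample
    maximum score across cores (a sample is as myeloid-infiltrated as its
    most infiltrated core).

    Returns a DataFrame ``sample_id, marker, compartment, score``.
    """
    rec = validate_counts(records)
    rec = rec[rec["marker"] == marker]
    keys = ["sample_id", "marker", "compartment"]
    # section counts of the same core are averaged (rounded) before binning,
    # mirroring the replicate handling for densities
    core_counts = (
        rec.groupby(keys + ["core_id"], sort=True)["cell_count"].mean().reset_index()
    )
    core_counts["score"] = cd33_score(np.rint(core_counts["cell_count"]).astype(int))
    out = core_counts.groupby(keys, sort=True)["score"].max().reset_index()
    return out


def composition(
    densities: pd.DataFrame,
    compartment: str,
    group_labels: Mapping[str, str],
    reference_marker: str = "CD45",
    mode: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Immune-cell composition fractions relative to a reference marker.

    For each group of samples, the fraction of the reference (CD45+) immune
    pool attributable to each marker within one compartment.  Markers overlap
    biologically (CD163+ cells are a subset of CD68+ cells), so fractions are
    reported per marker and need not sum to 1.

    Parameters
    ----------
    densities :
        Output of :func:`average_replicates`.
    compartment :
        ``stroma`` or ``tumor_nest``.
    group_labels :
        Mapping sample_id -> group label (e.g. NE subtype).  Samples absent
        from the mapping are excluded.
    mode :
        ``ratio_of_sums`` (default): group-summed marker density over
        group-summed reference density.  ``mean_of_ratios``: per-sample
        marker/reference ratio averaged within the group.

    Returns
    -------
    DataFrame
        Columns ``group, marker, fraction, n``; rows where the reference
        aggregate is zero carry ``fraction = NaN`` and are flagged in the
        boolean ``undefined`` column.
    """
    if mode not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError(f"unknown composition mode: {mode!r}")
    sub = densities[densities["compartment"] == compartment].copy()
    sub["group"] = sub["sample_id"].map(group_labels)
    sub = sub.dropna(subset=["group"])
    wide = sub.pivot_table(
        index=["group", "sample_id"], columns="marker", values="density"
    )
    if reference_marker not in wide.columns:
        raise ValueError(f"reference marker {reference_marker!r} absent")
    rows = []
    markers = [m for m in wide.columns if m != reference_marker]
    for group, block in wide.groupby(level="group", sort=True):
        ref = block[reference_marker]
        for marker in markers:
            pair = block[[marker, reference_marker]].dropna()
            n = len(pair)
            if mode == "ratio_of_sums":
                denom = pair[reference_marker].sum()
                frac = pair[marker].sum() / denom if denom > 0 else np.nan
            else:
                ok = pair[pair[reference_marker] > 0]
                frac = (
                    (ok[marker] / ok[reference_marker]).mean() if len(ok) else np.nan
                )
            rows.append(
                {
                    "group": group,
                    "marker": marker,
                    "fraction": frac,
                    "n": n,
                    "undefined": not np.isfinite(frac) if frac == frac else True,
                }
            )
    out = pd.DataFrame(rows)
    out["undefined"] = ~np.isfinite(out["fraction"].astype(float))
    return out
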