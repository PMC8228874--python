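"""Synthetic SCLC-like cohorts: counts, expression, gene sets, interactions.

The generator emulates the structure of a limited-stage SCLC tissue-microarray
study: ~32 patients, each contributing a primary tumor (two 1-mm cores, two
sections counted per core) and a matched lymph-node metastasis (one core, two
sections); samples carry NE-low / NE-high neuroendocrine subtype labels; five
immune markers (CD68, CD163, CD33, CD45, CD3) are counted per compartment
(stroma / tumor nest); and a targeted oncology panel of 2560 log2-scale gene
expression features is measured per sample.

Density model
-------------
Per-sample true log densities follow a one-factor model

    x[v] = mu[v, subtype] + lambda[v] * f + sigma[v] * eps[v]

with a single latent "infiltration" factor ``f`` per sample shared by all
markers, a subtype-specific mean (calibrated to the published group means),
and within-subtype biological noise of total log-sd ``log_sigma``.
Pairwise rank-correlation targets are honored by fitting the loadings
``lambda`` in log space, after (a) subtracting the correlation already
induced by the NE-subtype mean shifts and (b) inflating for the attenuation
caused by negative-binomial counting noise, so that the *realized* Spearman
correlation of measured densities matches the target.  Targets that would
require a non-positive-semi-definite latent correlation matrix, or loadings
larger than the within-subtype spread, are rejected with a diagnostic.

Observed counts are negative-binomial with mean = true density x measured
area (areas are log-normally jittered around compartment-typical values), so
density estimates carry realistic integer sampling noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import COUNT_COLUMNS

NE_LOW = "NE-low"
NE_HIGH = "NE-high"
SITES = ("primary", "ln")
DEFAULT_MARKERS = ("CD68", "CD163", "CD33", "CD45", "CD3")
COMPARTMENTS = ("stroma", "tumor_nest")

# Cohort-level density means (cells/mm^2) per (marker, compartment, subtype).
# CD68/CD163 values are the published group means; CD45/CD3 are derived from
# the published composition fractions (CD68 = 64%/71% of CD45 in tumor nests,
# CD3 = 38%/18%; stromal fractions do not differ by subtype).  CD33 stromal
# densities are chosen so expected per-core counts land in the 0-3 score bins.
DEFAULT_DENSITY_MEANS: dict[tuple[str, str, str], float] = {
    ("CD68", "stroma", NE_LOW): 625.0,
    ("CD68", "stroma", NE_HIGH): 305.0,
    ("CD163", "stroma", NE_LOW): 523.0,
    ("CD163", "stroma", NE_HIGH): 290.0,
    ("CD68", "tumor_nest", NE_LOW): 101.0,
    ("CD68", "tumor_nest", NE_HIGH): 28.0,
    ("CD163", "tumor_nest", NE_LOW): 54.0,
    ("CD163", "tumor_nest", NE_HIGH): 9.0,
    ("CD33", "stroma", NE_LOW): 50.0,
    ("CD33", "stroma", NE_HIGH): 17.0,
    ("CD33", "tumor_nest", NE_LOW): 3.0,
    ("CD33", "tumor_nest", NE_HIGH): 1.5,
    ("CD45", "stroma", NE_LOW): 1042.0,
    ("CD45", "stroma", NE_HIGH): 508.0,
    ("CD45", "tumor_nest", NE_LOW): 158.0,
    ("CD45", "tumor_nest", NE_HIGH): 39.0,
    ("CD3", "stroma", NE_LOW): 417.0,
    ("CD3", "stroma", NE_HIGH): 203.0,
    ("CD3", "tumor_nest", NE_LOW): 60.0,
    ("CD3", "tumor_nest", NE_HIGH): 7.0,
}

# Factor-feasible subset of the published marker correlations (see docs):
# keys are ((marker, compartment), (marker, compartment)) -> Spearman target.
DEFAULT_TARGET_CORRELATIONS: dict[tuple, float] = {
    (("CD68", "tumor_nest"), ("CD163", "tumor_nest")): 0.76,
    (("CD68", "stroma"), ("CD163", "stroma")): 0.455,
    (("CD163", "stroma"), ("CD33", "stroma")): 0.651,
}


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 32
    ne_high_fraction: float = 0.645
    markers: tuple = DEFAULT_MARKERS
    compartments: tuple = COMPARTMENTS
    density_means: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_MEANS)
    )
    #: negative-binomial size parameter of the per-section counts
    density_dispersion: float = 20.0
    #: within-subtype biological log-sd of true densities
    log_sigma: float = 0.6
    target_correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    #: factor loading (correlation units) for variables without a target
    default_loading: float = 0.35
    #: probability that the LN metastasis flips the patient's NE label
    ln_flip_prob: float = 0.1
    #: latent-factor correlation between a patient's primary and LN sample
    patient_factor_corr: float = 0.6
    area_means_um2: dict = field(
        default_factory=lambda: {"stroma": 300_000.0, "tumor_nest": 450_000.0}
    )
    area_log_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.ne_high_fraction <= 1:
            raise ValueError("ne_high_fraction must be in [0, 1]")
        if self.density_dispersion <= 0 or self.log_sigma <= 0:
            raise ValueError("dispersion parameters must be positive")
        for key, mean in self.density_means.items():
            if mean < 0:
                raise ValueError(f"negative density mean for {key}")
        for pair, rho in self.target_correlations.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"correlation target out of [-1,1] for {pair}")

    @property
    def variables(self) -> list[tuple[str, str]]:
        return [(m, c) for m in self.markers for c in self.compartments]


def _mean(self_means, var, subtype):
    return self_means.get((var[0], var[1], subtype), 0.0)


def _reliabilities(spec: CohortSpec) -> dict[tuple, float]:
    """Fraction of observed log-density variance that is biological signal.

    Delta-method approximation of the log-scale counting noise of an NB
    count with mean m and size k, ``1/m + 1/k`` per section, averaged over
    subtypes and replicate structure (primary: 4 sections; LN: 2).
    """
    p_high = spec.ne_high_fraction
    weights = {NE_LOW: 1 - p_high, NE_HIGH: p_high}
    k = spec.density_dispersion
    out = {}
    for var in spec.variables:
        area_mm2 = spec.area_means_um2[var[1]] / 1e6
        v_sec = 0.0
        for subtype, w in weights.items():
            m = max(_mean(spec.density_means, var, subtype) * area_mm2, 1e-3)
            v_sec += w * (1.0 / m + 1.0 / k)
        v_noise = 0.5 * (v_sec / 4 + v_sec / 2)  # half primary, half LN
        v_signal = _signal_var(spec, var)
        out[var] = v_signal / (v_signal + v_noise)
    return out


def _delta(spec: CohortSpec, var) -> float:
    lo = _mean(spec.density_means, var, NE_LOW)
    hi = _mean(spec.density_means, var, NE_HIGH)
    if lo <= 0 or hi <= 0:
        return 0.0
    return float(np.log(lo) - np.log(hi))


def _signal_var(spec: CohortSpec, var) -> float:
    pq = spec.ne_high_fraction * (1 - spec.ne_high_fraction)
    return _delta(spec, var) ** 2 * pq + spec.log_sigma**2


def _canonical_pair(pair):
    a, b = tuple(pair[0]), tuple(pair[1])
    return (a, b) if a <= b else (b, a)


def fit_factor_loadings(spec: CohortSpec) -> dict[tuple, float]:
    """Per-variable loadings of the shared infiltration factor.

    Converts each Spearman target into the within-subtype correlation the
    factor must supply (after removing the subtype-mixture contribution and
    inflating for counting attenuation), verifies the implied latent
    correlation matrix is positive semi-definite, and solves for loadings by
    log-space least squares.  Raises ``ValueError`` with a diagnostic when a
    target is unsatisfiable.
    """
    variables = spec.variables
    pq = spec.ne_high_fraction * (1 - spec.ne_high_fraction)
    s2 = spec.log_sigma**2
    rel = _reliabilities(spec)
    required: dict[tuple, float] = {}
    for pair, rho_s in spec.target_correlations.items():
        a, b = _canonical_pair(pair)
        if a not in variables or b not in variables:
            raise ValueError(f"correlation target references unknown pair {pair}")
        atten = np.sqrt(rel[a] * rel[b])
        rho_true = rho_s / atten
        if abs(rho_true) > 0.995:
            raise ValueError(
                f"target correlation {rho_s} for {pair} is unattainable: "
                f"counting noise caps the realizable correlation at "
                f"~{0.995 * atten:.3f}"
            )
        g = rho_true * np.sqrt(_signal_var(spec, a) * _signal_var(spec, b)) - (
            _delta(spec, a) * _delta(spec, b) * pq
        )
        c_ab = g / s2
        if c_ab >= 1:
            raise ValueError(
                f"target correlation {rho_s} for {pair} requires a "
                f"within-subtype correlation of {c_ab:.2f} >= 1 under the "
                "one-factor model (correlation matrix not PSD); lower the "
                "target or raise log_sigma"
            )
        if c_ab <= 0:
            warnings.warn(
                f"target {rho_s} for {pair} is already exceeded by the "
                "NE-subtype mean shifts; factor contribution set to 0",
                stacklevel=2,
            )
            continue
        required[(a, b)] = c_ab
    # PSD diagnostic on the requested within-subtype correlation matrix,
    # completed with the default loading product off the specified pairs
    idx = {v: i for i, v in enumerate(variables)}
    cmat = np.full((len(variables), len(variables)), spec.default_loading**2)
    np.fill_diagonal(cmat, 1.0)
    for (a, b), c_ab in required.items():
        cmat[idx[a], idx[b]] = cmat[idx[b], idx[a]] = c_ab
    if np.linalg.eigvalsh(cmat).min() < -1e-8:
        raise ValueError(
            "requested correlation targets imply a non-positive-semi-definite "
            "latent correlation matrix; relax the targets"
        )
    # log-space least squares: log rho_a + log rho_b = log c_ab, ridge toward
    # the default loading
    rho = {v: spec.default_loading for v in variables}
    if required:
        constrained = sorted({v for pair in required for v in pair})
        cidx = {v: i for i, v in enumerate(constrained)}
        n_eq = len(required)
        alpha = 1e-3
        A = np.zeros((n_eq + len(constrained), len(constrained)))
        y = np.zeros(n_eq + len(constrained))
        for r, ((a, b), c_ab) in enumerate(sorted(required.items())):
            A[r, cidx[a]] = A[r, cidx[b]] = 1.0
            y[r] = np.log(c_ab)
        for j, v in enumerate(constrained):
            A[n_eq + j, j] = np.sqrt(alpha)
            y[n_eq + j] = np.sqrt(alpha) * np.log(spec.default_loading)
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        for v, xv in zip(constrained, x):
            rho_v = float(np.exp(xv))
            if rho_v > 0.999:
                raise ValueError(
                    f"correlation targets require loading {rho_v:.3f} > 1 for "
                    f"{v}; unsatisfiable under the one-factor model"
                )
            rho[v] = rho_v
    return {v: rho[v] * spec.log_sigma for v in variables}


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample table and compartment-count table for a synthetic cohort.

    Returns
    -------
    samples :
        ``sample_id, patient_id, site, ne_subtype, infiltration`` - one
        primary and one matched LN sample per patient.  ``infiltration`` is
        the sample's latent factor value (useful for downstream validation;
        a real study never observes it).
    counts :
        one row per (sample, core, section, marker, compartment) with
        ``cell_count`` and measured ``area_um2``.
    """
    rng = np.random.default_rng(spec.seed)
    lam = fit_factor_loadings(spec)
    variables = spec.variables
    n = spec.n_patients
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    ne_primary = np.where(
        rng.random(n) < spec.ne_high_fraction, NE_HIGH, NE_LOW
    )
    flip = rng.random(n) < spec.ln_flip_prob
    ne_ln = np.where(
        flip, np.where(ne_primary == NE_HIGH, NE_LOW, NE_HIGH), ne_primary
    )
    f_primary = rng.standard_normal(n)
    rho_p = spec.patient_factor_corr
    f_ln = rho_p * f_primary + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)

    sample_rows = []
    for i, pid in enumerate(patient_ids):
        sample_rows.append(
            {
                "sample_id": f"{pid}_primary",
                "patient_id": pid,
                "site": "primary",
                "ne_subtype": ne_primary[i],
                "infiltration": f_primary[i],
            }
        )
        sample_rows.append(
            {
                "sample_id": f"{pid}_ln",
                "patient_id": pid,
                "site": "ln",
                "ne_subtype": ne_ln[i],
                "infiltration": f_ln[i],
            }
        )
    samples = pd.DataFrame(sample_rows)

    n_samples = len(samples)
    f = samples["infiltration"].to_numpy()
    subtype = samples["ne_subtype"].to_numpy()
    s = spec.log_sigma
    k = spec.density_dispersion

    # true log densities, samples x variables
    true_density = np.empty((n_samples, len(variables)))
    for j, var in enumerate(variables):
        lam_v = lam[var]
        sig_v = np.sqrt(max(s**2 - lam_v**2, 0.0))
        mu = np.array(
            [
                np.log(max(_mean(spec.density_means, var, st), 1e-12))
                - 0.5 * s**2
                for st in subtype
            ]
        )
        x = mu + lam_v * f + sig_v * rng.standard_normal(n_samples)
        true_density[:, j] = np.exp(x)
        # markers absent in a subtype (mean 0) have zero density
        zero = np.array(
            [_mean(spec.density_means, var, st) <= 0 for st in subtype]
        )
        true_density[zero, j] = 0.0

    # expand to cores and sections
    rows = []
    core_plan = {"primary": ("A", "B"), "ln": ("A",)}
    jit = spec.area_log_jitter
    for i in range(n_samples):
        site = samples["site"].iloc[i]
        sid = samples["sample_id"].iloc[i]
        for core in core_plan[site]:
            for section in ("1", "2"):
                for j, var in enumerate(variables):
                    rows.append((sid, core, section, var[0], var[1], i, j))
    idx = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "core_id",
            "section_id",
            "marker",
            "compartment",
            "_i",
            "_j",
        ],
    )
    area_mean = idx["compartment"].map(spec.area_means_um2).to_numpy()
    areas = area_mean * np.exp(
        jit * rng.standard_normal(len(idx)) - 0.5 * jit**2
    )
    mu_count = true_density[idx["_i"], idx["_j"]] * (areas / 1e6)
    counts = np.zeros(len(idx), dtype=int)
    pos = mu_count > 0
    counts[pos] = rng.negative_binomial(k, k / (k + mu_count[pos]))
    out = idx.drop(columns=["_i", "_j"]).assign(
        cell_count=counts, area_um2=areas
    )
    return samples, out[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

# representative named genes per module; the remainder of each module and the
# background are filled with synthetic identifiers
MODULE_SEED_GENES = {
    "immune": [
        "CSF1", "CXCR2", "IL4R", "VEGFC", "CXCL9", "CXCL10", "CD70", "CD27",
        "GZMA", "FCGR1A", "HLA-B", "TAP1", "CD74", "ITGAM", "ANXA1", "ITGB6",
        "MMP7", "CD44", "KRT5", "MYC", "TP63", "IFI27", "YBX3", "BIRC3",
        "REL", "TNFSF10", "CDK6", "LGALS3", "CAV2", "LAMB3",
    ],
    "proliferation": [
        "MKI67", "PCNA", "TOP2A", "CCNB1", "CDK1", "BUB1", "AURKA", "AURKB",
        "PLK1", "CDC20", "MCM2", "MCM3", "RRM2", "TYMS", "BRCA1", "RAD51",
        "FEN1", "LIG1", "POLE", "CHEK1",
    ],
    "neuroendocrine": [
        "ASCL1", "NEUROD1", "CHGA", "SYP", "NCAM1", "GRP", "ISL1", "CDH2",
        "DLL3", "INS", "FGF5", "SOX3", "FOXA2", "L1CAM", "DNAJC6", "TP73",
    ],
}

#: printed NE-low / NE-high group means (log2 panel units) and pooled SDs the
#: generator is calibrated to; exact at the reference effect size of 2.0
CALIBRATED_GENES = {
    "CSF1": (7.23, 5.91, 1.1),
    "VEGFC": (7.59, 5.95, 1.4),
    "IL4R": (8.71, 7.88, 2.0),
    "CXCR2": (5.5, 3.83, 1.6),
}

CALIBRATION_REFERENCE_EFFECT = 2.0


@dataclass
class PanelSpec:
    """Targeted expression-panel structure."""

    n_genes: int = 2560
    module_sizes: dict = field(
        default_factory=lambda: {
            "immune": 40,
            "proliferation": 40,
            "neuroendocrine": 20,
        }
    )
    module_assignments: dict | None = None
    #: log2 shift applied to module genes in the favoring phenotype
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    patient_sd: float = 0.4
    #: extra log2 shift of immune genes per unit of the infiltration factor
    infiltration_coupling: float = 0.3
    calibrated_genes: dict = field(default_factory=lambda: dict(CALIBRATED_GENES))

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.module_assignments is None:
            self.module_assignments = self._auto_assignments()
        modules = self.module_assignments
        if len(modules) > self.n_genes:
            raise ValueError("more assigned genes than n_genes")
        bad = set(modules.values()) - {
            "immune", "proliferation", "neuroendocrine", "background"
        }
        if bad:
            raise ValueError(f"unknown modules: {sorted(bad)}")

    def _auto_assignments(self) -> dict:
        assignments: dict[str, str] = {}
        for module, size in self.module_sizes.items():
            seeds = MODULE_SEED_GENES.get(module, [])
            names = list(seeds[:size])
            i = 1
            prefix = module[:4].upper()
            while len(names) < size:
                cand = f"{prefix}{i:03d}"
                if cand not in names:
                    names.append(cand)
                i += 1
            for g in names:
                if g in assignments:
                    raise ValueError(f"gene {g} assigned to two modules")
                assignments[g] = module
        return assignments

    @property
    def genes(self) -> list[str]:
        assigned = list(self.module_assignments)
        n_bg = self.n_genes - len(assigned)
        background = [f"GENE{i + 1:04d}" for i in range(n_bg)]
        return assigned + background

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.module_assignments.items() if m == module]


@dataclass
class ExpressionMatrix:
    """genes x samples log2 expression with sample metadata."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene identifiers: {dup}")
        meta_ids = set(self.samples["sample_id"])
        cols = set(self.values.columns)
        if cols - meta_ids:
            raise ValueError(
                f"expression columns without metadata: {sorted(cols - meta_ids)[:5]}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def label_series(self, column: str) -> pd.Series:
        return self.samples.set_index("sample_id")[column].reindex(
            self.values.columns
        )


def generate_expression(
    cohort: pd.DataFrame, panel: PanelSpec, seed: int = 0
) -> ExpressionMatrix:
    """Simulate the targeted panel for a generated cohort.

    Immune-module genes are shifted up by ``effect_size`` in NE-low samples
    (plus ``infiltration_coupling`` per unit of the latent infiltration
    factor); proliferation and neuroendocrine modules are shifted up in
    NE-high samples.  Matched primary/LN samples share a patient-level random
    effect so their profiles correlate.  Calibrated genes reproduce their
    printed group means at the reference effect size, scaling proportionally
    with ``effect_size``.
    """
    if "ne_subtype" not in cohort.columns:
        raise ValueError("cohort table must carry ne_subtype labels")
    rng = np.random.default_rng(seed)
    genes = panel.genes
    n_g = len(genes)
    sample_ids = list(cohort["sample_id"])
    n_s = len(sample_ids)

    baseline = panel.baseline_mean + panel.baseline_sd * rng.standard_normal(n_g)
    patients = list(dict.fromkeys(cohort["patient_id"]))
    u_pat = dict(
        zip(patients, panel.patient_sd * rng.standard_normal(len(patients)))
    )
    pat_eff = cohort["patient_id"].map(u_pat).to_numpy()
    is_low = (cohort["ne_subtype"] == NE_LOW).to_numpy(dtype=float)
    is_high = 1.0 - is_low
    infil = (
        cohort["infiltration"].to_numpy()
        if "infiltration" in cohort.columns
        else np.zeros(n_s)
    )

    effect_scale = panel.effect_size / CALIBRATION_REFERENCE_EFFECT
    mat = np.empty((n_g, n_s))
    modules = panel.module_assignments
    for gi, gene in enumerate(genes):
        module = modules.get(gene, "background")
        if gene in panel.calibrated_genes:
            lo_mean, hi_mean, sd = panel.calibrated_genes[gene]
            shift = (lo_mean - hi_mean) * effect_scale * is_low
            resid = np.sqrt(max(sd**2 - panel.patient_sd**2, 0.25))
            mat[gi] = hi_mean + shift + pat_eff + resid * rng.standard_normal(n_s)
            continue
        shift = np.zeros(n_s)
        if module == "immune":
            shift = panel.effect_size * is_low
            if panel.effect_size != 0:
                shift = shift + panel.infiltration_coupling * infil
        elif module in ("proliferation", "neuroendocrine"):
            shift = panel.effect_size * is_high
        mat[gi] = (
            baseline[gi] + shift + pat_eff + panel.noise_sd * rng.standard_normal(n_s)
        )
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return ExpressionMatrix(values=values, samples=cohort.copy())


def generate_gene_sets(
    panel: PanelSpec,
    n_decoys: int = 20,
    decoy_size: int = 30,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene-set collection: one set per module plus random decoy sets drawn
    from the background genes."""
    rng = np.random.default_rng(seed)
    sets = {
        "IMMUNE_RESPONSE": panel.module_genes("immune"),
        "PROLIFERATION": panel.module_genes("proliferation"),
        "NEUROENDOCRINE": panel.module_genes("neuroendocrine"),
    }
    background = [
        g for g in panel.genes if panel.module_assignments.get(g) is None
    ]
    size = min(decoy_size, max(len(background), 1))
    for i in range(n_decoys):
        members = rng.choice(background, size=size, replace=False)
        sets[f"DECOY_{i + 1:03d}"] = sorted(members.tolist())
    return {k: v for k, v in sets.items() if v}


def generate_interactions(
    panel: PanelSpec,
    density: float = 0.002,
    seed: int = 0,
    within_factor: float = 25.0,
) -> pd.DataFrame:
    """Random interaction edge table with module structure.

    Within-module gene pairs interact with probability
    ``min(1, within_factor * density)``; all other pairs with probability
    ``density``.  Scores are uniform in (0.4, 1.0].
    """
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = panel.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    edges: list[tuple[str, str]] = []
    within_pairs = set()
    p_within = min(1.0, within_factor * density)
    for module in ("immune", "proliferation", "neuroendocrine"):
        members = sorted(panel.module_genes(module))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = (members[i], members[j])
                within_pairs.add((gene_idx[pair[0]], gene_idx[pair[1]]))
                if rng.random() < p_within:
                    edges.append(pair)
    # cross-module / background pairs sampled by count
    n_total_pairs = n * (n - 1) // 2
    n_cross_pairs = n_total_pairs - len(within_pairs)
    n_draw = rng.binomial(n_cross_pairs, density) if density > 0 else 0
    seen = set(within_pairs)
    while n_draw > 0:
        a = rng.integers(0, n, size=2 * n_draw)
        b = rng.integers(0, n, size=2 * n_draw)
        for ai, bi in zip(a, b):
            if ai == bi:
                continue
            key = (min(ai, bi), max(ai, bi))
            if key in seen:
                continue
            seen.add(key)
            edges.append((genes[key[0]], genes[key[1]]))
            n_draw -= 1
            if n_draw == 0:
                break
    out = pd.DataFrame(edges, columns=["gene_a", "gene_b"])
    out["score"] = 1.0 - 0.6 * rng.random(len(out))  # uniform in (0.4, 1.0]
    lo = out[["gene_a", "gene_b"]].min(axis=1)
    hi = out[["gene_a", "gene_b"]].max(axis=1)
    out["gene_a"], out["gene_b"] = lo, hi
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
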