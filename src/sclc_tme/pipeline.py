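"""End-to-end orchestration: counts -> phenotypes -> pathways -> targets.

``run_pipeline`` executes the full analysis in order: replicate-averaged
densities and CD33 scores, MAD dichotomization and immune-phenotype calls,
marker correlation grids, per-group preranked GSEA profiles with the
z-scored pathway matrix, per-contrast differential expression with volcano
categories, and the filtered interaction networks with their connectivity
statistics.  Inputs are either simulated from the packaged study conditions
or read from user files; every output table carries the config digest and
seed, and reruns of the same config are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .association import correlation_matrix
from .config import PipelineConfig
from .differential import de_test, overlap_report
from .enrichment import gsea_preranked, nes_heatmap_matrix, rank_genes
from .morphometry import average_replicates, composition, score_cd33_cores
from .network import build_network, connectivity_stats, select_nodes
from .phenotyping import MacrophageRule, annotate, classify_phenotypes, macrophage_class
from .simulate import (
    CohortSpec,
    ExpressionMatrix,
    PanelSpec,
    generate_cohort,
    generate_expression,
    generate_gene_sets,
    generate_interactions,
)

log = logging.getLogger("sclc_tme")

ORDINAL_MARKERS = ("CD33", "MHCII")

#: group labels profiled in the pathway heat map (each vs its complement)
HEATMAP_GROUPS = (
    "NE-low",
    "NE-high",
    "oasis",
    "desert",
    "macrophage_high",
    "macrophage_low",
)

#: contrasts for differential expression / networks: (focal, reference)
CONTRASTS = (("NE-low", "NE-high"), ("oasis", "desert"))


def _simulated_inputs(config: PipelineConfig):
    spec = CohortSpec(
        n_patients=config.n_patients,
        ne_high_fraction=config.ne_high_fraction,
        seed=config.seed,
    )
    panel = PanelSpec(
        n_genes=config.n_genes,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
    )
    samples, counts = generate_cohort(spec)
    expr = generate_expression(samples, panel, seed=config.seed + 1)
    gene_sets = generate_gene_sets(panel, seed=config.seed + 2)
    edges = generate_interactions(
        panel, density=config.interaction_density, seed=config.seed + 3
    )
    return samples, counts, expr, gene_sets, edges


def _file_inputs(config: PipelineConfig):
    counts = tio.read_counts(config.counts_path)
    values = tio.read_expression(config.expression_path)
    gene_sets = tio.read_gmt(config.gene_sets_path)
    edges = tio.read_edges(config.edges_path) if config.edges_path else None
    count_ids = set(counts["sample_id"])
    expr_ids = set(values.columns)
    if count_ids != expr_ids:
        only_counts = sorted(count_ids - expr_ids)[:10]
        only_expr = sorted(expr_ids - count_ids)[:10]
        raise ValueError(
            "sample IDs differ between count table and expression matrix; "
            f"counts-only: {only_counts}; expression-only: {only_expr}"
        )
    samples = pd.DataFrame({"sample_id": sorted(expr_ids)})
    samples["patient_id"] = samples["sample_id"]
    samples["site"] = "unknown"
    samples["ne_subtype"] = np.nan
    expr = ExpressionMatrix(values=values, samples=samples)
    return samples, counts, expr, gene_sets, edges


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full compartment-resolved TME analysis.

    Returns a result bundle (dict) with the sample table, density and score
    tables, cutoffs, the annotation matrix, phenotypes, correlation grids,
    enrichment results and z-matrix, per-contrast DE tables, target sets,
    network statistics, and run metadata.  If ``config.out_dir`` is set the
    bundle is also written there as TSV/CSV/JSON files.
    """
    if config.simulate:
        samples, counts, expr, gene_sets, edges = _simulated_inputs(config)
    else:
        samples, counts, expr, gene_sets, edges = _file_inputs(config)
    log.info("inputs: %d samples, %d count rows, %d genes, %d gene sets",
             len(samples), len(counts), len(expr.genes), len(gene_sets))

    # --- morphometry ------------------------------------------------------
    densities = average_replicates(counts)
    cd33 = score_cd33_cores(counts).rename(columns={"score": "density"})
    continuous = densities[~densities["marker"].isin(ORDINAL_MARKERS)]
    ann_input = pd.concat([continuous, cd33], ignore_index=True)

    ne_labels = samples.set_index("sample_id")["ne_subtype"].dropna().to_dict()
    comp = {}
    if ne_labels:
        for compartment in ("stroma", "tumor_nest"):
            comp[compartment] = composition(
                densities[densities["marker"] != "CD33"],
                compartment,
                ne_labels,
                mode=config.composition_mode,
            )

    # --- phenotyping ------------------------------------------------------
    annotation, cutoffs = annotate(
        ann_input, c=config.mad_c, ordinal_markers=ORDINAL_MARKERS
    )
    if config.annotations_path:
        annotation = tio.read_annotations(config.annotations_path)
    phenotypes = classify_phenotypes(annotation)
    rule = MacrophageRule(min_fraction=config.macrophage_min_fraction)
    mac = []
    for sample_id, row in annotation.iterrows():
        try:
            mac.append(macrophage_class(row.to_dict(), rule))
        except ValueError:
            mac.append("missing")
    phenotypes["macrophage"] = mac

    # --- association ------------------------------------------------------
    wide = ann_input.pivot_table(
        index="sample_id", columns=["marker", "compartment"], values="density"
    )
    wide.columns = [f"{m}_{c}" for m, c in wide.columns]
    corr, corr_p = correlation_matrix(wide, method="spearman")

    # --- group labels for expression analyses -----------------------------
    labels = samples.set_index("sample_id")["ne_subtype"].to_dict()
    pheno_map = phenotypes.set_index("sample_id")
    group_members: dict[str, set] = {}
    for g in HEATMAP_GROUPS:
        if g in ("NE-low", "NE-high"):
            members = {s for s, v in labels.items() if v == g}
        elif g in ("oasis", "desert"):
            members = set(pheno_map.index[pheno_map["phenotype"] == g])
        else:
            members = set(pheno_map.index[pheno_map["macrophage"] == g])
        group_members[g] = members & set(expr.values.columns)

    # --- enrichment -------------------------------------------------------
    all_samples = list(expr.values.columns)
    enrich_rows = []
    rng_seed = config.seed + 10
    for g in HEATMAP_GROUPS:
        members = group_members[g]
        rest = set(all_samples) - members
        if len(members) < 2 or len(rest) < 2:
            log.warning("skipping enrichment group %s (too few samples)", g)
            continue
        lab = {s: ("in" if s in members else "out") for s in all_samples}
        ranked = rank_genes(expr.values, lab, "in", "out", metric=config.gsea_metric)
        res = gsea_preranked(
            ranked,
            gene_sets,
            p=config.gsea_weight,
            n_perm=config.n_perm,
            seed=rng_seed,
        )
        res["group"] = g
        enrich_rows.append(res)
        rng_seed += 1
    enrichment = (
        pd.concat(enrich_rows, ignore_index=True)
        if enrich_rows
        else pd.DataFrame(columns=["pathway", "group", "es", "nes", "p", "padj"])
    )
    try:
        nes_matrix = nes_heatmap_matrix(enrichment, nes_threshold=1.0)
    except ValueError:
        nes_matrix = pd.DataFrame()

    # --- differential expression and networks -----------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    target_sets: dict[str, set] = {}
    network_stats: dict[str, dict] = {}
    for focal, ref in CONTRASTS:
        mem_f, mem_r = group_members.get(focal, set()), group_members.get(ref, set())
        if len(mem_f) < 2 or len(mem_r) < 2:
            log.warning("skipping contrast %s vs %s (too few samples)", focal, ref)
            continue
        lab = {s: focal for s in mem_f} | {s: ref for s in mem_r}
        de = de_test(
            expr.values[[s for s in all_samples if s in lab]],
            lab,
            focal,
            ref,
            shrink_var=config.de_shrink_var,
            p_threshold=config.volcano_p_threshold,
            fc_low=config.fc_low,
            fc_high=config.fc_high,
            use_adjusted_p=config.volcano_p == "adjusted",
        )
        name = f"{focal}_vs_{ref}"
        de_tables[name] = de
        target_sets[f"up_in_{focal}"] = select_nodes(
            de,
            p_threshold=config.volcano_p_threshold,
            lfc_threshold=config.fc_low,
            p_column=config.network_p_column,
        )
        target_sets[f"up_in_{ref}"] = select_nodes(
            de.assign(log2fc=-de["log2fc"]),
            p_threshold=config.volcano_p_threshold,
            lfc_threshold=config.fc_low,
            p_column=config.network_p_column,
        )
    networks = {}
    if edges is not None:
        for name, nodes in target_sets.items():
            g = build_network(nodes, edges, min_score=config.network_min_score)
            networks[name] = g
            network_stats[name] = connectivity_stats(
                g, mode=config.edges_per_node_mode
            ).as_dict()

    overlaps = overlap_report({k: sorted(v) for k, v in target_sets.items()})

    bundle = {
        "samples": samples,
        "counts": counts,
        "densities": densities,
        "cd33_scores": cd33.rename(columns={"density": "score"}),
        "composition": comp,
        "cutoffs": cutoffs,
        "annotation": annotation,
        "phenotypes": phenotypes,
        "correlations": corr,
        "correlation_p": corr_p,
        "expression": expr,
        "gene_sets": gene_sets,
        "enrichment": enrichment,
        "nes_matrix": nes_matrix,
        "de": de_tables,
        "target_sets": target_sets,
        "networks": networks,
        "network_stats": network_stats,
        "overlaps": overlaps,
        "metadata": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "gsea_metric": config.gsea_metric,
            "edges_per_node_mode": config.edges_per_node_mode,
            "de_test": "welch_t" + ("+shrinkage" if config.de_shrink_var else ""),
            "volcano_p": config.volcano_p,
        },
    }
    if config.out_dir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = bundle["metadata"]

    def _tsv(df: pd.DataFrame, name: str, index=False):
        df.to_csv(out / name, sep="\t", index=index)

    _tsv(bundle["samples"], "samples.tsv")
    tio.write_counts(bundle["counts"], out / "counts.tsv")
    _tsv(bundle["densities"], "densities.tsv")
    _tsv(bundle["cd33_scores"], "cd33_scores.tsv")
    tio.write_annotations(bundle["annotation"], out / "annotation.csv")
    _tsv(bundle["phenotypes"], "phenotypes.tsv")
    _tsv(bundle["correlations"], "correlations_spearman.tsv", index=True)
    _tsv(bundle["correlation_p"], "correlations_spearman_p.tsv", index=True)
    tio.write_expression(bundle["expression"].values, out / "expression.tsv")
    tio.write_gmt(bundle["gene_sets"], out / "gene_sets.gmt")
    _tsv(bundle["enrichment"], "enrichment.tsv")
    _tsv(bundle["nes_matrix"], "nes_matrix.tsv", index=True)
    for name, de in bundle["de"].items():
        _tsv(de, f"de_{name.replace('/', '_')}.tsv", index=True)
    for compartment, df in bundle["composition"].items():
        _tsv(df, f"composition_{compartment}.tsv")
    _tsv(bundle["overlaps"], "overlaps.tsv")
    tio.write_json(
        {"stats": bundle["network_stats"], "metadata": meta},
        out / "network_stats.json",
    )
    tio.write_json(meta, out / "metadata.json")
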