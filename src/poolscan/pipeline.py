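"""End-to-end orchestration: simulate -> scan -> confirm -> regions -> expression -> clusters.

A single master seed drives every stochastic stage (child seeds are spawned
deterministically), so a rerun with the same config is byte-identical.  Each
stage writes its TSV outputs and contributes to a funnel report mirroring
the analysis flow: markers tested -> linked -> confirmed -> regions ->
genes -> EST candidates -> expression-associated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa_scan, clusters, confirm, expression, io, regions, simulate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "scan", "confirm", "regions", "expression", "clusters"],
    "simulate": {
        "n_families": 7,
        "family_size_range": [127, 174],
        "pool_fraction": 0.10,
        "qtl": [["chr11", 31.0, 0.10]],
        "baseline_csw": 0.25,
        "phenotype_noise_sd": 0.05,
        "marker_spacing_cm": 1.0,
        "mean_depth": 245.0,
        "error_rate": 0.005,
    },
    "scan": {
        "min_coverage": 5,
        "fdr_threshold": 0.05,
        "method": "bh",
        "sided": "one",
        # classically calibrated z for simulation-based inference; "se" is
        # the verbatim published arithmetic and is wildly anticonservative
        "scale": "sd",
    },
    "regions": {"half_width_bp": 150_000, "gene_spacing_bp": 50_000,
                "est_background_rate": 0.05},
    "expression": {"n_strains": 12, "n_days": 8, "noise_sd": 0.15,
                   "n_permutations": 2000},
    "clusters": {"n_genes": 500, "genome_size": 432_000_000, "mode": "clustered",
                 "clustered_fraction": 0.5, "threshold_mode": "absolute",
                 "threshold_value": 30_000, "n_permutations": 200},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the defaults (one level deep)."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def _child_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic child seeds below 2**31 for the pipeline stages."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages in order; return the funnel report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(int(config.get("seed", 0)))
    stages = config.get("stages", DEFAULT_CONFIG["stages"])
    report: dict = {"seed": config.get("seed", 0), "stages": list(stages),
                    "parameters": {k: config[k] for k in
                                   ("simulate", "scan", "regions", "expression", "clusters")
                                   if k in config}}
    state: dict = {}
    for stage in stages:
        runner = _STAGES.get(stage)
        if runner is None:
            raise RuntimeError(f"unknown pipeline stage {stage!r}")
        try:
            runner(config, seeds, state, outdir, report)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str, sort_keys=True)
    return report


def _stage_simulate(config, seeds, state, outdir, report):
    params = dict(config["simulate"])
    params["qtl"] = [tuple(q) for q in params.get("qtl", [])]
    params["family_size_range"] = tuple(params.get("family_size_range", (127, 174)))
    design = simulate.CrossDesign(seed=seeds[0], **params)
    pop = simulate.simulate_bc1(design)
    low, high = simulate.build_pools(pop, design.pool_fraction)
    depths = simulate.pooled_depths(
        pop, low, high, mean_depth=design.mean_depth,
        error_rate=design.error_rate, seed=seeds[1],
    )
    io.write_depth_table(depths, outdir / "pooled_depths.tsv")
    pop.individuals_frame().to_csv(outdir / "individuals.tsv", sep="\t", index=False)
    state.update(design=design, pop=pop, low=low, high=high, depths=depths)
    report["simulate"] = {
        "n_individuals": pop.n_individuals,
        "n_markers": len(pop.markers),
        "pool_sizes": [int(low.size), int(high.size)],
        "qtl_truth": [list(q) for q in pop.truth],
    }


def _stage_scan(config, seeds, state, outdir, report):
    depths = state.get("depths")
    if depths is None:
        raise ValueError("scan stage needs a depth table (run simulate or supply one)")
    result = bsa_scan.scan_depths(depths, **config["scan"])
    result.table.to_csv(outdir / "scan.tsv", sep="\t", index=False)
    io.write_linked_bed(result.table, outdir / "linked_markers.bed")
    state["scan"] = result
    report["scan"] = result.summary()


def _stage_confirm(config, seeds, state, outdir, report):
    scan = state["scan"]
    pop, low, high = state["pop"], state["low"], state["high"]
    linked = scan.linked
    if linked.empty:
        report["confirm"] = {"n_putative": 0, "n_positive": 0, "n_false_discovery": 0}
        state["positives"] = linked
        return
    all_counts = simulate.pool_genotype_counts(pop, low, high)
    is_linked = all_counts["marker_id"].isin(linked["marker_id"])
    counts = all_counts.loc[is_linked].copy()
    counts["indel_id"] = counts["marker_id"].str.replace("chr", "indel", regex=False)
    counts["linked_marker_id"] = counts["marker_id"]
    counts = counts.drop(columns=["marker_id"])
    # standardise indel deltas against the null background: genotype-count
    # deltas of the markers the scan did NOT call (the putative set itself
    # carries the signal under test and cannot serve as its own background)
    null_counts = all_counts.loc[~is_linked]
    _, _, background = bsa_scan.snp_index(
        null_counts["Maa"], null_counts["Mab"],
        null_counts["Paa"], null_counts["Pab"],
    )
    confirmed = confirm.confirm_markers(
        linked, counts, scale=config["scan"].get("scale", "sd"),
        background_deltas=background,
    )
    confirmed.to_csv(outdir / "confirmation.tsv", sep="\t", index=False)
    positives = confirmed.loc[confirmed["verdict"] == "positive"]
    state["positives"] = positives.rename(columns={"linked_marker_id": "marker_id"})
    report["confirm"] = {
        "n_putative": int(len(linked)),
        "n_positive": int(len(positives)),
        "n_false_discovery": int((confirmed["verdict"] == "false_discovery").sum()),
    }


def _stage_regions(config, seeds, state, outdir, report):
    params = config["regions"]
    positives = state.get("positives")
    design = state["design"]
    chrom_sizes = {
        c: int(round(l * simulate.BP_PER_CM)) + 1 for c, l in design.chromosomes.items()
    }
    if positives is None or positives.empty:
        report["regions"] = {"n_regions": 0, "n_genes": 0, "n_candidates": 0}
        state["candidates"] = pd.DataFrame(columns=["gene_id"])
        return
    pos_frame = positives[["marker_id", "chrom", "pos"]].drop_duplicates("marker_id")
    region_set = regions.define_regions(
        pos_frame, half_width_bp=params["half_width_bp"], chrom_sizes=chrom_sizes
    )
    regions.regions_to_bed(region_set, outdir / "regions.bed")
    genes, est = _synthetic_annotation(
        chrom_sizes, state["pop"].truth, params, seeds[3]
    )
    in_regions = regions.genes_in_regions(region_set, genes)
    candidates = regions.est_screen(in_regions, est)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    state["candidates"] = candidates
    report["regions"] = {
        "n_regions": int(len(region_set)),
        "n_genes": int(len(in_regions)),
        "n_candidates": int(len(candidates)),
        "planted_candidate_recovered": bool(
            candidates["gene_id"].str.startswith("candidate_").any()
        ),
    }


def _synthetic_annotation(chrom_sizes, qtl_truth, params, seed):
    """Tile a synthetic gene annotation over the genome, planting one
    EST-supported candidate gene at each true QTL position."""
    rng = np.random.default_rng(seed)
    spacing = params["gene_spacing_bp"]
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(1, size, spacing):
            rows.append((f"gene_{chrom}_{start}", chrom, start,
                         min(start + 2000, size), "+"))
    for i, (chrom, pos_cm, _eff) in enumerate(qtl_truth):
        pos = int(round(pos_cm * simulate.BP_PER_CM)) + 1
        rows.append((f"candidate_{i}", chrom, pos, pos + 1500, "+"))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    background = params["est_background_rate"]
    est_rows = []
    for gene in genes["gene_id"]:
        planted = gene.startswith("candidate_")
        for tissue in regions.DEFAULT_TISSUES:
            count = 5 if planted else int(rng.random() < background) * int(
                rng.integers(1, 10)
            )
            est_rows.append((gene, tissue, count))
    est = pd.DataFrame(est_rows, columns=["gene_id", "tissue", "count"])
    return genes, est


def _stage_expression(config, seeds, state, outdir, report):
    params = config["expression"]
    candidates = state.get("candidates", pd.DataFrame(columns=["gene_id"]))
    has_planted = bool(
        len(candidates) and candidates["gene_id"].str.startswith("candidate_").any()
    )
    bundle = simulate.simulate_expression_tables(
        n_strains=params["n_strains"], n_days=params["n_days"],
        association="positive" if has_planted else "none",
        noise_sd=params["noise_sd"], seed=seeds[4],
    )
    increments = expression.growth_increments(bundle.gland_volume)
    temporal = expression.temporal_association(
        bundle.temporal_expression,
        pd.Series(increments["increment"].to_numpy(), index=increments["day"]),
        n_permutations=params["n_permutations"], seed=seeds[5],
    )
    strains = expression.csw_association(
        bundle.strain_expression, bundle.csw, grouping="correlate",
        n_permutations=params["n_permutations"], seed=seeds[6],
    )
    report["expression"] = {
        "temporal": temporal,
        "csw": strains,
        "associated": bool(
            temporal["defined"] and strains["defined"]
            and temporal["pearson_p"] < 0.05 and strains["p"] < 0.05
        ),
    }


def _stage_clusters(config, seeds, state, outdir, report):
    params = config["clusters"]
    degs = simulate.simulate_deg_positions(
        n_genes=params["n_genes"], genome_size=params["genome_size"],
        mode=params["mode"], clustered_fraction=params.get("clustered_fraction", 0.5),
        seed=seeds[7],
    )
    summary = clusters.cluster_summary(degs, params["genome_size"])
    null = clusters.cluster_null_test(
        degs, {"genome": params["genome_size"]},
        threshold_mode=params["threshold_mode"],
        threshold_value=params["threshold_value"],
        n_permutations=params["n_permutations"], seed=seeds[7] + 1,
    )
    clusters.clusters_to_frame(
        clusters.call_clusters(degs, params["threshold_mode"],
                               params["threshold_value"],
                               genome_size=params["genome_size"])
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    report["clusters"] = {"summary": summary, "null_test": null}


_STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "confirm": _stage_confirm,
    "regions": _stage_regions,
    "expression": _stage_expression,
    "clusters": _stage_clusters,
}


def funnel(report: dict) -> dict:
    """The analysis funnel from a run report."""
    return {
        "markers_tested": report.get("scan", {}).get("n_markers", 0),
        "linked": report.get("scan", {}).get("n_linked", 0),
        "confirmed": report.get("confirm", {}).get("n_positive", 0),
        "regions": report.get("regions", {}).get("n_regions", 0),
        "genes": report.get("regions", {}).get("n_genes", 0),
        "est_candidates": report.get("regions", {}).get("n_candidates", 0),
        "expression_associated": int(
            bool(report.get("expression", {}).get("associated", False))
        ),
    }
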