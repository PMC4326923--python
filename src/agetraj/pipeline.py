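"""End-to-end orchestration behind a single YAML configuration.

Stages run in dependency order: simulate (or load) -> normalize -> MDS ->
DEG calling -> temporal clustering -> shape fits -> enrichment -> networks.
Every stochastic stage takes an explicit seed from the config; re-running an
identical config reproduces byte-identical TSV outputs. A manifest records
the config hash, seeds and row counts of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .clustering import (
    TemporalProfiles,
    fcm_fit,
    initial_direction_pct,
    monotonic_pct,
    standardize,
    summarize_clusters,
    validity_vote,
)
from .deg import call_degs
from .enrich import hypergeom_enrich, kappa_group
from .network import age_stratified_networks, build_network, components, hub_report
from .ordination import group_centroids, mds_of_samples
from .shapes import fit_shapes, summarize_peaks
from .simulate import SimConfig, simulate, simulate_gene_sets, write_truth

log = logging.getLogger("agetraj")

DEFAULTS = {
    "alpha_deg": 0.05,
    "alpha_shape": 0.05,
    "q_enrich": 0.05,
    "kappa_threshold": 0.4,
    "k_range": [2, 10],
    "fuzzifier": 2.0,
    "n_starts": 5,
    "r_threshold": 0.95,
    "positive_only": True,
    "log_transform": True,
    "pseudocount": 1.0,
    "n_perm": 10000,
    "restrict_in_range": True,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return merge_defaults(cfg)


def merge_defaults(cfg: dict) -> dict:
    out = dict(DEFAULTS)
    out.update(cfg)
    return out


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
    manifest["outputs"][path.name] = int(df.shape[0])
    log.info("wrote %s (%d rows)", path.name, df.shape[0])


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg = merge_defaults(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": cfg["seed"], "outputs": {}}

    # --- inputs: simulate or load ------------------------------------------
    if "counts" in cfg and cfg["counts"]:
        for key in ("counts", "samples"):
            if key not in cfg or not cfg[key]:
                raise KeyError(f"config missing required path: {key!r}")
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(f"config path {key!r} does not exist: {cfg[key]}")
        matrix = aio.read_counts(cfg["counts"])
        sheet = aio.read_sample_sheet(cfg["samples"])
        truth = None
        gene_sets = aio.read_gmt(cfg["gene_sets"]) if cfg.get("gene_sets") else None
    else:
        sim_cfg = SimConfig(**cfg.get("simulate", {}), seed=cfg["seed"])
        matrix, sheet, truth = simulate(sim_cfg)
        gene_sets = simulate_gene_sets(truth, n_random_sets=cfg.get("n_random_sets", 0), seed=cfg["seed"])
        aio.write_counts(matrix, out / "counts.tsv")
        aio.write_sample_sheet(sheet, out / "samples.tsv")
        write_truth(truth, out / "truth.tsv")
        aio.write_gmt(gene_sets, out / "sets.gmt")
        manifest["outputs"]["counts.tsv"] = matrix.shape[0]
        manifest["outputs"]["samples.tsv"] = len(sheet.sample_ids)
        manifest["outputs"]["truth.tsv"] = len(truth.gene_ids)
        manifest["outputs"]["sets.gmt"] = len(gene_sets)
    sheet.validate_against(matrix)

    # --- normalize ----------------------------------------------------------
    norm_rpkm = aio.rpkm(matrix)
    norm = (
        aio.log_transform(norm_rpkm, cfg["pseudocount"]) if cfg["log_transform"] else norm_rpkm
    )
    _write(norm.values.rename_axis("gene_id"), out / "norm.tsv", manifest)

    # --- MDS ----------------------------------------------------------------
    emb = mds_of_samples(norm)
    mds_df = emb.coordinates.copy()
    mds_df["age_weeks"] = sheet.age_of().reindex(mds_df.index)
    _write(mds_df.rename_axis("sample_id"), out / "mds.tsv", manifest)
    _write(group_centroids(emb, sheet), out / "mds_centroids.tsv", manifest)

    # --- DEG calling --------------------------------------------------------
    deg_res = call_degs(
        matrix, sheet, alpha=cfg["alpha_deg"], n_perm=cfg["n_perm"], seed=cfg["seed"]
    )
    _write(deg_res.calls, out / "degs.tsv", manifest)
    deg_genes = deg_res.deg_ids
    log.info("DEGs: %d of %d genes", len(deg_genes), len(deg_res.calls))

    # --- temporal clustering ------------------------------------------------
    profiles = standardize(norm, sheet, genes=deg_genes)
    k_lo, k_hi = cfg["k_range"]
    k_hi = min(k_hi, profiles.profiles.shape[0] - 1)
    chosen_k, validity, fits = validity_vote(
        profiles,
        range(k_lo, k_hi + 1),
        m=cfg["fuzzifier"],
        seed=cfg["seed"],
        n_starts=cfg["n_starts"],
    )
    fit = fits[chosen_k]
    manifest["chosen_k"] = chosen_k
    _write(validity.rename_axis("k"), out / "validity.tsv", manifest)
    _write(
        fit.membership.rename_axis("gene_id").rename(columns=lambda c: f"cluster_{c}"),
        out / "memberships.tsv",
        manifest,
    )
    cent = pd.DataFrame(fit.centroids, columns=profiles.ages).rename_axis("cluster")
    _write(cent, out / "centroids.tsv", manifest)
    summary = summarize_clusters(fit, profiles)
    _write(summary.table, out / "cluster_summary.tsv", manifest)
    mono, inv = monotonic_pct(summary)
    down, up = initial_direction_pct(summary)
    manifest["pct_monotonic"] = round(mono, 1)
    manifest["pct_inversion"] = round(inv, 1)
    manifest["pct_initial_down"] = round(down, 1)
    manifest["pct_initial_up"] = round(up, 1)

    # --- shape fits ---------------------------------------------------------
    shape_fits = fit_shapes(norm, sheet, genes=deg_genes, alpha=cfg["alpha_shape"])
    _write(shape_fits.table, out / "shapes.tsv", manifest)
    peaks = summarize_peaks(shape_fits, restrict_in_range=cfg["restrict_in_range"])
    manifest["n_u"] = peaks.n_u
    manifest["n_bell"] = peaks.n_bell
    manifest["median_peak_u"] = peaks.median_peak_u
    manifest["median_peak_bell"] = peaks.median_peak_bell

    # --- enrichment (per temporal cluster) ----------------------------------
    if gene_sets is not None and len(gene_sets):
        background = [g for g in matrix.gene_ids if g not in deg_res.dropped_genes]
        labels = fit.hard_labels
        rows = []
        for rank, ci in enumerate(fit.cluster_order, start=1):
            query = list(labels.index[labels == ci])
            if not query:
                continue
            res = hypergeom_enrich(query, gene_sets, background)
            t = res.table.copy()
            t.insert(0, "cluster", rank)
            rows.append(t)
            groups, _ = kappa_group(
                res, gene_sets, background,
                q_threshold=cfg["q_enrich"], kappa_threshold=cfg["kappa_threshold"],
            )
            manifest.setdefault("term_groups_per_cluster", {})[str(rank)] = len(groups)
        enrich_all = pd.concat(rows)
        _write(enrich_all.rename_axis("set_name"), out / "enrichment.tsv", manifest)

    # --- networks -----------------------------------------------------------
    net = build_network(
        norm, r_threshold=cfg["r_threshold"], positive_only=cfg["positive_only"]
    )
    aio.write_graph(net.graph, out / "network.graphml", out / "edges.tsv")
    manifest["outputs"]["edges.tsv"] = net.n_edges
    manifest["network_nodes"] = net.n_nodes
    manifest["network_edges"] = net.n_edges
    if net.n_nodes:
        hub = hub_report(net)
        manifest["hub"] = hub.hub
        manifest["hub_degree"] = hub.degree
        comp_rows = [
            {"component": i, "n_nodes": len(c), "members": ";".join(sorted(c))}
            for i, c in enumerate(components(net), start=1)
        ]
        _write(pd.DataFrame(comp_rows).set_index("component"), out / "components.tsv", manifest)
    nets, jac, composition = age_stratified_networks(
        norm, sheet, r_threshold=cfg["r_threshold"], genes=deg_genes,
        positive_only=cfg["positive_only"], cluster_labels=fit.hard_labels,
    )
    _write(jac.rename_axis("age_weeks"), out / "jaccard.tsv", manifest)
    if composition is not None:
        _write(composition.set_index("age"), out / "stratum_components.tsv", manifest)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
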