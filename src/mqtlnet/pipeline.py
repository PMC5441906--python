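"""End-to-end orchestration of the mQTL mapping and network pipeline.

Stage order: simulate/ingest -> qc -> trial -> corr -> gwas -> network.
Each stage is a pure function of its inputs plus the config, so a fixed
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import correlate, gwas, io, network, preprocess, simulate, trial
from .config import RunConfig
from .data import PhenotypeTable

log = logging.getLogger("mqtlnet")

STAGE_ORDER = ["simulate", "qc", "trial", "corr", "gwas", "network"]


@dataclass
class StageResult:
    name: str
    elapsed: float
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _graph_exports(pdg: network.PartiallyDirectedGraph) -> dict[str, str]:
    g = pdg.to_networkx()
    graphml = "\n".join(nx.generate_graphml(g))
    sif_lines = []
    for u, v, w in pdg.directed:
        sif_lines.append(f"{u}\tcauses\t{v}")
    for u, v, w in pdg.undirected:
        sif_lines.append(f"{u}\tcorrelates\t{v}")
    for s, t, w in pdg.snp_edges:
        sif_lines.append(f"{s}\tqtl\t{t}")
    dot_lines = ["digraph mqtlnet {"]
    for s in pdg.snp_nodes:
        dot_lines.append(f'  "{s}" [shape=box];')
    for u, v, w in pdg.directed:
        dot_lines.append(f'  "{u}" -> "{v}" [label="{w:.2f}"];')
    for u, v, w in pdg.undirected:
        dot_lines.append(f'  "{u}" -> "{v}" [dir=none, label="{w:.2f}"];')
    for s, t, w in pdg.snp_edges:
        label = "" if np.isnan(w) else f' [label="{w:.1f}%"]'
        dot_lines.append(f'  "{s}" -> "{t}"{label};')
    dot_lines.append("}")
    return {
        "network.graphml": graphml,
        "network.sif": "\n".join(sif_lines) + "\n",
        "network.dot": "\n".join(dot_lines) + "\n",
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all enabled stages and write artifacts + manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    stages = cfg.stages
    for s in stages:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}")
    log.info(
        "thresholds: QC missing<=%s het<=%s maf>=%s | FDR report %s network %s | "
        "skeleton alpha %s orient alpha %s | seed %s",
        cfg.max_missing, cfg.max_het, cfg.min_maf, cfg.fdr_report,
        cfg.fdr_network, cfg.alpha_skeleton, cfg.alpha_orient, cfg.seed,
    )

    results: dict[str, object] = {}
    stage_log: list[StageResult] = []
    geno = pheno = truth = None

    def tick(name):
        return time.perf_counter()

    # --- simulate / ingest ------------------------------------------------
    t0 = tick("simulate")
    if "simulate" in stages:
        cfg.sim.seed = cfg.seed
        geno = simulate.simulate_genotypes(cfg.sim)
        pheno, truth = simulate.simulate_metabolome(geno, cfg.sim)
        results["genotypes.tsv"] = pd.DataFrame(
            geno.dosage, index=geno.lines, columns=geno.snps
        )
        results["phenotypes.tsv"] = pheno.frame
        results["sim_truth.json"] = truth.to_json_dict()
    else:
        if cfg.genotype_path is None or cfg.phenotype_path is None:
            raise ValueError("simulate disabled but genotype_path/phenotype_path not given")
        fmt = "vcf" if str(cfg.genotype_path).endswith(".vcf") else "matrix_tsv"
        geno = io.read_genotypes(cfg.genotype_path, fmt)
        pheno = io.read_phenotypes(cfg.phenotype_path)
    stage_log.append(StageResult("simulate", time.perf_counter() - t0))

    # --- qc ---------------------------------------------------------------
    t0 = tick("qc")
    if "qc" in stages:
        geno, qc = preprocess.filter_snps(geno, cfg.max_missing, cfg.max_het, cfg.min_maf)
        results["qc_report.tsv"] = qc.per_snp
        log.info("QC kept %d SNPs (removed %s)", qc.n_kept, qc.removed)
        if cfg.cv_filter is not None:
            frame, dropped = preprocess.cv_filter(pheno.frame, cfg.cv_filter)
            pheno = PhenotypeTable(frame)
            log.info("CV filter dropped traits: %s", dropped)
        if cfg.boxcox:
            parts = []
            for tr, sub in pheno.frame.groupby("trait"):
                vals, fit = preprocess.boxcox_fit_transform(sub["value"])
                sub = sub.copy()
                sub["value"] = vals
                parts.append(sub)
            pheno = PhenotypeTable(pd.concat(parts, ignore_index=True))
    stage_log.append(StageResult("qc", time.perf_counter() - t0))

    # --- trial model ------------------------------------------------------
    em = blues = vc = None
    t0 = tick("trial")
    if "trial" in stages:
        em = trial.entry_means_all(pheno)
        blues = trial.blues_across_envs(em)
        vc = trial.varcomp_table(pheno)
        results["blues.tsv"] = blues.values
        results["variance_components.tsv"] = vc.table
    stage_log.append(StageResult("trial", time.perf_counter() - t0))

    # --- correlations -----------------------------------------------------
    t0 = tick("corr")
    if "corr" in stages:
        if blues is None:
            raise ValueError("corr stage requires the trial stage")
        summary = correlate.pairwise_correlations(blues)
        results["correlations_r.tsv"] = summary.r
        results["correlations_p.tsv"] = summary.p
        results["correlation_tiers.json"] = summary.to_json_dict()
        Z = correlate.cluster_traits(summary)
        results["trait_dendrogram.nwk"] = correlate.linkage_to_newick(
            Z, list(summary.r.columns)
        )
        md = correlate.metabolite_distance(blues)
        gd = correlate.genomic_distance(geno)
        r_mantel, p_mantel = correlate.distance_matrix_correlation(
            md, gd, n_perm=999, seed=cfg.seed
        )
        results["mantel.json"] = {"r": r_mantel, "p": p_mantel}
    stage_log.append(StageResult("corr", time.perf_counter() - t0))

    # --- gwas -------------------------------------------------------------
    gw = None
    t0 = tick("gwas")
    if "gwas" in stages:
        if em is None or vc is None:
            raise ValueError("gwas stage requires the trial stage")
        K = gwas.kinship(geno)
        sel = vc.significant_traits(cfg.varcomp_alpha)
        log.info("GWAS over %d traits with significant genotypic variance", len(sel))
        n_envs = len(pheno.envs)
        n_reps = pheno.frame["rep"].nunique()
        h2 = vc.table["H2"]
        gw = gwas.scan_all(
            em, geno, K, blues, h2, traits=sel,
            fdr_report=cfg.fdr_report, snpxe=cfg.snpxe if cfg.snpxe != "significant" else "below_cut",
        )
        results["gwas_results.tsv"] = gw.table
        manh = gw.table[["trait", "snp", "p_snp"]].copy()
        manh["neglog10p"] = -np.log10(manh["p_snp"].clip(lower=1e-300))
        results["manhattan.tsv"] = manh
    stage_log.append(StageResult("gwas", time.perf_counter() - t0))

    # --- network ----------------------------------------------------------
    t0 = tick("network")
    if "network" in stages:
        if gw is None or blues is None or vc is None:
            raise ValueError("network stage requires the gwas stage (mQTL anchors)")
        sel = vc.significant_traits(cfg.varcomp_alpha)
        sel_blues = trial.Blues(blues.values[sel]) if sel else None
        if sel_blues is None or len(sel) < 2:
            log.warning("fewer than 2 traits with significant genotypic variance; skipping network")
        else:
            skel, sepsets, records = network.pc_skeleton(sel_blues, cfg.alpha_skeleton)
            anchors = gw.network_anchors(cfg.fdr_network)
            pgw = {
                (row["trait"], row["snp"]): row["p_G"]
                for _, row in gw.table.iterrows()
                if np.isfinite(row.get("p_G", np.nan))
            }
            pdg = network.qpso_orient(
                skel, sepsets, anchors, geno, sel_blues,
                alpha_orient=cfg.alpha_orient, pg_weights=pgw,
            )
            results.update(_graph_exports(pdg))
            results["ci_tests.tsv"] = pd.DataFrame(
                [
                    {
                        "i": r.i, "j": r.j, "cond_set": ",".join(r.cond_set),
                        "partial_corr": r.partial_corr, "z": r.z, "p": r.p,
                    }
                    for r in records
                ]
            )
    stage_log.append(StageResult("network", time.perf_counter() - t0))

    manifest = io.write_outputs(
        results, outdir, config_dict=cfg.to_dict(), seed=cfg.seed, force=cfg.force
    )
    manifest["stages"] = [
        {"name": s.name, "elapsed_s": round(s.elapsed, 3)} for s in stage_log
    ]
    (outdir / "manifest.json").write_text(
        __import__("json").dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
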