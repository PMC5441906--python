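"""Synthetic genotype/metabolome generator with known ground truth.

The generator emulates the statistical structure of a replicated
multi-environment metabolomics field trial on an inbred crop panel:

* genotypes with family structure but no major population structure,
  built from per-family founder haplotype pools;
* metabolite traits whose genetic values follow a linear causal DAG,
  anchored by sparse large-effect QTL plus a polygenic background;
* per-environment main effects, genotype-by-environment deviations
  (by default twice the genotypic variance), incomplete-block field
  effects and replicate-level measurement noise.

Every random draw is recorded or re-derivable, so downstream estimators
(variance components, association scans, network orientation) can be
tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig
from .data import GenotypeMatrix, PhenotypeTable, PHENO_COLUMNS

__all__ = ["SimTruth", "simulate_genotypes", "simulate_metabolome", "trait_names"]


def trait_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"m{i + 1:0{width}d}" for i in range(n)]


@dataclass
class SimTruth:
    """Ground truth of a simulated metabolome."""

    dag: nx.DiGraph
    qtl_effects: dict[tuple[str, int], float]
    genetic_values: pd.DataFrame  # line x trait total genetic values
    heading_dates: pd.Series
    env_effects: pd.DataFrame  # env x trait
    realized_var: pd.DataFrame = field(default=None)  # trait x component

    def to_json_dict(self) -> dict:
        return {
            "dag_edges": [
                [u, v, float(d["weight"])] for u, v, d in self.dag.edges(data=True)
            ],
            "qtl_effects": [
                [t, int(s), float(e)] for (t, s), e in sorted(self.qtl_effects.items())
            ],
            "heading_dates": {k: float(v) for k, v in self.heading_dates.items()},
            "realized_var": self.realized_var.to_dict() if self.realized_var is not None else None,
        }


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate an inbred panel with family structure.

    Each family descends from two founder haplotypes; a line's allele at
    each locus is drawn from one of its family's founders, so lines of
    the same family share more alleles than lines of different families.
    Heterozygous and missing calls (residual in real inbred panels) are
    injected at the configured rates.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)

    fam_of = np.arange(cfg.n_lines) % cfg.n_families
    # two founder haplotypes per family
    founders = rng.random((cfg.n_families, 2, cfg.n_snps)) < p  # allele indicator
    pick = rng.integers(0, 2, size=(cfg.n_lines, cfg.n_snps))
    alleles = founders[fam_of[:, None], pick, np.arange(cfg.n_snps)[None, :]]
    dosage = 2.0 * alleles

    if cfg.het_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.het_rate] = 1.0
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    lwidth = len(str(cfg.n_lines))
    lines = [f"L{i + 1:0{lwidth}d}" for i in range(cfg.n_lines)]
    swidth = len(str(cfg.n_snps))
    snps = [f"S{j + 1:0{swidth}d}" for j in range(cfg.n_snps)]
    # simple map: SNPs spread uniformly over 21 nominal chromosomes
    chroms = [f"{1 + (j % 21)}A" for j in range(cfg.n_snps)]
    pos = np.round(np.linspace(0.0, 200.0, cfg.n_snps), 2)
    snp_map = pd.DataFrame({"chrom": chroms, "pos_cM": pos}, index=snps)
    return GenotypeMatrix(lines, snps, dosage, snp_map)


def _dag_from_edges(edges, traits: list[str]) -> nx.DiGraph:
    dag = nx.DiGraph()
    dag.add_nodes_from(traits)
    for parent, child, coef in edges:
        for t in (parent, child):
            if t not in dag:
                raise ValueError(f"dag edge references unknown trait {t!r}")
        dag.add_edge(parent, child, weight=float(coef))
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("dag_edges encode a cyclic graph")
    return dag


def _imputed_centered(dosage: np.ndarray) -> np.ndarray:
    filled = dosage.copy()
    mu = np.nanmean(filled, axis=0)
    idx = np.where(np.isnan(filled))
    filled[idx] = mu[idx[1]]
    return filled - filled.mean(axis=0)


def simulate_metabolome(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate replicated multi-environment metabolite abundances.

    Per-line genetic values are generated in topological order of the
    causal DAG: each trait receives its QTL contributions (effects in
    genetic-SD units on standardized dosage), the weighted sum of its
    parents' genetic values, and a polygenic deviate with variance
    ``var_G`` (genomically correlated under the default setting, so the
    family structure of the panel is visible to a GWAS).  Observations
    add an environment main effect, a G-by-E deviate, an incomplete
    block effect and a residual.
    """
    cfg.validate()
    traits = trait_names(cfg.n_traits)
    dag = _dag_from_edges(cfg.dag_edges, traits)
    for trait, snp, _ in cfg.qtl_map:
        if trait not in traits:
            raise ValueError(f"qtl_map references unknown trait {trait!r}")
        if not (0 <= int(snp) < geno.n_snps):
            raise ValueError(f"qtl snp index {snp} out of range")

    n, t = geno.n_lines, cfg.n_traits
    rng = np.random.default_rng([cfg.seed, 23])
    centered = _imputed_centered(geno.dosage)
    sd = centered.std(axis=0)
    sd[sd == 0] = 1.0
    standardized = centered / sd

    g_sd = np.sqrt(cfg.var_G)
    qtl_effects = {(tr, int(s)): float(e) for tr, s, e in cfg.qtl_map}

    # polygenic background
    if cfg.polygenic == "genomic" and cfg.var_G > 0:
        lo, hi = cfg.polygenic_snps or (0, geno.n_snps)
        if not (0 <= lo < hi <= geno.n_snps):
            raise ValueError(f"polygenic_snps range {cfg.polygenic_snps} out of bounds")
        p_hat = np.clip(np.nanmean(geno.dosage[:, lo:hi], axis=0) / 2.0, 1e-6, 1 - 1e-6)
        denom = np.sum(2 * p_hat * (1 - p_hat))
        b = rng.normal(size=(hi - lo, t)) * np.sqrt(cfg.var_G / denom)
        poly = centered[:, lo:hi] @ b
    else:
        poly = rng.normal(scale=g_sd, size=(n, t))

    direct = poly.copy()
    for (tr, s), eff in qtl_effects.items():
        direct[:, traits.index(tr)] += eff * g_sd * standardized[:, int(s)]

    g = np.zeros((n, t))
    for tr in nx.topological_sort(dag):
        j = traits.index(tr)
        g[:, j] = direct[:, j]
        for parent in dag.predecessors(tr):
            g[:, j] += dag[parent][tr]["weight"] * g[:, traits.index(parent)]

    envs = [f"E{e + 1}" for e in range(cfg.n_envs)]
    env_eff = rng.normal(scale=cfg.env_effect_sd, size=(cfg.n_envs, t))
    gxe = rng.normal(scale=np.sqrt(cfg.var_GxE), size=(cfg.n_envs, n, t))

    nb = max(1, cfg.n_blocks_per_rep)
    block_eff = rng.normal(
        scale=cfg.block_sd, size=(cfg.n_envs, cfg.n_reps, nb, t)
    )
    resid = rng.normal(
        scale=np.sqrt(cfg.var_resid), size=(cfg.n_envs, cfg.n_reps, n, t)
    )

    line_idx = np.arange(n)
    records = []
    for e in range(cfg.n_envs):
        for r in range(cfg.n_reps):
            blocks = (line_idx + r) % nb  # cyclic allocation within replicate
            vals = (
                env_eff[e][None, :]
                + g
                + gxe[e]
                + block_eff[e, r, blocks, :]
                + resid[e, r]
            )
            for i in range(n):
                records.append((geno.lines[i], envs[e], f"R{r + 1}", f"B{blocks[i] + 1}", vals[i]))

    frame = pd.DataFrame(
        [
            (line, env, rep, blk, traits[j], v[j])
            for line, env, rep, blk, v in records
            for j in range(t)
        ],
        columns=PHENO_COLUMNS,
    )

    heading_rng = np.random.default_rng([cfg.seed, 31])
    heading = pd.Series(
        np.round(160 + heading_rng.normal(scale=cfg.heading_date_sd, size=n), 1),
        index=geno.lines,
        name="heading_date",
    )

    gv = pd.DataFrame(g, index=geno.lines, columns=traits)
    realized = pd.DataFrame(
        {
            "var_G_realized": gv.var(axis=0, ddof=1),
            "var_GxE": cfg.var_GxE,
            "var_resid": cfg.var_resid,
        }
    )
    truth = SimTruth(
        dag=dag,
        qtl_effects=qtl_effects,
        genetic_values=gv,
        heading_dates=heading,
        env_effects=pd.DataFrame(env_eff, index=envs, columns=traits),
        realized_var=realized,
    )
    return PhenotypeTable(frame), truth
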