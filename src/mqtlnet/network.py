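"""Causal phenotype-network inference: PC skeleton + QTL-supervised orientation.

The undirected conditional-independence skeleton over metabolite BLUEs
is learnt with the PC algorithm's edge-deletion phase (Fisher-z partial
correlation tests).  Significant mQTL are then added as always-directed
SNP -> trait anchors, and each remaining undirected trait-trait edge is
oriented by instrumental-variable style votes: a QTL q private to trait
yi votes for yi -> yj when q is marginally associated with yj but
independent of yj given yi.  Orientations that would close a directed
cycle among traits are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix
from .trial import Blues

__all__ = [
    "CiTestRecord",
    "PartiallyDirectedGraph",
    "fisher_z_test",
    "pc_skeleton",
    "qpso_orient",
]

log = logging.getLogger(__name__)


@dataclass
class CiTestRecord:
    i: str
    j: str
    cond_set: tuple[str, ...]
    partial_corr: float
    z: float
    p: float


@dataclass
class PartiallyDirectedGraph:
    """Mixed graph over metabolite and SNP nodes.

    Trait-trait edges may be directed or undirected and carry the
    pairwise Pearson correlation as weight; SNP -> trait edges are
    always directed and weighted by p_G (percent genotypic variance
    explained).
    """

    trait_nodes: list[str]
    snp_nodes: list[str] = field(default_factory=list)
    directed: list[tuple[str, str, float]] = field(default_factory=list)  # trait -> trait
    undirected: list[tuple[str, str, float]] = field(default_factory=list)
    snp_edges: list[tuple[str, str, float]] = field(default_factory=list)  # snp -> trait

    def validate(self) -> None:
        nodes = set(self.trait_nodes) | set(self.snp_nodes)
        for u, v, _ in self.directed + self.undirected:
            if u not in self.trait_nodes or v not in self.trait_nodes:
                raise ValueError(f"trait edge endpoint missing: {u}-{v}")
        for s, t, _ in self.snp_edges:
            if s not in self.snp_nodes or t not in self.trait_nodes:
                raise ValueError(f"snp edge endpoint missing: {s}->{t}")
        dg = nx.DiGraph()
        dg.add_nodes_from(self.trait_nodes)
        dg.add_edges_from([(u, v) for u, v, _ in self.directed])
        if not nx.is_directed_acyclic_graph(dg):
            raise ValueError("directed trait edges contain a cycle")
        _ = nodes

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for t in self.trait_nodes:
            g.add_node(t, kind="metabolite")
        for s in self.snp_nodes:
            g.add_node(s, kind="snp")
        for u, v, w in self.directed:
            g.add_edge(u, v, kind="directed", weight=w)
        for u, v, w in self.undirected:
            g.add_edge(u, v, kind="undirected", weight=w)
            g.add_edge(v, u, kind="undirected", weight=w)
        for s, t, w in self.snp_edges:
            g.add_edge(s, t, kind="qtl", weight=w)
        return g


def _partial_corr(C: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given S from a correlation matrix."""
    if not S:
        return float(C[i, j])
    idx = [i, j, *S]
    sub = C[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular conditioning covariance") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise ValueError("singular conditioning covariance")
    return float(-prec[0, 1] / np.sqrt(denom))


def fisher_z_test(
    data: pd.DataFrame, i: str, j: str, cond_set: tuple[str, ...] = (), alpha: float = 0.01
) -> CiTestRecord:
    """Fisher-z conditional-independence test on Gaussian data.

    z = atanh(r_partial) * sqrt(n - |S| - 3), two-sided normal p.
    """
    if i == j:
        raise ValueError("cannot test a variable against itself")
    cols = [i, j, *cond_set]
    sub = data[cols].dropna()
    n = len(sub)
    if n <= len(cond_set) + 3:
        raise ValueError(f"n={n} too small for conditioning set of size {len(cond_set)}")
    C = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    r = _partial_corr(C, 0, 1, tuple(range(2, 2 + len(cond_set))))
    r = float(np.clip(r, -0.999999, 0.999999))
    z = np.arctanh(r) * np.sqrt(n - len(cond_set) - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    _ = alpha
    return CiTestRecord(i, j, tuple(cond_set), r, float(z), float(p))


def pc_skeleton(
    blues: Blues | pd.DataFrame,
    alpha: float = 0.01,
    max_cond: int | None = None,
) -> tuple[nx.Graph, dict[frozenset, tuple[str, ...]], list[CiTestRecord]]:
    """PC edge-deletion phase over the selected traits.

    Starts from the complete graph; for growing conditioning-set size
    l = 0, 1, 2, ... removes edge (i, j) as soon as some subset of the
    current neighbours of i (or j) of size l renders the pair
    conditionally independent at ``alpha``.  Traits are processed in
    lexicographic order, so the result is deterministic.
    """
    data = blues.values if isinstance(blues, Blues) else blues
    data = data.dropna(axis=0)
    traits = sorted(data.columns)
    n = len(data)
    g = nx.Graph()
    g.add_nodes_from(traits)
    g.add_edges_from(combinations(traits, 2))
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    records: list[CiTestRecord] = []

    ell = 0
    while True:
        if n <= ell + 3:
            warnings.warn(f"sample size {n} too small for conditioning sets of size {ell}; stopping")
            break
        if max_cond is not None and ell > max_cond:
            break
        any_big_enough = False
        for i, j in sorted(tuple(sorted(e)) for e in g.edges()):
            neighbors = sorted((set(g.neighbors(i)) | set(g.neighbors(j))) - {i, j})
            if len(neighbors) < ell:
                continue
            any_big_enough = True
            removed = False
            for S in combinations(neighbors, ell):
                rec = fisher_z_test(data, i, j, S, alpha)
                records.append(rec)
                if rec.p > alpha:
                    g.remove_edge(i, j)
                    sepsets[frozenset((i, j))] = S
                    removed = True
                    break
            if removed:
                continue
        if not any_big_enough:
            break
        ell += 1
        if ell > len(traits) - 2:
            break
    return g, sepsets, records


def qpso_orient(
    skeleton: nx.Graph,
    sepsets: dict[frozenset, tuple[str, ...]],
    mqtl: dict[str, list[str]],
    geno: GenotypeMatrix,
    blues: Blues | pd.DataFrame,
    alpha_orient: float = 0.05,
    pg_weights: dict[tuple[str, str], float] | None = None,
) -> PartiallyDirectedGraph:
    """Orient skeleton edges using mQTL as upstream causal anchors.

    For an undirected edge yi - yj, every anchor q in mqtl(yi) but not
    in mqtl(yj) casts a vote for yi -> yj when q is marginally
    associated with yj (p < alpha) AND independent of yj given yi
    (p >= alpha): the association of q with yj flowing only through yi
    is the signature of yi being causally upstream.  Edges are oriented
    to the strict-majority direction; ties or no votes leave the edge
    undirected; orientations closing a directed trait cycle are skipped.
    """
    data = blues.values if isinstance(blues, Blues) else blues
    data = data.dropna(axis=0)
    traits = sorted(skeleton.nodes)
    lines = list(data.index)

    geno_cols: dict[str, pd.Series] = {}

    def snp_series(s: str) -> pd.Series | None:
        if s not in geno_cols:
            col = geno.dosage[:, geno.snps.index(s)].astype(float).copy()
            m = np.nanmean(col)
            col[np.isnan(col)] = m
            ser = pd.Series(col, index=geno.lines).reindex(lines)
            if ser.std() == 0 or ser.isna().any():
                warnings.warn(f"anchor SNP {s} constant or missing among scored lines; skipped")
                geno_cols[s] = None
            else:
                geno_cols[s] = ser
        return geno_cols[s]

    def vote(q: str, parent: str, child: str) -> bool:
        ser = snp_series(q)
        if ser is None:
            return False
        df = pd.concat([ser.rename("_q"), data[[parent, child]]], axis=1).dropna()
        marg = fisher_z_test(df, "_q", child, (), alpha_orient)
        if marg.p >= alpha_orient:
            return False
        cond = fisher_z_test(df, "_q", child, (parent,), alpha_orient)
        return cond.p >= alpha_orient

    directed_g = nx.DiGraph()
    directed_g.add_nodes_from(traits)
    directed: list[tuple[str, str, float]] = []
    undirected: list[tuple[str, str, float]] = []

    corr = data.corr()

    for i, j in sorted(tuple(sorted(e)) for e in skeleton.edges()):
        anchors_i = [q for q in mqtl.get(i, []) if q not in set(mqtl.get(j, []))]
        anchors_j = [q for q in mqtl.get(j, []) if q not in set(mqtl.get(i, []))]
        votes_ij = sum(vote(q, i, j) for q in anchors_i)
        votes_ji = sum(vote(q, j, i) for q in anchors_j)
        w = float(corr.loc[i, j])
        if votes_ij > votes_ji:
            src, dst = i, j
        elif votes_ji > votes_ij:
            src, dst = j, i
        else:
            undirected.append((i, j, w))
            continue
        directed_g.add_edge(src, dst)
        if not nx.is_directed_acyclic_graph(directed_g):
            directed_g.remove_edge(src, dst)
            log.warning("orientation %s->%s rejected: would create a cycle", src, dst)
            undirected.append((i, j, w))
        else:
            directed.append((src, dst, w))

    snp_nodes: list[str] = []
    snp_edges: list[tuple[str, str, float]] = []
    for trait in sorted(mqtl):
        if trait not in skeleton.nodes:
            continue
        for s in mqtl[trait]:
            if snp_series(s) is None:
                continue
            if s not in snp_nodes:
                snp_nodes.append(s)
            w = float((pg_weights or {}).get((trait, s), np.nan))
            snp_edges.append((s, trait, w))

    pdg = PartiallyDirectedGraph(
        trait_nodes=traits,
        snp_nodes=snp_nodes,
        directed=directed,
        undirected=undirected,
        snp_edges=snp_edges,
    )
    pdg.validate()
    return pdg
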