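"""Metabolite correlation structure and metabolome-genome distance tests.

Pairwise Pearson correlations among trait BLUEs, significance tiers at
p < 0.05 / 0.01 / 0.001 (cumulative: a pair significant at 0.001 also
counts at the looser tiers), UPGMA clustering on 1 - r, and a Mantel
permutation test between metabolomic and genomic line-distance
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import GenotypeMatrix
from .trial import Blues

__all__ = [
    "CorrelationSummary",
    "pairwise_correlations",
    "cluster_traits",
    "linkage_to_newick",
    "metabolite_distance",
    "genomic_distance",
    "distance_matrix_correlation",
]

TIERS = (0.05, 0.01, 0.001)


def tier_percentages(counts: dict[float, int], n_pairs: int) -> dict[float, float]:
    """Cumulative significance-tier percentages: 100 * count / n_pairs."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    return {tier: 100.0 * c / n_pairs for tier, c in counts.items()}


@dataclass
class CorrelationSummary:
    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: int
    tier_counts: dict[float, int]
    tier_percent: dict[float, float]

    def to_json_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "tier_counts": {str(k): v for k, v in self.tier_counts.items()},
            "tier_percent": {str(k): round(v, 2) for k, v in self.tier_percent.items()},
        }


def pairwise_correlations(blues: Blues) -> CorrelationSummary:
    """Pearson r and two-sided t-test p for every unordered trait pair."""
    vals = blues.values.dropna(axis=0)
    n = len(vals)
    if n < 3:
        raise ValueError("need >= 3 lines for correlation tests")
    traits = list(vals.columns)
    const = [t for t in traits if vals[t].nunique() <= 1]
    if const:
        warnings.warn(f"constant traits excluded from significance counts: {const}")

    X = vals.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    np.fill_diagonal(p, 0.0)

    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    iu = np.triu_indices(len(traits), k=1)
    valid = ~np.isnan(r[iu])
    n_pairs = len(traits) * (len(traits) - 1) // 2
    pv = p[iu][valid]
    counts = {tier: int(np.sum(pv < tier)) for tier in TIERS}
    percent = tier_percentages(counts, n_pairs)
    return CorrelationSummary(rdf, pdf, n_pairs, counts, percent)


def cluster_traits(summary: CorrelationSummary) -> np.ndarray:
    """Average-linkage (UPGMA) linkage matrix on distance 1 - r."""
    r = summary.r.to_numpy()
    if np.isnan(r).any():
        raise ValueError("correlation matrix contains missing values")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def metabolite_distance(blues: Blues) -> pd.DataFrame:
    """Euclidean distance between lines on standardized BLUEs."""
    vals = blues.values.dropna(axis=0)
    z = (vals - vals.mean()) / vals.std(ddof=1).replace(0, np.nan)
    z = z.dropna(axis=1)
    X = z.to_numpy(dtype=float)
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    return pd.DataFrame(np.sqrt(d2), index=vals.index, columns=vals.index)


def genomic_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing distance: mean dosage mismatch over non-missing SNPs, in [0, 1]."""
    d = geno.dosage
    n = geno.n_lines
    out = np.zeros((n, n))
    mask = ~np.isnan(d)
    for i in range(n):
        both = mask[i] & mask
        diff = np.abs(d[i][None, :] - np.where(mask, d, 0.0)) / 2.0
        diff[~both] = 0.0
        cnt = both.sum(axis=1)
        out[i] = np.where(cnt > 0, diff.sum(axis=1) / cnt, np.nan)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=geno.lines, columns=geno.lines)


def distance_matrix_correlation(
    metabolite_dist: pd.DataFrame,
    genomic_dist: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test: correlation of two line-distance matrices.

    r is the Pearson correlation of the lower-triangle entries; the
    permutation p-value re-labels the lines of the second matrix.
    """
    lines = list(metabolite_dist.index)
    if list(genomic_dist.index) != lines:
        common = [l for l in lines if l in genomic_dist.index]
        if len(common) != len(lines) or len(common) != len(genomic_dist):
            raise ValueError("distance matrices cover different line sets")
        genomic_dist = genomic_dist.loc[common, common]
    A = metabolite_dist.to_numpy(dtype=float)
    B = genomic_dist.to_numpy(dtype=float)
    if A.shape != B.shape:
        raise ValueError("distance matrix dimension mismatch")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    if a.std() == 0 or B[iu].std() == 0:
        raise ValueError("constant off-diagonal distances; correlation undefined")
    a = (a - a.mean()) / a.std()

    def corr_with(Bm: np.ndarray) -> float:
        b = Bm[iu]
        return float(np.mean(a * (b - b.mean()) / b.std()))

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p
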