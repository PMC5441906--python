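"""Kinship-corrected multi-environment association scan for metabolite traits.

Per-environment adjusted entry means of all lines are stacked and
modelled as

    Y = X beta + S s + (S x X) m + Z u + e,

with environment effects beta, a fixed allele-substitution effect s for
the tested SNP, a random SNP-by-environment interaction m, a polygenic
line effect u with covariance proportional to a genomic relationship
matrix K, and residual e.  Variance parameters of the null model are
estimated once per trait by REML and reused across SNPs (the standard
population-parameters-previously-determined shortcut), the SNP effect
is tested with a Wald F statistic, and the interaction variance with a
boundary-corrected likelihood ratio test.  Multiple testing is
controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .data import GenotypeMatrix
from .trial import EntryMeans, Blues
from .reml import reml_fit, lrt_variance

__all__ = [
    "GwasResult",
    "kinship",
    "mlm_scan",
    "scan_all",
    "fdr_adjust",
    "variance_explained",
    "pg",
    "genomic_inflation",
]


def kinship(geno: GenotypeMatrix, ridge: float = 1e-6) -> pd.DataFrame:
    """Genomic relationship matrix (VanRaden centered cross-product).

    Missing dosages are mean-imputed per SNP; columns are centered at
    twice the allele frequency and the cross-product is scaled by
    sum(2 p (1 - p)), so the mean diagonal is near 1.  A small ridge
    keeps the matrix positive definite.
    """
    if geno.n_snps < 2:
        raise ValueError("need >= 2 SNPs to build a kinship matrix")
    d = geno.dosage.copy()
    mu = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mu[idx[1]]
    p = mu / 2.0
    denom = float(np.sum(2 * p * (1 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    Zc = d - 2 * p
    K = Zc @ Zc.T / denom
    K[np.diag_indices_from(K)] += ridge
    return pd.DataFrame(K, index=geno.lines, columns=geno.lines)


@dataclass
class GwasResult:
    """Association-scan results: one row per (trait, SNP)."""

    table: pd.DataFrame  # trait, snp, chrom, pos_cM, effect, wald_F, p_snp, p_snpxe, q, significant, R2, p_G
    joint_r2: dict[str, float] | None = None  # per-trait joint adjusted R2 over significant SNPs

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.table[self.table["trait"] == trait]

    def network_anchors(self, q_threshold: float = 0.10) -> dict[str, list[str]]:
        """trait -> significant SNP ids at the network FDR level."""
        t = self.table
        sig = t[t["q"] < q_threshold]
        return {tr: sorted(sub["snp"]) for tr, sub in sig.groupby("trait")}


def _stack_trait(em: EntryMeans, trait: str) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    long = em.stacked(trait).dropna(subset=["value"])
    envs = sorted(long["env"].unique())
    lines = list(long["line"])
    y = long["value"].to_numpy(dtype=float)
    E = pd.get_dummies(long["env"])[envs].to_numpy(dtype=float)
    return y, E, lines, list(long["env"])


def _impute_center(col: np.ndarray) -> np.ndarray:
    col = col.astype(float).copy()
    m = np.nanmean(col)
    col[np.isnan(col)] = m
    return col - col.mean()


def mlm_scan(
    em: EntryMeans,
    geno: GenotypeMatrix,
    K: pd.DataFrame | None,
    trait: str,
    snpxe: str = "none",
    snpxe_pcut: float | None = None,
    fix_gamma_zero: bool = False,
) -> pd.DataFrame:
    """Mixed-model association scan for one trait.

    Parameters
    ----------
    K
        Genomic relationship matrix, or None to suppress the polygenic
        term entirely (plain fixed-effects scan; used to demonstrate
        stratification inflation).
    snpxe
        "none", "all", or "below_cut": whether to fit the random
        SNP-by-environment interaction and report its LRT p-value.
    fix_gamma_zero
        Pin the polygenic variance ratio at zero while keeping the
        mixed-model code path (testing hook: must reproduce OLS).
    """
    if em is None or trait not in em.means:
        raise KeyError(f"no entry means for trait {trait!r}")
    if snpxe not in ("none", "all", "below_cut"):
        raise ValueError("snpxe must be 'none', 'all' or 'below_cut'")
    y, E, obs_lines, obs_envs = _stack_trait(em, trait)
    n = y.size
    line_index = {l: i for i, l in enumerate(geno.lines)}
    rows = np.array([line_index[l] for l in obs_lines])

    use_mixed = K is not None
    if use_mixed:
        Km = K.loc[geno.lines, geno.lines].to_numpy(dtype=float)
        eigval = np.linalg.eigvalsh(Km)
        if eigval[0] < -1e-8:
            raise ValueError("kinship matrix is not positive semi-definite")
        ZKZ = Km[np.ix_(rows, rows)]
        if fix_gamma_zero:
            gamma = 0.0
        else:
            L = np.linalg.cholesky(Km + 1e-10 * np.eye(len(Km)))
            Zu = L[rows, :]
            null = reml_fit(y, E, [Zu], ["u"])
            gamma = float(null.gamma[0])
        lam, Q = np.linalg.eigh(ZKZ)
        w = 1.0 / (1.0 + gamma * np.clip(lam, 0.0, None))
        yr = Q.T @ y
        Er = Q.T @ E
    else:
        gamma = 0.0
        w = np.ones(n)
        yr, Er = y, E
        Q = None

    sw = np.sqrt(w)
    yw = yr * sw
    Ew = Er * sw[:, None]

    effects = np.full(geno.n_snps, np.nan)
    fstats = np.full(geno.n_snps, np.nan)
    pvals = np.full(geno.n_snps, np.nan)

    for j in range(geno.n_snps):
        s_line = _impute_center(geno.dosage[:, j])
        if np.allclose(s_line, 0.0):
            continue
        s_obs = s_line[rows]
        sr = (Q.T @ s_obs) if Q is not None else s_obs
        sw_col = sr * sw
        Xw = np.hstack([Ew, sw_col[:, None]])
        beta, res_ss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        dof = n - rank
        if dof <= 0 or rank < Xw.shape[1]:
            continue
        rss = float(res_ss[0]) if res_ss.size else float(np.sum((yw - Xw @ beta) ** 2))
        sigma2 = rss / dof
        XtX_inv_last = np.linalg.pinv(Xw.T @ Xw)[-1, -1]
        se = np.sqrt(sigma2 * XtX_inv_last)
        effects[j] = beta[-1]
        fstats[j] = (beta[-1] / se) ** 2
        pvals[j] = stats.f.sf(fstats[j], 1, dof)

    out = pd.DataFrame(
        {
            "trait": trait,
            "snp": geno.snps,
            "effect": effects,
            "wald_F": fstats,
            "p_snp": pvals,
            "p_snpxe": np.nan,
        }
    )
    if geno.snp_map is not None:
        out["chrom"] = [
            geno.snp_map.loc[s, "chrom"] if s in geno.snp_map.index else "Not Mapped"
            for s in geno.snps
        ]
        out["pos_cM"] = [
            geno.snp_map.loc[s, "pos_cM"] if s in geno.snp_map.index else np.nan
            for s in geno.snps
        ]

    if snpxe != "none":
        if snpxe == "all":
            test_idx = np.flatnonzero(~np.isnan(pvals))
        else:
            cut = snpxe_pcut if snpxe_pcut is not None else 1e-3
            test_idx = np.flatnonzero(pvals < cut)
        p_int = _snpxe_lrt(y, E, obs_envs, rows, geno, test_idx, K)
        out.loc[test_idx, "p_snpxe"] = p_int
    return out


def _snpxe_lrt(y, E, obs_envs, rows, geno, test_idx, K) -> np.ndarray:
    """Boundary-corrected LRT for the random SNP x environment variance."""
    if len(test_idx) == 0:
        return np.array([])
    if K is not None:
        Km = K.loc[geno.lines, geno.lines].to_numpy(dtype=float)
        L = np.linalg.cholesky(Km + 1e-10 * np.eye(len(Km)))
        Zu = L[rows, :]
        Zlist_base = [Zu]
        base_names = ["u"]
    else:
        Zlist_base = []
        base_names = []
    out = np.empty(len(test_idx))
    for k, j in enumerate(test_idx):
        s_line = _impute_center(geno.dosage[:, j])
        s_obs = s_line[rows]
        X = np.hstack([E, s_obs[:, None]])
        Zm = E * s_obs[:, None]  # one random interaction effect per environment
        full = reml_fit(y, X, Zlist_base + [Zm], base_names + ["snpxe"])
        reduced = reml_fit(y, X, Zlist_base, base_names)
        try:
            out[k] = lrt_variance(full.loglik, reduced.loglik, tol=1e-4)
        except ValueError:
            out[k] = 1.0  # numerically flat: no evidence for interaction variance
    return out


def fdr_adjust(pvalues: np.ndarray | pd.Series, q_threshold: float = 0.20):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values outside [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = q_ok
    flags = q < q_threshold
    return q, flags


def variance_explained(
    blues: Blues, geno: GenotypeMatrix, snps: list[str], trait: str
) -> tuple[pd.Series, float]:
    """Percent phenotypic variance explained by selected SNPs.

    Marginal R2 per SNP is the squared Pearson correlation of the trait
    BLUEs with the dosage (x100); the joint value is the adjusted R2 of
    the multiple regression on all selected SNPs (rank-aware, so
    duplicated or collinear SNPs do not inflate it).
    """
    if not snps:
        raise ValueError("no SNPs selected")
    yv = blues.values[trait].dropna()
    lines = list(yv.index)
    li = [geno.lines.index(l) for l in lines]
    y = yv.to_numpy(dtype=float)
    n = y.size

    r2 = {}
    cols = []
    for s in snps:
        x = _impute_center(geno.dosage[:, geno.snps.index(s)])[li]
        if np.allclose(x, 0):
            warnings.warn(f"SNP {s} constant among scored lines; R2 set to 0")
            r2[s] = 0.0
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[s] = 100.0 * r * r
        cols.append(x)

    if cols:
        X = np.column_stack([np.ones(n)] + cols)
        rank = np.linalg.matrix_rank(X)
        beta = np.linalg.pinv(X) @ y
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2_joint = 1.0 - np.sum(resid**2) / tss
        k = rank - 1
        if n - k - 1 > 0:
            adj = 1.0 - (1.0 - r2_joint) * (n - 1) / (n - k - 1)
        else:
            adj = np.nan
        joint = 100.0 * adj
    else:
        joint = 0.0
    return pd.Series(r2), float(joint)


def pg(r2_percent: float, h2: float) -> tuple[float, bool]:
    """Percent genotypic variance explained: single-SNP R2 standardized by H2.

    Returns (p_G, capped_flag); capped at 100 when R2 exceeds the
    genotypic fraction of the phenotypic variance.
    """
    if not (0 <= r2_percent <= 100):
        raise ValueError(f"R2 percent {r2_percent} outside [0, 100]")
    if h2 is None or not np.isfinite(h2) or h2 <= 0:
        warnings.warn("non-positive heritability; p_G undefined")
        return np.nan, False
    if h2 > 1:
        raise ValueError(f"heritability {h2} above 1")
    val = r2_percent / h2
    if val > 100:
        return 100.0, True
    return val, False


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def scan_all(
    em: EntryMeans,
    geno: GenotypeMatrix,
    K: pd.DataFrame | None,
    blues: Blues,
    h2: pd.Series,
    traits: list[str] | None = None,
    fdr_report: float = 0.20,
    snpxe: str = "below_cut",
) -> GwasResult:
    """Scan every (selected) trait; FDR per trait; R2 and p_G for all SNPs."""
    traits = traits if traits is not None else em.traits
    frames = []
    joint = {}
    for trait in traits:
        res = mlm_scan(em, geno, K, trait, snpxe="none")
        q, flags = fdr_adjust(res["p_snp"].to_numpy(), fdr_report)
        res["q"] = q
        res["significant"] = flags
        if snpxe != "none":
            sig_idx = np.flatnonzero(flags)
            y, E, obs_lines, obs_envs = _stack_trait(em, trait)
            line_index = {l: i for i, l in enumerate(geno.lines)}
            rows = np.array([line_index[l] for l in obs_lines])
            p_int = _snpxe_lrt(y, E, obs_envs, rows, geno, sig_idx, K)
            res.loc[res.index[sig_idx], "p_snpxe"] = p_int

        res["R2"] = np.nan
        res["p_G"] = np.nan
        res["p_G_capped"] = False
        sig_snps = list(res.loc[res["significant"], "snp"])
        if sig_snps:
            r2, joint_adj = variance_explained(blues, geno, sig_snps, trait)
            joint[trait] = joint_adj
            h2_t = float(h2.get(trait, np.nan))
            for s in sig_snps:
                i = res.index[res["snp"] == s][0]
                res.loc[i, "R2"] = r2[s]
                val, capped = pg(r2[s], h2_t)
                res.loc[i, "p_G"] = val
                res.loc[i, "p_G_capped"] = capped
        frames.append(res)
    return GwasResult(pd.concat(frames, ignore_index=True), joint_r2=joint)
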