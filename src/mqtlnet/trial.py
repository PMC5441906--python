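"""Multi-environment trial modelling for replicated metabolite data.

Two-stage analysis in the plant-breeding tradition:

1. per environment, adjusted entry means per line with replicate and
   incomplete-block effects recovered as random nuisance;
2. across environments, fixed-effect BLUEs per line.

Alongside, a one-step random-effects model on the replicate-level data
estimates the genotypic, genotype-by-environment and residual variance
components by REML, from which entry-mean heritability and
per-environment repeatability are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PhenotypeTable
from .reml import reml_fit, lrt_variance, RemlResult

__all__ = [
    "EntryMeans",
    "Blues",
    "VarianceComponents",
    "adjusted_entry_means",
    "entry_means_all",
    "blues_across_envs",
    "reml_varcomp",
    "varcomp_table",
    "heritability",
    "repeatability",
    "subgroup_heritability",
]


@dataclass
class EntryMeans:
    """Adjusted entry means: per trait, a line x environment matrix."""

    means: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return sorted(self.means)

    @property
    def envs(self) -> list[str]:
        first = self.means[self.traits[0]]
        return list(first.columns)

    @property
    def lines(self) -> list[str]:
        first = self.means[self.traits[0]]
        return list(first.index)

    def stacked(self, trait: str) -> pd.DataFrame:
        """Long format (line, env, value) with missing cells dropped."""
        m = self.means[trait]
        out = m.stack().rename("value").reset_index()
        out.columns = ["line", "env", "value"]
        return out


@dataclass
class Blues:
    """Best linear unbiased estimates of line values across environments."""

    values: pd.DataFrame  # line x trait

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lines(self) -> list[str]:
        return list(self.values.index)


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def _fit_entry_means_one(sub: pd.DataFrame) -> pd.Series:
    """Line as fixed effect; replicate and block-within-replicate random."""
    lines = sorted(sub["line"].unique())
    X = pd.get_dummies(sub["line"].astype(str))[lines].to_numpy(dtype=float)
    Z_blocks, names = [], []
    if sub["rep"].nunique() > 1:
        Z_blocks.append(_dummies(sub["rep"]))
        names.append("rep")
    rb = sub["rep"].astype(str) + ":" + sub["block"].astype(str)
    if rb.nunique() > sub["rep"].nunique():
        Z_blocks.append(_dummies(rb))
        names.append("block")
    y = sub["value"].to_numpy(dtype=float)
    res = reml_fit(y, X, Z_blocks, names)
    est = pd.Series(res.beta, index=lines)
    return est - est.mean() + y.mean()


def adjusted_entry_means(pheno: PhenotypeTable, env: str) -> pd.DataFrame:
    """Adjusted entry means for one environment (line x trait)."""
    sub_env = pheno.frame[pheno.frame["env"] == env]
    if sub_env.empty:
        raise ValueError(f"no observations for environment {env!r}")
    out = {}
    for trait, sub in sub_env.groupby("trait"):
        out[trait] = _fit_entry_means_one(sub)
    return pd.DataFrame(out).reindex(pheno.lines)


def entry_means_all(pheno: PhenotypeTable) -> EntryMeans:
    per_env = {env: adjusted_entry_means(pheno, env) for env in pheno.envs}
    em = EntryMeans()
    for trait in pheno.traits:
        em.means[trait] = pd.DataFrame(
            {env: per_env[env][trait] for env in pheno.envs}
        )
    return em


def blues_across_envs(em: EntryMeans) -> Blues:
    """Across-environment BLUEs from the entry-mean tables.

    Fits line + environment as fixed effects (least squares, deviation
    coding for environments) per trait, so a complete table reduces to
    the per-line row mean.  Lines missing everywhere are dropped with a
    warning.
    """
    if len(em.envs) < 2:
        raise ValueError("need entry means from at least 2 environments")
    out = {}
    for trait in em.traits:
        m = em.means[trait]
        long = em.stacked(trait)
        lines = [l for l in m.index if m.loc[l].notna().any()]
        missing_all = set(m.index) - set(lines)
        if missing_all:
            warnings.warn(f"trait {trait}: lines with no entry mean dropped: {sorted(missing_all)}")
        long = long[long["line"].isin(lines)]
        Xl = pd.get_dummies(long["line"])[lines].to_numpy(dtype=float)
        envs = list(m.columns)
        Ed = pd.get_dummies(long["env"])[envs].to_numpy(dtype=float)
        # deviation coding: env effects sum to zero -> line columns are BLUEs
        Xe = Ed[:, :-1] - Ed[:, -1:]
        X = np.hstack([Xl, Xe])
        beta, *_ = np.linalg.lstsq(X, long["value"].to_numpy(dtype=float), rcond=None)
        out[trait] = pd.Series(beta[: len(lines)], index=lines).reindex(m.index)
    return Blues(pd.DataFrame(out))


@dataclass
class VarianceComponents:
    """Per-trait REML variance components and derived ratios."""

    table: pd.DataFrame  # index trait; sigma2_G, sigma2_GxE, sigma2_e, loglik, p_G_lrt, H2, w2_*

    def significant_traits(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return sorted(t.index[t["p_G_lrt"] < alpha])


def reml_varcomp(
    pheno: PhenotypeTable,
    trait: str,
    include_rep: bool = True,
    include_block: bool = True,
    lrt: bool = True,
) -> dict[str, float]:
    """One-step REML variance components for a single trait.

    Model: value = env (+ rep within env, fixed) + block within rep
    (random) + line (random) + line x env (random) + residual.  Returns
    the three headline components, the restricted log-likelihood and a
    boundary-corrected LRT p-value for the genotypic variance.
    """
    sub = pheno.for_trait(trait)
    if sub["env"].nunique() < 2 or sub["rep"].nunique() < 2:
        raise ValueError("need >= 2 environments and >= 2 replicates for the one-step model")
    y = sub["value"].to_numpy(dtype=float)

    X_parts = [_dummies(sub["env"])]
    if include_rep and sub["rep"].nunique() > 1:
        er = sub["env"].astype(str) + ":" + sub["rep"].astype(str)
        X_parts.append(_dummies(er))
    X = np.hstack(X_parts)

    Z_blocks, names = [], []
    if include_block:
        erb = (
            sub["env"].astype(str) + ":" + sub["rep"].astype(str) + ":" + sub["block"].astype(str)
        )
        if erb.nunique() > (sub["env"].nunique() * sub["rep"].nunique()):
            Z_blocks.append(_dummies(erb))
            names.append("block")
    Z_line = _dummies(sub["line"])
    Z_blocks.append(Z_line)
    names.append("line")
    le = sub["line"].astype(str) + ":" + sub["env"].astype(str)
    Z_blocks.append(_dummies(le))
    names.append("line_env")

    full = reml_fit(y, X, Z_blocks, names)
    if not full.converged:
        raise RuntimeError(f"REML did not converge for trait {trait}")

    out = {
        "sigma2_G": full.sigma2["line"],
        "sigma2_GxE": full.sigma2["line_env"],
        "sigma2_e": full.sigma2["resid"],
        "loglik": full.loglik,
    }
    if lrt:
        line_idx = names.index("line")
        reduced = reml_fit(y, X, Z_blocks, names, fix_gamma={line_idx: 0.0})
        out["p_G_lrt"] = lrt_variance(full.loglik, reduced.loglik)
    return out


def heritability(sigma2_G: float, sigma2_GxE: float, sigma2_e: float,
                 n_envs: int, n_reps: int) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H2 = s2_G / (s2_G + s2_GxE / nE + s2_e / (nE * nRep)).
    """
    for v in (sigma2_G, sigma2_GxE, sigma2_e):
        if v < 0:
            raise ValueError("variance components must be >= 0")
    denom = sigma2_G + sigma2_GxE / n_envs + sigma2_e / (n_envs * n_reps)
    if denom == 0:
        return np.nan
    return sigma2_G / denom


def repeatability(sigma2_G: float, sigma2_e: float, n_reps: int) -> float:
    """Within-environment repeatability w2 = s2_G / (s2_G + s2_e / nRep)."""
    if sigma2_G < 0 or sigma2_e < 0:
        raise ValueError("variance components must be >= 0")
    denom = sigma2_G + sigma2_e / n_reps
    if denom == 0:
        return np.nan
    return sigma2_G / denom


def _within_env_varcomp(sub: pd.DataFrame) -> tuple[float, float]:
    """Two-component (line, residual) REML within one environment."""
    y = sub["value"].to_numpy(dtype=float)
    X_parts = [np.ones((len(sub), 1))]
    if sub["rep"].nunique() > 1:
        X_parts.append(_dummies(sub["rep"]))
    X = np.hstack(X_parts)
    Z_blocks, names = [], []
    rb = sub["rep"].astype(str) + ":" + sub["block"].astype(str)
    if rb.nunique() > sub["rep"].nunique():
        Z_blocks.append(_dummies(rb))
        names.append("block")
    Z_blocks.append(_dummies(sub["line"]))
    names.append("line")
    res = reml_fit(y, X, Z_blocks, names)
    return res.sigma2["line"], res.sigma2["resid"]


def varcomp_table(pheno: PhenotypeTable, with_repeatability: bool = True) -> VarianceComponents:
    """REML components, H2 and per-environment w2 for every trait."""
    envs = pheno.envs
    n_envs, n_reps = len(envs), pheno.frame["rep"].nunique()
    rows = {}
    for trait in pheno.traits:
        vc = reml_varcomp(pheno, trait)
        row = dict(vc)
        row["H2"] = heritability(vc["sigma2_G"], vc["sigma2_GxE"], vc["sigma2_e"], n_envs, n_reps)
        if with_repeatability:
            sub = pheno.for_trait(trait)
            for env in envs:
                s2g, s2e = _within_env_varcomp(sub[sub["env"] == env])
                row[f"w2_{env}"] = repeatability(s2g, s2e, n_reps)
        rows[trait] = row
    return VarianceComponents(pd.DataFrame(rows).T)


def subgroup_heritability(
    pheno: PhenotypeTable,
    heading_dates: pd.Series,
    n_groups: int = 3,
    min_group: int = 10,
) -> pd.Series:
    """Mean trait heritability within maturity subgroups.

    Lines are split into ``n_groups`` equal-frequency groups by heading
    date (terciles by default); variance components and H2 are estimated
    within each group, and the mean H2 across traits is reported per
    group.  A degenerate covariate (all dates equal) falls back to an
    equal-size random split with a warning.
    """
    lines = pheno.lines
    hd = heading_dates.reindex(lines)
    if hd.isna().any():
        raise ValueError("heading date missing for some lines")
    if hd.nunique() == 1:
        warnings.warn("heading dates constant; using equal-size random split")
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(lines))
        groups = pd.Series(perm % n_groups, index=lines)
    else:
        groups = pd.Series(
            pd.qcut(hd.rank(method="first"), n_groups, labels=False), index=lines
        )
    n_envs = len(pheno.envs)
    n_reps = pheno.frame["rep"].nunique()
    out = {}
    labels = ["early", "intermediate", "late"] if n_groups == 3 else [
        f"group{i + 1}" for i in range(n_groups)
    ]
    for gi in range(n_groups):
        members = groups.index[groups == gi]
        if len(members) < min_group:
            warnings.warn(f"maturity group {labels[gi]} has only {len(members)} lines")
        sub = PhenotypeTable(pheno.frame[pheno.frame["line"].isin(members)])
        h2s = []
        for trait in sub.traits:
            vc = reml_varcomp(sub, trait, lrt=False)
            h2s.append(
                heritability(vc["sigma2_G"], vc["sigma2_GxE"], vc["sigma2_e"], n_envs, n_reps)
            )
        out[labels[gi]] = float(np.nanmean(h2s))
    return pd.Series(out)
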