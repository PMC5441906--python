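"""Genotype QC, drift normalization and variance-stabilizing transforms.

SNP quality control follows the conventions of array-genotyped inbred
panels: loci are dropped when monomorphic, when more than 5% of calls
are missing, when residual heterozygosity exceeds 5%, or when the minor
allele frequency falls below 5% (all thresholds configurable).  Minor
allele frequency is computed on non-missing calls with heterozygotes
contributing one copy of each allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix

__all__ = [
    "QcReport",
    "BoxCoxFit",
    "filter_snps",
    "normalize_to_reference",
    "boxcox_fit_transform",
    "cv_filter",
]


@dataclass
class QcReport:
    per_snp: pd.DataFrame  # missing_frac, het_frac, maf, monomorphic, kept
    removed: dict[str, int]

    @property
    def n_kept(self) -> int:
        return int(self.per_snp["kept"].sum())

    def to_tsv(self, path) -> None:
        self.per_snp.to_csv(path, sep="\t", index_label="snp")


def filter_snps(
    geno: GenotypeMatrix,
    max_missing: float = 0.05,
    max_het: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the four SNP QC rules and return the passing submatrix.

    The rules are evaluated independently per SNP, so their order does
    not affect the kept set; a SNP may be counted removed under several
    rules at once.
    """
    for name, v in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name}={v} outside [0,1]")
    if geno.n_snps == 0 or geno.n_lines == 0:
        raise ValueError("empty genotype matrix")

    d = geno.dosage
    n_called = np.sum(~np.isnan(d), axis=0)
    missing_frac = 1.0 - n_called / geno.n_lines
    with np.errstate(invalid="ignore"):
        het_frac = np.nansum(d == 1, axis=0) / np.maximum(n_called, 1)
        alt_freq = np.nansum(d, axis=0) / np.maximum(2 * n_called, 1)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    mono = np.array([len(np.unique(col[~np.isnan(col)])) <= 1 for col in d.T])
    mono |= n_called == 0

    kept = (
        ~mono
        & (missing_frac <= max_missing)
        & (het_frac <= max_het)
        & (maf >= min_maf)
    )
    per_snp = pd.DataFrame(
        {
            "missing_frac": missing_frac,
            "het_frac": het_frac,
            "maf": maf,
            "monomorphic": mono,
            "kept": kept,
        },
        index=geno.snps,
    )
    removed = {
        "monomorphic": int(mono.sum()),
        "missing": int((missing_frac > max_missing).sum()),
        "heterozygosity": int((het_frac > max_het).sum()),
        "maf": int((maf < min_maf).sum()),
        "total_removed": int((~kept).sum()),
    }
    return geno.subset_snps(kept), QcReport(per_snp, removed)


def normalize_to_reference(
    values: pd.Series, batches: pd.Series, reference: pd.Series
) -> pd.Series:
    """Divide each observation by its batch's mixed-sample reference.

    A pooled "mixed sample" measured in every batch captures systematic
    drift across the measurement sequence; dividing by it and rescaling
    by the grand mean of references yields drift-corrected relative
    abundances on the original scale.
    """
    reference = reference.astype(float)
    if (reference <= 0).any():
        bad = reference[reference <= 0].index.tolist()
        raise ValueError(f"non-positive reference for batch(es) {bad}")
    unknown = set(batches.unique()) - set(reference.index)
    if unknown:
        raise ValueError(f"batches without reference value: {sorted(unknown)}")
    ref_per_obs = batches.map(reference).astype(float)
    return values / ref_per_obs.values * reference.mean()


@dataclass
class BoxCoxFit:
    lmbda: float
    shift: float
    loglik: float

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if np.any(x <= 0):
            raise ValueError("values non-positive after shift")
        if self.lmbda == 0:
            return np.log(x)
        return (np.power(x, self.lmbda) - 1.0) / self.lmbda


def _boxcox_loglik(x: np.ndarray, lmbda: float) -> float:
    # profile log-likelihood of the normal model after transforming
    n = x.size
    if lmbda == 0:
        z = np.log(x)
    else:
        z = (np.power(x, lmbda) - 1.0) / lmbda
    var = z.var()
    if var <= 0:
        return -np.inf
    return -0.5 * n * np.log(var) + (lmbda - 1.0) * np.sum(np.log(x))


def boxcox_fit_transform(
    values: np.ndarray | pd.Series,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, BoxCoxFit]:
    """Fit a Box-Cox power transform by profile likelihood on a lambda grid.

    The exponent is chosen to maximize the normal profile log-likelihood
    over the grid (default -2..2 in steps of 0.1).  Ties are broken
    toward the identity (lambda = 1), then toward the log (lambda = 0).
    A shift is applied first if any value is non-positive.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct finite values")
    if grid is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)

    shift = 0.0
    if x.min() <= 0:
        shift = 1e-6 - x.min()
    xs = x + shift

    logliks = np.array([_boxcox_loglik(xs, lm) for lm in grid])
    best = np.max(logliks)
    # tie-break toward 1, then 0, then smallest |lambda|
    candidates = np.flatnonzero(np.isclose(logliks, best, rtol=0, atol=1e-9))
    order = sorted(
        candidates,
        key=lambda i: (abs(grid[i] - 1.0) > 1e-12, abs(grid[i]) > 1e-12, abs(grid[i])),
    )
    i = order[0]
    fit = BoxCoxFit(lmbda=float(grid[i]), shift=shift, loglik=float(logliks[i]))
    full = np.asarray(values, dtype=float)
    return fit.transform(full), fit


def cv_filter(
    pheno_frame: pd.DataFrame, max_cv: float | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Drop traits whose replicate-level coefficient of variation exceeds a cut.

    A light stand-in for platform-specific metabolite QC: per trait, the
    CV of replicate values within each (line, environment) cell is
    averaged; traits above ``max_cv`` are removed.  Disabled (None) by
    default.
    """
    if max_cv is None:
        return pheno_frame, []
    dropped = []
    for trait, sub in pheno_frame.groupby("trait"):
        cell = sub.groupby(["line", "env"])["value"]
        mean_abs = cell.mean().abs()
        cv = (cell.std(ddof=1) / mean_abs.replace(0, np.nan)).mean()
        if np.isfinite(cv) and cv > max_cv:
            dropped.append(trait)
    kept = pheno_frame[~pheno_frame["trait"].isin(dropped)].copy()
    return kept, dropped
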