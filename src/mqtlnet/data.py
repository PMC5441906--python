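"""Core in-memory containers shared across the pipeline.

Genotypes are held as a lines x SNPs dosage matrix (0 = homozygous
reference/major, 1 = heterozygous, 2 = homozygous alternate/minor,
NaN = missing call).  Replicated phenotypes are held in long format, one
row per (line, environment, replicate, trait) observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["line", "env", "rep", "block", "trait", "value"]


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix for a panel of (mostly inbred) lines.

    Parameters
    ----------
    lines
        Unique line identifiers, one per matrix row.
    snps
        Unique SNP identifiers, one per matrix column.
    dosage
        Float array of shape ``(n_lines, n_snps)`` with entries in
        {0, 1, 2} or NaN for missing calls.
    snp_map
        Optional map with index = SNP id and columns ``chrom`` (label,
        "Not Mapped" allowed) and ``pos_cM`` (float centimorgans).
    """

    lines: list[str]
    snps: list[str]
    dosage: np.ndarray
    snp_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.lines), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.lines)} lines x {len(self.snps)} SNPs"
            )
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line ids")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[tuple(bad)]} at line "
                f"{self.lines[bad[0]]}, snp {self.snps[bad[1]]}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a view-like copy restricted to SNP columns where ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        snps = [self.snps[i] for i in idx]
        snp_map = None
        if self.snp_map is not None:
            snp_map = self.snp_map.loc[[s for s in snps if s in self.snp_map.index]]
        return GenotypeMatrix(list(self.lines), snps, self.dosage[:, idx].copy(), snp_map)

    def column(self, snp: str) -> np.ndarray:
        return self.dosage[:, self.snps.index(snp)]


@dataclass
class PhenotypeTable:
    """Long-format replicated observations of metabolite abundances."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        self.frame = self.frame[PHENO_COLUMNS].copy()
        if not pd.api.types.is_numeric_dtype(self.frame["value"]):
            bad = self.frame[pd.to_numeric(self.frame["value"], errors="coerce").isna()]
            raise ValueError(f"non-numeric phenotype values at rows {list(bad.index[:5])}")
        key = ["line", "env", "rep", "trait"]
        dup = self.frame.duplicated(subset=key)
        if dup.any():
            first = self.frame[dup].iloc[0]
            raise ValueError(
                "duplicate observation for "
                f"(line={first['line']}, env={first['env']}, "
                f"rep={first['rep']}, trait={first['trait']})"
            )

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    @property
    def envs(self) -> list[str]:
        return sorted(self.frame["env"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.frame["line"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.frame[self.frame["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub
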