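"""Readers and writers for the pipeline's external formats.

Genotypes: tab-separated lines x SNPs matrix (header = SNP ids, first
column = line id, missing = "NA") with an optional 2-column map file,
or a VCF (GT fields converted to dosage, multi-allelic records
rejected).  Phenotypes: long-format CSV.  Results: TSV/JSON/GraphML/
Newick, plus a manifest carrying the config hash and content hashes so
reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, PhenotypeTable, PHENO_COLUMNS

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_outputs",
]


def write_genotypes(geno: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(geno.dosage, index=geno.lines, columns=geno.snps)
    with np.errstate(invalid="ignore"):
        out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index_label="line")
    if map_path is not None and geno.snp_map is not None:
        geno.snp_map.to_csv(map_path, sep="\t", index_label="snp")


def _read_matrix_tsv(path: Path, map_path: Path | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lines = [str(x) for x in df.index]
    snps = [str(c) for c in df.columns]
    dosage = np.empty(df.shape, dtype=float)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, v in enumerate(row):
            if v == "NA" or v is None or (isinstance(v, float) and np.isnan(v)):
                dosage[i, j] = np.nan
            else:
                try:
                    dosage[i, j] = float(v)
                except ValueError as exc:
                    raise ValueError(f"malformed genotype value {v!r} at row {i + 2}") from exc
    snp_map = None
    if map_path is not None and Path(map_path).exists():
        snp_map = pd.read_csv(map_path, sep="\t", index_col=0)
    return GenotypeMatrix(lines, snps, dosage, snp_map)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    snps, rows, chroms, pos = [], [], [], []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS} not supported")
        sid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snps.append(sid)
        chroms.append(var.CHROM)
        pos.append(float(var.POS))
        gts = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        rows.append(dos)
    dosage = np.array(rows).T if rows else np.empty((len(lines), 0))
    snp_map = pd.DataFrame({"chrom": chroms, "pos_cM": pos}, index=snps)
    return GenotypeMatrix(lines, snps, dosage, snp_map)


def read_genotypes(path: str | Path, fmt: str = "matrix_tsv", map_path: str | Path | None = None) -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "matrix_tsv":
        return _read_matrix_tsv(path, map_path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.frame.to_csv(path, index=False, float_format="%.17g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype={"line": str, "env": str, "rep": str, "block": str, "trait": str})
    missing = [c for c in PHENO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype CSV missing columns: {missing}")
    vals = pd.to_numeric(frame["value"], errors="coerce")
    bad = frame[vals.isna() & frame["value"].notna()]
    if not bad.empty:
        raise ValueError(f"non-numeric phenotype value at CSV row {bad.index[0] + 2}")
    frame["value"] = vals
    return PhenotypeTable(frame)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    results: dict[str, object],
    outdir: str | Path,
    config_dict: dict | None = None,
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Write every artifact in ``results`` and a manifest of content hashes.

    ``results`` maps relative file names to objects: DataFrames are
    written as TSV, dicts/lists as JSON, strings verbatim (e.g. Newick
    or GraphML text).  Identical inputs and seed reproduce byte-identical
    numeric tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")

    written = {}
    for name, obj in results.items():
        path = outdir / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        path.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", float_format="%.10g")
        elif isinstance(obj, (dict, list)):
            path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))
        elif isinstance(obj, str):
            path.write_text(obj)
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
        written[name] = _sha256(path)

    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": written,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
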