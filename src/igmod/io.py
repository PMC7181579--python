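"""File I/O: PLINK text PED/MAP, genotype CSV, and scan result TSV."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .contingency import MISSING, GenotypeMatrix

logger = logging.getLogger("igmod")


def _recode_alleles(allele_pairs: np.ndarray, snp_id: str) -> np.ndarray:
    """Additive minor-allele coding of one SNP's allele pairs.

    ``allele_pairs``: (n, 2) array of single-character allele strings, '0'
    for missing.  The minor allele is the less frequent one in the sample;
    ties break lexicographically by allele character.
    """
    flat = allele_pairs.ravel()
    obs = flat[flat != "0"]
    alleles = sorted(set(obs.tolist()))
    if len(alleles) > 2:
        raise ValueError(f"SNP {snp_id}: more than two alleles {alleles}")
    if len(alleles) == 0:
        return np.full(allele_pairs.shape[0], MISSING, dtype=np.int8)
    if len(alleles) == 1:
        minor = alleles[0]  # monomorphic: count the only allele
    else:
        c0 = int((obs == alleles[0]).sum())
        c1 = int((obs == alleles[1]).sum())
        # lexicographic tie-break: alleles is sorted, prefer the first
        minor = alleles[0] if c0 <= c1 else alleles[1]
    missing_row = (allele_pairs == "0").any(axis=1)
    g = (allele_pairs == minor).sum(axis=1).astype(np.int8)
    g[missing_row] = MISSING
    return g


def read_ped_map(ped_path, map_path):
    """Read PLINK text PED/MAP into a GenotypeMatrix plus phenotype.

    Phenotype column must be coded 1/2 (unaffected/affected) with 0/-9
    missing; individuals with missing phenotype are dropped with a log
    entry.  Genotypes are recoded additively by per-SNP minor allele.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "snp_id", "cm", "bp"], dtype={"snp_id": str})
    m = len(map_df)
    rows, phenos = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * m}")
            phenos.append(parts[5])
            rows.append(parts[6:])
    if not rows:
        raise ValueError(f"{ped_path}: no individuals")
    pheno_raw = np.array(phenos)
    keep = np.isin(pheno_raw, ("1", "2"))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_ped_map: dropped %d individuals with missing phenotype", dropped)
    if not keep.any():
        raise ValueError("all individuals have missing phenotype")
    alleles = np.array(rows, dtype="<U8")[keep]
    pheno = (pheno_raw[keep] == "2").astype(np.int8)
    geno = np.empty((alleles.shape[0], m), dtype=np.int8)
    for j in range(m):
        geno[:, j] = _recode_alleles(alleles[:, 2 * j:2 * j + 2], map_df["snp_id"].iloc[j])
    gm = GenotypeMatrix(geno, map_df["snp_id"].tolist(),
                        positions=map_df["bp"].to_numpy())
    return gm, pheno


def read_genotype_csv(path, phenotype_col: str = "phenotype"):
    """Read an additive-coded genotype CSV (header of SNP ids + phenotype).

    Cells must be 0/1/2 or NA; the phenotype column must be 0/1.
    """
    df = pd.read_csv(path)
    if phenotype_col not in df.columns:
        raise ValueError(f"missing phenotype column {phenotype_col!r}")
    pheno = df[phenotype_col].to_numpy()
    if not np.isin(pheno, (0, 1)).all():
        raise ValueError("phenotype column must be binary 0/1")
    snp_cols = [c for c in df.columns if c != phenotype_col]
    geno = df[snp_cols].to_numpy(dtype=float)
    bad = ~(np.isnan(geno) | np.isin(geno, (0, 1, 2)))
    if bad.any():
        raise ValueError("genotype cells must be 0, 1, 2 or NA")
    g = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(g, snp_cols), pheno.astype(np.int8)


_PVAL_COLS = ("p_liberal", "p_conservative", "p_logreg", "p_lrt", "p_tig")


def write_results(table: pd.DataFrame, path) -> None:
    """Write a scan result table as TSV, p-values in 6-significant-digit
    scientific notation; round-trippable with :func:`read_results`."""
    out = table.copy()
    for col in out.columns:
        if col in _PVAL_COLS:
            out[col] = out[col].map(lambda p: f"{p:.5e}" if np.isfinite(p) else "NA")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values="NA")
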