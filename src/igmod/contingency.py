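"""Genotype-phenotype contingency structures.

Every estimator in this package is a plug-in functional of a single
3 x 3 x 2 contingency tensor ``X[i, j, k]``: the number of individuals
carrying ``i`` copies of the minor allele at the first locus, ``j`` copies at
the second, with disease status ``k`` (0 = unaffected, 1 = affected).  This
module builds and validates those tensors from additive-coded genotype
columns.

Missing genotypes are handled by pairwise-complete deletion: an individual
missing either genotype of a pair is dropped for that pair only, so the
effective sample size ``N`` may vary between pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call.
MISSING = -1

_VALID_GENOTYPES = frozenset({MISSING, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for ``n`` individuals at ``m`` SNPs.

    Parameters
    ----------
    genotypes
        Integer matrix of shape ``(n, m)`` with entries in ``{0, 1, 2}``
        (minor-allele count) or :data:`MISSING`.
    snp_ids
        Unique identifier per SNP, length ``m``.
    positions
        Optional base-pair positions, length ``m``.
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (individuals x SNPs)")
        if g.shape[0] < 1 or g.shape[1] < 1:
            raise ValueError("need at least one individual and one SNP")
        if not np.isin(g, list(_VALID_GENOTYPES)).all():
            bad = np.unique(g[~np.isin(g, list(_VALID_GENOTYPES))])
            raise ValueError(f"genotype entries must be 0/1/2 or {MISSING}; found {bad}")
        self.genotypes = g.astype(np.int8, copy=False)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.snp_ids) != g.shape[1]:
            raise ValueError("snp_ids length must equal number of SNPs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions)
            if self.positions.shape != (g.shape[1],):
                raise ValueError("positions length must equal number of SNPs")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.genotypes[:, j]


def validate_phenotype(status, require_both_classes: bool = False) -> np.ndarray:
    """Validate a binary phenotype vector (0 = unaffected, 1 = affected)."""
    d = np.asarray(status)
    if d.ndim != 1:
        raise ValueError("phenotype must be a 1-D vector")
    if not np.isin(d, (0, 1)).all():
        raise ValueError("phenotype must be binary with entries in {0, 1}")
    d = d.astype(np.int8, copy=False)
    if require_both_classes and (d.min() == d.max()):
        raise ValueError("both phenotype classes must be present")
    return d


@dataclass(frozen=True)
class PairCounts:
    """3 x 3 x 2 contingency tensor for one SNP pair against disease status."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3, 2):
            raise ValueError("counts must have shape (3, 3, 2)")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() < 1:
            raise ValueError("counts must tally at least one individual")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def N(self) -> int:
        """Total number of individuals counted."""
        return int(self.counts.sum())

    def genotype_table(self) -> np.ndarray:
        """3 x 3 genotype cross-tabulation, pooled over disease status."""
        return self.counts.sum(axis=2)


def count_pair(g1, g2, pheno) -> PairCounts:
    """Tally the 3 x 3 x 2 contingency tensor for two genotype columns.

    Individuals missing either genotype are excluded pairwise; ``N``
    reflects the exclusions.  Raises if no individual has complete data or
    the phenotype is not binary.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    d = validate_phenotype(pheno)
    if not (len(g1) == len(g2) == len(d)):
        raise ValueError("genotype columns and phenotype must have equal length")
    mask = (g1 != MISSING) & (g2 != MISSING)
    if not mask.any():
        raise ValueError("no individual with complete genotype data for this pair")
    g1c = g1[mask].astype(np.int64)
    g2c = g2[mask].astype(np.int64)
    dc = d[mask].astype(np.int64)
    if ((g1c < 0) | (g1c > 2) | (g2c < 0) | (g2c > 2)).any():
        raise ValueError("genotypes must be coded 0/1/2 (or missing)")
    flat = (g1c * 3 + g2c) * 2 + dc
    counts = np.bincount(flat, minlength=18).reshape(3, 3, 2)
    return PairCounts(counts)


@dataclass(frozen=True)
class ProbTable:
    """Relative frequencies of a :class:`PairCounts` tensor with margins.

    ``e_factor`` is the conditional-dependence factor
    ``E[i,j,k] = p[i,j,k] p[.,.,k] / (p[i,.,k] p[.,j,k])`` and ``l_factor``
    the linkage-disequilibrium factor
    ``L[i,j] = p[i,j,.] / (p[i,.,.] p[.,j,.])``.  Cells whose denominator is
    zero carry ``nan`` (the downstream 0*log conventions never read them).
    """

    p: np.ndarray
    p_ij: np.ndarray = field(repr=False)
    p_i: np.ndarray = field(repr=False)
    p_j: np.ndarray = field(repr=False)
    p_ik: np.ndarray = field(repr=False)
    p_jk: np.ndarray = field(repr=False)
    p_k: np.ndarray = field(repr=False)
    e_factor: np.ndarray = field(repr=False)
    l_factor: np.ndarray = field(repr=False)


def normalize(counts: PairCounts | np.ndarray) -> ProbTable:
    """Turn a contingency tensor into relative frequencies plus margins."""
    c = counts.counts if isinstance(counts, PairCounts) else np.asarray(counts)
    n = c.sum()
    if n < 1:
        raise ValueError("empty contingency tensor")
    p = c / n
    p_ij = p.sum(axis=2)
    p_i = p.sum(axis=(1, 2))
    p_j = p.sum(axis=(0, 2))
    p_ik = p.sum(axis=1)
    p_jk = p.sum(axis=0)
    p_k = p.sum(axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        e = p * p_k[None, None, :] / (p_ik[:, None, :] * p_jk[None, :, :])
        l = p_ij / np.outer(p_i, p_j)
    return ProbTable(p=p, p_ij=p_ij, p_i=p_i, p_j=p_j, p_ik=p_ik,
                     p_jk=p_jk, p_k=p_k, e_factor=e, l_factor=l)
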