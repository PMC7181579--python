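"""Exhaustive pairwise interaction scan with LD filtering.

`PairwiseInteractionScan` is the modelling entry point: construct it from a
genotype matrix and binary phenotype, call :meth:`fit`, and inspect the
returned :class:`ScanResults`.  Every unordered SNP pair (i < j) is tested
with the modified entropy statistic; pairs in linkage disequilibrium
(squared genotype correlation above ``ld_r2_max``) are excluded, since the
statistic assumes linkage equilibrium.  P-values under both gamma shapes are
always reported; the significance flag uses the configured criterion, and
flagged pairs receive an HLO classification and submodel label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, io
from .comparators import logreg_interaction_1df, lrt_4df, tig_pvalue
from .contingency import MISSING, GenotypeMatrix, validate_phenotype
from .entropy import _components, pair_counts_all
from .hlo import classify_hlo, match_submodel


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two additive genotype columns.

    Composite LD on pooled samples with pairwise-complete deletion.
    Returns ``nan`` when either column is constant or fewer than two
    complete individuals overlap.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    mask = (g1 != MISSING) & (g2 != MISSING)
    if mask.sum() < 2:
        return float("nan")
    a, b = g1[mask], g2[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class ScanConfig:
    """Decision-rule and filtering options for a pairwise scan."""

    criterion: str = "liberal"
    alpha_global: float = 0.05
    per_test_level: float | None = None
    ld_r2_max: float | None = 0.01
    methods: tuple[str, ...] = ()
    statistic: str = "igmod"
    cell_alpha: float = 0.1
    min_cell_n: int = 10
    adjust_main_effects: bool = True
    tig_n_perm: int = 999
    tig_seed: int = 0


@dataclass
class ScanResults:
    """Per-pair statistics, p-values, flags and HLO labels of one scan."""

    table: pd.DataFrame
    config: ScanConfig
    cutoff: float
    per_test_level: float
    n_pairs_enumerated: int
    filtered: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_pairs_tested(self) -> int:
        return len(self.table)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            f"Pairwise interaction scan ({self.config.statistic}, "
            f"{self.config.criterion} criterion)",
            f"pairs enumerated: {self.n_pairs_enumerated}; tested: "
            f"{self.n_pairs_tested}; LD-filtered: {len(self.filtered)}",
            f"per-test level {self.per_test_level:.3g} -> statistic cutoff "
            f"{self.cutoff:.6f} bits",
            f"significant pairs: {int(self.table['significant'].sum())}",
        ]
        sig = self.significant
        if len(sig):
            lines.append(sig.to_string(index=False, max_rows=20))
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        io.write_results(self.table, path)


class PairwiseInteractionScan:
    """Exhaustive two-locus entropy scan of a case-control genotype matrix."""

    def __init__(self, genotypes, phenotype, snp_ids=None):
        if isinstance(genotypes, GenotypeMatrix):
            self.gm = genotypes
        else:
            g = np.asarray(genotypes)
            ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(g.shape[1])]
            self.gm = GenotypeMatrix(g, list(ids))
        self.pheno = validate_phenotype(phenotype, require_both_classes=True)
        if len(self.pheno) != self.gm.n_individuals:
            raise ValueError("phenotype length must match number of individuals")
        if self.gm.n_snps < 2:
            raise ValueError("need at least two SNPs to scan")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype_col: str = "phenotype"):
        snp_cols = [c for c in df.columns if c != phenotype_col]
        return cls(df[snp_cols].to_numpy(), df[phenotype_col].to_numpy(), snp_cols)

    def fit(self, config: ScanConfig | None = None, **kwargs) -> ScanResults:
        if config is None:
            config = ScanConfig(**kwargs)
        elif kwargs:
            raise ValueError("pass either a ScanConfig or keyword options, not both")
        X = self.gm.genotypes
        m = self.gm.n_snps
        ids = self.gm.snp_ids
        a_idx, b_idx = np.triu_indices(m, k=1)

        counts = pair_counts_all(X, self.pheno)
        c = np.moveaxis(counts[:, :, :, a_idx, b_idx], -1, 0)  # (P, 3, 3, 2)
        n_pair = c.sum(axis=(1, 2, 3))

        # LD filter and degenerate columns
        r2 = np.array([ld_r2(X[:, i], X[:, j]) for i, j in zip(a_idx, b_idx)])
        if config.ld_r2_max is None:
            keep = np.ones(len(a_idx), dtype=bool)
            reason = np.array([""] * len(a_idx), dtype=object)
        else:
            keep = np.isfinite(r2) & (r2 <= config.ld_r2_max)
            reason = np.where(~np.isfinite(r2), "undefined_r2",
                              np.where(r2 > (config.ld_r2_max or np.inf), "ld", ""))
        filtered = pd.DataFrame({
            "snp1": [ids[i] for i in a_idx[~keep]],
            "snp2": [ids[j] for j in b_idx[~keep]],
            "r2": r2[~keep],
            "reason": reason[~keep],
        })

        comp = _components(c[keep])
        stat = comp[config.statistic]
        n_kept = n_pair[keep]

        n_total = self.gm.n_individuals
        lib = calibration.make_null(n_total, "liberal")
        con = calibration.make_null(n_total, "conservative")
        p_lib = lib.dist.sf(np.clip(comp["igmod"], 0.0, None))
        p_con = con.dist.sf(np.clip(comp["igmod0"], 0.0, None))

        if config.per_test_level is not None:
            level = config.per_test_level
        else:
            level = config.alpha_global / max(int(keep.sum()), 1)
        null = calibration.make_null(n_total, config.criterion)
        cutoff = calibration.cutoff(null, level)
        significant = stat > cutoff

        rows = pd.DataFrame({
            "snp1": [ids[i] for i in a_idx[keep]],
            "snp2": [ids[j] for j in b_idx[keep]],
            "n": n_kept.astype(int),
            "r2": r2[keep],
            "igmod": comp["igmod"],
            "igmod0": comp["igmod0"],
            "p_liberal": p_lib,
            "p_conservative": p_con,
            "significant": significant,
        })

        hlo_strings = np.array([""] * len(rows), dtype=object)
        submodels = np.array([""] * len(rows), dtype=object)
        kept_counts = c[keep]
        for pos in np.flatnonzero(significant):
            h = classify_hlo(kept_counts[pos], cell_alpha=config.cell_alpha,
                             min_cell_n=config.min_cell_n,
                             adjust_main_effects=config.adjust_main_effects)
            hlo_strings[pos] = str(h)
            submodels[pos] = match_submodel(h)
        rows["hlo"] = hlo_strings
        rows["submodel"] = submodels

        for method in config.methods:
            pvals = np.full(len(rows), np.nan)
            rng = np.random.default_rng(config.tig_seed)
            for pos in range(len(rows)):
                if method == "logreg":
                    pvals[pos] = logreg_interaction_1df(kept_counts[pos]).pvalue
                elif method == "lrt":
                    pvals[pos] = lrt_4df(kept_counts[pos]).pvalue
                elif method == "tig":
                    pvals[pos] = tig_pvalue(kept_counts[pos],
                                            n_perm=config.tig_n_perm, rng=rng).pvalue
                else:
                    raise ValueError(f"unknown comparator method {method!r}")
            rows[f"p_{method}"] = pvals

        return ScanResults(rows, config, float(cutoff), float(level),
                           n_pairs_enumerated=len(a_idx), filtered=filtered)


def pairwise_scan(gm, pheno, config: ScanConfig | None = None, **kwargs) -> ScanResults:
    """Functional wrapper around :class:`PairwiseInteractionScan`."""
    return PairwiseInteractionScan(gm, pheno).fit(config, **kwargs)
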