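"""Case-control genotype simulation under two-locus interaction models.

Datasets mirror the reference simulation design: 100 SNPs of which 2
interact, 800 cases and 800 controls, null-SNP minor allele frequencies
drawn uniformly from (0.05, 0.5), 1000 replicates per configuration.

The interacting pair is sampled retrospectively: the 9-cell genotype
distribution of cases is ``P(G|D1) ∝ P(G) f(G)`` and of controls
``P(G|D0) ∝ P(G) (1 - f(G))`` with ``P(G)`` the Hardy-Weinberg product and
``f`` the model's penetrance table, so the target case/control counts are
exact in every replicate.  Null SNPs are independent Hardy-Weinberg draws.
Phenotype order is cases first, then controls.  All randomness derives from
``(seed, replicate_index)``, so any subset of replicates is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration
from .comparators import logreg_interaction_1df, lrt_4df, tig_pvalue
from .contingency import GenotypeMatrix, PairCounts
from .entropy import _components, pair_statistics
from .hlo import classify_hlo, match_submodel
from .models import ModelSpec

DEFAULT_THRESHOLDS = (5e-2, 5e-3, 5e-4, 5e-5, 5e-6)


@dataclass(frozen=True)
class SimConfig:
    """One simulation configuration (defaults mirror the reference design)."""

    model_spec: ModelSpec
    n_cases: int = 800
    n_controls: int = 800
    n_snps: int = 100
    interacting_idx: tuple[int, int] = (0, 1)
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("need at least two SNPs")
        a, b = self.interacting_idx
        if a == b or not (0 <= a < self.n_snps) or not (0 <= b < self.n_snps):
            raise ValueError("interacting_idx must be two distinct valid indices")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("null MAF range must lie within (0, 0.5]")


def _rng_for(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate_index)]))


def sample_interacting_pair(model_spec: ModelSpec, n_cases: int, n_controls: int,
                            rng: np.random.Generator):
    """Draw the interacting pair's genotype columns and the phenotype.

    Exact categorical sampling over the 9 genotype cells from the
    case-conditional and control-conditional distributions; cases first.
    """
    from .models import hwe_probs

    w = np.outer(hwe_probs(model_spec.maf1), hwe_probs(model_spec.maf2))
    pen = model_spec.penetrance.pen
    p_case = (w * pen).ravel()
    p_ctrl = (w * (1.0 - pen)).ravel()
    if n_cases > 0 and p_case.sum() <= 0:
        raise ValueError("case-conditional genotype distribution has zero mass")
    if n_controls > 0 and p_ctrl.sum() <= 0:
        raise ValueError("control-conditional genotype distribution has zero mass")
    cols = []
    for n_k, p_k in ((n_cases, p_case), (n_controls, p_ctrl)):
        if n_k == 0:
            cols.append(np.empty(0, dtype=np.int64))
            continue
        cell_counts = rng.multinomial(n_k, p_k / p_k.sum())
        cols.append(np.repeat(np.arange(9), cell_counts))
    cells = np.concatenate(cols)
    g1 = (cells // 3).astype(np.int8)
    g2 = (cells % 3).astype(np.int8)
    pheno = np.concatenate([np.ones(n_cases, dtype=np.int8),
                            np.zeros(n_controls, dtype=np.int8)])
    return g1, g2, pheno


def sample_null_snps(n_individuals: int, n_snps: int, maf_range: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Null SNP columns: per-SNP MAF ~ Uniform(range), genotypes i.i.d. HWE."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must lie within (0, 0.5]")
    mafs = rng.uniform(lo, hi, size=n_snps)
    return rng.binomial(2, mafs[None, :], size=(n_individuals, n_snps)).astype(np.int8)


def simulate_dataset(config: SimConfig, replicate_index: int):
    """One replicate: a GenotypeMatrix plus phenotype, reproducible from (seed, rep)."""
    rng = _rng_for(config.seed, replicate_index)
    n = config.n_cases + config.n_controls
    g1, g2, pheno = sample_interacting_pair(config.model_spec, config.n_cases,
                                            config.n_controls, rng)
    X = np.empty((n, config.n_snps), dtype=np.int8)
    a, b = config.interacting_idx
    X[:, a] = g1
    X[:, b] = g2
    null_cols = [j for j in range(config.n_snps) if j not in (a, b)]
    if null_cols:
        X[:, null_cols] = sample_null_snps(n, len(null_cols), config.null_maf_range, rng)
    gm = GenotypeMatrix(X, [f"snp{j}" for j in range(config.n_snps)])
    return gm, pheno


@dataclass
class StudyResult:
    """Outcome of a type-I-error or power study."""

    kind: str
    records: pd.DataFrame
    n_replicates: int
    seed: int
    rejections: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.kind} study: {self.n_replicates} replicates (seed {self.seed})"]
        if self.rejections is not None:
            lines.append(self.rejections.to_string(index=False))
        if self.kind == "power":
            pw = self.power()
            lines.append("overall power: " +
                         ", ".join(f"{k}={v:.3f}" for k, v in pw.items()))
        return "\n".join(lines)

    # power-study accessors -------------------------------------------------
    def power(self) -> dict[str, float]:
        det = [c for c in self.records.columns if c.startswith("detected_")]
        return {c.removeprefix("detected_"): float(self.records[c].mean()) for c in det}

    def submodel_table(self) -> pd.DataFrame:
        """Frequency of each observed HLO pattern and conditional power."""
        det = [c for c in self.records.columns if c.startswith("detected_")]
        grp = self.records.groupby("hlo", sort=False)
        out = grp.agg(n=("hlo", "size"), submodel=("submodel", "first"),
                      **{c.removeprefix("detected_"): (c, "mean") for c in det})
        out["freq"] = out["n"] / len(self.records)
        return out.sort_values("freq", ascending=False).reset_index()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


class TypeIStudy:
    """Empirical type-I error of the entropy statistic over null SNP pairs.

    For every replicate of every configuration, gamma p-values are computed
    for all non-interacting pairs (all pairs except the interacting one —
    4949 of 4950 at the default 100 SNPs, including pairs that contain one
    interacting SNP) and compared with the nominal thresholds.
    """

    def __init__(self, configs, thresholds=DEFAULT_THRESHOLDS,
                 criterion: str = "liberal", statistic: str = "igmod"):
        if not configs:
            raise ValueError("need at least one configuration")
        self.configs = list(configs)
        self.thresholds = tuple(thresholds)
        self.criterion = criterion
        self.statistic = statistic

    def run(self) -> StudyResult:
        thr = np.asarray(self.thresholds)
        rows = []
        for ci, cfg in enumerate(self.configs):
            null = calibration.make_null(cfg.n_cases + cfg.n_controls, self.criterion)
            a, b = sorted(cfg.interacting_idx)
            for rep in range(cfg.n_replicates):
                gm, pheno = simulate_dataset(cfg, rep)
                stats_ = pair_statistics(gm.genotypes, pheno, (self.statistic,))
                pairs = stats_["pairs"]
                keep = ~((pairs[:, 0] == a) & (pairs[:, 1] == b))
                pv = calibration.pvalue(
                    np.clip(stats_[self.statistic][keep], 0.0, None), null)
                rows.append({
                    "config": ci, "model": cfg.model_spec.model_name,
                    "maf": cfg.model_spec.maf1, "replicate": rep,
                    "n_pairs": int(keep.sum()),
                    **{f"rej_{t:g}": int((pv <= t).sum()) for t in thr},
                })
        rec = pd.DataFrame(rows)
        total = rec["n_pairs"].sum()
        rej = pd.DataFrame({
            "threshold": thr,
            "rejections": [rec[f"rej_{t:g}"].sum() for t in thr],
        })
        rej["type_i_error"] = rej["rejections"] / total
        rej["n_pairs"] = total
        return StudyResult("type1", rec, int(rec.shape[0]),
                           self.configs[0].seed, rejections=rej,
                           extras={"criterion": self.criterion, "statistic": self.statistic})


class PowerStudy:
    """Detection rate for the interacting pair, with HLO submodel breakdown.

    ``methods`` is a subset of {"entropy", "logreg", "lrt", "tig"}.  The
    entropy statistic is detected when it exceeds ``entropy_cutoff``
    (default: the liberal gamma threshold at per-test level 1e-5); the
    regression/LRT/permutation comparators when their p-value falls below
    ``comparator_level``.  Non-converged comparator fits count as
    non-detections.  Only the interacting pair itself is simulated and
    tested; its draws coincide with the first columns of the full dataset.
    """

    def __init__(self, config: SimConfig, methods=("entropy", "logreg"),
                 entropy_cutoff: float | None = None,
                 comparator_level: float = 1e-5,
                 statistic: str = "igmod",
                 criterion: str = "liberal",
                 n_perm: int = 999,
                 cell_alpha: float = 0.1, min_cell_n: int = 10,
                 adjust_main_effects: bool = True):
        self.config = config
        self.methods = tuple(methods)
        unknown = set(self.methods) - {"entropy", "logreg", "lrt", "tig"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        n = config.n_cases + config.n_controls
        if entropy_cutoff is None:
            entropy_cutoff = calibration.cutoff(calibration.make_null(n, criterion), 1e-5)
        self.entropy_cutoff = float(entropy_cutoff)
        self.comparator_level = float(comparator_level)
        self.statistic = statistic
        self.n_perm = int(n_perm)
        self.hlo_kwargs = dict(cell_alpha=cell_alpha, min_cell_n=min_cell_n,
                               adjust_main_effects=adjust_main_effects)

    def run(self) -> StudyResult:
        cfg = self.config
        rows = []
        for rep in range(cfg.n_replicates):
            rng = _rng_for(cfg.seed, rep)
            g1, g2, pheno = sample_interacting_pair(cfg.model_spec, cfg.n_cases,
                                                    cfg.n_controls, rng)
            counts = np.zeros((3, 3, 2), dtype=np.int64)
            np.add.at(counts, (g1, g2, pheno), 1)
            comp = _components(counts.astype(float))
            stat = float(comp[self.statistic])
            hlo = classify_hlo(counts, **self.hlo_kwargs)
            row = {"replicate": rep, "statistic": stat, "hlo": str(hlo),
                   "submodel": match_submodel(hlo)}
            for method in self.methods:
                if method == "entropy":
                    row["detected_entropy"] = stat > self.entropy_cutoff
                elif method == "logreg":
                    res = logreg_interaction_1df(PairCounts(counts))
                    row["p_logreg"] = res.pvalue
                    row["detected_logreg"] = bool(res.converged and
                                                  res.pvalue < self.comparator_level)
                elif method == "lrt":
                    res = lrt_4df(PairCounts(counts))
                    row["p_lrt"] = res.pvalue
                    row["detected_lrt"] = bool(res.converged and np.isfinite(res.pvalue)
                                               and res.pvalue < self.comparator_level)
                elif method == "tig":
                    res = tig_pvalue(counts, n_perm=self.n_perm,
                                     rng=np.random.default_rng(
                                         np.random.SeedSequence([cfg.seed, rep, 7])))
                    row["p_tig"] = res.pvalue
                    row["detected_tig"] = bool(res.pvalue < self.comparator_level)
            rows.append(row)
        rec = pd.DataFrame(rows)
        return StudyResult("power", rec, cfg.n_replicates, cfg.seed,
                           extras={"entropy_cutoff": self.entropy_cutoff,
                                   "statistic": self.statistic,
                                   "model": cfg.model_spec.model_name,
                                   "maf": cfg.model_spec.maf1})


def run_type1_study(configs, thresholds=DEFAULT_THRESHOLDS, criterion="liberal",
                    statistic="igmod") -> StudyResult:
    """Functional wrapper around :class:`TypeIStudy`."""
    return TypeIStudy(configs, thresholds, criterion, statistic).run()


def run_power_study(config, methods=("entropy", "logreg"), **kwargs) -> StudyResult:
    """Functional wrapper around :class:`PowerStudy`."""
    return PowerStudy(config, methods, **kwargs).run()
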