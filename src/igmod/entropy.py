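"""Entropy-based interaction statistics for a 3 x 3 x 2 contingency tensor.

The central quantity is the modified information gain

    IGmod = IG(D|G) - IG(D|G1) - IG(D|G2)

which removes both loci's main effects from the second-order information
gain and therefore isolates the interaction signal.  It equals, via the
interaction-information identity,

    IGmod = CMI(G1;G2 | D) - MI(G1;G2)

where the conditional mutual information ``CMI`` (here ``igmod0``) is the
case-weighted plus control-weighted within-stratum mutual information of the
two genotypes.  In a population without linkage disequilibrium the two
estimators target the same quantity, but their sampling null laws differ:
``2 N ln2 * igmod`` is asymptotically chi-square(4) and
``2 N ln2 * igmod0`` chi-square(8), i.e. gamma nulls with shape 2 and 4 on
the bits scale (see :mod:`igmod.calibration`).

All statistics are plug-in maximum-likelihood estimators in bits, with the
convention ``0 * log 0 = 0``: terms with a zero numerator are skipped, so a
genotype class absent from a stratum simply contributes nothing.  ``geno_cmi``
is the same summation as ``igmod0`` in natural-log units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contingency import PairCounts

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class EntropyStat:
    """An entropy statistic with its kind and the sample size it used."""

    value: float
    kind: str
    n: int
    units: str = "bits"


def _tensor(counts) -> np.ndarray:
    c = counts.counts if isinstance(counts, PairCounts) else np.asarray(counts, dtype=float)
    if c.shape[-3:] != (3, 3, 2):
        raise ValueError("expected a (..., 3, 3, 2) contingency tensor")
    return np.asarray(c, dtype=float)


def _require_both_classes(c: np.ndarray) -> None:
    pk = c.sum(axis=(-3, -2))
    if np.any(pk <= 0):
        raise ValueError("both phenotype classes must be present")


def _xlogx_ratio(num: np.ndarray, den: np.ndarray, out_weight: np.ndarray | None = None) -> np.ndarray:
    """Sum of ``w * log2(num/den)`` terms with the 0*log0 := 0 convention.

    ``out_weight`` defaults to ``num``.  Terms with zero weight are skipped
    regardless of the denominator, matching the plug-in estimator restricted
    to the observed support.
    """
    w = num if out_weight is None else out_weight
    res = np.zeros(np.broadcast_shapes(w.shape, num.shape, den.shape))
    nz = w > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.broadcast_to(w, res.shape)[nz] * np.log2(
            np.broadcast_to(num, res.shape)[nz] / np.broadcast_to(den, res.shape)[nz]
        )
    res[nz] = vals
    return res


def shannon_entropy(probs) -> float:
    """Shannon entropy ``-sum p log2 p`` in bits of a probability vector."""
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def _components(c: np.ndarray) -> dict[str, np.ndarray]:
    """Batched second/first-order information gains and CMI for (..., 3, 3, 2)."""
    n = c.sum(axis=(-3, -2, -1), keepdims=True)
    p = c / n
    p_ij = p.sum(-1, keepdims=True)
    p_k = p.sum((-3, -2), keepdims=True)
    p_ik = p.sum(-2, keepdims=True)
    p_jk = p.sum(-3, keepdims=True)
    p_i = p.sum((-2, -1), keepdims=True)
    p_j = p.sum((-3, -1), keepdims=True)
    ax = (-3, -2, -1)
    ig2 = _xlogx_ratio(p, p_ij * p_k).sum(ax)
    ig1_1 = _xlogx_ratio(p_ik, p_i * p_k).sum(ax)
    ig1_2 = _xlogx_ratio(p_jk, p_j * p_k).sum(ax)
    # within-stratum MI weighted by stratum mass: p_ijk * log2(p^k_ij/(p^k_i. p^k_.j))
    with np.errstate(divide="ignore", invalid="ignore"):
        den = p_ik * p_jk / p_k
    igmod0 = _xlogx_ratio(p, den).sum(ax)
    return {
        "ig2": ig2,
        "ig1_1": ig1_1,
        "ig1_2": ig1_2,
        "igmod": ig2 - ig1_1 - ig1_2,
        "igmod0": igmod0,
    }


def information_gain_2nd(counts) -> EntropyStat:
    """Second-order information gain ``IG(D|G)``, Kwon et al.'s estimator."""
    c = _tensor(counts)
    _require_both_classes(c)
    return EntropyStat(float(_components(c)["ig2"]), "IG2", int(c.sum()))


def information_gain_1st(counts, locus: int) -> EntropyStat:
    """First-order (main-effect) information gain for locus 1 or 2."""
    if locus not in (1, 2):
        raise ValueError("locus must be 1 or 2")
    c = _tensor(counts)
    _require_both_classes(c)
    comp = _components(c)
    return EntropyStat(float(comp[f"ig1_{locus}"]), "IG1", int(c.sum()))


def igmod(counts) -> EntropyStat:
    """Modified information gain ``IG(D|G) - IG(D|G1) - IG(D|G2)``."""
    c = _tensor(counts)
    _require_both_classes(c)
    return EntropyStat(float(_components(c)["igmod"]), "IGMOD", int(c.sum()))


def igmod0(counts) -> EntropyStat:
    """Conditional-mutual-information form of the modified estimator (bits).

    Case-weighted plus control-weighted within-stratum mutual information;
    always non-negative, and equal to :func:`igmod` whenever the pooled
    genotype margins factorize exactly.
    """
    c = _tensor(counts)
    _require_both_classes(c)
    return EntropyStat(float(_components(c)["igmod0"]), "IGMOD0", int(c.sum()))


def geno_cmi(counts) -> EntropyStat:
    """Zuo et al.'s GenoCMI: the ``igmod0`` summation in natural-log units."""
    c = _tensor(counts)
    _require_both_classes(c)
    val = float(_components(c)["igmod0"]) * _LN2
    return EntropyStat(val, "GENOCMI", int(c.sum()), units="nats")


def mutual_information(table3x3) -> float:
    """Plug-in mutual information (bits) of a 3 x 3 genotype count table."""
    t = np.asarray(table3x3, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("expected a 3 x 3 table")
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    p = t / n
    pi = p.sum(1, keepdims=True)
    pj = p.sum(0, keepdims=True)
    return float(_xlogx_ratio(p, pi * pj).sum())


def t_ig_fan(counts) -> EntropyStat:
    """Fan et al.'s ``T_IG``: genotype MI in controls minus MI in cases (bits).

    Signed; the sign flips under a case/control label swap.  Significance is
    assessed by the permutation scheme in :mod:`igmod.comparators`.
    """
    c = _tensor(counts)
    cases = c[..., 1]
    controls = c[..., 0]
    if cases.sum() <= 0 or controls.sum() <= 0:
        raise ValueError("both strata must be non-empty")
    val = mutual_information(controls) - mutual_information(cases)
    return EntropyStat(float(val), "TIG", int(c.sum()))


# ---------------------------------------------------------------------------
# vectorized all-pairs kernel


def pair_counts_all(genotypes: np.ndarray, pheno: np.ndarray) -> np.ndarray:
    """Contingency tensors for all ordered SNP pairs of a genotype matrix.

    Returns an array of shape ``(3, 3, 2, m, m)`` whose ``[..., a, b]`` slice
    is the tensor for the pair (column ``a``, column ``b``).  Missing
    genotypes are excluded pairwise, so the per-pair total varies.
    """
    X = np.asarray(genotypes)
    d = np.asarray(pheno)
    n, m = X.shape
    counts = np.empty((3, 3, 2, m, m))
    for k in (0, 1):
        Xk = X[d == k]
        ind = [(Xk == g).astype(np.float64) for g in range(3)]
        for i in range(3):
            for j in range(3):
                counts[i, j, k] = ind[i].T @ ind[j]
    return counts


def pair_statistics(genotypes, pheno, statistics=("igmod", "igmod0")) -> dict[str, np.ndarray]:
    """Entropy statistics for every unordered SNP pair ``a < b``.

    Returns a dict with one flat array per requested statistic plus
    ``"pairs"`` (index pairs, shape ``(P, 2)``) and ``"n"`` (per-pair sample
    size after pairwise deletion).
    """
    X = np.asarray(genotypes)
    d = np.asarray(pheno)
    counts = pair_counts_all(X, d)
    m = X.shape[1]
    a, b = np.triu_indices(m, k=1)
    c = np.moveaxis(counts[:, :, :, a, b], -1, 0)  # (P, 3, 3, 2)
    comp = _components(c)
    out: dict[str, np.ndarray] = {s: comp[s] for s in statistics}
    out["pairs"] = np.column_stack([a, b])
    out["n"] = c.sum(axis=(-3, -2, -1))
    return out
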