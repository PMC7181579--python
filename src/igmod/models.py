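"""Two-locus disease models: odds tables, penetrance, prevalence, heritability.

Five interaction models are provided.  Four (multiplicative, epistasis,
two-allele and XOR, after Wan et al.) are parameterized by a prevalence
parameter ``alpha`` and a multiplicative interaction parameter ``theta``;
rows index the genotype at the first locus (aa, aA, AA) and columns the
second (bb, bB, BB), minor alleles in capitals.  The fifth ("no margin",
after Ritchie et al.) is a fixed table with interaction but no marginal
effects at minor allele frequency 0.25.

Given a target prevalence ``K`` and heritability ``h2``

    h2 = sum_ij P(G_ij) (P(D1|G_ij) - K)^2 / (K (1 - K)),

``solve_model_params`` determines (alpha, theta) by nested one-dimensional
root finding: the inner bracket solves alpha for the prevalence at fixed
theta (prevalence is strictly increasing in alpha), the outer solves theta
for the heritability (increasing in theta once alpha is re-solved).  Both
loci share one minor allele frequency per configuration, and genotypes
follow Hardy-Weinberg proportions with independent loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

PARAMETERIZED_MODELS = ("multiplicative", "epistasis", "two_allele", "xor")
MODELS = PARAMETERIZED_MODELS + ("no_margin",)

#: Fixed odds of the no-margin model (Ritchie et al.), MAF 0.25.
NO_MARGIN_ODDS = np.array([
    [0.03, 0.10, 0.08],
    [0.09, 0.01, 0.04],
    [0.10, 0.01, 0.00],
])

#: Default targets: prevalence 0.1; heritability 0.03 for the
#: multiplicative model and 0.02 for the other parameterized models.
DEFAULT_PREVALENCE = 0.1
DEFAULT_H2 = {"multiplicative": 0.03, "epistasis": 0.02, "two_allele": 0.02, "xor": 0.02}

#: MAF of the interacting loci in the no-margin model.
NO_MARGIN_MAF = 0.25


@dataclass(frozen=True)
class OddsTable:
    """3 x 3 odds ``P(D1|G)/P(D0|G)`` of a two-locus model."""

    odds: np.ndarray
    model_name: str
    alpha: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        o = np.asarray(self.odds, dtype=float)
        if o.shape != (3, 3):
            raise ValueError("odds table must be 3 x 3")
        if (o < 0).any():
            raise ValueError("odds must be non-negative")
        object.__setattr__(self, "odds", o)


@dataclass(frozen=True)
class PenetranceTable:
    """3 x 3 penetrances ``f(G_ij) = P(D1 | G_ij)``."""

    pen: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pen, dtype=float)
        if p.shape != (3, 3):
            raise ValueError("penetrance table must be 3 x 3")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "pen", p)


@dataclass(frozen=True)
class ModelSpec:
    """A solved model configuration ready for simulation."""

    model_name: str
    maf1: float
    maf2: float
    prevalence: float
    h2: float
    alpha: float | None
    theta: float | None
    odds: OddsTable
    penetrance: PenetranceTable


def odds_table(model_name: str, alpha: float | None = None, theta: float | None = None) -> OddsTable:
    """Symbolic odds pattern of a named model at given (alpha, theta)."""
    if model_name == "no_margin":
        return OddsTable(NO_MARGIN_ODDS.copy(), model_name)
    if model_name not in PARAMETERIZED_MODELS:
        raise ValueError(f"unknown model {model_name!r}; choose from {MODELS}")
    if alpha is None or theta is None:
        raise ValueError("alpha and theta are required for parameterized models")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if theta <= -1:
        raise ValueError("theta must exceed -1")
    a, t = float(alpha), float(theta)
    u = 1.0 + t
    if model_name == "multiplicative":
        o = np.array([[a, a, a],
                      [a, a * u, a * u ** 2],
                      [a, a * u ** 2, a * u ** 4]])
    elif model_name == "epistasis":
        o = np.array([[a, a * u, a * u],
                      [a * u, a, a],
                      [a * u, a, a]])
    elif model_name == "two_allele":
        o = np.array([[a, a, a * u],
                      [a, a * u, a],
                      [a * u, a, a]])
    else:  # xor
        o = np.array([[a, a * u, a],
                      [a * u, a, a * u],
                      [a, a * u, a]])
    return OddsTable(o, model_name, alpha=a, theta=t)


def odds_to_penetrance(o: OddsTable | np.ndarray) -> PenetranceTable:
    """Convert odds to penetrances cell-wise, ``p = o / (1 + o)``."""
    odds = o.odds if isinstance(o, OddsTable) else np.asarray(o, dtype=float)
    return PenetranceTable(odds / (1.0 + odds))


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities [(1-q)^2, 2q(1-q), q^2]."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("minor allele frequency must lie in (0, 0.5]")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def _joint_geno_probs(maf1: float, maf2: float) -> np.ndarray:
    return np.outer(hwe_probs(maf1), hwe_probs(maf2))


def prevalence(pen: PenetranceTable | np.ndarray, maf1: float, maf2: float) -> float:
    """Population prevalence ``K = sum_ij P(G_ij) f(G_ij)`` (no LD)."""
    p = pen.pen if isinstance(pen, PenetranceTable) else np.asarray(pen, dtype=float)
    return float((_joint_geno_probs(maf1, maf2) * p).sum())


def heritability(pen: PenetranceTable | np.ndarray, maf1: float, maf2: float) -> float:
    """Broad-sense heritability of the binary trait on the penetrance scale."""
    p = pen.pen if isinstance(pen, PenetranceTable) else np.asarray(pen, dtype=float)
    w = _joint_geno_probs(maf1, maf2)
    K = float((w * p).sum())
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence is degenerate; heritability undefined")
    return float((w * (p - K) ** 2).sum() / (K * (1.0 - K)))


def _pen_for(model_name: str, alpha: float, theta: float) -> np.ndarray:
    return odds_to_penetrance(odds_table(model_name, alpha, theta)).pen


def solve_model_params(model_name: str, maf: float,
                       prevalence_target: float = DEFAULT_PREVALENCE,
                       h2_target: float | None = None) -> ModelSpec:
    """Solve (alpha, theta) of a parameterized model for target K and h2.

    Both constraints are met to 1e-8; the result is deterministic.  Raises a
    ``ValueError`` if no root lies in the search brackets
    (alpha in (1e-9, 1e3), theta in (0, 1e3)).
    """
    if model_name == "no_margin":
        return no_margin_spec()
    if model_name not in PARAMETERIZED_MODELS:
        raise ValueError(f"unknown model {model_name!r}")
    if h2_target is None:
        h2_target = DEFAULT_H2[model_name]
    K = float(prevalence_target)
    if not 0.0 < K < 1.0:
        raise ValueError("prevalence target must lie in (0, 1)")
    if h2_target < 0:
        raise ValueError("heritability target must be non-negative")

    def alpha_for(theta: float) -> float:
        def f(a: float) -> float:
            return prevalence(_pen_for(model_name, a, theta), maf, maf) - K
        try:
            return brentq(f, 1e-9, 1e3, xtol=1e-15, rtol=8.9e-16)
        except ValueError as exc:
            raise ValueError(
                f"prevalence {K} not attainable for {model_name} at theta={theta}"
            ) from exc

    if h2_target == 0.0:
        theta = 0.0
        a0 = K / (1.0 - K)
        pen = _pen_for(model_name, a0, theta)
        return ModelSpec(model_name, maf, maf, K, 0.0, a0, theta,
                         odds_table(model_name, a0, theta), PenetranceTable(pen))

    def h2_gap(theta: float) -> float:
        a = alpha_for(theta)
        return heritability(_pen_for(model_name, a, theta), maf, maf) - h2_target

    try:
        theta = brentq(h2_gap, 1e-9, 1e3, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:
        raise ValueError(
            f"heritability {h2_target} not attainable for {model_name} at MAF {maf}"
        ) from exc
    a = alpha_for(theta)
    pen = _pen_for(model_name, a, theta)
    return ModelSpec(model_name, maf, maf,
                     prevalence(pen, maf, maf), heritability(pen, maf, maf),
                     a, theta, odds_table(model_name, a, theta), PenetranceTable(pen))


def no_margin_spec(as_penetrance: bool = False) -> ModelSpec:
    """The fixed no-margin model at MAF 0.25.

    The published table is headed "odds" and is converted to penetrances via
    ``p = o/(1+o)`` by default; ``as_penetrance=True`` reads the same numbers
    directly as penetrances (the convention of the model's original source).
    The zero cell yields penetrance 0 under either reading.
    """
    q = NO_MARGIN_MAF
    if as_penetrance:
        pen = PenetranceTable(NO_MARGIN_ODDS.copy())
    else:
        pen = odds_to_penetrance(NO_MARGIN_ODDS)
    return ModelSpec("no_margin", q, q,
                     prevalence(pen, q, q), heritability(pen, q, q),
                     None, None, OddsTable(NO_MARGIN_ODDS.copy(), "no_margin"), pen)


def case_control_odds(pen: PenetranceTable | np.ndarray, maf1: float, maf2: float,
                      n_case: int, n_control: int) -> np.ndarray:
    """Expected per-cell case:control count ratio in a case-control sample.

    ``pen/(1-pen) * (n_case/n_control) * (1-K)/K``; a penetrance-1 cell maps
    to ``inf``.
    """
    p = pen.pen if isinstance(pen, PenetranceTable) else np.asarray(pen, dtype=float)
    K = prevalence(p, maf1, maf2)
    if not 0.0 < K < 1.0:
        raise ValueError("degenerate prevalence")
    with np.errstate(divide="ignore"):
        out = p / (1.0 - p) * (n_case / n_control) * (1.0 - K) / K
    return out


def study_configurations() -> list[ModelSpec]:
    """The 12 solved model-by-MAF configurations of the simulation design.

    Four parameterized models at MAFs 0.1, 0.2 and 0.4, prevalence 0.1,
    heritability 0.03 (multiplicative) or 0.02 (others).
    """
    return [solve_model_params(m, q) for m in PARAMETERIZED_MODELS for q in (0.1, 0.2, 0.4)]
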