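"""HLO classification of two-locus genotype cells and submodel matching.

One step of the model-based multifactor dimensionality reduction (MB-MDR)
procedure: each of the nine genotype combinations is labeled High-risk (H),
Low-risk (L) or undetermined (O) by a per-cell association test between the
trait and membership in that cell.

By default the cell test is a score (Rao) test of the cell indicator added
to a logistic model with codominant main effects for both loci, so a cell is
H/L when its case load deviates from what the loci's *marginal* effects
predict.  This main-effect adjustment is what makes the classification an
interaction readout: under a multiplicative model the common low-penetrance
(aa, bb) cell is classified H — it carries more cases than its margins
imply — reproducing the catalogued multiplicative pattern HLL/LHH/LHH.
``adjust_main_effects=False`` falls back to an unadjusted two-proportion
chi-square of the cell against its complement.  Cells with fewer than
``min_cell_n`` individuals are O regardless (insufficient information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import PairCounts

_CELL_DESIGN = np.array(
    [[1.0, float(i == 1), float(i == 2), float(j == 1), float(j == 2)]
     for i in range(3) for j in range(3)]
)


@dataclass(frozen=True)
class HLOMatrix:
    """3 x 3 matrix of labels in {H, L, O}; serializes row-wise as 'HLL/LHH/LHH'."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype="<U1")
        if lab.shape != (3, 3):
            raise ValueError("labels must be 3 x 3")
        if not np.isin(lab, ("H", "L", "O")).all():
            raise ValueError("labels must be 'H', 'L' or 'O'")
        object.__setattr__(self, "labels", lab)

    def __str__(self) -> str:
        return "/".join("".join(row) for row in self.labels)

    @classmethod
    def from_string(cls, s: str) -> "HLOMatrix":
        rows = s.split("/")
        if len(rows) != 3 or any(len(r) != 3 for r in rows):
            raise ValueError("expected a string like 'HLL/LHH/LHH'")
        return cls(np.array([list(r) for r in rows]))

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return str(self) == other
        if isinstance(other, HLOMatrix):
            return bool((self.labels == other.labels).all())
        return NotImplemented

    def __hash__(self) -> int:
        return hash(str(self))


#: Ideal large-sample HLO patterns of the five catalogued models.
IDEAL_HLO = {
    "multiplicative": "HLL/LHH/LHH",
    "epistasis": "LHH/HLL/HLL",
    "two_allele": "LLH/LHL/HLL",
    "xor": "LHL/HLH/LHL",
    "no_margin": "LHH/HLL/HLO",
}


def ideal_hlo(model_name: str) -> HLOMatrix:
    """Catalogued large-sample HLO pattern of a named interaction model."""
    try:
        return HLOMatrix.from_string(IDEAL_HLO[model_name])
    except KeyError:
        raise ValueError(f"unknown model {model_name!r}") from None


def _counts(counts) -> np.ndarray:
    c = counts.counts if isinstance(counts, PairCounts) else np.asarray(counts, dtype=float)
    if c.shape != (3, 3, 2):
        raise ValueError("expected a (3, 3, 2) contingency tensor")
    return np.asarray(c, dtype=float)


def _adjusted_z(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-cell score-test z for the cell indicator given codominant main effects."""
    X = _CELL_DESIGN
    beta = np.zeros(5)
    beta[0] = np.log((y.sum() + 0.5) / (w.sum() - y.sum() + 0.5))
    for _ in range(60):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = w * mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, X.T @ (y - w * mu))
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, X.T @ (y - w * mu), rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = w * mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X
    Hinv = np.linalg.pinv(H)
    z = np.full(9, np.nan)
    for c in range(9):
        u = y[c] - w[c] * mu[c]
        v = W[c] - (W[c] * X[c]) @ Hinv @ (X[c] * W[c])
        if v > 1e-12:
            z[c] = u / np.sqrt(v)
    return z


def _unadjusted_z(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed two-proportion z of each cell's case fraction vs its complement."""
    tot_w, tot_y = w.sum(), y.sum()
    z = np.full(9, np.nan)
    for c in range(9):
        w_in, y_in = w[c], y[c]
        w_out, y_out = tot_w - w_in, tot_y - y_in
        if w_in <= 0 or w_out <= 0:
            continue
        p_pool = tot_y / tot_w
        var = p_pool * (1 - p_pool) * (1 / w_in + 1 / w_out)
        if var <= 0:
            continue
        z[c] = (y_in / w_in - y_out / w_out) / np.sqrt(var)
    return z


def classify_hlo(counts, cell_alpha: float = 0.1, min_cell_n: int = 10,
                 adjust_main_effects: bool = True) -> HLOMatrix:
    """Label each genotype cell H, L or O.

    A cell is H (L) when its test z exceeds (falls below) the two-sided
    normal critical value at ``cell_alpha``; O otherwise, and always O when
    the cell holds fewer than ``min_cell_n`` individuals or the test is
    degenerate.
    """
    c = _counts(counts)
    w = c.sum(-1).ravel()
    y = c[..., 1].ravel()
    if y.sum() <= 0 or y.sum() >= w.sum():
        return HLOMatrix(np.full((3, 3), "O"))
    z = _adjusted_z(w, y) if adjust_main_effects else _unadjusted_z(w, y)
    zcrit = stats.norm.isf(cell_alpha / 2.0)
    labels = np.full(9, "O", dtype="<U1")
    ok = (w >= min_cell_n) & np.isfinite(z)
    labels[ok & (z > zcrit)] = "H"
    labels[ok & (z < -zcrit)] = "L"
    return HLOMatrix(labels.reshape(3, 3))


# ---------------------------------------------------------------------------
# submodel catalog

def _pattern(spec: str) -> list[list[frozenset]]:
    """Parse a pattern string where lowercase h/l mean 'H or O' / 'L or O'."""
    table = {"H": frozenset("H"), "L": frozenset("L"), "O": frozenset("O"),
             "h": frozenset("HO"), "l": frozenset("LO")}
    return [[table[ch] for ch in row] for row in spec.split("/")]


#: Catalogued submodel categories.  Each category lists the published
#: wildcard pattern (lowercase letter = "that label or O") first and, where
#: the wildcard form does not admit it, the exact ideal matrix of the
#: corresponding generating model.  Matching is first-match in this order.
DEFAULT_CATALOG: list[tuple[str, list[list[frozenset]]]] = [
    ("Multi", _pattern("HLl/LHH/Lhh")),
    ("Epi", _pattern("LHh/hlO/hll")),
    ("Epi", _pattern(IDEAL_HLO["epistasis"])),
    ("XOR", _pattern("OOL/OOH/LHO")),
    ("XOR", _pattern(IDEAL_HLO["xor"])),
    ("Multi incompl", _pattern("Hll/lOh/lhh")),
]


def match_submodel(hlo: HLOMatrix, catalog=None) -> str:
    """First catalog category whose pattern admits the matrix; else 'Other'."""
    if catalog is None:
        catalog = DEFAULT_CATALOG
    lab = hlo.labels
    for name, pattern in catalog:
        if all(lab[i][j] in pattern[i][j] for i in range(3) for j in range(3)):
            return name
    return "Other"
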