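"""Reference interaction tests used for benchmarking.

Three comparators accompany the entropy statistic:

* a 1-df Wald test of the product term in an additive-coded logistic model
  (the convention of PLINK's ``--epistasis`` module);
* a 4-df likelihood-ratio test comparing a main-effects model with additive
  and dominance terms for both loci against the full 9-parameter model;
* a permutation test for Fan et al.'s ``T_IG``.

All logistic likelihoods depend on the data only through the 18 cells of the
pair's contingency tensor, so fits are performed by Newton/IRLS on the nine
aggregated genotype-cell covariate patterns — identical likelihood to an
individual-level fit, orders of magnitude faster in the simulation studies.
Non-converged fits are flagged and counted as non-detections by the study
drivers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contingency import PairCounts, count_pair
from .entropy import t_ig_fan

_CELLS = [(i, j) for i in range(3) for j in range(3)]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: int | None
    pvalue: float
    converged: bool = True
    df_reduced: bool = False


def _as_counts(counts) -> np.ndarray:
    c = counts.counts if isinstance(counts, PairCounts) else np.asarray(counts, dtype=float)
    if c.shape != (3, 3, 2):
        raise ValueError("expected a (3, 3, 2) contingency tensor")
    return np.asarray(c, dtype=float)


def _fit_logistic_cells(X: np.ndarray, w: np.ndarray, y: np.ndarray,
                        max_iter: int = 60, tol: float = 1e-10):
    """Newton fit of an aggregated binomial logistic model.

    ``X``: covariate rows per genotype cell, ``w``: cell totals, ``y``: cell
    case counts.  Returns (beta, cov, loglik, converged).
    """
    keep = w > 0
    Xk, wk, yk = X[keep], w[keep], y[keep]
    beta = np.zeros(X.shape[1])
    tot_y, tot_w = yk.sum(), wk.sum()
    beta[0] = np.log((tot_y + 0.5) / (tot_w - tot_y + 0.5))
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xk @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = wk * mu * (1.0 - mu)
        H = (Xk * W[:, None]).T @ Xk
        g = Xk.T @ (yk - wk * mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(Xk @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(yk > 0, yk * np.log(mu), 0.0) + \
            np.where(wk - yk > 0, (wk - yk) * np.log1p(-mu), 0.0)
    loglik = float(np.sum(ll))
    W = wk * mu * (1.0 - mu)
    H = (Xk * W[:, None]).T @ Xk
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
        converged = False
    return beta, cov, loglik, converged


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    from scipy.linalg import qr

    if X.shape[0] == 0:
        return np.array([], dtype=int)
    r = qr(X, mode="r", pivoting=True)
    rr, piv = r[0], r[1]
    diag = np.abs(np.diag(rr))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    return np.sort(piv[:rank])


def _saturated_loglik(w: np.ndarray, y: np.ndarray) -> float:
    keep = w > 0
    wk, yk = w[keep], y[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(yk > 0, yk * np.log(yk / wk), 0.0) + \
            np.where(wk - yk > 0, (wk - yk) * np.log1p(-yk / wk), 0.0)
    return float(np.sum(ll))


def _cells_from_inputs(g1, g2, pheno) -> np.ndarray:
    if isinstance(g1, PairCounts) or (np.asarray(g1).shape == (3, 3, 2) and g2 is None):
        return _as_counts(g1)
    return _as_counts(count_pair(g1, g2, pheno))


def logreg_interaction_1df(g1, g2=None, pheno=None) -> TestResult:
    """Wald test of the interaction term in logit = b0 + b1 g1 + b2 g2 + b3 g1 g2.

    Accepts either two genotype columns plus a phenotype, or a
    :class:`PairCounts` tensor directly.  Non-convergence or separation is
    flagged with a ``nan`` p-value.
    """
    c = _cells_from_inputs(g1, g2, pheno)
    if c.sum(axis=(0, 1))[0] <= 0 or c.sum(axis=(0, 1))[1] <= 0:
        raise ValueError("both phenotype classes must be present")
    X = np.array([[1.0, i, j, i * j] for i, j in _CELLS])
    w = c.sum(-1).ravel()
    y = c[..., 1].ravel()
    beta, cov, _, converged = _fit_logistic_cells(X, w, y)
    if not converged or cov is None or cov[3, 3] <= 0:
        return TestResult("logreg_1df", np.nan, 1, np.nan, converged=False)
    z = beta[3] / np.sqrt(cov[3, 3])
    return TestResult("logreg_1df", float(z * z), 1, float(stats.chi2.sf(z * z, 1)))


def lrt_4df(g1, g2=None, pheno=None) -> TestResult:
    """LRT of the 8-parameter full model against additive + dominance effects.

    Null: intercept plus additive (0/1/2) and dominance ({0,1,0}) codes for
    both loci; full adds the four products a1a2, a1d2, d1a2, d1d2.  The
    statistic is chi-square with df 4, or fewer when empty genotype cells
    make the full design rank-deficient (flagged via ``df_reduced``).
    """
    c = _cells_from_inputs(g1, g2, pheno)
    if c.sum(axis=(0, 1))[0] <= 0 or c.sum(axis=(0, 1))[1] <= 0:
        raise ValueError("both phenotype classes must be present")
    w = c.sum(-1).ravel()
    y = c[..., 1].ravel()
    add = {0: 0.0, 1: 1.0, 2: 2.0}
    dom = {0: 0.0, 1: 1.0, 2: 0.0}
    X0 = np.array([[1.0, add[i], dom[i], add[j], dom[j]] for i, j in _CELLS])
    X1 = np.column_stack([
        X0,
        [add[i] * add[j] for i, j in _CELLS],
        [add[i] * dom[j] for i, j in _CELLS],
        [dom[i] * add[j] for i, j in _CELLS],
        [dom[i] * dom[j] for i, j in _CELLS],
    ])
    keep = w > 0
    X0r = X0[:, _independent_columns(X0[keep])]
    X1r = X1[:, _independent_columns(X1[keep])]
    r0, r1 = X0r.shape[1], X1r.shape[1]
    df = int(r1 - r0)
    _, _, ll0, conv0 = _fit_logistic_cells(X0r, w, y)
    if not conv0:
        return TestResult("lrt_4df", np.nan, df, np.nan, converged=False, df_reduced=df < 4)
    # the full model saturates the observed cells whenever its design spans them,
    # so its maximized likelihood has a closed form even under separation
    if r1 == int(keep.sum()):
        ll1 = _saturated_loglik(w, y)
    else:
        _, _, ll1, conv1 = _fit_logistic_cells(X1r, w, y)
        if not conv1:
            return TestResult("lrt_4df", np.nan, df, np.nan, converged=False, df_reduced=df < 4)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    if df <= 0:
        return TestResult("lrt_4df", float(lrt), 0, 1.0, df_reduced=True)
    return TestResult("lrt_4df", float(lrt), df, float(stats.chi2.sf(lrt, df)),
                      df_reduced=df < 4)


def tig_pvalue(counts, n_perm: int = 999, rng=None) -> TestResult:
    """Two-sided permutation p-value for Fan et al.'s ``T_IG``.

    Case/control labels are permuted with class sizes fixed, which is
    equivalent to drawing each permuted case table from a multivariate
    hypergeometric distribution over the 9 pooled genotype cells;
    ``p = (1 + #{|T*| >= |T|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    c = _as_counts(counts)
    n_case = int(round(c[..., 1].sum()))
    n_ctrl = int(round(c[..., 0].sum()))
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("both strata must be non-empty")
    rng = np.random.default_rng(rng)
    t_obs = t_ig_fan(c).value
    totals = np.asarray(np.rint(c.sum(-1).ravel()), dtype=np.int64)
    hits = 0
    for _ in range(n_perm):
        cases = rng.multivariate_hypergeometric(totals, n_case)
        perm = np.stack([(totals - cases).reshape(3, 3), cases.reshape(3, 3)], axis=-1)
        if abs(t_ig_fan(perm).value) >= abs(t_obs) - 1e-15:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return TestResult("tig_perm", float(t_obs), None, float(p))
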