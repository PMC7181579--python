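"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with explicit Python loops and
``math.log`` so it shares no code path with the package's vectorized
implementations.
"""

import math


def _margins(c):
    """All margins of a 3x3x2 count table given as nested lists/array."""
    N = sum(c[i][j][k] for i in range(3) for j in range(3) for k in range(2))
    p = [[[c[i][j][k] / N for k in range(2)] for j in range(3)] for i in range(3)]
    p_ij = [[sum(p[i][j]) for j in range(3)] for i in range(3)]
    p_i = [sum(p_ij[i]) for i in range(3)]
    p_j = [sum(p_ij[i][j] for i in range(3)) for j in range(3)]
    p_ik = [[sum(p[i][j][k] for j in range(3)) for k in range(2)] for i in range(3)]
    p_jk = [[sum(p[i][j][k] for i in range(3)) for k in range(2)] for j in range(3)]
    p_k = [sum(p_ik[i][k] for i in range(3)) for k in range(2)]
    return N, p, p_ij, p_i, p_j, p_ik, p_jk, p_k


def oracle_entropy_stats(c):
    """Term-by-term evaluation of every entropy statistic, in bits.

    ``c`` is any indexable 3x3x2 table of non-negative counts with both
    disease strata populated.
    """
    N, p, p_ij, p_i, p_j, p_ik, p_jk, p_k = _margins(c)
    log2 = lambda x: math.log(x, 2)

    ig2 = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(2):
                if p[i][j][k] > 0:
                    ig2 += p[i][j][k] * log2(p[i][j][k] / (p_ij[i][j] * p_k[k]))
    ig1_1 = 0.0
    for i in range(3):
        for k in range(2):
            if p_ik[i][k] > 0:
                ig1_1 += p_ik[i][k] * log2(p_ik[i][k] / (p_i[i] * p_k[k]))
    ig1_2 = 0.0
    for j in range(3):
        for k in range(2):
            if p_jk[j][k] > 0:
                ig1_2 += p_jk[j][k] * log2(p_jk[j][k] / (p_j[j] * p_k[k]))

    # within-stratum mutual information, stratum-mass weighted
    igmod0 = 0.0
    for k in range(2):
        for i in range(3):
            for j in range(3):
                if p[i][j][k] > 0:
                    num = p[i][j][k] / p_k[k]
                    den = (p_ik[i][k] / p_k[k]) * (p_jk[j][k] / p_k[k])
                    igmod0 += p[i][j][k] * log2(num / den)

    def mi_of_stratum(k):
        tot = sum(c[i][j][k] for i in range(3) for j in range(3))
        q = [[c[i][j][k] / tot for j in range(3)] for i in range(3)]
        qi = [sum(q[i]) for i in range(3)]
        qj = [sum(q[i][j] for i in range(3)) for j in range(3)]
        mi = 0.0
        for i in range(3):
            for j in range(3):
                if q[i][j] > 0:
                    mi += q[i][j] * log2(q[i][j] / (qi[i] * qj[j]))
        return mi

    return {
        "ig2": ig2,
        "ig1_1": ig1_1,
        "ig1_2": ig1_2,
        "igmod": ig2 - ig1_1 - ig1_2,
        "igmod0": igmod0,
        "geno_cmi": igmod0 * math.log(2),
        "tig": mi_of_stratum(0) - mi_of_stratum(1),
        "mi_pooled": oracle_mutual_information(
            [[c[i][j][0] + c[i][j][1] for j in range(3)] for i in range(3)]),
    }


def oracle_mutual_information(t):
    """Plug-in MI (bits) of a 3x3 count table via explicit loops."""
    tot = sum(t[i][j] for i in range(3) for j in range(3))
    p = [[t[i][j] / tot for j in range(3)] for i in range(3)]
    pi = [sum(p[i]) for i in range(3)]
    pj = [sum(p[i][j] for i in range(3)) for j in range(3)]
    mi = 0.0
    for i in range(3):
        for j in range(3):
            if p[i][j] > 0:
                mi += p[i][j] * math.log(p[i][j] / (pi[i] * pj[j]), 2)
    return mi


def oracle_pair_tally(g1, g2, pheno, missing=-1):
    """Exhaustive per-individual tally of the 3x3x2 tensor."""
    counts = [[[0, 0] for _ in range(3)] for _ in range(3)]
    for a, b, d in zip(g1, g2, pheno):
        if a == missing or b == missing:
            continue
        counts[a][b][d] += 1
    return counts


def oracle_gamma_sf_shape2(y):
    """Closed-form upper tail of a unit-scale gamma with shape 2."""
    return (1.0 + y) * math.exp(-y)


def oracle_gamma_sf_shape4(y):
    """Closed-form upper tail of a unit-scale gamma with shape 4."""
    return math.exp(-y) * (1.0 + y + y * y / 2.0 + y ** 3 / 6.0)
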