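import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igmod import entropy
from igmod.contingency import MISSING, count_pair
from conftest import random_tensor
from oracles import oracle_entropy_stats, oracle_mutual_information

LN2 = math.log(2)


def det_table():
    """Status fully determined by genotype cell, phenotype balanced 50/50."""
    c = np.zeros((3, 3, 2), dtype=int)
    c[0, 0, 0] = 50  # these cells are pure controls
    c[1, 1, 0] = 50
    c[0, 1, 1] = 50  # these pure cases
    c[2, 2, 1] = 50
    return c


class TestShannonEntropy:
    @pytest.mark.parametrize("probs,expected", [
        ([0.5, 0.5], 1.0),
        ([1.0, 0.0], 0.0),
        ([0.1, 0.9], -(0.1 * math.log2(0.1) + 0.9 * math.log2(0.9))),
    ])
    def test_values(self, probs, expected):
        assert entropy.shannon_entropy(probs) == pytest.approx(expected, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            entropy.shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValueError, match="sum"):
            entropy.shannon_entropy([0.5, 0.4])


class TestInformationGains:
    def test_independence_gives_zero(self):
        # every genotype cell split 50/50 case-control -> exact product table
        c = np.full((3, 3, 2), 10, dtype=int)
        assert entropy.information_gain_2nd(c).value == pytest.approx(0.0, abs=1e-12)
        assert entropy.information_gain_1st(c, 1).value == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_table_gives_one_bit(self):
        c = det_table()
        assert entropy.information_gain_2nd(c).value == pytest.approx(1.0, abs=1e-12)

    def test_locus_margin_determines_status(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[0, :, 0] = [10, 5, 5]   # locus-1 genotype 0 -> control
        c[1, :, 1] = [10, 5, 5]   # genotype 1 -> case
        assert entropy.information_gain_1st(c, 1).value == pytest.approx(1.0, abs=1e-12)

    def test_single_class_raises(self):
        c = np.zeros((3, 3, 2), dtype=int)
        c[..., 1] = 5
        for fn in (entropy.information_gain_2nd, entropy.igmod, entropy.igmod0,
                   entropy.geno_cmi):
            with pytest.raises(ValueError, match="class"):
                fn(c)


class TestIGmod:
    def test_exact_product_main_effect_table(self):
        # locus 1 drives status, locus 2 independent: counts u_i * v_j * w(i,k)
        v = np.array([4, 2, 1])
        c = np.zeros((3, 3, 2))
        cell = np.array([[30, 10], [20, 20], [5, 25]])  # locus1 x status
        for i in range(3):
            c[i] = np.outer(v, cell[i])
        assert entropy.igmod(c).value == pytest.approx(0.0, abs=1e-12)
        assert entropy.information_gain_2nd(c).value > 0.1  # main effect is there

    def test_igmod0_zero_when_conditionally_independent(self):
        c = np.zeros((3, 3, 2))
        for k, (u, v) in enumerate([(np.array([5, 3, 1]), np.array([2, 2, 1])),
                                    (np.array([1, 2, 3]), np.array([1, 1, 4]))]):
            c[..., k] = np.outer(u, v)
        assert entropy.igmod0(c).value == pytest.approx(0.0, abs=1e-12)

    def test_mutual_information_examples(self):
        assert entropy.mutual_information(np.outer([3, 2, 1], [1, 2, 3])) == \
            pytest.approx(0.0, abs=1e-12)
        assert entropy.mutual_information(np.eye(3)) == pytest.approx(math.log2(3))
        with pytest.raises(ValueError, match="empty"):
            entropy.mutual_information(np.zeros((3, 3)))

    def test_tig_symmetry_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        sub = rng.integers(1, 20, size=(3, 3))
        same = np.stack([sub, sub], axis=-1)
        assert entropy.t_ig_fan(same).value == pytest.approx(0.0, abs=1e-12)
        c = random_tensor(np.random.default_rng(1))
        assert entropy.t_ig_fan(c).value == pytest.approx(
            -entropy.t_ig_fan(c[..., ::-1]).value, abs=1e-12)
        empty = np.zeros((3, 3, 2)); empty[..., 0] = 1
        with pytest.raises(ValueError, match="strata"):
            entropy.t_ig_fan(empty)


class TestInvariants:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_decomposition_identity(self, seed):
        c = random_tensor(np.random.default_rng(seed))
        lhs = entropy.igmod(c).value
        rhs = (entropy.information_gain_2nd(c).value
               - entropy.information_gain_1st(c, 1).value
               - entropy.information_gain_1st(c, 2).value)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_igmod0_nonnegative_and_base_change(self, seed):
        c = random_tensor(np.random.default_rng(seed))
        v = entropy.igmod0(c).value
        assert v >= -1e-12
        g = entropy.geno_cmi(c)
        assert g.units == "nats"
        assert g.value == pytest.approx(v * LN2, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = random_tensor(rng)
        pi, pj = rng.permutation(3), rng.permutation(3)
        cp = c[pi][:, pj]
        for fn in (entropy.igmod, entropy.igmod0, entropy.information_gain_2nd):
            assert fn(c).value == pytest.approx(fn(cp).value, abs=1e-12)

    def test_no_ld_equivalence_on_factorizing_margins(self):
        # X_ijk = u_i * v_j * w_k has an exact outer-product genotype margin
        rng = np.random.default_rng(5)
        for _ in range(20):
            u = rng.integers(1, 6, 3)
            v = rng.integers(1, 6, 3)
            w = rng.integers(1, 6, 2)
            c = u[:, None, None] * v[None, :, None] * w[None, None, :]
            assert entropy.igmod(c).value == pytest.approx(
                entropy.igmod0(c).value, abs=1e-12)

    def test_oracle_equivalence_fixture(self, fixture_counts):
        ref = oracle_entropy_stats(fixture_counts)
        assert entropy.information_gain_2nd(fixture_counts).value == \
            pytest.approx(ref["ig2"], abs=1e-12)
        assert entropy.information_gain_1st(fixture_counts, 1).value == \
            pytest.approx(ref["ig1_1"], abs=1e-12)
        assert entropy.information_gain_1st(fixture_counts, 2).value == \
            pytest.approx(ref["ig1_2"], abs=1e-12)
        assert entropy.igmod(fixture_counts).value == pytest.approx(ref["igmod"], abs=1e-12)
        assert entropy.igmod0(fixture_counts).value == pytest.approx(ref["igmod0"], abs=1e-12)
        assert entropy.geno_cmi(fixture_counts).value == \
            pytest.approx(ref["geno_cmi"], abs=1e-12)
        assert entropy.t_ig_fan(fixture_counts).value == pytest.approx(ref["tig"], abs=1e-12)
        assert entropy.mutual_information(fixture_counts.sum(-1)) == \
            pytest.approx(ref["mi_pooled"], abs=1e-12)


class TestPairwiseKernel:
    def test_matches_per_pair_path_with_missing_data(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 3, size=(120, 6)).astype(np.int8)
        X[rng.random(X.shape) < 0.1] = MISSING
        pheno = rng.integers(0, 2, 120)
        pheno[:3] = [0, 1, 1]  # ensure both classes
        res = entropy.pair_statistics(X, pheno)
        for row, (a, b) in enumerate(res["pairs"]):
            pc = count_pair(X[:, a], X[:, b], pheno)
            assert res["n"][row] == pc.N
            assert res["igmod"][row] == pytest.approx(entropy.igmod(pc).value, abs=1e-10)
            assert res["igmod0"][row] == pytest.approx(entropy.igmod0(pc).value, abs=1e-10)

    def test_oracle_equivalence_thousand_random_tensors(self):
        rng = np.random.default_rng(123)
        tensors = np.stack([random_tensor(rng, max_count=30) for _ in range(1000)])
        comp = entropy._components(tensors.astype(float))
        for idx in range(1000):
            ref = oracle_entropy_stats(tensors[idx])
            for key in ("ig2", "ig1_1", "ig1_2", "igmod", "igmod0"):
                assert comp[key][idx] == pytest.approx(ref[key], abs=1e-10), (idx, key)
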