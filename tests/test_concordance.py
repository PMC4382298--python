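"""Spearman concordance and the four resampling schemes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crsig import (
    ConfigError,
    DegenerateInputError,
    GeneSetCollection,
    model_bootstrap,
    model_permutation,
    overlap_correlation,
    pair_bootstrap,
    permutation_test,
    spearman,
)
from crsig.concordance import _spearman_rows


def midrank_pearson(a, b) -> float:
    """Brute-force Spearman: explicit midranks then a plain Pearson sum."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    ra, rb = midranks(list(a)), midranks(list(b))
    n = len(ra)
    ma, mb = sum(ra) / n, sum(rb) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den


class TestSpearman:
    def test_identity_gives_one(self):
        v = np.array([3.0, 1.0, 7.0, 2.0])
        assert spearman(v, v) == pytest.approx(1.0)

    def test_three_point_example(self):
        # 1 − 6·Σd²/(n(n²−1)) with Σd² = 6
        assert spearman(np.array([1.0, 2, 3]), np.array([3.0, 1, 2])) == pytest.approx(-0.5)

    def test_ties_match_midrank_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            a = rng.integers(0, 5, size=12).astype(float)  # heavy ties
            b = rng.integers(0, 5, size=12).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            assert spearman(a, b) == pytest.approx(midrank_pearson(a, b), abs=1e-12)
            assert spearman(a, b) == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)

    def test_series_align_on_terms_and_drop_missing(self):
        a = pd.Series({"T1": 1.0, "T2": 2.0, "T3": 3.0, "T4": np.nan, "T5": 5.0})
        b = pd.Series({"T2": 5.0, "T3": 1.0, "T1": 2.0, "T5": 0.5, "T6": 9.0})
        # pairwise-complete terms: T1, T2, T3, T5
        assert spearman(a, b) == pytest.approx(
            stats.spearmanr([1, 2, 3, 5], [2, 5, 1, 0.5]).statistic, abs=1e-12
        )

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman(np.array([1.0, 1, 1, 1]), np.array([1.0, 2, 3, 4]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ConfigError):
            spearman(np.array([1.0, 2]), np.array([2.0, 1]))


class TestPermutationTest:
    def test_observed_maximum_hits_add_one_floor(self):
        a = np.arange(30.0)
        res = permutation_test(a, a + np.linspace(0, 0.01, 30), n_perm=999, seed=4)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.001)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = [
            permutation_test(rng.normal(size=25), rng.normal(size=25), n_perm=199, seed=s).p
            for s in range(300)
        ]
        assert stats.kstest(ps, "uniform").statistic < 0.07

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(size=40)
        r1 = permutation_test(a, b, n_perm=499, seed=11)
        r2 = permutation_test(a, b, n_perm=499, seed=11)
        assert r1.p == r2.p and r1.r == r2.r

    def test_invalid_n_perm(self):
        with pytest.raises(ConfigError):
            permutation_test(np.arange(5.0), np.arange(5.0), n_perm=0)


class TestPairBootstrap:
    def test_identical_vectors_give_degenerate_unit_ci(self):
        a = np.arange(20.0)
        res = pair_bootstrap(a, a, n_boot=200, seed=3)
        assert res.ci == (1.0, 1.0) and res.r == pytest.approx(1.0)

    def test_coverage_of_known_concordance(self):
        # bivariate normal with rho = 0.6; population Spearman = (6/pi) asin(rho/2)
        rho = 0.6
        target = 6 / math.pi * math.asin(rho / 2)
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=(60, 2)) @ np.linalg.cholesky([[1, rho], [rho, 1]]).T
            res = pair_bootstrap(x[:, 0], x[:, 1], n_boot=300, seed=int(rng.integers(2**31)))
            hits += res.ci[0] <= target <= res.ci[1]
        assert 0.90 <= hits / n_rep <= 0.99

    def test_stable_when_doubling_resamples(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=50), rng.normal(size=50)
        c1 = pair_bootstrap(a, b, n_boot=1000, seed=5).ci
        c2 = pair_bootstrap(a, b, n_boot=2000, seed=5).ci
        assert abs(c1[0] - c2[0]) < 0.05 and abs(c1[1] - c2[1]) < 0.05


class TestOverlapCorrelation:
    def test_formula_values(self, small_collection):
        coll = GeneSetCollection(
            sets={
                "A": frozenset(f"g{i}" for i in range(10)),
                "B": frozenset(f"g{i}" for i in range(5, 25)),  # overlap 5, sizes 10/20
                "C": frozenset(f"h{i}" for i in range(8)),       # disjoint
                "D": frozenset(f"g{i}" for i in range(10)),      # identical to A
            }
        )
        corr = overlap_correlation(coll, ["A", "B", "C", "D"])
        m = corr.matrix
        assert m.loc["A", "B"] == pytest.approx(5 / math.sqrt(200), abs=1e-6)
        assert m.loc["A", "B"] == pytest.approx(0.353553, abs=1e-6)
        assert m.loc["A", "C"] == 0.0
        assert m.loc["A", "D"] == pytest.approx(1.0)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_disjoint_collection_gives_identity(self):
        coll = GeneSetCollection(
            sets={f"T{i}": frozenset(f"g{i}_{j}" for j in range(6)) for i in range(4)}
        )
        corr = overlap_correlation(coll, list(coll.term_ids))
        assert np.allclose(corr.values(), np.eye(4))
        assert not corr.clipped

    def test_set_system_matrix_is_gram_hence_psd(self):
        # normalized indicator vectors make the matrix a Gram matrix
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(60)]
        sets = {
            f"T{i}": frozenset(rng.choice(genes, size=rng.integers(5, 25), replace=False))
            for i in range(12)
        }
        corr = overlap_correlation(GeneSetCollection(sets=sets), list(sets))
        assert corr.min_eigenvalue > -1e-10
        assert np.linalg.eigvalsh(corr.values()).min() >= 0

    def test_unknown_term_rejected(self, small_collection):
        with pytest.raises(ConfigError):
            overlap_correlation(small_collection, ["T1", "nope"])


def paired_overlap_collection(n_pairs=15, size=20, shared=10, seed=0):
    sets = {}
    g = 0
    for k in range(n_pairs):
        common = [f"g{g + i}" for i in range(shared)]
        only_a = [f"g{g + shared + i}" for i in range(size - shared)]
        only_b = [f"g{g + size + i}" for i in range(size - shared)]
        g += 2 * size - shared
        sets[f"P{k}a"] = frozenset(common + only_a)
        sets[f"P{k}b"] = frozenset(common + only_b)
    return GeneSetCollection(sets=sets)


class TestModelSchemes:
    def test_identity_corr_null_matches_permutation_null(self):
        # simulated-r distribution under an identity matrix equals the
        # rank-shuffle null (both are ranks of exchangeable vectors)
        k, n = 30, 2000
        rng = np.random.default_rng(15)
        model_draws = rng.standard_normal((n, 2, k))
        r_model = _spearman_rows(model_draws[:, 0, :], model_draws[:, 1, :])
        base = stats.rankdata(rng.normal(size=k))
        perms = rng.permuted(np.tile(base, (n, 1)), axis=1)
        r_perm = _spearman_rows(np.tile(stats.rankdata(rng.normal(size=k)), (n, 1)), perms)
        assert stats.ks_2samp(r_model, r_perm).statistic < 0.05

    def test_zero_observed_r_gives_half_p(self):
        coll = paired_overlap_collection()
        terms = list(coll.term_ids)
        corr = overlap_correlation(coll, terms)
        rng = np.random.default_rng(44)
        a = rng.normal(size=len(terms))
        # rotate b until the observed correlation is essentially zero
        b = None
        for _ in range(2000):
            cand = rng.permutation(a)
            if abs(spearman(a, cand)) < 0.01:
                b = cand
                break
        assert b is not None
        res = model_permutation(a, b, corr, n_sim=1999, seed=7)
        assert 0.40 < res.p < 0.60

    def test_model_permutation_deterministic(self):
        coll = paired_overlap_collection()
        corr = overlap_correlation(coll, list(coll.term_ids))
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=30), rng.normal(size=30)
        p1 = model_permutation(a, b, corr, n_sim=299, seed=13).p
        p2 = model_permutation(a, b, corr, n_sim=299, seed=13).p
        assert p1 == p2

    def test_model_bootstrap_ci_centered_near_observed_r(self):
        coll = paired_overlap_collection(n_pairs=15, shared=0)
        corr = overlap_correlation(coll, list(coll.term_ids))
        a = np.linspace(-15, 15, 30) * 2  # structure much larger than unit noise
        res = model_bootstrap(a, a, corr, n_sim=500, seed=9)
        assert res.r == pytest.approx(1.0)
        assert res.ci[0] > 0.8
        assert res.ci[0] <= 1.0 and (res.ci[0] + res.ci[1]) / 2 > 0.85

    def test_model_bootstrap_zero_vectors_reduce_to_null_spread(self):
        coll = paired_overlap_collection(n_pairs=10)
        corr = overlap_correlation(coll, list(coll.term_ids))
        zero = np.zeros(20)
        res = model_bootstrap(zero, zero, corr, n_sim=500, seed=2)
        assert math.isnan(res.r)
        assert res.ci[0] < 0 < res.ci[1]

    def test_model_bootstrap_deterministic(self):
        coll = paired_overlap_collection(n_pairs=10)
        corr = overlap_correlation(coll, list(coll.term_ids))
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert (
            model_bootstrap(a, b, corr, n_sim=300, seed=3).ci
            == model_bootstrap(a, b, corr, n_sim=300, seed=3).ci
        )

    def test_missing_terms_dropped_identically_across_schemes(self):
        coll = paired_overlap_collection(n_pairs=10)
        terms = list(coll.term_ids)
        rng = np.random.default_rng(10)
        a = pd.Series(rng.normal(size=20), index=terms)
        b = pd.Series(rng.normal(size=20), index=terms)
        a.iloc[3] = np.nan
        b.iloc[7] = np.nan
        corr = overlap_correlation(coll, terms)
        results = [
            permutation_test(a, b, n_perm=99, seed=0),
            pair_bootstrap(a, b, n_boot=99, seed=0),
            model_permutation(a, b, corr, n_sim=99, seed=0),
            model_bootstrap(a, b, corr, n_sim=99, seed=0),
        ]
        assert {res.n_terms for res in results} == {18}
        assert {res.n_dropped for res in results} == {2}
        assert len({res.r for res in results}) == 1
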