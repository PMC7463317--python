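"""Weir–Cockerham theta, permutation tests and IBD regression."""

import itertools

import numpy as np
import pytest
from scipy import stats

from popstruct.fst import (
    fst_permutation_test,
    ibd_regression,
    linearize_fst,
    pairwise_fst_matrix,
    wc_theta,
)
from popstruct.genotypes import MISSING
from popstruct.simulate import SimulationConfig, generate_dataset

from conftest import make_matrix


def oracle_theta(groups_calls):
    """Textbook Weir–Cockerham estimator, coded independently with loops.

    ``groups_calls``: list of (n_i x L) arrays of 0/1/2/missing calls.
    Returns the multilocus ratio-of-sums estimate.
    """
    L = groups_calls[0].shape[1]
    sum_a = sum_abc = 0.0
    for l in range(L):
        ns, ps, hs = [], [], []
        for g in groups_calls:
            col = g[:, l]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            ns.append(col.size)
            ps.append(col.sum() / (2 * col.size))
            hs.append(np.mean(col == 1))
        r = len(ns)
        if r < 2:
            continue
        ns = np.array(ns, float)
        ps = np.array(ps)
        hs = np.array(hs)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r - 1)
        if nc <= 0:
            continue
        pbar = (ns * ps).sum() / ns.sum()
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / ns.sum()
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


class TestWcTheta:
    def test_fixed_differences_give_one(self):
        gm = make_matrix(
            [[0, 0], [0, 0], [2, 2], [2, 2]], codes=["A", "A", "B", "B"]
        )
        assert wc_theta(gm) == pytest.approx(1.0)

    def test_matches_textbook_oracle_on_toys(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            ga = rng.integers(0, 3, size=(3, 4)).astype(np.int8)
            gb = rng.integers(0, 3, size=(3, 4)).astype(np.int8)
            gm = make_matrix(np.vstack([ga, gb]), codes=["A"] * 3 + ["B"] * 3)
            expected = oracle_theta([ga, gb])
            assert wc_theta(gm) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_with_missing_and_three_groups(self):
        rng = np.random.default_rng(23)
        groups = []
        for _ in range(3):
            g = rng.integers(0, 3, size=(5, 6)).astype(np.int8)
            g[rng.random(g.shape) < 0.2] = MISSING
            groups.append(g)
        gm = make_matrix(
            np.vstack(groups), codes=["A"] * 5 + ["B"] * 5 + ["C"] * 5
        )
        assert wc_theta(gm) == pytest.approx(oracle_theta(groups), abs=1e-12)

    def test_panmictic_near_zero(self):
        cfg = SimulationConfig(
            n_clusters=1, cluster_fst=(0.0,), within_cluster_fst=0.0,
            n_collections_per_cluster=(2,), n_individuals_per_collection=200,
            n_loci=3000, seed=2,
        )
        gm, _ = generate_dataset(cfg)
        assert abs(wc_theta(gm)) < 0.005

    def test_invariant_to_locus_order_and_allele_relabeling(self, two_pop_matrix):
        base = wc_theta(two_pop_matrix)
        shuffled = two_pop_matrix.subset_loci([1, 0])
        assert wc_theta(shuffled) == pytest.approx(base, abs=1e-14)
        flipped = two_pop_matrix.subset_loci([0, 1])
        calls = flipped.calls.copy()
        calls[:, 0] = np.where(calls[:, 0] == MISSING, MISSING, 2 - calls[:, 0])
        flipped.calls = calls
        assert wc_theta(flipped) == pytest.approx(base, abs=1e-14)


class TestPermutationTest:
    def test_maximal_theta_min_p(self):
        # groups large enough that no random relabeling reproduces the split
        gm = make_matrix(
            np.vstack([np.zeros((20, 5)), np.full((20, 5), 2)]).astype(np.int8),
            codes=["A"] * 20 + ["B"] * 20,
        )
        p = fst_permutation_test(gm, range(20), range(20, 40), n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_matches_exhaustive_relabeling_tiny(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 2)).astype(np.int8)
        gm = make_matrix(calls, codes=["A"] * 3 + ["B"] * 3)
        theta_obs = wc_theta(gm)
        # enumerate all 20 ways to choose group A from the pooled six
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            ga = calls[list(combo)]
            gb = calls[[i for i in range(6) if i not in combo]]
            total += 1
            if oracle_theta([ga, gb]) >= theta_obs - 1e-12:
                hits += 1
        exact = hits / total
        p = fst_permutation_test(gm, range(3), range(3, 6), n_perm=20_000, seed=5)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert p == pytest.approx(exact, abs=4 * se + 1e-3)

    def test_duplicate_collections_null(self):
        # one pool split arbitrarily in two: theta within the permutation spread
        rng = np.random.default_rng(9)
        calls = rng.binomial(2, 0.4, size=(60, 30)).astype(np.int8)
        gm = make_matrix(calls, codes=["A"] * 30 + ["B"] * 30)
        p = fst_permutation_test(gm, range(30), range(30, 60), n_perm=500, seed=2)
        assert p > 0.01


class TestPairwiseMatrix:
    def test_layout_and_holm_flags(self, three_cluster_data):
        gm, _ = three_cluster_data
        mat, pairs = pairwise_fst_matrix(gm, n_perm=200, seed=4)
        codes = gm.collection_order()
        for p in pairs:
            a, b = p.pair
            assert mat.loc[b, a] == pytest.approx(p.theta)
            assert mat.loc[a, b] == pytest.approx(p.p_value)
        # distinct clusters at drift 0.1 must all differentiate
        assert all(p.theta > 0.05 for p in pairs)
        assert all(p.significant_after_holm for p in pairs)


class TestLinearizeAndIbd:
    @pytest.mark.parametrize("theta,expected", [(0.0, 0.0), (0.5, 1.0), (0.217, 0.217 / 0.783)])
    def test_linearize_values(self, theta, expected):
        assert linearize_fst(theta) == pytest.approx(expected, abs=1e-12)

    def test_linearize_infinite_rejected(self):
        with pytest.raises(ValueError):
            linearize_fst(1.0)

    def test_collinear_r2_one(self):
        reg = ibd_regression([0.0, 0.1, 0.2, 0.3], [0, 100, 200, 300])
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.001)

    def test_zero_distance_variance_rejected(self):
        with pytest.raises(ValueError):
            ibd_regression([0.1, 0.2, 0.3], [5, 5, 5])

    def test_null_slope_ci_coverage(self):
        """With a flat truth the 95% slope CI covers zero >= 90% of runs."""
        rng = np.random.default_rng(11)
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.uniform(0, 1000, size=37)
            y = rng.normal(0.1, 0.02, size=37)
            res = stats.linregress(x, y)
            half = res.stderr * stats.t.ppf(0.975, 35)
            covered += (res.slope - half) <= 0 <= (res.slope + half)
        assert covered / n_rep >= 0.90

    def test_recovers_linear_truth(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 2000, size=37)
        slope_true = 5e-5
        y = 0.02 + slope_true * x + rng.normal(0, 0.01, size=37)
        reg = ibd_regression(y, x)
        se = 0.01 / (np.std(x) * np.sqrt(37))
        assert reg.slope == pytest.approx(slope_true, abs=2.5 * se)
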