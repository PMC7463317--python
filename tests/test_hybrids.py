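"""F1 simulation, CI-overlap classification, and baseline assignment."""

import numpy as np
import pytest

from popstruct.admixture import AdmixtureRunResult
from popstruct.genotypes import MISSING
from popstruct.hybrids import (
    HybridSimulationSpec,
    assign_individuals,
    classify_by_ci_overlap,
    simulate_f1_hybrids,
)
from conftest import make_matrix


def _run(Q, lower, upper):
    Q = np.asarray(Q, float)
    return AdmixtureRunResult(
        K=Q.shape[1], Q=Q, Q_lower=np.asarray(lower, float),
        Q_upper=np.asarray(upper, float), P=np.zeros((Q.shape[1], 1)),
        F=np.zeros(Q.shape[1]), alpha=1.0, L=0.0, lnlik_mean=0.0,
        lnlik_var=0.0, burn_in=0, length=0, seed=0,
    )


class TestF1Simulation:
    def _pools(self, calls_a, calls_b):
        calls = np.vstack([calls_a, calls_b]).astype(np.int8)
        n = len(calls_a)
        gm = make_matrix(calls, codes=["A"] * n + ["B"] * len(calls_b))
        return gm, np.arange(n), np.arange(n, n + len(calls_b))

    def test_opposite_fixation_all_het(self):
        gm, pa, pb = self._pools(np.zeros((10, 8)), np.full((10, 8), 2))
        spec = HybridSimulationSpec(pa, pb, n_per_pool=10, n_hybrids=25, seed=1)
        hyb, _, _ = simulate_f1_hybrids(gm, spec)
        assert (hyb.calls == 1).all()

    def test_intermediate_frequencies_genotype_distribution(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.5, size=(200, 5)).astype(np.int8)
        b = rng.binomial(2, 0.5, size=(200, 5)).astype(np.int8)
        gm, pa, pb = self._pools(a, b)
        spec = HybridSimulationSpec(pa, pb, n_per_pool=200, n_hybrids=10_000, seed=3)
        hyb, sa, sb = simulate_f1_hybrids(gm, spec)
        # realized parental freqs, then exact genotype expectation
        fa = gm.calls[sa].mean(axis=0) / 2
        fb = gm.calls[sb].mean(axis=0) / 2
        for j in range(5):
            p_het = fa[j] * (1 - fb[j]) + fb[j] * (1 - fa[j])
            obs = (hyb.calls[:, j] == 1).mean()
            se = np.sqrt(p_het * (1 - p_het) / 10_000)
            assert obs == pytest.approx(p_het, abs=4 * se)

    def test_expected_heterozygosity_closed_form(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, rng.uniform(0.2, 0.8, 12), size=(150, 12)).astype(np.int8)
        b = rng.binomial(2, rng.uniform(0.2, 0.8, 12), size=(150, 12)).astype(np.int8)
        gm, pa, pb = self._pools(a, b)
        spec = HybridSimulationSpec(pa, pb, n_per_pool=150, n_hybrids=5_000, seed=5)
        hyb, sa, sb = simulate_f1_hybrids(gm, spec)
        fa = gm.calls[sa].mean(axis=0) / 2
        fb = gm.calls[sb].mean(axis=0) / 2
        expected = fa * (1 - fb) + fb * (1 - fa)
        realized = (hyb.calls == 1).mean(axis=0)
        se = np.sqrt(expected * (1 - expected) / 5_000)
        assert (np.abs(realized - expected) <= 4 * se).all()

    def test_all_missing_locus_propagates(self):
        a = np.zeros((5, 2), dtype=np.int8)
        a[:, 1] = MISSING
        b = np.full((5, 2), 2, dtype=np.int8)
        gm, pa, pb = self._pools(a, b)
        spec = HybridSimulationSpec(pa, pb, n_per_pool=5, n_hybrids=8, seed=6)
        hyb, _, _ = simulate_f1_hybrids(gm, spec)
        assert (hyb.calls[:, 1] == MISSING).all()

    def test_overlapping_pools_rejected(self):
        with pytest.raises(ValueError):
            HybridSimulationSpec(np.arange(5), np.arange(3, 8), n_per_pool=3)


class TestCiOverlapClassification:
    def test_clear_overlap_is_admixed(self):
        run = _run([[0.5, 0.5]], [[0.4, 0.4]], [[0.6, 0.6]])
        cls = classify_by_ci_overlap(run, (0, 1))
        assert cls.table.status.iloc[0] == "admixed"

    def test_disjoint_intervals_pure(self):
        run = _run([[0.95, 0.05]], [[0.9, 0.0]], [[1.0, 0.1]])
        cls = classify_by_ci_overlap(run, (0, 1))
        assert cls.table.status.iloc[0] == "pure-A"

    def test_widening_never_flips_to_pure(self):
        rng = np.random.default_rng(7)
        Q = rng.dirichlet([1, 1], size=30)
        half = rng.uniform(0.02, 0.2, size=(30, 2))
        run_narrow = _run(Q, np.clip(Q - half, 0, 1), np.clip(Q + half, 0, 1))
        run_wide = _run(Q, np.clip(Q - 2 * half, 0, 1), np.clip(Q + 2 * half, 0, 1))
        narrow = classify_by_ci_overlap(run_narrow, (0, 1)).table.overlap
        wide = classify_by_ci_overlap(run_wide, (0, 1)).table.overlap
        assert (wide >= narrow).all()

    def test_identical_focal_clusters_rejected(self):
        run = _run([[0.5, 0.5]], [[0.4, 0.4]], [[0.6, 0.6]])
        with pytest.raises(ValueError):
            classify_by_ci_overlap(run, (1, 1))


class TestAssignment:
    def test_identical_baselines_symmetric(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.4, size=(30, 20)).astype(np.int8)
        calls = np.vstack([base, base, rng.binomial(2, 0.4, size=(5, 20))]).astype(np.int8)
        gm = make_matrix(calls, codes=["A"] * 30 + ["B"] * 30 + ["Q"] * 5)
        res = assign_individuals(
            gm, {"A": range(30), "B": range(30, 60)}, queries=range(60, 65)
        )
        np.testing.assert_allclose(res.probabilities.to_numpy(), 0.5, atol=1e-12)

    def test_strong_discrimination(self):
        rng = np.random.default_rng(9)
        a = rng.binomial(2, 0.9, size=(60, 50)).astype(np.int8)
        b = rng.binomial(2, 0.1, size=(60, 50)).astype(np.int8)
        query = np.full((1, 50), 2, dtype=np.int8)
        gm = make_matrix(np.vstack([a, b, query]), codes=["A"] * 60 + ["B"] * 60 + ["Q"])
        res = assign_individuals(gm, {"A": range(60), "B": range(60, 120)}, [120])
        assert res.probabilities.iloc[0]["A"] > 0.999

    def test_one_locus_hand_computed_posterior(self):
        """Single-locus toy against the compound-Dirichlet closed form."""
        a = np.array([[2], [2], [1]], dtype=np.int8)    # counts: 5 of allele1, 1 of allele0
        b = np.array([[0], [0], [1]], dtype=np.int8)    # counts: 1 of allele1, 5 of allele0
        q = np.array([[2]], dtype=np.int8)
        gm = make_matrix(np.vstack([a, b, q]), codes=["A"] * 3 + ["B"] * 3 + ["Q"])
        lam = 0.5
        def hom1(c1, n):
            return (c1 + lam) / (n + 2 * lam) * (c1 + lam + 1) / (n + 1 + 2 * lam)
        pa, pb = hom1(5, 6), hom1(1, 6)
        res = assign_individuals(gm, {"A": range(3), "B": range(3, 6)}, [6])
        assert res.probabilities.iloc[0]["A"] == pytest.approx(pa / (pa + pb), abs=1e-12)

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(10)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 15), size=(41, 15)).astype(np.int8)
        gm = make_matrix(calls, codes=["A"] * 20 + ["B"] * 20 + ["Q"])
        res1 = assign_individuals(gm, {"A": range(20), "B": range(20, 40)}, [40])
        perm = list(rng.permutation(15))
        res2 = assign_individuals(
            gm.subset_loci(perm), {"A": range(20), "B": range(20, 40)}, [40]
        )
        np.testing.assert_allclose(
            res1.probabilities.to_numpy(), res2.probabilities.to_numpy(), atol=1e-12
        )

    def test_leave_one_out_never_inflates_self_assignment(self):
        rng = np.random.default_rng(11)
        a = rng.binomial(2, 0.7, size=(25, 30)).astype(np.int8)
        b = rng.binomial(2, 0.3, size=(25, 30)).astype(np.int8)
        gm = make_matrix(np.vstack([a, b]), codes=["A"] * 25 + ["B"] * 25)
        baselines = {"A": range(25), "B": range(25, 50)}
        for qi in range(5):
            with_loo = assign_individuals(gm, baselines, [qi])
            without = assign_individuals(gm, baselines, [qi], query_baseline={})
            assert (
                with_loo.probabilities.iloc[0]["A"]
                <= without.probabilities.iloc[0]["A"] + 1e-12
            )

    def test_all_missing_query_uniform_with_warning(self):
        calls = np.vstack([
            np.zeros((4, 5)), np.full((4, 5), 2), np.full((1, 5), MISSING)
        ]).astype(np.int8)
        gm = make_matrix(calls, codes=["A"] * 4 + ["B"] * 4 + ["Q"])
        with pytest.warns(UserWarning):
            res = assign_individuals(gm, {"A": range(4), "B": range(4, 8)}, [8])
        np.testing.assert_allclose(res.probabilities.to_numpy(), 0.5)
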