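"""Admixture Gibbs sampler, run alignment, and K-selection statistics."""

from itertools import permutations, product

import numpy as np
import pytest

from popstruct.admixture import (
    AdmixtureRunResult,
    align_runs,
    evanno_delta_k,
    g_prime_similarity,
    puechmaille_estimators,
    run_admixture_mcmc,
    select_k,
)
from popstruct.simulate import (
    SimulationConfig,
    align_clusters_to_truth,
    generate_dataset,
)


def _fake_run(Q, K=None):
    Q = np.asarray(Q, float)
    K = K or Q.shape[1]
    return AdmixtureRunResult(
        K=K, Q=Q, Q_lower=np.clip(Q - 0.05, 0, 1), Q_upper=np.clip(Q + 0.05, 0, 1),
        P=np.zeros((K, 1)), F=np.zeros(K), alpha=1.0, L=0.0,
        lnlik_mean=0.0, lnlik_var=0.0, burn_in=0, length=0, seed=0,
    )


class TestSampler:
    def test_k1_degenerate(self, three_cluster_data):
        gm, _ = three_cluster_data
        run = run_admixture_mcmc(gm, K=1, burn_in=10, length=30, seed=1)[0]
        assert np.allclose(run.Q, 1.0)
        assert np.isfinite(run.L)

    def test_rows_sum_to_one_and_ci_ordered(self, three_cluster_data):
        gm, _ = three_cluster_data
        run = run_admixture_mcmc(gm, K=3, burn_in=100, length=300, thin=10, seed=2)[0]
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (run.Q_lower <= run.Q_upper + 1e-12).all()
        assert (run.Q_lower >= -1e-12).all() and (run.Q_upper <= 1 + 1e-12).all()

    def test_cluster_recovery(self, three_cluster_data):
        """Pure individuals are assigned to their true cluster."""
        gm, truth = three_cluster_data
        run = run_admixture_mcmc(gm, K=3, burn_in=300, length=900, thin=20, seed=3)[0]
        q = align_clusters_to_truth(run.Q, truth.q_true)
        accuracy = np.mean(q.argmax(axis=1) == truth.q_true.argmax(axis=1))
        assert accuracy >= 0.95

    def test_f1_individuals_half_ancestry(self):
        cfg = SimulationConfig(
            n_clusters=2, cluster_fst=(0.15, 0.15), within_cluster_fst=0.0,
            n_collections_per_cluster=(1, 1), n_individuals_per_collection=50,
            n_loci=91, admixture_zone={2: (0, 1, 1.0)}, seed=14,
        )
        gm, truth = generate_dataset(cfg)
        run = run_admixture_mcmc(gm, K=2, burn_in=300, length=900, thin=20, seed=4)[0]
        zone = np.array([c == "C02" for c in gm.collection_codes])
        mean_q = run.Q[zone].mean(axis=0)
        assert 0.45 <= mean_q[0] <= 0.55

    def test_k_exceeding_individuals_rejected(self, three_cluster_data):
        gm, _ = three_cluster_data
        with pytest.raises(ValueError):
            run_admixture_mcmc(gm.subset_individuals(range(3)), K=5,
                               burn_in=5, length=5, seed=0)


class TestAlignment:
    def test_label_swap_recovered(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(3) * 0.2, size=40)
        runs = [_fake_run(Q), _fake_run(Q[:, [2, 0, 1]])]
        consensus, perms = align_runs(runs)
        np.testing.assert_allclose(consensus, Q, atol=1e-12)

    def test_consensus_beats_single_runs(self):
        rng = np.random.default_rng(1)
        Q_true = rng.dirichlet(np.ones(3) * 0.2, size=60)
        runs = []
        for _ in range(6):
            noise = rng.normal(0, 0.05, Q_true.shape)
            q = np.clip(Q_true + noise, 1e-6, None)
            q /= q.sum(axis=1, keepdims=True)
            perm = list(rng.permutation(3))
            runs.append(_fake_run(q[:, perm]))
        consensus, _ = align_runs(runs)
        d_cons = np.linalg.norm(consensus - Q_true)
        d_single = min(
            min(np.linalg.norm(r.Q[:, list(p)] - Q_true) for p in permutations(range(3)))
            for r in runs
        )
        assert d_cons < d_single

    def test_matches_joint_brute_force_three_runs(self):
        rng = np.random.default_rng(2)
        Qs = [rng.dirichlet(np.ones(3), size=12) for _ in range(3)]
        runs = [_fake_run(q) for q in Qs]
        _, perms = align_runs(runs)

        def total(sel):
            aligned = [Qs[i][:, list(sel[i])] for i in range(3)]
            return sum(
                g_prime_similarity(aligned[i], aligned[j])
                for i in range(3) for j in range(i + 1, 3)
            )

        best = max(
            ([tuple(range(3)), p1, p2] for p1 in permutations(range(3))
             for p2 in permutations(range(3))),
            key=total,
        )
        assert total(perms) == pytest.approx(total(best), abs=1e-12)


class TestEvanno:
    def test_linear_evidence_gives_zero(self):
        L = {k: [-100.0 - 10 * k + e for e in (-0.1, 0.0, 0.1)] for k in range(1, 6)}
        dk = evanno_delta_k(L)
        assert np.allclose(dk.to_numpy(), 0.0, atol=1e-9)

    def test_hand_computed_grid(self):
        # means (-100, -50, -45); sd at K=2 equal to 2 -> Delta K(2) = 22.5
        L = {1: [-100.0, -100.0], 2: [-52.0, -48.0], 3: [-45.0, -45.0]}
        sd2 = np.std([-52.0, -48.0], ddof=1)
        dk = evanno_delta_k(L)
        assert dk[2] == pytest.approx(abs(-45 - 2 * (-50) + (-100)) / sd2)

    def test_zero_sd_reported_nan(self):
        L = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        assert np.isnan(evanno_delta_k(L)[2])

    def test_requires_consecutive_k(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [0], 3: [0], 5: [0]})

    def test_pure_function(self):
        L = {1: [-9.0, -8.0], 2: [-5.0, -4.0], 3: [-4.5, -4.4]}
        assert evanno_delta_k(L).equals(evanno_delta_k(L))


class TestPuechmaille:
    LABELS = ["g0", "g0", "g1", "g1", "g2", "g2", "g3", "g3"]

    def _runs(self, counts):
        """Fake runs where run i shows ``counts[i]`` clusters above 0.5:
        each counted cluster dominates one two-individual collection."""
        out = []
        for c in counts:
            Q = np.full((8, 4), 0.1 / 3)
            for i in range(8):
                Q[i, (i // 2) % max(c, 1)] = 0.9
            out.append(_fake_run(Q, K=4))
        return out

    def test_all_identical_three_clusters(self):
        runs = self._runs([3, 3, 3])
        tab = puechmaille_estimators({4: runs}, self.LABELS)
        assert (tab.loc[4] == 3).all()

    def test_aberrant_run_max_vs_med(self):
        runs = self._runs([3] * 9 + [4])
        tab = puechmaille_estimators({4: runs}, self.LABELS)
        assert tab.loc[4, "MaxMed"] == 4 and tab.loc[4, "MaxMean"] == 4
        assert tab.loc[4, "MedMed"] == 3 and tab.loc[4, "MedMean"] == 3

    def test_missing_labels_rejected(self):
        with pytest.raises(Exception):
            puechmaille_estimators({4: self._runs([3])}, None)


class TestSelectK:
    def test_three_clusters_selected(self, three_cluster_data):
        gm, _ = three_cluster_data
        runs_by_k = {
            K: run_admixture_mcmc(gm, K, burn_in=200, length=400, thin=20,
                                  replicates=3, seed=30 + K)
            for K in range(1, 6)
        }
        rep = select_k(runs_by_k, gm.collection_codes)
        votes = list(rep.best_k.values())
        assert rep.best_k_evanno == 3
        assert sum(v == 3 for v in votes) >= 3
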