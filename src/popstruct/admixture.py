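"""Bayesian admixture clustering with correlated allele frequencies.

This is the classic admixture model: each individual i carries ancestry
proportions q_i over K clusters (Dirichlet(alpha) prior), each gene copy
has a latent cluster of origin z, and cluster allele frequencies follow
the correlated-frequencies (F-model) prior — a single ancestral
frequency per locus with per-cluster drift F_k, so
p_kl ~ Beta(p_Al (1-F_k)/F_k, (1-p_Al)(1-F_k)/F_k). Inference is by
Gibbs sampling with Metropolis updates for alpha, F_k and the ancestral
frequencies; no sampling-location prior is used.

The model-evidence proxy L(K) is the standard harmonic-style estimate
mean(lnL) - var(lnL)/2 over retained sweeps, used by the Evanno Delta-K
and the four cluster-count estimators (MedMed/MedMean/MaxMed/MaxMean)
for choosing K. Replicate runs are aligned with a CLUMPP-style search
over cluster-label permutations maximizing the pairwise G' similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "AdmixtureRunResult",
    "run_admixture_mcmc",
    "align_runs",
    "g_prime_similarity",
    "evanno_delta_k",
    "puechmaille_estimators",
    "KSelectionReport",
]


@dataclass
class AdmixtureRunResult:
    K: int
    Q: np.ndarray                 # (n, K) posterior-mean ancestry
    Q_lower: np.ndarray           # (n, K) 90% credible lower bounds
    Q_upper: np.ndarray           # (n, K) 90% credible upper bounds
    P: np.ndarray                 # (K, L) posterior-mean cluster frequencies
    F: np.ndarray                 # (K,) posterior-mean drift parameters
    alpha: float                  # posterior-mean admixture concentration
    L: float                      # model evidence estimate mean - var/2
    lnlik_mean: float
    lnlik_var: float
    burn_in: int
    length: int
    seed: int | None
    individuals: list[str] | None = None

    def q_dataframe(self) -> pd.DataFrame:
        idx = self.individuals or list(range(self.Q.shape[0]))
        return pd.DataFrame(self.Q, index=idx, columns=[f"q{k+1}" for k in range(self.K)])


def _sample_categorical(rng: np.random.Generator, w: np.ndarray) -> np.ndarray:
    """Sample from categorical distributions along the last axis of w."""
    cum = np.cumsum(w, axis=-1)
    u = rng.random(w.shape[:-1])[..., None] * cum[..., -1:]
    return (u > cum).sum(axis=-1)


try:  # compiled kernel for the copy-origin update; numpy fallback below
    from numba import njit

    @njit(cache=True)
    def _z_update_kernel(Q, P, copy_i, copy_l, copy_a, u, n_ik, c1, c0):
        K = Q.shape[1]
        for c in range(copy_i.size):
            i = copy_i[c]
            l = copy_l[c]
            tot = 0.0
            for k in range(K):
                pk = P[k, l] if copy_a[c] else 1.0 - P[k, l]
                tot += Q[i, k] * pk
            r = u[c] * tot
            acc = 0.0
            z = K - 1
            for k in range(K):
                pk = P[k, l] if copy_a[c] else 1.0 - P[k, l]
                acc += Q[i, k] * pk
                if r < acc:
                    z = k
                    break
            n_ik[i, z] += 1.0
            if copy_a[c]:
                c1[z, l] += 1.0
            else:
                c0[z, l] += 1.0

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def run_admixture_mcmc(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 100_000,
    length: int = 1_000_000,
    replicates: int = 1,
    thin: int = 50,
    seed: int | None = None,
    credible_mass: float = 0.90,
) -> list[AdmixtureRunResult]:
    """Run replicate Gibbs-sampler chains for a given K.

    ``burn_in`` and ``length`` count MCMC sweeps (full updates of all
    latent variables); the defaults mirror long production settings and
    should be scaled down ~100x for test-profile runs. Every source of
    randomness derives from ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    master = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        rep_seed = int(master.integers(0, 2**31 - 1))
        out.append(
            _one_chain(gm, K, burn_in, length, thin, rep_seed, credible_mass)
        )
    return out


def _one_chain(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int,
    length: int,
    thin: int,
    seed: int,
    credible_mass: float,
) -> AdmixtureRunResult:
    rng = np.random.default_rng(seed)
    calls = gm.calls
    n, L = calls.shape
    d = calls.astype(np.int64)
    obs = calls >= 0
    d_obs = np.where(obs, d, 0)
    n_het = obs & (d == 1)

    # flatten observed gene copies into index arrays (individual, locus,
    # allele) once; the z-update then works on one (n_copies, K) array
    ii, ll_idx = np.nonzero(obs)
    copy_i = np.concatenate([ii, ii])
    copy_l = np.concatenate([ll_idx, ll_idx])
    first_allele = (d[ii, ll_idx] >= 1).astype(np.int8)   # het copies: one of each
    second_allele = (d[ii, ll_idx] == 2).astype(np.int8)
    copy_a = np.concatenate([first_allele, second_allele])
    n_copies = copy_i.size

    # init: a k-means partition of the dosage matrix seeds Q and P, so that
    # short chains start near a sensible mode instead of spending most of
    # their budget escaping label-merged configurations; run-to-run
    # variability comes from the k-means restart seed and the MCMC stream
    with np.errstate(invalid="ignore", divide="ignore"):
        p_mean = d_obs.sum(axis=0) / np.maximum(2 * obs.sum(axis=0), 1)
    pA = np.clip(p_mean, 0.05, 0.95)
    if K == 1:
        Q = np.ones((n, 1))
        P = np.clip(pA[None, :].copy(), 0.01, 0.99)
    else:
        from sklearn.cluster import KMeans

        X = np.where(obs, d, 0).astype(float) + (~obs) * p_mean[None, :] * 2
        labels = KMeans(K, n_init=4, random_state=seed % (2**31)).fit_predict(X)
        Q = np.full((n, K), 0.1 / max(K - 1, 1))
        Q[np.arange(n), labels] = 0.9
        Q /= Q.sum(axis=1, keepdims=True)
        P = np.empty((K, L))
        for k in range(K):
            member = labels == k
            if member.any():
                with np.errstate(invalid="ignore", divide="ignore"):
                    pk = d_obs[member].sum(axis=0) / np.maximum(
                        2 * obs[member].sum(axis=0), 1
                    )
            else:
                pk = pA
            P[k] = np.clip(0.8 * pk + 0.2 * pA, 0.01, 0.99)
    F = np.full(K, 0.01)
    alpha = 1.0

    # F-model prior on F_k: Beta(0.1, 9.9) — mean 0.01, long right tail
    f_a, f_b = 0.1, 9.9
    # alpha random-walk sd: scaled up from the classic 0.025 so that short
    # chains still traverse the (0, 10) prior range within burn-in
    alpha_sd = 0.025 if burn_in >= 20_000 else 0.15
    pA_sd = 0.05
    f_sd = 0.3  # on logit scale

    total = burn_in + length
    keep_every = max(1, thin)
    q_samples = []
    lnliks = []
    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L))
    F_sum = np.zeros(K)
    alpha_sum = 0.0
    n_ret = 0

    ln2 = np.log(2.0)
    from scipy.special import gammaln

    for sweep in range(total):
        # --- z: cluster of origin for every gene copy -------------------
        n_ik = np.zeros((n, K))
        c1 = np.zeros((K, L))
        c0 = np.zeros((K, L))
        if _HAVE_NUMBA:
            _z_update_kernel(
                Q, P, copy_i, copy_l, copy_a, rng.random(n_copies), n_ik, c1, c0
            )
        else:
            p_copy = np.where(copy_a[:, None], P.T[copy_l], (1.0 - P.T)[copy_l])
            z = _sample_categorical(rng, Q[copy_i] * p_copy)
            n_ik += np.bincount(copy_i * K + z, minlength=n * K).reshape(n, K)
            is1 = copy_a == 1
            c1 += np.bincount(z[is1] * L + copy_l[is1], minlength=K * L).reshape(K, L)
            c0 += np.bincount(z[~is1] * L + copy_l[~is1], minlength=K * L).reshape(K, L)

        # --- Q | z ------------------------------------------------------
        if K == 1:
            Q = np.ones((n, 1))
        else:
            g = rng.gamma(alpha + n_ik)
            Q = g / g.sum(axis=1, keepdims=True)
            np.clip(Q, 1e-12, None, out=Q)
            Q /= Q.sum(axis=1, keepdims=True)

        # --- P | z under the correlated-frequencies prior ---------------
        lam = (1.0 - F) / F                              # (K,)
        P = rng.beta(
            c1 + pA[None, :] * lam[:, None],
            c0 + (1.0 - pA[None, :]) * lam[:, None],
        )
        np.clip(P, 1e-9, 1 - 1e-9, out=P)

        # --- ancestral frequencies pA (Metropolis, Uniform(0,1) prior) --
        prop = pA + rng.normal(0, pA_sd, size=L)
        prop = np.where(prop < 0, -prop, prop)
        prop = np.where(prop > 1, 2 - prop, prop)        # reflect into (0,1)
        prop = np.clip(prop, 1e-6, 1 - 1e-6)
        lp_cur = _beta_logpdf_sum(P, pA, lam)
        lp_prop = _beta_logpdf_sum(P, prop, lam)
        acc = np.log(rng.random(L)) < (lp_prop - lp_cur)
        pA = np.where(acc, prop, pA)

        # --- drift F_k (Metropolis on logit scale, Beta prior) ----------
        for k in range(K):
            logit = np.log(F[k] / (1 - F[k]))
            f_p = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, f_sd))))
            f_p = min(max(f_p, 1e-6), 1 - 1e-6)
            lam_p = (1 - f_p) / f_p
            cur = _beta_logpdf_sum_k(P[k], pA, lam[k]) + _beta_prior(F[k], f_a, f_b)
            new = _beta_logpdf_sum_k(P[k], pA, lam_p) + _beta_prior(f_p, f_a, f_b)
            # Jacobian of the logit transform
            jac = np.log(f_p * (1 - f_p)) - np.log(F[k] * (1 - F[k]))
            if np.log(rng.random()) < new - cur + jac:
                F[k] = f_p
                lam[k] = lam_p

        # --- alpha (Metropolis RW, Uniform(0,10) prior) -----------------
        if K > 1:
            a_p = alpha + rng.normal(0, alpha_sd)
            if 0 < a_p < 10:
                lnq = np.log(Q).sum()
                cur = n * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * lnq
                new = n * (gammaln(K * a_p) - K * gammaln(a_p)) + (a_p - 1) * lnq
                if np.log(rng.random()) < new - cur:
                    alpha = a_p

        # --- bookkeeping ------------------------------------------------
        if sweep >= burn_in:
            u = Q @ P                                     # (n, L) allele-1 copy prob
            np.clip(u, 1e-12, 1 - 1e-12, out=u)
            ll = np.where(
                obs,
                d_obs * np.log(u) + (2 - d_obs) * np.log(1 - u) + n_het * ln2,
                0.0,
            ).sum()
            lnliks.append(float(ll))
            Q_sum += Q
            P_sum += P
            F_sum += F
            alpha_sum += alpha
            n_ret += 1
            if (sweep - burn_in) % keep_every == 0:
                q_samples.append(Q.copy())

    lnliks = np.asarray(lnliks)
    q_arr = np.asarray(q_samples)
    lo = (1 - credible_mass) / 2
    return AdmixtureRunResult(
        K=K,
        Q=Q_sum / n_ret,
        Q_lower=np.quantile(q_arr, lo, axis=0),
        Q_upper=np.quantile(q_arr, 1 - lo, axis=0),
        P=P_sum / n_ret,
        F=F_sum / n_ret,
        alpha=alpha_sum / n_ret,
        L=float(lnliks.mean() - lnliks.var() / 2.0),
        lnlik_mean=float(lnliks.mean()),
        lnlik_var=float(lnliks.var()),
        burn_in=burn_in,
        length=length,
        seed=seed,
        individuals=list(gm.individuals),
    )


def _beta_logpdf_sum(P: np.ndarray, pA: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Sum over clusters of the Beta log-density of P given pA, per locus."""
    from scipy.special import betaln

    a = pA[None, :] * lam[:, None]
    b = (1 - pA[None, :]) * lam[:, None]
    val = (a - 1) * np.log(P) + (b - 1) * np.log(1 - P) - betaln(a, b)
    return val.sum(axis=0)


def _beta_logpdf_sum_k(P_k: np.ndarray, pA: np.ndarray, lam_k: float) -> float:
    from scipy.special import betaln

    a = pA * lam_k
    b = (1 - pA) * lam_k
    return float(((a - 1) * np.log(P_k) + (b - 1) * np.log(1 - P_k) - betaln(a, b)).sum())


def _beta_prior(x: float, a: float, b: float) -> float:
    return float((a - 1) * np.log(x) + (b - 1) * np.log(1 - x))


# ---------------------------------------------------------------------------
# run alignment (label switching)
# ---------------------------------------------------------------------------

def g_prime_similarity(qa: np.ndarray, qb: np.ndarray) -> float:
    """G' similarity between two aligned Q matrices (1 = identical)."""
    n = qa.shape[0]
    return 1.0 - float(np.linalg.norm(qa - qb)) / np.sqrt(2.0 * n)


def align_runs(
    runs: Sequence[AdmixtureRunResult],
    max_exhaustive: int = 20_000,
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Align replicate runs over cluster-label permutations.

    Maximizes the average pairwise G' similarity. When the joint search
    space (K!)^(R-1) is small it is searched exhaustively (FullSearch);
    otherwise runs are aligned greedily to the first run and refined by
    iterated conditional updates until stable. Returns the consensus
    (mean aligned Q) and the permutation applied to each run.
    """
    if not runs:
        raise ValueError("no runs to align")
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share K")
    Qs = [r.Q for r in runs]
    R = len(Qs)
    if R == 1 or K == 1:
        perms = [tuple(range(K))] * R
        return Qs[0].copy(), perms

    all_perms = list(permutations(range(K)))

    def total_sim(perm_choice: Sequence[tuple[int, ...]]) -> float:
        aligned = [Qs[i][:, list(perm_choice[i])] for i in range(R)]
        s = 0.0
        for i in range(R):
            for j in range(i + 1, R):
                s += g_prime_similarity(aligned[i], aligned[j])
        return s

    n_joint = len(all_perms) ** (R - 1)
    if n_joint <= max_exhaustive:
        best, best_s = None, -np.inf
        for choice in product(all_perms, repeat=R - 1):
            full = [tuple(range(K)), *choice]
            s = total_sim(full)
            if s > best_s:
                best_s, best = s, full
        perms = list(best)
    else:
        # greedy alignment to run 0, then ICM refinement
        perms = [tuple(range(K))]
        for i in range(1, R):
            best_p = max(
                all_perms,
                key=lambda p: g_prime_similarity(Qs[0], Qs[i][:, list(p)]),
            )
            perms.append(best_p)
        improved = True
        while improved:
            improved = False
            for i in range(1, R):
                others = [Qs[j][:, list(perms[j])] for j in range(R) if j != i]
                best_p = max(
                    all_perms,
                    key=lambda p: sum(
                        g_prime_similarity(o, Qs[i][:, list(p)]) for o in others
                    ),
                )
                if best_p != perms[i]:
                    perms[i] = best_p
                    improved = True
    consensus = np.mean([Qs[i][:, list(perms[i])] for i in range(R)], axis=0)
    return consensus, perms


# ---------------------------------------------------------------------------
# choosing K
# ---------------------------------------------------------------------------

@dataclass
class KSelectionReport:
    table: pd.DataFrame           # per K: L_mean, L_sd, delta_k, four estimators
    best_k_evanno: int | None
    best_k: dict[str, int]        # per Puechmaille statistic


def evanno_delta_k(L_by_k: Mapping[int, Sequence[float]]) -> pd.Series:
    """Evanno's Delta K from replicate evidence values per K.

    Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K),
    defined for interior K only; NaN where the replicate sd is zero.
    """
    ks = sorted(L_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least three consecutive K values")
    means = {k: float(np.mean(L_by_k[k])) for k in ks}
    sds = {k: float(np.std(L_by_k[k], ddof=1)) if len(L_by_k[k]) > 1 else 0.0 for k in ks}
    out = {}
    for k in ks[1:-1]:
        num = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        out[k] = num / sds[k] if sds[k] > 0 else np.nan
    return pd.Series(out, name="delta_k")


def puechmaille_estimators(
    runs_by_k: Mapping[int, Sequence[AdmixtureRunResult]],
    collection_codes: Sequence[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """MedMed/MedMean/MaxMed/MaxMean cluster-count estimators per K.

    For each run, a cluster "counts" if at least one collection's mean
    (Mean family) or median (Med family) membership in it exceeds the
    threshold; per-run counts are then combined across runs by their
    median (Med- prefix) or maximum (Max- prefix).
    """
    codes = np.asarray(collection_codes)
    uniq = list(dict.fromkeys(codes))
    rows = []
    for K, runs in sorted(runs_by_k.items()):
        counts_mean, counts_med = [], []
        for r in runs:
            mean_stat = np.vstack([r.Q[codes == c].mean(axis=0) for c in uniq])
            med_stat = np.vstack([np.median(r.Q[codes == c], axis=0) for c in uniq])
            counts_mean.append(int(np.sum((mean_stat > threshold).any(axis=0))))
            counts_med.append(int(np.sum((med_stat > threshold).any(axis=0))))
        rows.append(
            {
                "K": K,
                "MedMed": int(np.median(counts_med)),
                "MedMean": int(np.median(counts_mean)),
                "MaxMed": int(np.max(counts_med)),
                "MaxMean": int(np.max(counts_mean)),
            }
        )
    return pd.DataFrame(rows).set_index("K")


def select_k(
    runs_by_k: Mapping[int, Sequence[AdmixtureRunResult]],
    collection_codes: Sequence[str],
    threshold: float = 0.5,
) -> KSelectionReport:
    """Full K-selection report: evidence summaries, Delta K and the four
    cluster-count estimators with their chosen K (modal value over the
    K grid for each estimator)."""
    L_by_k = {k: [r.L for r in v] for k, v in runs_by_k.items()}
    ks = sorted(L_by_k)
    tab = pd.DataFrame(
        {
            "L_mean": [float(np.mean(L_by_k[k])) for k in ks],
            "L_sd": [
                float(np.std(L_by_k[k], ddof=1)) if len(L_by_k[k]) > 1 else np.nan
                for k in ks
            ],
        },
        index=pd.Index(ks, name="K"),
    )
    try:
        dk = evanno_delta_k(L_by_k)
        tab["delta_k"] = dk.reindex(tab.index)
        best_evanno = int(dk.idxmax()) if dk.notna().any() else None
    except ValueError:
        tab["delta_k"] = np.nan
        best_evanno = None
    pm = puechmaille_estimators(runs_by_k, collection_codes, threshold)
    tab = tab.join(pm)
    # Below the true K every count is capped at K, so the informative read
    # is the saturation point: the smallest analyzed K at which the count
    # falls below K (the model stops populating all clusters). If the grid
    # never saturates, the count at the largest K is used.
    best: dict[str, int] = {}
    ks_sorted = sorted(runs_by_k)
    for stat in ("MedMed", "MedMean", "MaxMed", "MaxMean"):
        chosen = int(pm.loc[ks_sorted[-1], stat])
        for k in ks_sorted:
            if int(pm.loc[k, stat]) < k:
                chosen = int(pm.loc[k, stat])
                break
        best[stat] = chosen
    return KSelectionReport(tab, best_evanno, best)
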