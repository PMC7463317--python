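"""Exact Hardy–Weinberg tests and genotypic linkage-disequilibrium tests.

The HWE test is Levene's exact conditional test: given the observed
allele counts, the number of heterozygotes h follows a known discrete
distribution, and for biallelic loci that distribution can be enumerated
completely — no Markov chain is needed. The probability-test p-value
sums P(h') over all outcomes no more probable than the observed one;
one-sided deficit/excess p-values give the direction of departure. A
Monte-Carlo sampler with the conventional chain parameterization
(dememorization / batches / iterations per batch) is kept as a
cross-check mode only.

The LD test is the genotypic log-likelihood-ratio (G) test on the 3x3
genotype contingency table of a locus pair within one collection, with a
Monte-Carlo permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = [
    "HweTestResult",
    "LdTestResult",
    "hwe_exact_test",
    "hwe_test_collection",
    "ld_genotypic_test",
    "ld_all_pairs",
    "MCChainConfig",
]


@dataclass(frozen=True)
class MCChainConfig:
    """Markov-chain parameters retained for the Monte-Carlo cross-check."""

    dememorization: int = 10_000
    batches: int = 1_000
    iterations_per_batch: int = 10_000


@dataclass(frozen=True)
class HweTestResult:
    p_value: float
    p_deficit: float
    p_excess: float
    direction: str  # "deficit" | "excess" | "none"
    testable: bool


@dataclass(frozen=True)
class LdTestResult:
    g_statistic: float
    p_value: float
    n_permutations_used: int
    testable: bool


def _levene_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given allele counts.

    ``n_a`` is the minor-allele count out of ``2n`` gene copies. Returns
    (h values, log P(h)); h runs over counts with the parity of n_a from
    max(0, n_a - n)…n_a. P(h) = n! 2^h n_a! n_b! / (n_aa! h! n_bb! (2n)!).
    """
    n_b = 2 * n - n_a
    h_min = max(n_a - n, 0)
    hs = np.arange(h_min + (n_a - h_min) % 2, n_a + 1, 2)
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logp = (
        gammaln(n + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
        - gammaln(2 * n + 1)
    )
    return hs, logp


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> HweTestResult:
    """Levene-conditional exact HWE test for one biallelic locus.

    The probability test sums outcomes with P(h') <= P(h_obs) (with a
    small relative tolerance for float ties). Direction is the side with
    the smaller one-sided p. Monomorphic input is untestable (p = 1).
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("genotype counts must be nonnegative with at least one")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return HweTestResult(1.0, 1.0, 1.0, "none", testable=False)
    minor = min(n_a, n_b)
    hs, logp = _levene_log_probs(minor, n)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hs == n_ab)
    if obs.size != 1:  # parity violation cannot happen with valid counts
        raise AssertionError("observed heterozygote count not in support")
    i = int(obs[0])
    p_obs = probs[i]
    p_value = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    p_deficit = float(probs[: i + 1].sum())   # h' <= h_obs
    p_excess = float(probs[i:].sum())         # h' >= h_obs
    if p_deficit < p_excess:
        direction = "deficit"
    elif p_excess < p_deficit:
        direction = "excess"
    else:
        direction = "none"
    return HweTestResult(min(p_value, 1.0), min(p_deficit, 1.0), min(p_excess, 1.0), direction, True)


def hwe_exact_test_mc(
    n_aa: int, n_ab: int, n_bb: int, chain: MCChainConfig | None = None,
    seed: int | None = None,
) -> HweTestResult:
    """Monte-Carlo version of the probability test (cross-check only).

    Samples heterozygote counts from the exact conditional distribution;
    the chain parameterization sets the total draw count
    (batches x iterations_per_batch, capped for practicality).
    """
    chain = chain or MCChainConfig()
    exact = hwe_exact_test(n_aa, n_ab, n_bb)
    if not exact.testable:
        return exact
    n = n_aa + n_ab + n_bb
    minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hs, logp = _levene_log_probs(minor, n)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    n_draws = min(chain.batches * chain.iterations_per_batch, 200_000)
    rng = np.random.default_rng(seed)
    draws = rng.choice(hs.size, size=n_draws, p=probs)
    p_obs = probs[int(np.flatnonzero(hs == n_ab)[0])]
    k = int(np.sum(probs[draws] <= p_obs * (1 + 1e-12)))
    p_mc = (1 + k) / (1 + n_draws)
    return HweTestResult(p_mc, exact.p_deficit, exact.p_excess, exact.direction, True)


def hwe_test_collection(gm: GenotypeMatrix, collection: str) -> "np.ndarray":
    """Exact HWE tests for every locus in one collection.

    Returns a structured list of (locus_id, result) pairs; monomorphic
    cells come back untestable.
    """
    calls = gm.calls[gm.indices_of(collection)]
    results = []
    for j, lid in enumerate(gm.locus_ids):
        col = calls[:, j]
        col = col[col >= 0]
        if col.size == 0:
            results.append((lid, HweTestResult(1.0, 1.0, 1.0, "none", False)))
            continue
        n_aa = int(np.sum(col == 0))
        n_ab = int(np.sum(col == 1))
        n_bb = int(np.sum(col == 2))
        results.append((lid, hwe_exact_test(n_aa, n_ab, n_bb)))
    return results


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of independence on a contingency table."""
    table = table.astype(float)
    total = table.sum()
    if total == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def _table_from_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    t = np.zeros((3, 3), dtype=np.int64)
    np.add.at(t, (a, b), 1)
    return t


def ld_genotypic_test(
    gm: GenotypeMatrix,
    collection: str,
    locus_a: str,
    locus_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> LdTestResult:
    """Permutation G-test of genotypic association between two loci.

    One locus's genotypes are shuffled across individuals within the
    collection; p = (1 + #{G_perm >= G_obs}) / (1 + n_perm), the
    standard unbiased Monte-Carlo estimator. A locus monomorphic in the
    collection makes the table degenerate (untestable).
    """
    idx = gm.indices_of(collection)
    ja = gm.locus_ids.index(locus_a)
    jb = gm.locus_ids.index(locus_b)
    a = gm.calls[idx, ja]
    b = gm.calls[idx, jb]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(int), b[ok].astype(int)
    if a.size < 2 or np.unique(a).size < 2 or np.unique(b).size < 2:
        return LdTestResult(0.0, 1.0, 0, testable=False)
    g_obs = _g_statistic(_table_from_pairs(a, b))
    rng = np.random.default_rng(seed)
    count = 0
    b_perm = b.copy()
    for _ in range(n_perm):
        rng.shuffle(b_perm)
        if _g_statistic(_table_from_pairs(a, b_perm)) >= g_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return LdTestResult(g_obs, p, n_perm, testable=True)


def ld_all_pairs(
    gm: GenotypeMatrix,
    collection: str,
    n_perm: int = 1_000,
    seed: int | None = None,
) -> list[tuple[str, str, LdTestResult]]:
    """All locus-pair LD tests within one collection (seeded per pair)."""
    rng = np.random.default_rng(seed)
    out = []
    ids = gm.locus_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            out.append(
                (ids[i], ids[j], ld_genotypic_test(gm, collection, ids[i], ids[j], n_perm, sub_seed))
            )
    return out
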