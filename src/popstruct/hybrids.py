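"""Hybrid-zone diagnostics: in-silico F1 simulation, credible-interval
classification of admixed vs pure fish, and baseline assignment.

The F1 simulator draws, at every locus, one gamete from each parental
pool's allele frequencies — the standard in-silico hybridization model.
Individuals are called admixed when the 90% credible intervals of their
ancestry in the two focal clusters overlap; otherwise they are assigned
pure toward the cluster with the higher posterior-mean ancestry.
Individual assignment uses the posterior-predictive (compound Dirichlet)
genotype likelihood per baseline with leave-one-out correction when the
query belongs to a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import AdmixtureRunResult
from .genotypes import MISSING, GenotypeMatrix, SnpLocus

__all__ = [
    "HybridSimulationSpec",
    "simulate_f1_hybrids",
    "classify_by_ci_overlap",
    "AdmixtureClassification",
    "assign_individuals",
    "AssignmentResult",
]


@dataclass
class HybridSimulationSpec:
    """Specification for an in-silico F1 cross between two pools.

    ``pool_a`` / ``pool_b`` are individual indices into the source
    matrix; ``n_per_pool`` individuals are subsampled from each to form
    the parental baselines before estimating gamete frequencies.
    """

    pool_a: np.ndarray
    pool_b: np.ndarray
    n_per_pool: int = 150
    n_hybrids: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pool_a = np.asarray(self.pool_a, dtype=int)
        self.pool_b = np.asarray(self.pool_b, dtype=int)
        if np.intersect1d(self.pool_a, self.pool_b).size:
            raise ValueError("parental pools must be disjoint")
        if self.n_per_pool > min(self.pool_a.size, self.pool_b.size):
            raise ValueError("n_per_pool exceeds a pool size")


def simulate_f1_hybrids(
    gm: GenotypeMatrix, spec: HybridSimulationSpec, collection_code: str = "F1SIM"
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Create in-silico F1 hybrids between two parental pools.

    Returns ``(hybrids, subset_a, subset_b)`` where the subsets are the
    randomly selected parental individuals actually used. Each hybrid
    receives one allele drawn from pool A's frequencies and one from
    pool B's, independently across loci. A locus with no data in either
    pool yields missing hybrid calls.
    """
    rng = np.random.default_rng(spec.seed)
    sub_a = rng.choice(spec.pool_a, size=spec.n_per_pool, replace=False)
    sub_b = rng.choice(spec.pool_b, size=spec.n_per_pool, replace=False)

    def pool_freq(idx: np.ndarray) -> np.ndarray:
        calls = gm.calls[idx]
        obs = calls >= 0
        n = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(obs, calls, 0).sum(axis=0) / n
        return np.where(n > 0, f, np.nan)

    fa = pool_freq(sub_a)
    fb = pool_freq(sub_b)
    L = gm.n_loci
    calls = np.full((spec.n_hybrids, L), MISSING, dtype=np.int8)
    ok = ~np.isnan(fa) & ~np.isnan(fb)
    ga = rng.binomial(1, np.where(ok, fa, 0.0), size=(spec.n_hybrids, L))
    gb = rng.binomial(1, np.where(ok, fb, 0.0), size=(spec.n_hybrids, L))
    calls[:, ok] = (ga + gb)[:, ok].astype(np.int8)
    hybrids = GenotypeMatrix(
        individuals=[f"{collection_code}_{i:03d}" for i in range(spec.n_hybrids)],
        collection_codes=[collection_code] * spec.n_hybrids,
        loci=[SnpLocus(l.locus_id, l.alleles) for l in gm.loci],
        calls=calls,
    )
    return hybrids, sub_a, sub_b


# ---------------------------------------------------------------------------
# credible-interval overlap classification
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureClassification:
    table: pd.DataFrame            # per individual: status, overlap, q bounds
    fraction_overlapping: dict[str, float]   # per collection/group


def classify_by_ci_overlap(
    run: AdmixtureRunResult,
    focal: tuple[int, int],
    group_labels: Sequence[str] | None = None,
) -> AdmixtureClassification:
    """Classify individuals as admixed or pure from interval overlap.

    An individual is *admixed* iff the credible intervals of its
    ancestry in the two focal clusters overlap; otherwise it is *pure*
    toward the cluster with the higher posterior-mean ancestry. Widening
    either interval can only move pure calls toward admixed, never the
    reverse.
    """
    a, b = focal
    if a == b:
        raise ValueError("focal clusters must differ")
    lo_a, hi_a = run.Q_lower[:, a], run.Q_upper[:, a]
    lo_b, hi_b = run.Q_lower[:, b], run.Q_upper[:, b]
    overlap = (lo_a <= hi_b) & (lo_b <= hi_a)
    toward_a = run.Q[:, a] >= run.Q[:, b]
    status = np.where(overlap, "admixed", np.where(toward_a, "pure-A", "pure-B"))
    ids = run.individuals or [str(i) for i in range(run.Q.shape[0])]
    table = pd.DataFrame(
        {
            "status": status,
            "overlap": overlap,
            "q_a": run.Q[:, a],
            "q_a_lower": lo_a,
            "q_a_upper": hi_a,
            "q_b": run.Q[:, b],
            "q_b_lower": lo_b,
            "q_b_upper": hi_b,
        },
        index=ids,
    )
    fractions: dict[str, float] = {}
    if group_labels is not None:
        g = np.asarray(group_labels)
        for grp in dict.fromkeys(group_labels):
            fractions[grp] = float(overlap[g == grp].mean())
    else:
        fractions["all"] = float(overlap.mean())
    return AdmixtureClassification(table, fractions)


# ---------------------------------------------------------------------------
# individual assignment (genetic stock identification)
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    probabilities: pd.DataFrame    # individuals x baselines, rows sum to 1
    top_group: pd.Series
    leave_one_out: pd.Series       # bool per individual


def assign_individuals(
    gm: GenotypeMatrix,
    baselines: Mapping[str, Sequence[int]],
    queries: Sequence[int],
    prior_weight: float = 0.5,
    query_baseline: Mapping[int, str] | None = None,
) -> AssignmentResult:
    """Assign query individuals to baseline groups.

    For each baseline, the genotype probability at a locus is the
    posterior-predictive draw of the individual's two alleles from the
    baseline's allele counts with a symmetric Dirichlet prior
    (``prior_weight`` per allele; the 1/number-of-alleles convention
    gives 0.5 for SNPs). Counts update sequentially between the two
    draws, and an unseen allele keeps nonzero probability through the
    prior. When a query belongs to a baseline its own alleles are
    removed first (leave-one-out). Per-locus log-probabilities are
    summed and normalized across baselines; all-missing queries come
    back uniform with a warning.
    """
    import warnings

    if len(baselines) < 2:
        raise ValueError("need at least two baselines")
    lam = float(prior_weight)
    base_names = list(baselines)
    counts1: dict[str, np.ndarray] = {}
    counts_tot: dict[str, np.ndarray] = {}
    for name, idx in baselines.items():
        calls = gm.calls[np.asarray(idx, dtype=int)]
        obs = calls >= 0
        counts1[name] = np.where(obs, calls, 0).sum(axis=0).astype(float)
        counts_tot[name] = 2.0 * obs.sum(axis=0).astype(float)

    membership: dict[int, str] = {}
    if query_baseline is not None:
        membership = dict(query_baseline)
    else:
        for name, idx in baselines.items():
            for i in np.asarray(idx, dtype=int):
                membership[int(i)] = name

    rows = []
    loo_flags = []
    ids = []
    for qi in queries:
        qi = int(qi)
        ids.append(gm.individuals[qi])
        g_row = gm.calls[qi]
        obs = g_row >= 0
        own = membership.get(qi)
        loo_flags.append(own is not None)
        if not obs.any():
            warnings.warn(f"query {gm.individuals[qi]} has no genotypes; uniform assignment")
            rows.append(np.full(len(base_names), 1.0 / len(base_names)))
            continue
        logp = np.zeros(len(base_names))
        for bi, name in enumerate(base_names):
            c1 = counts1[name].copy()
            ct = counts_tot[name].copy()
            if name == own:
                c1 = c1 - np.where(obs, g_row, 0)
                ct = ct - np.where(obs, 2.0, 0.0)
                c1 = np.maximum(c1, 0.0)
                ct = np.maximum(ct, 0.0)
            c0 = ct - c1
            g = g_row[obs].astype(int)
            c1o, c0o, cto = c1[obs], c0[obs], ct[obs]
            # sequential posterior-predictive draws of the two alleles
            p_hom1 = np.log(c1o + lam) + np.log(c1o + lam + 1) - np.log(cto + 2 * lam) - np.log(cto + 2 * lam + 1)
            p_hom0 = np.log(c0o + lam) + np.log(c0o + lam + 1) - np.log(cto + 2 * lam) - np.log(cto + 2 * lam + 1)
            p_het = (
                np.log(2.0)
                + np.log(c1o + lam)
                + np.log(c0o + lam)
                - np.log(cto + 2 * lam)
                - np.log(cto + 2 * lam + 1)
            )
            per_locus = np.where(g == 2, p_hom1, np.where(g == 0, p_hom0, p_het))
            logp[bi] = per_locus.sum()
        logp -= logp.max()
        p = np.exp(logp)
        rows.append(p / p.sum())

    probs = pd.DataFrame(rows, index=ids, columns=base_names)
    return AssignmentResult(
        probabilities=probs,
        top_group=probs.idxmax(axis=1),
        leave_one_out=pd.Series(loo_flags, index=ids, name="leave_one_out"),
    )
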