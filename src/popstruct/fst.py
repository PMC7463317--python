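"""Weir–Cockerham F-statistics, permutation tests and isolation by distance.

The differentiation estimator is Weir & Cockerham's theta, built from the
per-locus variance components a (among populations), b (among individuals
within populations) and c (within individuals), with the multilocus
estimate as the ratio of summed components. Negative per-locus estimates
are retained as computed — truncating them would bias downstream sums
and regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import asin, cos, radians, sin, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import holm_sequential_bonferroni
from .genotypes import GenotypeMatrix

__all__ = [
    "wc_components",
    "wc_theta",
    "fst_permutation_test",
    "pairwise_fst_matrix",
    "linearize_fst",
    "ibd_regression",
    "great_circle_km",
    "PairwiseFstResult",
    "IbdRegression",
]


@dataclass(frozen=True)
class PairwiseFstResult:
    pair: tuple[str, str]
    theta: float
    p_value: float
    significant_after_holm: bool = False


@dataclass(frozen=True)
class IbdRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    points: list[tuple[float, float]]


def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components.

    Parameters
    ----------
    n, p, h
        Arrays of shape ``(..., r, L)``: per-group sample sizes
        (genotyped individuals), second-allele frequencies and observed
        heterozygote proportions, with the group axis second-to-last.
        Groups with ``n = 0`` at a locus are excluded from that locus.

    Returns
    -------
    (a, b, c)
        Component arrays of shape ``(..., L)``; NaN where fewer than two
        groups carry data or the estimator is undefined.
    """
    n = np.asarray(n, dtype=float)
    p = np.where(n > 0, p, 0.0)
    h = np.where(n > 0, h, 0.0)
    r = np.sum(n > 0, axis=-2)                       # per-locus populated groups
    n_tot = np.sum(n, axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_tot / r
        nc = (n_tot - np.sum(n**2, axis=-2) / n_tot) / (r - 1)
        pbar = np.sum(n * p, axis=-2) / n_tot
        s2 = np.sum(n * (p - pbar[..., None, :]) ** 2, axis=-2) / ((r - 1) * nbar)
        hbar = np.sum(n * h, axis=-2) / n_tot
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _group_summaries(gm: GenotypeMatrix, groups: Sequence[np.ndarray]):
    """Stack per-group (n, p, h) arrays of shape (r, L)."""
    ns, ps, hs = [], [], []
    for idx in groups:
        calls = gm.calls[np.asarray(idx, dtype=int)]
        nonmiss = calls >= 0
        n = nonmiss.sum(axis=0).astype(float)
        dos = np.where(nonmiss, calls, 0).sum(axis=0).astype(float)
        het = np.where(nonmiss, calls == 1, False).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(n > 0, dos / (2 * n), 0.0))
            hs.append(np.where(n > 0, het / n, 0.0))
        ns.append(n)
    return np.stack(ns), np.stack(ps), np.stack(hs)


def wc_theta(
    gm: GenotypeMatrix,
    groups: Mapping[str, Sequence[int]] | None = None,
    return_components: bool = False,
):
    """Multilocus Weir–Cockerham theta over the given groups.

    ``groups`` maps group name -> individual indices (defaults to the
    matrix's collections). The multilocus estimate is
    ``sum(a) / sum(a + b + c)`` over loci with defined components; the
    per-locus components are returned on request.
    """
    if groups is None:
        groups = gm.groups()
    idx_list = [np.asarray(v, dtype=int) for v in groups.values()]
    if len(idx_list) < 2:
        raise ValueError("need at least two groups")
    n, p, h = _group_summaries(gm, idx_list)
    if not np.any(np.sum(n > 0, axis=0) >= 2):
        raise ValueError("no locus has data in at least two groups")
    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(a)
        den = np.nansum(denom)
    theta = float(num / den) if den != 0 else float("nan")
    if return_components:
        per_locus = pd.DataFrame(
            {"a": a, "b": b, "c": c, "theta": a / denom}, index=gm.locus_ids
        )
        return theta, per_locus
    return theta


def _theta_from_summaries(n, p, h) -> np.ndarray:
    """Multilocus theta for stacked summaries of shape (..., r, L)."""
    a, b, c = wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nansum(a, axis=-1) / np.nansum(a + b + c, axis=-1)


def fst_permutation_test(
    gm: GenotypeMatrix,
    group_a: Sequence[int],
    group_b: Sequence[int],
    n_perm: int = 10_000,
    seed: int | None = None,
    return_theta: bool = False,
):
    """Permutation significance for the two-group theta.

    Individuals are shuffled between the two groups preserving sizes;
    p = (1 + #{theta_perm >= theta_obs}) / (1 + n_perm). The null
    thetas are computed with the same estimator, vectorized over all
    permutations at once.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    pool = np.concatenate([group_a, group_b])
    calls = gm.calls[pool]
    nonmiss = (calls >= 0).astype(float)
    dos = np.where(calls >= 0, calls, 0).astype(float)
    het = (calls == 1).astype(float)
    n_a = group_a.size
    n_pool = pool.size

    def summaries(mask: np.ndarray):
        # mask: (P, n_pool) booleans selecting group A
        m = mask.astype(float)
        nA = m @ nonmiss
        nB = nonmiss.sum(axis=0) - nA
        dA = m @ dos
        dB = dos.sum(axis=0) - dA
        hA = m @ het
        hB = het.sum(axis=0) - hA
        n = np.stack([nA, nB], axis=-2)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.stack([dA / (2 * nA), dB / (2 * nB)], axis=-2)
            hh = np.stack([hA / nA, hB / nB], axis=-2)
        return n, np.nan_to_num(p), np.nan_to_num(hh)

    obs_mask = np.zeros((1, n_pool), dtype=bool)
    obs_mask[0, :n_a] = True
    theta_obs = float(_theta_from_summaries(*summaries(obs_mask))[0])

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n_pool), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n_pool)[:n_a]] = True
    theta_perm = _theta_from_summaries(*summaries(masks))
    count = int(np.sum(theta_perm >= theta_obs - 1e-12))
    p_value = (1 + count) / (1 + n_perm)
    if return_theta:
        return p_value, theta_obs
    return p_value


def pairwise_fst_matrix(
    gm: GenotypeMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[PairwiseFstResult]]:
    """All-pairs theta with permutation p-values and Holm flags.

    Returns a square DataFrame with theta in the lower triangle and
    permutation p in the upper triangle (the conventional heat-map
    layout), plus tidy per-pair results. Holm's correction is applied
    jointly across all pairs.
    """
    codes = gm.collection_order()
    if len(codes) < 2:
        raise ValueError("need at least two collections")
    rng = np.random.default_rng(seed)
    results: list[PairwiseFstResult] = []
    mat = pd.DataFrame(np.nan, index=codes, columns=codes)
    for a, b in combinations(codes, 2):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p, theta = fst_permutation_test(
            gm, gm.indices_of(a), gm.indices_of(b), n_perm=n_perm, seed=sub_seed,
            return_theta=True,
        )
        results.append(PairwiseFstResult((a, b), theta, p))
        mat.loc[b, a] = theta
        mat.loc[a, b] = p
    flags = holm_sequential_bonferroni([r.p_value for r in results], alpha=alpha)
    results = [
        PairwiseFstResult(r.pair, r.theta, r.p_value, bool(f))
        for r, f in zip(results, flags)
    ]
    return mat, results


def linearize_fst(theta: float | np.ndarray) -> float | np.ndarray:
    """Rousset's linearization theta / (1 - theta); undefined at 1."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta >= 1):
        raise ValueError("linearized FST is infinite at theta = 1")
    out = theta / (1.0 - theta)
    return float(out) if out.ndim == 0 else out


def ibd_regression(
    linearized: Sequence[float], distances_km: Sequence[float]
) -> IbdRegression:
    """OLS of linearized FST on geographic distance (isolation by distance)."""
    y = np.asarray(linearized, dtype=float)
    x = np.asarray(distances_km, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three matched points")
    if np.ptp(x) == 0:
        raise ValueError("distances have zero variance")
    res = stats.linregress(x, y)
    return IbdRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        points=list(zip(x.tolist(), y.tolist())),
    )


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km — a fallback when waterway distances are
    not supplied; real shortest-water paths should be preferred."""
    rlat1, rlon1, rlat2, rlon2 = map(radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = rlat2 - rlat1, rlon2 - rlon1
    h = sin(dlat / 2) ** 2 + cos(rlat1) * cos(rlat2) * sin(dlon / 2) ** 2
    return 2 * 6371.0 * asin(sqrt(h))
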