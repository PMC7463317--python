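"""Per-collection diversity statistics and multiple-testing correction.

Observed heterozygosity Ho, unbiased expected heterozygosity
uHe = [2n/(2n-1)] (1 - p^2 - q^2), and the inbreeding coefficient
FIS = (uHe - Ho)/uHe are computed per locus and summarized as mean ± SE
over loci (SE = sd over loci / sqrt(L)), the conventional per-sample
summary of SNP panel screens.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "inbreeding_coefficient",
    "diversity_table",
    "holm_sequential_bonferroni",
]


def _collection_calls(gm: GenotypeMatrix, collection: str) -> np.ndarray:
    return gm.calls[gm.indices_of(collection)]


def observed_heterozygosity(gm: GenotypeMatrix, collection: str) -> pd.Series:
    """Per-locus Ho = heterozygote count / non-missing count.

    Loci with no calls in the collection are NaN (excluded from means).
    """
    calls = _collection_calls(gm, collection)
    n = np.sum(calls >= 0, axis=0).astype(float)
    het = np.sum(calls == 1, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / n, np.nan)
    return pd.Series(ho, index=gm.locus_ids, name="Ho")


def unbiased_expected_heterozygosity(gm: GenotypeMatrix, collection: str) -> pd.Series:
    """Per-locus uHe with the 2n/(2n-1) small-sample correction.

    Requires at least two genotyped individuals at a locus; monomorphic
    loci give 0.
    """
    calls = _collection_calls(gm, collection)
    n = np.sum(calls >= 0, axis=0).astype(float)
    dosage = np.where(calls >= 0, calls, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage / (2.0 * n)
        uhe = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    uhe = np.where(n >= 2, uhe, np.nan)
    return pd.Series(uhe, index=gm.locus_ids, name="uHe")


def inbreeding_coefficient(gm: GenotypeMatrix, collection: str) -> pd.Series:
    """Per-locus FIS = (uHe - Ho) / uHe; NaN where uHe = 0 (monomorphic)."""
    ho = observed_heterozygosity(gm, collection)
    uhe = unbiased_expected_heterozygosity(gm, collection)
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = (uhe - ho) / uhe
    fis[uhe <= 0] = np.nan
    return fis.rename("Fis")


def _mean_se(x: pd.Series) -> tuple[float, float]:
    v = x.dropna().to_numpy()
    if v.size == 0:
        return float("nan"), float("nan")
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), se


def diversity_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-collection summary: n, Ho, uHe, FIS as mean ± SE over loci."""
    rows = []
    for code in gm.collection_order():
        ho = observed_heterozygosity(gm, code)
        uhe = unbiased_expected_heterozygosity(gm, code)
        fis = inbreeding_coefficient(gm, code)
        ho_m, ho_se = _mean_se(ho)
        uhe_m, uhe_se = _mean_se(uhe)
        fis_m, fis_se = _mean_se(fis)
        rows.append(
            {
                "collection": code,
                "n_individuals": int(len(gm.indices_of(code))),
                "Ho_mean": ho_m,
                "Ho_se": ho_se,
                "uHe_mean": uhe_m,
                "uHe_se": uhe_se,
                "Fis_mean": fis_m,
                "Fis_se": fis_se,
            }
        )
    return pd.DataFrame(rows).set_index("collection")


def holm_sequential_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) rejection flags.

    Sort p ascending and reject while p_(i) <= alpha / (m - i + 1);
    the first failure stops all later rejections. Flags are returned in
    the input order. Controls family-wise error at alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject
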