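"""Discriminant analysis of principal components (DAPC).

Allele dosages are centered (missing values imputed with the locus
mean), reduced by PCA, and the retained principal components are fed to
a linear discriminant analysis on predefined group labels. The output
reports per-axis percent of discriminant variance and maps discriminant
loadings back to loci, so the markers driving each axis can be ranked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genotypes import GenotypeMatrix

__all__ = ["DapcResult", "dapc"]


@dataclass
class DapcResult:
    coordinates: pd.DataFrame        # individuals x discriminant axes
    percent_variance: np.ndarray     # per discriminant axis
    loadings: pd.DataFrame           # loci x axes, squared-normalized contributions
    n_pcs_retained: int
    group_labels: list[str]

    def group_centroids(self) -> pd.DataFrame:
        g = pd.Series(self.group_labels, index=self.coordinates.index, name="group")
        return self.coordinates.groupby(g).mean()


def dapc(
    gm: GenotypeMatrix,
    group_labels: Sequence[str] | None = None,
    retained_pcs: int | float | None = None,
) -> DapcResult:
    """Run DAPC on a genotype matrix.

    ``retained_pcs`` may be an integer count, a variance target in
    (0, 1), or None for the default: the smallest count explaining >=90%
    of total variance, capped at n/3. If the within-group scatter is
    singular the PC count is reduced automatically.
    """
    labels = list(group_labels) if group_labels is not None else list(gm.collection_codes)
    if len(labels) != gm.n_individuals:
        raise ValueError("one group label per individual required")
    n_groups = len(set(labels))
    if n_groups < 2:
        raise ValueError("need at least two groups")

    d = gm.dosage()
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(d))
    d[inds] = col_mean[inds[1]]
    d -= d.mean(axis=0)

    n = d.shape[0]
    max_pcs = min(n - n_groups, d.shape[1], max(1, n - 1))
    pca = PCA(n_components=min(max_pcs, min(n - 1, d.shape[1])))
    scores = pca.fit_transform(d)
    evr = pca.explained_variance_ratio_

    if retained_pcs is None:
        target = 0.90
        n_pcs = int(np.searchsorted(np.cumsum(evr), target) + 1)
        n_pcs = min(n_pcs, max(1, n // 3), scores.shape[1])
    elif isinstance(retained_pcs, float) and 0 < retained_pcs < 1:
        n_pcs = int(np.searchsorted(np.cumsum(evr), retained_pcs) + 1)
        n_pcs = min(n_pcs, scores.shape[1])
    else:
        n_pcs = int(retained_pcs)
        if n_pcs >= n - n_groups + 1:
            raise ValueError("retained_pcs must be < n_individuals - n_groups")
    n_pcs = max(1, n_pcs)

    lda = None
    while n_pcs >= 1:
        try:
            lda = LinearDiscriminantAnalysis(solver="eigen")
            coords = lda.fit_transform(scores[:, :n_pcs], labels)
            break
        except np.linalg.LinAlgError:
            n_pcs -= 1  # singular within-group scatter: shrink the basis
    if lda is None:
        raise RuntimeError("LDA failed for every PC count")

    n_axes = coords.shape[1]
    ev = lda.explained_variance_ratio_[:n_axes]
    pct = 100.0 * ev / ev.sum() if ev.sum() > 0 else np.zeros(n_axes)

    # map discriminant vectors back through the PCA rotation to loci
    disc_in_locus_space = pca.components_[:n_pcs].T @ lda.scalings_[:, :n_axes]
    contrib = disc_in_locus_space**2
    contrib = contrib / contrib.sum(axis=0, keepdims=True)

    axes = [f"LD{i+1}" for i in range(n_axes)]
    return DapcResult(
        coordinates=pd.DataFrame(coords, index=gm.individuals, columns=axes),
        percent_variance=np.asarray(pct),
        loadings=pd.DataFrame(contrib, index=gm.locus_ids, columns=axes),
        n_pcs_retained=n_pcs,
        group_labels=labels,
    )
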