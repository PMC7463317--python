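"""Core data model for biallelic SNP genotype panels.

Genotypes are stored as an individuals x loci matrix of small integers:
0 = homozygote for the first allele, 1 = heterozygote, 2 = homozygote for
the second allele, and :data:`MISSING` (-1) for a failed or absent call.
Each individual belongs to exactly one sample collection (a site/time
sample), which is the unit of every per-population statistic downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "SnpLocus",
    "SampleCollection",
    "GenotypeMatrix",
    "CandidateLocus",
    "allele_frequencies",
    "missingness_summary",
    "filter_individuals_by_missingness",
    "select_assayable_snps",
]


@dataclass(frozen=True)
class SnpLocus:
    """A single biallelic SNP locus.

    Parameters
    ----------
    locus_id
        Short label, e.g. ``"Ssp210"``.
    alleles
        Ordered pair of allele symbols. The genotype codes 0/1/2 count
        copies of ``alleles[1]`` (the "second" allele).
    flank_length
        Length in bases of the sequenced read the SNP sits in (optional).
    snp_position
        1-based offset of the SNP within that read (optional).
    minor_allele_count_discovery
        Minor-allele count among the discovery-panel haplotypes (optional).
    monomorphic
        Set when only one allele was ever observed; such loci are retained
        in the matrix but each statistic decides its own handling.
    """

    locus_id: str
    alleles: tuple[str, str] = ("A", "B")
    flank_length: int | None = None
    snp_position: int | None = None
    minor_allele_count_discovery: int | None = None
    monomorphic: bool = False

    def __post_init__(self) -> None:
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"locus {self.locus_id}: alleles must be distinct")
        if self.snp_position is not None and self.flank_length is not None:
            if not (1 <= self.snp_position <= self.flank_length):
                raise ValueError(
                    f"locus {self.locus_id}: snp_position {self.snp_position} "
                    f"outside [1, {self.flank_length}]"
                )


@dataclass(frozen=True)
class SampleCollection:
    """Metadata for one sampling site/time (a 'collection')."""

    code: str
    region: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    year: int | None = None
    month: int | None = None
    site: str | None = None
    ripe: bool = False

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"{self.code}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"{self.code}: longitude {self.longitude} out of range")


@dataclass
class GenotypeMatrix:
    """Individuals x loci biallelic genotype matrix with sample membership.

    ``calls`` is an ``(n_individuals, n_loci)`` int8 array in
    {0, 1, 2, MISSING}. ``collection_codes[i]`` names the collection of
    individual ``i``; optional :class:`SampleCollection` metadata lives in
    ``collections``.
    """

    individuals: list[str]
    collection_codes: list[str]
    loci: list[SnpLocus]
    calls: np.ndarray
    collections: dict[str, SampleCollection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = self.calls.shape if self.calls.ndim == 2 else (0, 0)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-dimensional")
        if len(self.individuals) != n:
            raise ValueError("individuals length does not match calls rows")
        if len(self.collection_codes) != n:
            raise ValueError("collection_codes length does not match calls rows")
        if len(self.loci) != L:
            raise ValueError("loci length does not match calls columns")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def collection_order(self) -> list[str]:
        """Unique collection codes in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.collection_codes:
            seen.setdefault(c)
        return list(seen)

    def indices_of(self, code: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.collection_codes) == code)
        if idx.size == 0:
            raise KeyError(f"no individuals in collection {code!r}")
        return idx

    def groups(self) -> dict[str, np.ndarray]:
        """Mapping collection code -> individual indices (first-appearance order)."""
        return {c: self.indices_of(c) for c in self.collection_order()}

    # -- views ----------------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Float copy of calls with missing as NaN (count of second allele)."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            collection_codes=[self.collection_codes[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index].copy(),
            collections=dict(self.collections),
        )

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            collection_codes=list(self.collection_codes),
            loci=[self.loci[j] for j in index],
            calls=self.calls[:, index].copy(),
            collections=dict(self.collections),
        )

    def drop_loci(self, locus_ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(locus_ids)
        keep = [j for j, loc in enumerate(self.loci) if loc.locus_id not in drop]
        return self.subset_loci(keep)

    def concat_individuals(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.locus_ids != other.locus_ids:
            raise ValueError("cannot concatenate matrices with different loci")
        return GenotypeMatrix(
            individuals=self.individuals + other.individuals,
            collection_codes=self.collection_codes + other.collection_codes,
            loci=list(self.loci),
            calls=np.vstack([self.calls, other.calls]),
            collections={**self.collections, **other.collections},
        )

    def relabel_collections(self, mapping: Mapping[str, str]) -> "GenotypeMatrix":
        codes = [mapping.get(c, c) for c in self.collection_codes]
        return replace(self, collection_codes=codes)


# ---------------------------------------------------------------------------
# summaries and filters
# ---------------------------------------------------------------------------

def allele_frequencies(
    gm: GenotypeMatrix,
    grouping: Mapping[str, Sequence[int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group second-allele frequencies and non-missing gene-copy counts.

    Parameters
    ----------
    gm
        Genotype matrix.
    grouping
        Mapping group name -> individual indices. Defaults to the
        matrix's collections. Groups may cover a subset of individuals
        but must be non-empty.

    Returns
    -------
    (freq, n)
        Two DataFrames indexed by group with one column per locus:
        frequency of the second allele (NaN where a group has no calls at
        a locus — undefined, deliberately not 0) and the count of
        non-missing gene copies (2 x genotyped individuals).
    """
    if grouping is None:
        grouping = gm.groups()
    rows_f, rows_n = [], []
    for name, idx in grouping.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"group {name!r} is empty")
        d = gm.dosage()[idx]
        n_copies = 2.0 * np.sum(~np.isnan(d), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nansum(d, axis=0) / n_copies
        freq[n_copies == 0] = np.nan
        rows_f.append(freq)
        rows_n.append(n_copies)
    cols = gm.locus_ids
    names = list(grouping)
    return (
        pd.DataFrame(rows_f, index=names, columns=cols),
        pd.DataFrame(rows_n, index=names, columns=cols),
    )


def missingness_summary(gm: GenotypeMatrix) -> dict:
    """Per-individual and per-locus missing fractions.

    Also reports the share of individuals with <10% missing calls, a
    standard panel-quality headline figure.
    """
    miss = gm.missing_mask()
    per_ind = miss.mean(axis=1) if gm.n_loci else np.zeros(gm.n_individuals)
    per_locus = miss.mean(axis=0) if gm.n_individuals else np.zeros(gm.n_loci)
    return {
        "per_individual": pd.Series(per_ind, index=gm.individuals, name="missing_fraction"),
        "per_locus": pd.Series(per_locus, index=gm.locus_ids, name="missing_fraction"),
        "share_below_10pct": float(np.mean(per_ind < 0.10)) if gm.n_individuals else float("nan"),
    }


def filter_individuals_by_missingness(
    gm: GenotypeMatrix, max_missing_fraction: float = 0.30
) -> GenotypeMatrix:
    """Drop individuals whose missing-call fraction exceeds the threshold.

    Removal is strict (> threshold); an individual at exactly the
    threshold is retained. Idempotent and order-preserving.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = gm.missing_mask().mean(axis=1)
    keep = np.flatnonzero(frac <= max_missing_fraction)
    return gm.subset_individuals(keep)


# ---------------------------------------------------------------------------
# assay-panel design filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateLocus:
    """A candidate RAD locus considered for SNP-assay design.

    ``discovery_genotypes`` are 0/1/2/MISSING calls for the discovery
    panel individuals; ``n_snps_in_read`` counts diallelic SNPs observed
    in the read.
    """

    locus: SnpLocus
    n_snps_in_read: int
    discovery_genotypes: tuple[int, ...] | None = None


def select_assayable_snps(
    candidates: Sequence[CandidateLocus],
    min_minor_allele_count: int = 2,
    position_range: tuple[int, int] = (41, 95),
) -> list[SnpLocus]:
    """Filter candidate RAD loci down to assayable single-SNP markers.

    Keeps loci that (a) carry exactly one diallelic SNP, (b) show the
    minor allele at least ``min_minor_allele_count`` times among the
    discovery haplotypes, and (c) have the SNP positioned inside
    ``position_range`` (inclusive at both ends), leaving flanking sequence
    for primer design. Candidates without discovery genotypes are skipped
    with a warning.
    """
    lo, hi = position_range
    kept: list[SnpLocus] = []
    for cand in candidates:
        if cand.discovery_genotypes is None:
            warnings.warn(
                f"candidate {cand.locus.locus_id} lacks discovery genotypes; skipped"
            )
            continue
        if cand.n_snps_in_read != 1:
            continue
        pos = cand.locus.snp_position
        if pos is None or not lo <= pos <= hi:
            continue
        g = np.asarray(cand.discovery_genotypes)
        g = g[g != MISSING]
        second = int(g.sum())
        total = 2 * g.size
        if min(second, total - second) < min_minor_allele_count:
            continue
        kept.append(cand.locus)
    return kept
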