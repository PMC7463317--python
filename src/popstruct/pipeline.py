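"""End-to-end orchestration of the population-structure workflow.

Stages (each can be toggled off): missingness filtering, per-collection
diversity + HWE, the pairwise FST matrix, the two-method outlier
consensus, admixture clustering over a K grid with K selection, DAPC,
the hybrid-zone diagnostic, individual assignment, and isolation by
distance. Every stochastic stage is seeded from the master seed, and a
JSON manifest records parameters, seeds and per-stage wall time so any
run can be reproduced exactly.

Two chain-length profiles are provided: ``paper`` carries the long
production settings (1e5 burn-in + 1e6 sweeps x 10 replicates for the
clustering; 1e5 envelope iterations; 1e4 permutations) and ``test``
scales them down ~100x for desk-scale runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture, diversity, fst, hwe_ld, hybrids, outliers
from .dapc import dapc as _run_dapc
from .genotypes import GenotypeMatrix, filter_individuals_by_missingness, missingness_summary
from .io import read_genepop, read_table, write_table
from .simulate import generate_dataset, sprat_like_config

__all__ = ["PipelineConfig", "PROFILES", "run_pipeline"]

PROFILES: dict[str, dict] = {
    "paper": {
        "structure_burn_in": 100_000,
        "structure_length": 1_000_000,
        "structure_replicates": 10,
        "fdist_iterations": 100_000,
        "fst_permutations": 10_000,
        "ld_permutations": 10_000,
        "bayes_sweeps": 5_000,
        "bayes_burn_sweeps": 1_000,
    },
    "test": {
        "structure_burn_in": 300,
        "structure_length": 900,
        "structure_replicates": 3,
        "fdist_iterations": 10_000,
        "fst_permutations": 500,
        "ld_permutations": 200,
        "bayes_sweeps": 800,
        "bayes_burn_sweeps": 200,
    },
}


@dataclass
class PipelineConfig:
    genotypes_path: str | None = None       # genepop (.gen) or table (.tsv)
    synthetic_scale: float | None = 0.15    # used when no genotype file given
    distance_matrix_path: str | None = None
    out_dir: str = "popstruct_out"
    profile: str = "test"
    seed: int = 0
    k_range: tuple[int, int] = (1, 5)
    max_missing_fraction: float = 0.30
    stages: tuple[str, ...] = (
        "filter",
        "diversity",
        "fst",
        "outliers",
        "structure",
        "dapc",
        "ibd",
    )
    regions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


def _load_genotypes(cfg: PipelineConfig, rng: np.random.Generator):
    if cfg.genotypes_path:
        path = Path(cfg.genotypes_path)
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix in (".gen", ".genepop"):
            return read_genepop(path), None
        return read_table(path), None
    sim_cfg = sprat_like_config(seed=int(rng.integers(0, 2**31 - 1)),
                                scale=cfg.synthetic_scale or 0.15)
    gm, truth = generate_dataset(sim_cfg)
    return gm, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = PROFILES[cfg.profile]
    master = np.random.default_rng(cfg.seed)
    manifest: dict = {
        "profile": cfg.profile,
        "seed": cfg.seed,
        "stages": {},
    }

    gm, truth = _load_genotypes(cfg, master)
    write_table(gm, out / "genotypes_input.tsv")

    def stage(name: str):
        return name in cfg.stages

    results: dict = {"genotypes": gm, "truth": truth}

    if stage("filter"):
        t0 = time.perf_counter()
        before = gm.n_individuals
        gm = filter_individuals_by_missingness(gm, cfg.max_missing_fraction)
        summ = missingness_summary(gm)
        manifest["stages"]["filter"] = {
            "n_before": before,
            "n_after": gm.n_individuals,
            "share_below_10pct_missing": summ["share_below_10pct"],
            "seconds": time.perf_counter() - t0,
        }
        results["genotypes"] = gm

    if stage("diversity"):
        t0 = time.perf_counter()
        div = diversity.diversity_table(gm)
        hwe_rows = []
        for code in gm.collection_order():
            for lid, res in hwe_ld.hwe_test_collection(gm, code):
                hwe_rows.append(
                    {"collection": code, "locus": lid, "p": res.p_value,
                     "direction": res.direction, "testable": res.testable}
                )
        hwe_df = pd.DataFrame(hwe_rows)
        testable = hwe_df[hwe_df.testable]
        n_dev = int((testable.p < 0.05).sum())
        holm = diversity.holm_sequential_bonferroni(testable.p.to_numpy())
        div.to_csv(out / "diversity_table.tsv", sep="\t")
        hwe_df.to_csv(out / "hwe_tests.tsv", sep="\t", index=False)
        manifest["stages"]["diversity"] = {
            "n_hwe_tests": int(len(testable)),
            "n_hwe_deviations_0.05": n_dev,
            "n_hwe_deviations_holm": int(holm.sum()),
            "seconds": time.perf_counter() - t0,
        }
        results["diversity"] = div
        results["hwe"] = hwe_df

    if stage("fst"):
        t0 = time.perf_counter()
        seed = int(master.integers(0, 2**31 - 1))
        mat, pairs = fst.pairwise_fst_matrix(gm, n_perm=prof["fst_permutations"], seed=seed)
        mat.to_csv(out / "pairwise_fst_matrix.tsv", sep="\t")
        tidy = pd.DataFrame(
            [{"a": p.pair[0], "b": p.pair[1], "theta": p.theta, "p": p.p_value,
              "holm_significant": p.significant_after_holm} for p in pairs]
        )
        tidy.to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
        thetas = tidy.theta.to_numpy()
        manifest["stages"]["fst"] = {
            "seed": seed,
            "theta_min": float(np.nanmin(thetas)),
            "theta_max": float(np.nanmax(thetas)),
            "n_holm_significant": int(tidy.holm_significant.sum()),
            "seconds": time.perf_counter() - t0,
        }
        results["fst_matrix"] = mat
        results["fst_pairs"] = pairs

    if stage("outliers"):
        t0 = time.perf_counter()
        seed_fd = int(master.integers(0, 2**31 - 1))
        seed_bs = int(master.integers(0, 2**31 - 1))
        fd = outliers.fdist_scan(gm, n_iterations=prof["fdist_iterations"], seed=seed_fd)
        bs = outliers.bayes_fmodel_scan(
            gm,
            n_sweeps=prof["bayes_sweeps"],
            n_burn_sweeps=prof["bayes_burn_sweeps"],
            seed=seed_bs,
        )
        cons = outliers.consensus_outliers(fd.flagged_directional, bs.flagged,
                                           scope="all-collections")
        fd.table.to_csv(out / "fdist_scan.tsv", sep="\t")
        bs.table.to_csv(out / "bayes_fmodel_scan.tsv", sep="\t")
        (out / "consensus_outliers.txt").write_text(
            "\n".join(sorted(cons.consensus)) + "\n"
        )
        manifest["stages"]["outliers"] = {
            "seed_fdist": seed_fd,
            "seed_bayes": seed_bs,
            "n_fdist_directional": len(fd.flagged_directional),
            "n_bayes_flagged": len(bs.flagged),
            "n_consensus": len(cons.consensus),
            "seconds": time.perf_counter() - t0,
        }
        results["outliers"] = cons

    if stage("structure"):
        t0 = time.perf_counter()
        k_lo, k_hi = cfg.k_range
        runs_by_k = {}
        for K in range(k_lo, k_hi + 1):
            seed = int(master.integers(0, 2**31 - 1))
            runs_by_k[K] = admixture.run_admixture_mcmc(
                gm, K,
                burn_in=prof["structure_burn_in"],
                length=prof["structure_length"],
                replicates=prof["structure_replicates"],
                seed=seed,
            )
        report = admixture.select_k(runs_by_k, gm.collection_codes)
        report.table.to_csv(out / "k_selection.tsv", sep="\t")
        best_k = report.best_k.get("MedMean") or k_lo
        consensus, _ = admixture.align_runs(runs_by_k[best_k])
        qdf = pd.DataFrame(
            consensus,
            index=gm.individuals,
            columns=[f"q{k+1}" for k in range(best_k)],
        )
        qdf.insert(0, "collection", gm.collection_codes)
        qdf.to_csv(out / f"consensus_Q_K{best_k}.tsv", sep="\t")
        manifest["stages"]["structure"] = {
            "k_range": [k_lo, k_hi],
            "best_k_evanno": report.best_k_evanno,
            "best_k": report.best_k,
            "seconds": time.perf_counter() - t0,
        }
        results["k_selection"] = report
        results["runs_by_k"] = runs_by_k
        results["consensus_Q"] = consensus

    if stage("dapc"):
        t0 = time.perf_counter()
        res = _run_dapc(gm)
        res.coordinates.to_csv(out / "dapc_coordinates.tsv", sep="\t")
        res.loadings.to_csv(out / "dapc_loadings.tsv", sep="\t")
        manifest["stages"]["dapc"] = {
            "n_pcs": res.n_pcs_retained,
            "percent_variance": [float(x) for x in res.percent_variance[:3]],
            "seconds": time.perf_counter() - t0,
        }
        results["dapc"] = res

    if stage("ibd") and "fst_pairs" in results:
        t0 = time.perf_counter()
        codes = gm.collection_order()
        ref = codes[0]
        dist = None
        if cfg.distance_matrix_path:
            dist = pd.read_csv(cfg.distance_matrix_path, sep="\t", index_col=0)
        elif all(
            gm.collections.get(c) and gm.collections[c].latitude is not None
            for c in codes
        ):
            ref_c = gm.collections[ref]
            dist = pd.DataFrame(
                {
                    ref: [
                        fst.great_circle_km(
                            ref_c.latitude, ref_c.longitude,
                            gm.collections[c].latitude, gm.collections[c].longitude,
                        )
                        for c in codes
                    ]
                },
                index=codes,
            ).T
        if dist is not None:
            theta_by_pair = {frozenset(p.pair): p.theta for p in results["fst_pairs"]}
            xs, ys = [], []
            for c in codes:
                if c == ref or c not in dist.columns:
                    continue
                th = theta_by_pair.get(frozenset((ref, c)))
                if th is None or th >= 1:
                    continue
                xs.append(float(dist.loc[ref, c]))
                ys.append(fst.linearize_fst(th))
            if len(xs) >= 3 and np.ptp(xs) > 0:
                reg = fst.ibd_regression(ys, xs)
                manifest["stages"]["ibd"] = {
                    "reference": ref,
                    "slope": reg.slope,
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "seconds": time.perf_counter() - t0,
                }
                results["ibd"] = reg

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
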