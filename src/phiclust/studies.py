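"""Headline simulation studies.

Each function here reruns one of the package's standard validation
experiments end to end — generate data, run the full pipeline, reduce
to a single number.  They are used by the test suite and by
``scripts/acceptance.py``; sizes are chosen so each study runs in
seconds to a few minutes on one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import phiclust_from_matrix
from .preprocess import preprocess_counts
from .rmt import mp_model, scaled_svd
from .simulate import (
    GroupSimSpec,
    PlantedSpec,
    differentiation_path,
    planted_rank_one,
    splatter_lite,
)
from .truth import kmeans_baseline, pc_coords

__all__ = [
    "planted_outlier_counts",
    "pure_noise_phiclust",
    "merge_sensitivity",
    "path_regression",
    "noise_split_phiclust",
]


def _seeds(seed: int, n: int, stride: int = 7919) -> list[int]:
    return [(seed * 104729 + i * stride) % (2**31 - 1) for i in range(n)]


def planted_outlier_counts(n_seeds: int = 25, seed: int = 0, theta: float = 5.0) -> list[int]:
    """Number of TW-exceeding singular values in the planted rank-1
    recipe (350 genes x 201 cells, two-block vectors), per seed.

    With a detectable planted signal the modal count is 1: the planted
    component and nothing else.
    """
    counts = []
    for s in _seeds(seed, n_seeds):
        ds = planted_rank_one(PlantedSpec(theta=theta, seed=s))
        svd = scaled_svd(ds.matrix)
        mp = mp_model(svd.n_genes, svd.n_cells, alpha_tw=0.01)
        counts.append(int(np.sum(svd.eigenvalues > mp.tw_lambda_star)))
    return counts


def pure_noise_phiclust(
    n_seeds: int = 50,
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 500,
) -> list[float]:
    """phiclust of a single gamma-Poisson cluster with no DE structure,
    full pipeline, one value per seed (expected: all 0)."""
    out = []
    for s in _seeds(seed, n_seeds):
        ds = splatter_lite(
            GroupSimSpec(n_genes=n_genes, n_cells=n_cells, n_groups=1, de_prob=0.0, seed=s)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = phiclust_from_matrix(preprocess_counts(ds.counts), config=RunConfig(seed=s))
        out.append(r.phiclust)
    return out


def merge_sensitivity(
    de_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10),
    n_seeds: int = 10,
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 600,
    threshold: float = 0.9,
) -> tuple[float, pd.DataFrame]:
    """Sensitivity of phiclust to a merged cluster.

    Three groups are simulated; two are merged into one cluster and the
    merged cluster's phiclust is averaged over seeds per DE-gene
    fraction.  Returns the smallest fraction whose mean reaches the
    threshold, plus the per-point table.
    """
    rows = []
    for p in de_grid:
        vals = []
        for s in _seeds(seed + int(p * 100_000), n_seeds):
            ds = splatter_lite(
                GroupSimSpec(n_genes=n_genes, n_cells=n_cells, n_groups=3, de_prob=p, seed=s)
            )
            lab = ds.labels
            merged = lab.index[(lab == "group0") | (lab == "group1")].tolist()
            sub = ds.counts.subset_cells(merged)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = phiclust_from_matrix(preprocess_counts(sub), config=RunConfig(seed=s))
            vals.append(r.phiclust)
        rows.append({"de_prob": p, "mean_phiclust": float(np.mean(vals))})
    table = pd.DataFrame(rows)
    hit = table.loc[table["mean_phiclust"] >= threshold, "de_prob"]
    return (float(hit.min()) if not hit.empty else float("nan")), table


def path_regression(
    n_seeds: int = 20,
    seed: int = 0,
    gradient_strength: float = 5.0,
    n_genes: int = 1000,
    n_cells: int = 300,
) -> tuple[list[float], list[float]]:
    """Differentiation path with and without the true pseudotime as a
    confounder covariate.

    Returns (uncorrected, corrected) phiclust lists; a strong gradient
    gives uncorrected values near 1, and regressing out the latent
    ordering should drive the corrected values to 0.
    """
    uncorr, corr = [], []
    for s in _seeds(seed, n_seeds):
        ds = differentiation_path(
            n_genes=n_genes, n_cells=n_cells, gradient_strength=gradient_strength, seed=s
        )
        cov = pd.DataFrame({"pseudotime": ds.pseudotime.values}, index=ds.pseudotime.index)
        uncorr.append(phiclust_from_matrix(ds.matrix, config=RunConfig(seed=s)).phiclust)
        corr.append(
            phiclust_from_matrix(ds.matrix, covariates=cov, config=RunConfig(seed=s)).phiclust
        )
    return uncorr, corr


def noise_split_phiclust(
    n_seeds: int = 20,
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 600,
) -> list[float]:
    """Over-clustering guard: split a pure-noise cluster in two with
    seeded k-means (k = 2) on the leading principal coordinates and run
    the full pipeline on each half.  Returns both halves' phiclust per
    seed (expected: all 0)."""
    out = []
    for s in _seeds(seed, n_seeds):
        ds = splatter_lite(
            GroupSimSpec(n_genes=n_genes, n_cells=n_cells, n_groups=1, de_prob=0.0, seed=s)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x = preprocess_counts(ds.counts)
            svd = scaled_svd(x)
            km = kmeans_baseline(pc_coords(svd, 10), k=2, seed=s)
            for half in (0, 1):
                cells = [c for c, k in zip(x.cell_ids, km) if k == half]
                sub = ds.counts.subset_cells(cells)
                r = phiclust_from_matrix(preprocess_counts(sub), config=RunConfig(seed=s))
                out.append(r.phiclust)
    return out
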