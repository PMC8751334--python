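"""Ground-truth validation metrics: tARI, tSIL and baselines.

With known ground-truth labels, the best any clustering algorithm can
do is limited by the overlap of the label-conditional distributions of
the informative singular-vector coordinates — the Bayes error.  An
approximate Bayes classifier (one Gaussian per ground-truth cluster on
the outlying singular-vector coordinates, cells assigned to the highest
density) turns that ceiling into an adjusted Rand index, the
theoretically achievable ARI (tARI).  tSIL is the silhouette of the
same classification on the first singular vector.  These are the
quantities the clusterability measure is validated against: no
empirical clustering should beat tARI, and phiclust should track it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .config import RunConfig
from .core import phiclust_from_matrix
from .preprocess import preprocess_counts
from .rmt import MPModel, ScaledSVD, mp_model, scaled_svd

__all__ = [
    "TruthResult",
    "bayes_classify",
    "ari",
    "tsil",
    "kmeans_baseline",
    "evaluate_dataset",
    "validation_grid",
]


@dataclass
class TruthResult:
    tari: float
    tsil: float
    ari_kmeans: float
    n_components_used: int
    phiclust: float = float("nan")


def bayes_classify(svd: ScaledSVD, mp: MPModel, labels: np.ndarray) -> np.ndarray:
    """Approximate Bayes classification on the outlying coordinates.

    Uses only singular vectors whose eigenvalue exceeds the MP upper
    edge.  Per ground-truth cluster a full-covariance Gaussian is
    fitted by maximum likelihood (diagonal fallback when the cluster
    has fewer cells than coordinates + 1); each cell goes to the
    cluster with the highest fitted density, ties toward the larger
    cluster.  With no outlying vectors the classifier is undefined and
    every cell lands in one cluster.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two ground-truth clusters")
    lam = svd.eigenvalues
    use = np.flatnonzero(lam > mp.a)
    if use.size == 0:
        return np.full(labels.shape, uniq[0], dtype=labels.dtype)
    coords = svd.V[:, use]
    # larger clusters first so argmax tie-breaking favors them
    order = np.argsort(-counts)
    uniq = uniq[order]
    dens = np.empty((labels.size, uniq.size))
    for j, k in enumerate(uniq):
        pts = coords[labels == k]
        mu = pts.mean(axis=0)
        if pts.shape[0] < coords.shape[1] + 1:
            warnings.warn(f"cluster {k!r} too small for full covariance; using diagonal")
            cov = np.diag(pts.var(axis=0) + 1e-12)
        else:
            cov = np.cov(pts, rowvar=False, bias=True) + 1e-12 * np.eye(coords.shape[1])
            cov = np.atleast_2d(cov)
        dens[:, j] = multivariate_normal(mean=mu, cov=cov, allow_singular=True).logpdf(coords)
    return uniq[np.argmax(dens, axis=1)]


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (permutation-invariant)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def tsil(first_vector_coords: np.ndarray, predicted) -> float:
    """Mean silhouette of a classification on 1-D coordinates
    (Euclidean).  Undefined for a single predicted cluster; returns NaN
    with a warning then."""
    predicted = np.asarray(predicted)
    if np.unique(predicted).size < 2:
        warnings.warn("silhouette undefined for a single predicted cluster")
        return float("nan")
    x = np.asarray(first_vector_coords, float).reshape(-1, 1)
    return float(silhouette_score(x, predicted, metric="euclidean"))


def kmeans_baseline(coords: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """Seeded k-means (k-means++ init, 10 restarts) on the given
    coordinates, the conventional empirical baseline."""
    coords = np.atleast_2d(np.asarray(coords, float))
    if coords.shape[0] < coords.shape[1]:
        coords = coords.T
    if k > coords.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    return km.fit_predict(coords)


def pc_coords(svd: ScaledSVD, n_pcs: int = 10) -> np.ndarray:
    """Cells x n_pcs principal-component coordinates (V scaled by the
    singular values)."""
    n = min(n_pcs, svd.gamma.size)
    return svd.V[:, :n] * svd.gamma[:n]


def evaluate_dataset(
    dataset,
    config: RunConfig | None = None,
    n_pcs_kmeans: int = 10,
) -> TruthResult:
    """phiclust, tARI, tSIL and the k-means ARI for one simulated
    dataset with ground-truth labels.

    Counts are preprocessed as a single cluster (the point is whether
    the substructure inside is detectable); already-real matrices are
    used as-is.
    """
    config = config or RunConfig()
    if dataset.counts is not None:
        x = preprocess_counts(dataset.counts).values
    else:
        x = dataset.matrix
    labels = np.asarray(dataset.labels)
    svd = scaled_svd(x)
    mp = mp_model(svd.n_genes, svd.n_cells, config.alpha_tw)
    pred = bayes_classify(svd, mp, labels)
    tari = ari(labels, pred)
    sil = tsil(svd.V[:, 0], pred)
    k = np.unique(labels).size
    km = kmeans_baseline(pc_coords(svd, n_pcs_kmeans), k=k, seed=config.seed)
    res = phiclust_from_matrix(x, config=config)
    n_used = int(np.sum(svd.eigenvalues > mp.tw_lambda_star))
    return TruthResult(
        tari=tari,
        tsil=sil,
        ari_kmeans=ari(labels, km),
        n_components_used=n_used,
        phiclust=res.phiclust,
    )


def validation_grid(
    de_probs: tuple[float, ...] = (0.005, 0.0075, 0.01, 0.015, 0.02, 0.03, 0.05, 0.08),
    n_seeds: int = 10,
    n_genes: int = 1500,
    n_cells: int = 400,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Two-group simulation grid relating phiclust to tARI.

    Sweeps the DE-gene fraction (the signal-to-noise dial) and records
    phiclust, tARI, tSIL and the k-means ARI per run.  Returns the raw
    per-run table; aggregate with a groupby on ``de_prob``.
    """
    from .simulate import GroupSimSpec, splatter_lite

    config = config or RunConfig()
    rows = []
    for p in de_probs:
        for s in range(n_seeds):
            spec = GroupSimSpec(
                n_genes=n_genes, n_cells=n_cells, n_groups=2, de_prob=p,
                seed=seed * 100_003 + s * 1009 + int(p * 10_000),
            )
            ds = splatter_lite(spec)
            r = evaluate_dataset(ds, config=config)
            rows.append(
                {
                    "de_prob": p,
                    "seed": s,
                    "phiclust": r.phiclust,
                    "tari": r.tari,
                    "tsil": r.tsil,
                    "ari_kmeans": r.ari_kmeans,
                    "n_components": r.n_components_used,
                }
            )
    return pd.DataFrame(rows)


def phiclust_tari_correlation(grid: pd.DataFrame) -> float:
    """Pearson correlation between mean phiclust and mean tARI across
    the grid points."""
    m = grid.groupby("de_prob")[["phiclust", "tari"]].mean()
    return float(pearsonr(m["phiclust"], m["tari"])[0])
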