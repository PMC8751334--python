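"""Synthetic data generators.

Everything the pipeline is validated on is generated here: planted
rank-1 signal matrices (noise plus a known low-rank perturbation, where
the recovered theta and phi can be checked against truth), a
gamma-Poisson multi-group count simulator in the style of Splatter
(group-structured overdispersed counts; no attempt at BCV trends or
dropout logistic), weighted-mixture cluster pairs built from two source
clusters, differentiation paths (a smooth expression gradient along a
latent ordering), and a multiplicative-noise variant.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import substream
from .io import CountMatrix
from .preprocess import ProcessedMatrix
from .rmt import mp_model, scaled_svd

__all__ = [
    "PlantedSpec",
    "GroupSimSpec",
    "SimulatedDataset",
    "planted_rank_one",
    "planted_rank_one_additive_to_real",
    "splatter_lite",
    "weighted_mixture",
    "differentiation_path",
    "multiplicative_planted",
]

# Where the mixture "clean-up" puts spectra: removed outliers land on
# the bulk upper edge; the transcriptome mode is restored at this
# multiple of the edge so it again dominates the spectrum.
TRANSCRIPTOME_RESTORE_FACTOR = 1.5


@dataclass
class PlantedSpec:
    """Planted rank-1 geometry: a two-block cell vector (pos_cells
    entries +1/sqrt(n_cells), rest negative) and a two-block gene
    vector, scaled by the signal singular value theta."""

    n_genes: int = 350
    n_cells: int = 201
    theta: float = 5.0
    noise: str = "normal"  # or "poisson"
    pos_cells: int = 67
    pos_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pos_cells < self.n_cells):
            raise ValueError("pos_cells must lie strictly inside (0, n_cells)")
        if not (0 < self.pos_genes < self.n_genes):
            raise ValueError("pos_genes must lie strictly inside (0, n_genes)")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.noise not in ("normal", "poisson"):
            raise ValueError(f"unknown noise {self.noise!r}")


@dataclass
class GroupSimSpec:
    """Gamma-Poisson multi-group count simulation.

    Gene base means are Gamma(mean_shape, rate=mean_rate); per group a
    gene is differentially expressed with probability ``de_prob`` and
    its mean is multiplied by exp(N(de_loc, de_scale)), inverted with
    probability 1/2; per-cell library sizes are
    LogNormal(lib_loc, lib_scale); counts are Poisson(lib * group
    expression fraction).
    """

    n_genes: int = 2000
    n_cells: int = 500
    n_groups: int = 2
    group_proportions: tuple[float, ...] | None = None
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    de_prob: float = 0.1
    de_loc: float = 0.1
    de_scale: float = 0.4
    lib_loc: float = 9.5
    lib_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_proportions is None:
            self.group_proportions = tuple([1.0 / self.n_groups] * self.n_groups)
        if len(self.group_proportions) != self.n_groups:
            raise ValueError("one proportion per group required")
        if abs(sum(self.group_proportions) - 1.0) > 1e-8:
            raise ValueError("group proportions must sum to 1")
        if not (0.0 <= self.de_prob <= 1.0):
            raise ValueError("de_prob must lie in [0, 1]")


@dataclass
class SimulatedDataset:
    """A generated dataset plus its ground truth."""

    matrix: np.ndarray | None = None
    counts: CountMatrix | None = None
    labels: pd.Series | None = None
    true_theta: float | None = None
    true_cell_vector: np.ndarray | None = None
    true_gene_vector: np.ndarray | None = None
    pseudotime: pd.Series | None = None
    provenance: dict = field(default_factory=dict)


def _block_vector(n: int, n_pos: int) -> np.ndarray:
    v = np.full(n, -1.0 / np.sqrt(n))
    v[:n_pos] = 1.0 / np.sqrt(n)
    return v


def planted_rank_one(spec: PlantedSpec) -> SimulatedDataset:
    """Noise plus a planted rank-1 signal of scaled singular value theta.

    The output is ``X + sqrt(n_genes) * theta * u v^T`` with X i.i.d.
    mean 0 / variance 1 (standard normal, or Poisson(1) centered and
    scaled), so the signal alone has scaled singular value exactly
    theta and the noise bulk follows the MP law.
    """
    rng = substream(spec.seed, "simulation/planted")
    G, N = spec.n_genes, spec.n_cells
    if spec.noise == "normal":
        X = rng.standard_normal((G, N))
    else:
        X = (rng.poisson(1.0, size=(G, N)) - 1.0) / 1.0  # mean 1, variance 1
    v = _block_vector(N, spec.pos_cells)
    u = _block_vector(G, spec.pos_genes)
    mat = X + np.sqrt(G) * spec.theta * np.outer(u, v)
    labels = pd.Series(
        np.where(v > 0, "pos", "neg"),
        index=[f"cell{i}" for i in range(N)],
        name="cluster",
    )
    return SimulatedDataset(
        matrix=mat,
        labels=labels,
        true_theta=spec.theta,
        true_cell_vector=v,
        true_gene_vector=u,
        provenance={"generator": "planted_rank_one", "noise": spec.noise, "seed": spec.seed},
    )


def planted_rank_one_additive_to_real(
    matrix: ProcessedMatrix | np.ndarray,
    theta: float,
    seed: int = 0,
    pos_cells: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Add a rank-1 signal to an existing preprocessed matrix.

    The cell vector is the two-block pattern; the gene vector is drawn
    from a normal distribution and normalized to unit length.  Returns
    (perturbed matrix, gene vector, cell vector).
    """
    x = matrix.values if isinstance(matrix, ProcessedMatrix) else np.asarray(matrix, float)
    rng = substream(seed, "simulation/planted-real")
    G, N = x.shape
    v = _block_vector(N, pos_cells if pos_cells is not None else N // 3)
    u = rng.standard_normal(G)
    u /= np.linalg.norm(u)
    if theta == 0:
        return x.copy(), u, v
    return x + np.sqrt(G) * theta * np.outer(u, v), u, v


def splatter_lite(spec: GroupSimSpec) -> SimulatedDataset:
    """Gamma-Poisson group simulation (see :class:`GroupSimSpec`)."""
    rng = substream(spec.seed, "simulation/groups")
    G, N, K = spec.n_genes, spec.n_cells, spec.n_groups
    base = rng.gamma(spec.mean_shape, scale=1.0 / spec.mean_rate, size=G)
    base = np.maximum(base, 1e-12)
    group_means = np.empty((G, K))
    de_mask = np.zeros((G, K), dtype=bool)
    for k in range(K):
        de = rng.uniform(size=G) < spec.de_prob
        fac = np.exp(spec.de_loc + spec.de_scale * rng.standard_normal(G))
        invert = rng.uniform(size=G) < 0.5
        fac = np.where(invert, 1.0 / fac, fac)
        f = np.where(de, fac, 1.0)
        de_mask[:, k] = de
        group_means[:, k] = base * f
    # expression fractions per group
    group_means /= group_means.sum(axis=0, keepdims=True)
    assign = rng.choice(K, size=N, p=np.asarray(spec.group_proportions))
    lib = rng.lognormal(spec.lib_loc, spec.lib_scale, size=N)
    lam = group_means[:, assign] * lib[None, :]
    counts = rng.poisson(lam)
    cm = CountMatrix(
        counts,
        [f"gene{g}" for g in range(G)],
        [f"cell{i}" for i in range(N)],
    )
    labels = pd.Series(
        [f"group{k}" for k in assign], index=cm.cell_ids, name="cluster"
    )
    return SimulatedDataset(
        counts=cm,
        labels=labels,
        provenance={
            "generator": "splatter_lite",
            "seed": spec.seed,
            "de_prob": spec.de_prob,
            "de_mask_per_group": de_mask.sum(axis=0).tolist(),
        },
    )


def _cleanup_cluster(x: np.ndarray, alpha_tw: float = 0.01) -> np.ndarray:
    """Flatten a processed cluster's spectrum: outlying singular values
    are moved to the bulk upper edge and the transcriptome mode (the
    smallest value after standardization) is restored above the bulk,
    at TRANSCRIPTOME_RESTORE_FACTOR times the edge."""
    svd = scaled_svd(x)
    mp = mp_model(svd.n_genes, svd.n_cells, alpha_tw)
    gamma = svd.gamma.copy()
    gamma[gamma**2 > mp.tw_lambda_star] = mp.gamma_plus
    gamma[-1] = TRANSCRIPTOME_RESTORE_FACTOR * mp.gamma_plus
    out = np.sqrt(svd.n_genes) * (svd.U * gamma) @ svd.V.T
    return out.T if svd.transposed else out


def weighted_mixture(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    alpha: float,
    n_cells_per_cluster: int = 150,
    seed: int = 0,
) -> SimulatedDataset:
    """Two synthetic clusters as weighted averages of two source
    clusters' expression profiles.

    Each source (a processed genes x cells matrix) is first cleaned of
    its own substructure (see :func:`_cleanup_cluster`).  Cluster 1
    cells are ``alpha * a + (1 - alpha) * b`` for randomly drawn source
    columns a, b; cluster 2 flips the weights.  ``alpha = 0.5`` makes
    the clusters identically distributed; ``alpha`` near 0 or 1 makes
    them maximally different.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    A = profiles_a.values if isinstance(profiles_a, ProcessedMatrix) else np.asarray(profiles_a, float)
    B = profiles_b.values if isinstance(profiles_b, ProcessedMatrix) else np.asarray(profiles_b, float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("source clusters must share the gene axis")
    rng = substream(seed, "simulation/mixture")
    n = n_cells_per_cluster
    # each synthetic cell consumes a distinct source cell: reusing a
    # source column would plant spurious pairwise correlations
    if A.shape[1] < 2 * n or B.shape[1] < 2 * n:
        raise ValueError(f"need at least {2 * n} cells in each source cluster")
    A = _cleanup_cluster(A)
    B = _cleanup_cluster(B)
    ia = rng.permutation(A.shape[1])[: 2 * n]
    ib = rng.permutation(B.shape[1])[: 2 * n]
    c1 = alpha * A[:, ia[:n]] + (1.0 - alpha) * B[:, ib[:n]]
    c2 = (1.0 - alpha) * A[:, ia[n:]] + alpha * B[:, ib[n:]]
    mat = np.concatenate([c1, c2], axis=1)
    labels = pd.Series(
        ["c1"] * n + ["c2"] * n,
        index=[f"cell{i}" for i in range(2 * n)],
        name="cluster",
    )
    return SimulatedDataset(
        matrix=mat,
        labels=labels,
        provenance={"generator": "weighted_mixture", "alpha": alpha, "seed": seed},
    )


def differentiation_path(
    n_genes: int = 1000,
    n_cells: int = 300,
    gradient_strength: float = 5.0,
    seed: int = 0,
) -> SimulatedDataset:
    """A large cluster with a gradually changing expression profile.

    Noise plus a rank-1 term whose cell-side pattern is linear in a
    latent ordering (recorded as true pseudotime); the gene side is a
    random unit vector.  ``gradient_strength`` is the scaled singular
    value of the gradient term.
    """
    if gradient_strength < 0:
        raise ValueError("gradient_strength must be >= 0")
    rng = substream(seed, "simulation/path")
    t = rng.uniform(0.0, 1.0, size=n_cells)
    v = t - t.mean()
    v /= np.linalg.norm(v)
    u = rng.standard_normal(n_genes)
    u /= np.linalg.norm(u)
    X = rng.standard_normal((n_genes, n_cells))
    mat = X + np.sqrt(n_genes) * gradient_strength * np.outer(u, v)
    cells = [f"cell{i}" for i in range(n_cells)]
    return SimulatedDataset(
        matrix=mat,
        labels=pd.Series(["path"] * n_cells, index=cells, name="cluster"),
        true_theta=gradient_strength,
        true_cell_vector=v,
        true_gene_vector=u,
        pseudotime=pd.Series(t, index=cells, name="pseudotime"),
        provenance={"generator": "differentiation_path", "seed": seed},
    )


def multiplicative_planted(
    n_genes: int = 350,
    n_cells: int = 201,
    theta: float = 5.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Multiplicative-noise dataset ``(I + P)^{1/2} X`` with a rank-1
    gene-space signal P whose eigenvalue is theta in the scaled
    (divide-by-n_genes) spectral units; the noise bulk still follows
    the MP law and the outlying eigenvalue sits at
    ``lambda = (theta + 1)(theta + c) / theta``."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = substream(seed, "simulation/mult")
    c = n_cells / n_genes
    X = rng.standard_normal((n_genes, n_cells))
    w = rng.standard_normal(n_genes)
    w /= np.linalg.norm(w)
    # theta is in MP-scaled units: the population-covariance spike is
    # theta / c, and (I + s w w^T)^{1/2} = I + (sqrt(1 + s) - 1) w w^T
    s = theta / c
    mat = X + (np.sqrt(1.0 + s) - 1.0) * np.outer(w, w @ X)
    return SimulatedDataset(
        matrix=mat,
        labels=pd.Series(
            ["all"] * n_cells, index=[f"cell{i}" for i in range(n_cells)], name="cluster"
        ),
        true_theta=theta,
        true_gene_vector=w,
        provenance={"generator": "multiplicative_planted", "seed": seed},
    )
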