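"""Random-matrix null model: scaled SVD, Marchenko-Pastur bulk,
Tracy-Widom outlier threshold, and the normality gate.

Conventions
-----------
The processed matrix is genes x cells with ``n_genes >= n_cells``
(enforced by transposition).  Raw singular values are divided by
``sqrt(n_genes)``; in these units the noise bulk of an i.i.d.
mean-0/variance-1 matrix occupies ``[1 - sqrt(c), 1 + sqrt(c)]`` with
``c = n_cells / n_genes``, and the eigenvalues ``lambda = gamma**2``
occupy ``[(1 - sqrt(c))**2, (1 + sqrt(c))**2]``.

The largest eigenvalue of a finite null matrix fluctuates around the
upper edge on the Tracy-Widom (beta = 1) scale; the outlier threshold
is the Johnstone-centered TW quantile at ``1 - alpha_tw``.  A component
above the threshold is only called significant if its cell-singular
vector also fails a Shapiro-Wilk normality test (singular vectors of a
pure noise matrix are normal), Benjamini-Hochberg adjusted across the
threshold-passing set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.interpolate
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .config import substream
from .preprocess import ProcessedMatrix

__all__ = [
    "ScaledSVD",
    "MPModel",
    "tracy_widom_quantile",
    "scaled_svd",
    "mp_model",
    "mp_density",
    "sample_mp",
    "ks_bulk_test",
    "significant_components",
]

# Shapiro-Wilk validity cap: larger vectors are subsampled.
SW_MAX_N = 5000


@dataclass
class ScaledSVD:
    """SVD of a processed matrix in MP units.

    ``gamma`` is sorted descending; ``U`` holds gene-singular vectors,
    ``V`` cell-singular vectors (both as columns, unit norm).  If the
    input had fewer genes than cells it was transposed first and
    ``transposed`` records the swap.
    """

    gamma: np.ndarray
    U: np.ndarray
    V: np.ndarray
    c: float
    n_genes: int
    n_cells: int
    transposed: bool = False

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.gamma**2

    def reconstruct(self) -> np.ndarray:
        return np.sqrt(self.n_genes) * (self.U * self.gamma) @ self.V.T


@dataclass
class MPModel:
    """MP bulk edges and the TW outlier threshold for one geometry."""

    c: float
    gamma_minus: float
    gamma_plus: float
    a: float  # upper eigenvalue edge (1 + sqrt(c))**2
    b: float  # lower eigenvalue edge (1 - sqrt(c))**2
    tw_lambda_star: float
    alpha_tw: float


# Tracy-Widom beta=1 quantiles via the shifted-gamma approximation of
# Chiani (2014): TW1 is matched in its first three moments by
# Gamma(k, theta) - alpha.  Max CDF error ~1e-3 over the whole range.
_TW1_K = 46.44604884387787
_TW1_THETA = 0.18605402228279682
_TW1_ALPHA = 9.848007781128567


def tracy_widom_quantile(p: float | np.ndarray) -> float | np.ndarray:
    """Quantile function of the Tracy-Widom beta=1 distribution."""
    return scipy.stats.gamma.ppf(p, _TW1_K, scale=_TW1_THETA) - _TW1_ALPHA


def tracy_widom_cdf(x: float | np.ndarray) -> float | np.ndarray:
    """CDF of the Tracy-Widom beta=1 distribution."""
    return scipy.stats.gamma.cdf(np.asarray(x) + _TW1_ALPHA, _TW1_K, scale=_TW1_THETA)


def scaled_svd(processed: ProcessedMatrix | np.ndarray) -> ScaledSVD:
    """Thin SVD with singular values scaled to MP units.

    Values are divided by ``sqrt(n_genes)``; the sign of each component
    is fixed so the largest-magnitude entry of the cell-singular vector
    is positive.
    """
    x = processed.values if isinstance(processed, ProcessedMatrix) else np.asarray(processed, float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(x)):
        i, j = np.argwhere(~np.isfinite(x))[0]
        raise ValueError(f"non-finite entry at ({i}, {j})")
    transposed = x.shape[0] < x.shape[1]
    if transposed:
        x = x.T
    n_genes, n_cells = x.shape
    U, s, Vt = np.linalg.svd(x, full_matrices=False)
    V = Vt.T
    # sign convention on the cell side
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    U *= flip
    V *= flip
    return ScaledSVD(
        gamma=s / np.sqrt(n_genes),
        U=U,
        V=V,
        c=n_cells / n_genes,
        n_genes=n_genes,
        n_cells=n_cells,
        transposed=transposed,
    )


def mp_model(n_genes: int, n_cells: int, alpha_tw: float = 0.01) -> MPModel:
    """MP edges plus the TW threshold for an n_genes x n_cells matrix.

    The threshold is on the eigenvalue scale: ``lambda* = mu + sigma *
    q_TW1(1 - alpha_tw)`` with Johnstone's centering and scaling for the
    largest eigenvalue of a white Wishart matrix.
    """
    if n_cells < 2 or n_genes < n_cells:
        raise ValueError("need n_genes >= n_cells >= 2")
    if not (0.0 < alpha_tw < 1.0):
        raise ValueError("alpha_tw must lie in (0, 1)")
    c = n_cells / n_genes
    sc = np.sqrt(c)
    mu = (np.sqrt(n_genes - 1) + np.sqrt(n_cells)) ** 2 / n_genes
    sigma = (
        (np.sqrt(n_genes - 1) + np.sqrt(n_cells))
        * (1 / np.sqrt(n_genes - 1) + 1 / np.sqrt(n_cells)) ** (1 / 3)
        / n_genes
    )
    lam_star = mu + sigma * float(tracy_widom_quantile(1 - alpha_tw))
    return MPModel(
        c=c,
        gamma_minus=1 - sc,
        gamma_plus=1 + sc,
        a=(1 + sc) ** 2,
        b=(1 - sc) ** 2,
        tw_lambda_star=max(lam_star, (1 + sc) ** 2),
        alpha_tw=alpha_tw,
    )


def mp_density(s: np.ndarray, c: float) -> np.ndarray:
    """MP density on the singular-value scale for cell-to-gene ratio c."""
    s = np.asarray(s, float)
    a = (1 + np.sqrt(c)) ** 2
    b = (1 - np.sqrt(c)) ** 2
    lam = s**2
    inside = (lam > b) & (lam < a)
    out = np.zeros_like(s)
    out[inside] = np.sqrt((a - lam[inside]) * (lam[inside] - b)) / (np.pi * c * s[inside])
    return out


def sample_mp(c: float, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw n i.i.d. singular values from the MP law with ratio c.

    Inverse-CDF sampling on a numerically integrated density grid;
    deterministic given the seed.
    """
    if not (0.0 < c <= 1.0):
        raise ValueError("c must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "mp-sampling")
    lo, hi = 1 - np.sqrt(c), 1 + np.sqrt(c)
    grid = np.linspace(lo, hi, 20001)
    pdf = mp_density(grid, c)
    cdf = scipy.integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    # strictly increasing subset for the inverse
    keep = np.concatenate(([True], np.diff(cdf) > 0))
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf[keep], grid[keep])


def mp_mean(c: float) -> float:
    """Mean of the MP singular-value law (by quadrature)."""
    lo, hi = 1 - np.sqrt(c), 1 + np.sqrt(c)
    grid = np.linspace(lo, hi, 200001)
    pdf = mp_density(grid, c)
    return float(np.trapezoid(grid * pdf, grid))


def bulk_values(svd: ScaledSVD, mp: MPModel) -> np.ndarray:
    """Bulk singular values: below the TW eigenvalue threshold, with the
    transcriptome mode (the smallest value, pinned near 0 by the
    cell-wise standardization) excluded."""
    lam = svd.eigenvalues
    bulk = svd.gamma[lam <= mp.tw_lambda_star]
    if bulk.size == 0:
        raise ValueError("empty bulk")
    return bulk[:-1] if bulk.size > 1 else bulk  # gamma sorted desc: last = smallest


def ks_bulk_test(
    svd: ScaledSVD,
    mp: MPModel,
    seed: int | np.random.Generator = 0,
    n_samples: int = 1000,
) -> float:
    """Two-sample KS test of the observed bulk against MP samples.

    Returns the raw p-value; the pipeline applies Benjamini-Hochberg
    across clusters.
    """
    bulk = bulk_values(svd, mp)
    if bulk.size < 10:
        raise ValueError(f"only {bulk.size} bulk singular values (need >= 10)")
    ref = sample_mp(mp.c, n_samples, seed)
    return float(scipy.stats.ks_2samp(bulk, ref).pvalue)


def shapiro_pvalue(v: np.ndarray, rng: np.random.Generator | None = None) -> float:
    """Shapiro-Wilk normality p-value of a singular vector's entries,
    subsampling above the test's validity range."""
    v = np.asarray(v, float)
    if v.size > SW_MAX_N:
        rng = rng or np.random.default_rng(0)
        v = rng.choice(v, size=SW_MAX_N, replace=False)
    return float(scipy.stats.shapiro(v).pvalue)


def significant_components(
    svd: ScaledSVD,
    mp: MPModel,
    alpha_sw: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[list[int], dict[int, tuple[float, float]]]:
    """Indices of components carrying signal.

    A component qualifies if its eigenvalue exceeds the TW threshold
    AND its cell-singular vector deviates from normality (Shapiro-Wilk,
    BH-adjusted across the TW-passing set, at level ``alpha_sw``).
    Returns the index list plus ``{index: (p_raw, p_adj)}`` for every
    TW-passing component.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "sw-subsample")
    lam = svd.eigenvalues
    tw_pass = [int(i) for i in np.flatnonzero(lam > mp.tw_lambda_star)]
    if not tw_pass:
        return [], {}
    raw = np.array([shapiro_pvalue(svd.V[:, i], rng) for i in tw_pass])
    adj = multipletests(raw, method="fdr_bh")[1]
    details = {i: (float(r), float(q)) for i, r, q in zip(tw_pass, raw, adj)}
    keep = [i for i, q in zip(tw_pass, adj) if q < alpha_sw]
    return keep, details
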