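"""Clusterability from outlying singular values.

The measured expression matrix is modeled as noise plus a low-rank
signal, ``X_tilde = X + P``.  Low-rank perturbation theory maps each
outlying scaled singular value ``gamma`` of the measured matrix to the
singular value ``theta`` of the unobserved signal matrix, and from
``theta`` to the squared cosine ``phi`` of the angle between the
measured and signal cell-singular vectors.  ``phiclust`` is the largest
``phi`` over the significant components: 0 means the within-cluster
variability is consistent with pure noise, values near 1 mean the
leading measured vector is almost parallel to the noise-free signal and
sub-clustering should succeed.

A signal weaker than ``theta = c**(1/4)`` (the BBP detection
threshold, with ``c`` the cell-to-gene ratio) leaves no trace in the
spectrum; ``phi`` is exactly 0 there and grows monotonically with
``theta`` above it.

Nuisance covariates (depth, cell cycle, stress, pseudotime, ...) are
removed by regressing each significant cell-singular vector on the
covariates and shrinking the squared singular value by
``(1 - adjusted R^2)``; a corrected value that falls back below the
outlier threshold contributes ``phi = 0``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import RunConfig, substream
from .io import CountMatrix
from .preprocess import ProcessedMatrix, preprocess_counts
from .rmt import MPModel, ScaledSVD, mp_model, scaled_svd, ks_bulk_test, significant_components
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificantComponent",
    "PhiclustResult",
    "theta_additive",
    "gamma_from_theta",
    "phi_cell",
    "phi_gene",
    "theta_multiplicative",
    "phi_mult",
    "regress_confounders",
    "correct_singular_values",
    "phiclust_from_matrix",
    "compute_phiclust",
    "estimate_uncertainty",
    "variance_driving_genes",
]

log = logging.getLogger(__name__)


@dataclass
class SignificantComponent:
    """One outlying component and everything derived from it."""

    index: int
    gamma: float
    gamma_corrected: float
    theta: float
    phi: float
    phi_gene: float
    sw_p: float
    sw_p_adjusted: float
    adj_r2: float
    r2_per_covariate: dict[str, float] = field(default_factory=dict)


@dataclass
class PhiclustResult:
    """Per-cluster clusterability summary."""

    cluster_id: str
    phiclust: float
    g_phiclust: float
    sigma_plus: float
    sigma_minus: float
    bulk_ks_p: float
    bulk_ks_p_adjusted: float
    n_cells: int
    n_genes: int
    c: float
    noise_model: str
    components: list[SignificantComponent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# theta <-> gamma maps and the angle formulas
# ---------------------------------------------------------------------------

def gamma_from_theta(theta: float, c: float) -> float:
    """Forward map: measured scaled singular value produced by a signal
    of strength theta, ``gamma**2 = (theta**2 + 1)(theta**2 + c) /
    theta**2`` (additive noise, theta above the detection threshold)."""
    t2 = theta**2
    return float(np.sqrt((t2 + 1.0) * (t2 + c) / t2))


def theta_additive(gamma: float, c: float) -> float:
    """Signal singular value recovered from an outlying gamma.

    Closed form ``theta = sqrt(2c / (gamma^2 - (c+1) -
    sqrt((gamma^2 - (c+1))^2 - 4c)))``, the branch with
    ``theta > c**(1/4)``; valid only strictly above the bulk edge
    ``gamma > 1 + sqrt(c)``.
    """
    edge = 1.0 + np.sqrt(c)
    if gamma <= edge:
        raise ValueError(f"gamma={gamma:.6g} is inside the noise bulk (edge {edge:.6g})")
    d = gamma**2 - (c + 1.0)
    # rationalized: 2c / (d - sqrt(d^2 - 4c)) == (d + sqrt(d^2 - 4c)) / 2,
    # which avoids catastrophic cancellation for strong signal
    theta = float(np.sqrt((d + np.sqrt(d**2 - 4.0 * c)) / 2.0))
    # the closed form must invert the forward map exactly
    if abs(gamma_from_theta(theta, c) - gamma) > 1e-10 * max(1.0, gamma):
        raise ArithmeticError("theta(gamma) failed the forward-identity check")
    return theta


def phi_cell(theta: float, c: float) -> float:
    """Squared cosine between measured and signal cell-singular vectors:
    ``phi = 1 - c(1 + theta^2) / (theta^2 (theta^2 + c))``.

    Zero at the detection threshold ``theta = c**(1/4)`` and for any
    weaker signal; increases to 1 as theta grows.
    """
    if theta < c**0.25:
        return 0.0
    t2 = theta**2
    return max(0.0, 1.0 - c * (1.0 + t2) / (t2 * (t2 + c)))


def phi_gene(theta: float, c: float) -> float:
    """Gene-side conjugate: ``phi_g = 1 - (c + theta^2) /
    (theta^2 (theta^2 + 1))``; zero at ``theta = c**(1/4)``."""
    if theta < c**0.25:
        return 0.0
    t2 = theta**2
    return max(0.0, 1.0 - (c + t2) / (t2 * (t2 + 1.0)))


def theta_multiplicative(lam: float, c: float) -> float:
    """Signal eigenvalue under the multiplicative model
    ``X_tilde = (I + P)^{1/2} X``:
    ``theta = 2c / (lambda - c - 1 - sqrt((lambda - a)(lambda - b)))``
    with eigenvalue edges ``a, b = (1 +/- sqrt(c))**2``."""
    a = (1.0 + np.sqrt(c)) ** 2
    b = (1.0 - np.sqrt(c)) ** 2
    if lam <= a:
        raise ValueError(f"lambda={lam:.6g} is inside the noise bulk (edge {a:.6g})")
    return float(2.0 * c / (lam - c - 1.0 - np.sqrt((lam - a) * (lam - b))))


def phi_mult(theta: float, c: float) -> float:
    """Squared cosine under multiplicative noise:
    ``phi = (1/theta) (theta^2 - c) / (theta (c+1) + 2c)``.

    Zero at ``theta**2 = c``; saturates at ``1/(c+1)`` rather than 1
    for strong signal.
    """
    if theta**2 - c <= 1e-12 * max(1.0, c):
        return 0.0
    return float((theta**2 - c) / (theta * (theta * (c + 1.0) + 2.0 * c)))


# ---------------------------------------------------------------------------
# confounder regression
# ---------------------------------------------------------------------------

def regress_confounders(
    svd: ScaledSVD,
    covariates: pd.DataFrame | None,
    indices: list[int],
) -> dict[int, tuple[float, dict[str, float]]]:
    """OLS of each indexed cell-singular vector on the covariates.

    Returns ``{index: (adjusted R^2 of the joint fit, {covariate:
    single-covariate R^2})}``.  The joint adjusted R^2 (clamped to
    [0, 1]) is what shrinks the singular value; the per-covariate
    breakdown is attribution only.  Constant covariates are dropped;
    statsmodels handles remaining collinearity by pseudo-inverse.
    """
    out: dict[int, tuple[float, dict[str, float]]] = {}
    if covariates is None or covariates.shape[1] == 0:
        return {i: (0.0, {}) for i in indices}
    if covariates.shape[0] != svd.n_cells:
        raise ValueError(
            f"covariate table has {covariates.shape[0]} rows for {svd.n_cells} cells"
        )
    usable = covariates.loc[:, covariates.std(axis=0) > 0]
    dropped = set(covariates.columns) - set(usable.columns)
    if dropped:
        warnings.warn(f"dropping constant covariates: {sorted(dropped)}")
    if usable.shape[1] == 0:
        return {i: (0.0, {}) for i in indices}
    X = sm.add_constant(usable.to_numpy(float))
    for i in indices:
        y = svd.V[:, i]
        fit = sm.OLS(y, X).fit()
        adj = float(np.clip(fit.rsquared_adj, 0.0, 1.0))
        per = {}
        for name in usable.columns:
            f1 = sm.OLS(y, sm.add_constant(usable[name].to_numpy(float))).fit()
            per[str(name)] = float(max(0.0, f1.rsquared))
        out[i] = (adj, per)
        log.info("component %d: adjusted R^2 = %.4f", i, adj)
    return out


def correct_singular_values(gamma: float, adj_r2: float) -> float:
    """Shrink a singular value by the confounder-explained variance:
    ``gamma_corrected = gamma * sqrt(1 - adj_r2)`` (squared singular
    values are variances, so the correction is multiplicative on the
    eigenvalue scale)."""
    if not (0.0 <= adj_r2 <= 1.0):
        raise ValueError("adjusted R^2 must lie in [0, 1]")
    return float(gamma * np.sqrt(1.0 - adj_r2))


# ---------------------------------------------------------------------------
# the per-cluster pipeline
# ---------------------------------------------------------------------------

def _components_from_svd(
    svd: ScaledSVD,
    mp: MPModel,
    config: RunConfig,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> list[SignificantComponent]:
    """Gate, correct and score the outlying components of one matrix."""
    rng = rng or config.rng("sw-subsample")
    keep, sw = significant_components(svd, mp, alpha_sw=config.alpha_sw, seed=rng)
    reg = regress_confounders(svd, covariates, keep)
    comps: list[SignificantComponent] = []
    for i in keep:
        adj_r2, per = reg[i]
        g = float(svd.gamma[i])
        g_corr = correct_singular_values(g, adj_r2)
        if config.noise_model == "multiplicative":
            in_bulk = g_corr**2 <= mp.tw_lambda_star
            theta = 0.0 if in_bulk else theta_multiplicative(g_corr**2, svd.c)
            phi = 0.0 if in_bulk else phi_mult(theta, svd.c)
            phig = 0.0
        else:
            in_bulk = g_corr**2 <= mp.tw_lambda_star
            theta = 0.0 if in_bulk else theta_additive(g_corr, svd.c)
            phi = 0.0 if in_bulk else phi_cell(theta, svd.c)
            phig = 0.0 if in_bulk else phi_gene(theta, svd.c)
        comps.append(
            SignificantComponent(
                index=i,
                gamma=g,
                gamma_corrected=g_corr,
                theta=theta,
                phi=phi,
                phi_gene=phig,
                sw_p=sw[i][0],
                sw_p_adjusted=sw[i][1],
                adj_r2=adj_r2,
                r2_per_covariate=per,
            )
        )
    return comps


def _aggregate(comps: list[SignificantComponent]) -> tuple[float, float]:
    """phiclust = max phi, g-phiclust = max phi_gene; ties on phi go to
    the component with the larger gamma (list is gamma-descending)."""
    if not comps:
        return 0.0, 0.0
    return max(c.phi for c in comps), max(c.phi_gene for c in comps)


def phiclust_from_matrix(
    matrix: ProcessedMatrix | np.ndarray,
    covariates: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    cluster_id: str = "cluster",
    with_uncertainty: bool = False,
) -> PhiclustResult:
    """Run the spectral pipeline on an already-preprocessed matrix."""
    config = config or RunConfig()
    svd = scaled_svd(matrix)
    mp = mp_model(svd.n_genes, svd.n_cells, config.alpha_tw)
    comps = _components_from_svd(svd, mp, config, covariates)
    try:
        ks_p = ks_bulk_test(svd, mp, config.rng("mp-sampling"))
    except ValueError:
        ks_p = float("nan")
    phi, phig = _aggregate(comps)
    sp, sm_ = (0.0, 0.0)
    if with_uncertainty and comps:
        sp, sm_ = estimate_uncertainty(svd, comps, config)
    log.info(
        "%s: %d cells, %d significant components, phiclust=%.4f",
        cluster_id, svd.n_cells, len(comps), phi,
    )
    return PhiclustResult(
        cluster_id=cluster_id,
        phiclust=phi,
        g_phiclust=phig,
        sigma_plus=sp,
        sigma_minus=sm_,
        bulk_ks_p=ks_p,
        bulk_ks_p_adjusted=ks_p,  # overwritten by the multi-cluster driver
        n_cells=svd.n_cells,
        n_genes=svd.n_genes,
        c=svd.c,
        noise_model=config.noise_model,
        components=comps,
    )


def compute_phiclust(
    counts: CountMatrix,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    with_uncertainty: bool = False,
) -> list[PhiclustResult]:
    """Full pipeline per cluster: preprocess each cluster's cells, run
    the spectral analysis, and BH-adjust the bulk KS p-values across
    clusters."""
    config = config or RunConfig()
    labels = labels.reindex([c for c in counts.cell_ids if c in labels.index])
    results: list[PhiclustResult] = []
    for cluster in sorted(labels.dropna().unique()):
        cells = labels.index[labels == cluster].tolist()
        if len(cells) < 10:
            raise ValueError(f"cluster {cluster!r} has {len(cells)} cells (need >= 10)")
        if len(cells) < config.min_cluster_size_warn:
            warnings.warn(
                f"cluster {cluster!r} has only {len(cells)} cells; the random-matrix "
                "null is asymptotic and small clusters are unreliable"
            )
        sub = counts.subset_cells(cells)
        processed = preprocess_counts(sub)
        cov = None
        if covariates is not None:
            missing = [c for c in cells if c not in covariates.index]
            if missing:
                raise ValueError(f"covariates missing for cells: {missing[:5]}")
            cov = covariates.loc[cells]
            if config.covariates:
                cov = cov[[c for c in config.covariates if c in cov.columns]]
        results.append(
            phiclust_from_matrix(
                processed, cov, config, cluster_id=str(cluster),
                with_uncertainty=with_uncertainty,
            )
        )
    if results:
        adj = multipletests([r.bulk_ks_p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.bulk_ks_p_adjusted = float(q)
    return results


# ---------------------------------------------------------------------------
# uncertainty by noise resampling
# ---------------------------------------------------------------------------

def estimate_uncertainty(
    svd: ScaledSVD,
    components: list[SignificantComponent],
    config: RunConfig | None = None,
) -> tuple[float, float]:
    """Asymmetric spread of phiclust under resampled noise.

    The signal is approximated from the significant components with the
    perturbation-theory singular values, ``P_s = sqrt(n_genes) *
    sum_i theta_i U_i V_i^T``; each draw adds a fresh i.i.d. standard
    normal matrix and reruns SVD plus gating (no re-preprocessing).
    Draws where no component survives contribute phiclust = 0, so the
    error bar reflects detection failure near the threshold.
    ``sigma_plus`` / ``sigma_minus`` are RMS deviations of the draws
    above / below the point estimate.
    """
    config = config or RunConfig()
    if not components:
        return 0.0, 0.0
    rng = config.rng("resampling")
    point, _ = _aggregate(components)
    idx = [c.index for c in components]
    thetas = np.array([c.theta for c in components])
    P_s = np.sqrt(svd.n_genes) * (svd.U[:, idx] * thetas) @ svd.V[:, idx].T
    mp = mp_model(svd.n_genes, svd.n_cells, config.alpha_tw)
    values = []
    for _ in range(config.n_boot):
        noise = rng.standard_normal(P_s.shape)
        s = scaled_svd(P_s + noise)
        comps = _components_from_svd(s, mp, config, covariates=None, rng=rng)
        values.append(_aggregate(comps)[0])
    values = np.asarray(values)
    above = values[values > point] - point
    below = values[values < point] - point
    sigma_plus = float(np.sqrt(np.mean(above**2))) if above.size else 0.0
    sigma_minus = float(np.sqrt(np.mean(below**2))) if below.size else 0.0
    return sigma_plus, sigma_minus


# ---------------------------------------------------------------------------
# variance-driving genes
# ---------------------------------------------------------------------------

def variance_driving_genes(
    svd: ScaledSVD,
    gene_ids: list[str],
    component_index: int,
    significant: list[int],
    top_n: int = 20,
) -> pd.DataFrame:
    """Rank genes by |loading| in one significant gene-singular vector.

    Genes with large positive (negative) entries are concentrated in
    cells with positive (negative) entries of the matching cell-singular
    vector, so they explain the detected separation.
    """
    if component_index not in significant:
        raise ValueError(f"component {component_index} is not significant")
    u = svd.U[:, component_index]
    order = np.argsort(-np.abs(u))[: max(0, top_n)]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "gene_id": [gene_ids[i] for i in order],
            "loading": u[order],
            "sign": np.sign(u[order]).astype(int),
            "component_index": component_index,
        }
    )
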