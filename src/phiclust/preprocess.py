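"""Preprocessing: counts -> doubly standardized expression matrix.

The random-matrix null (a Marchenko-Pastur bulk) holds for a matrix of
i.i.d. entries with mean 0 and variance 1.  Raw counts are nowhere near
that: per-cell depth varies by orders of magnitude and per-gene means
span decades.  The pipeline therefore (1) scales every cell to a common
target total and applies log1p, (2) drops degenerate genes, and
(3) standardizes first gene-wise then cell-wise.  After the second step
every column has exactly mean 0 and variance 1, which pins the noise
bulk to the MP law with edges 1 +/- sqrt(c) (in units of singular value
/ sqrt(n_genes)) and drives the shared "transcriptome mode" to singular
value 0.

Standard deviations here are population (1/n) ones: the Frobenius norm
of the output is then exactly sqrt(n_genes * n_cells), matching the MP
scaling convention used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "ProcessedMatrix",
    "normalize_log",
    "filter_degenerate",
    "standardize",
    "preprocess_counts",
    "build_covariates",
    "DEFAULT_MITO_PREFIXES",
    "DEFAULT_RIBO_PREFIXES",
]

log = logging.getLogger(__name__)

DEFAULT_MITO_PREFIXES = ("MT-",)
DEFAULT_RIBO_PREFIXES = ("RPL", "RPS")

MIN_GENES = 10
MIN_CELLS = 10


@dataclass
class ProcessedMatrix:
    """Doubly standardized genes x cells matrix with provenance flags."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False
    logged: bool = False
    gene_standardized: bool = False
    cell_standardized: bool = False
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def normalize_log(counts: CountMatrix, scale: str = "median", target: float | None = None) -> np.ndarray:
    """Depth-normalize each cell to a common total, then log1p.

    ``scale="median"`` targets the median of the per-cell totals;
    ``scale="fixed"`` uses ``target``.  A cell with zero total counts
    has no defined scaling and is rejected by name.
    """
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {counts.cell_ids[zero[0]]!r} has zero total counts")
    if scale == "median":
        t = float(np.median(totals))
    elif scale == "fixed":
        if target is None or target <= 0:
            raise ValueError("fixed scaling needs a positive target total")
        t = float(target)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return np.log1p(counts.values * (t / totals)[None, :])


def filter_degenerate(matrix: np.ndarray, gene_ids: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop genes with zero variance across cells.

    Gene-wise standardization divides by the per-gene standard
    deviation, so constant genes must go first.  Returns the filtered
    matrix, the surviving gene ids, and the dropped ids.
    """
    matrix = np.asarray(matrix, dtype=float)
    var = matrix.var(axis=1)
    keep = var > 0
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    out = matrix[keep]
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    if out.shape[0] < MIN_GENES:
        raise ValueError(f"only {out.shape[0]} genes remain after filtering (need >= {MIN_GENES})")
    if out.shape[1] < MIN_CELLS:
        raise ValueError(f"only {out.shape[1]} cells present (need >= {MIN_CELLS})")
    if dropped:
        log.info("dropped %d zero-variance genes", len(dropped))
    return out, kept_ids, dropped


def standardize(matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Standardize gene-wise then cell-wise, iterated to convergence.

    Each sweep subtracts the per-gene mean and divides by the per-gene
    standard deviation, then does the same per cell.  A single sweep
    leaves the rows off by O(1/sqrt(n_cells)), so sweeps repeat (always
    ending on the cell step) until the rows are standardized to ``tol``
    as well; the result is a fixed point, so re-applying the function
    is a no-op.  Columns end with exactly mean 0 and variance 1, which
    annihilates the all-ones gene direction and pins the transcriptome
    mode at singular value 0.
    """
    x = np.asarray(matrix, dtype=float)
    g_std = x.std(axis=1)
    if np.any(g_std == 0):
        raise ValueError("constant gene row; run filter_degenerate first")
    for _ in range(max_iter):
        g_std = x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=1, keepdims=True)) / g_std
        c_std = x.std(axis=0, keepdims=True)
        if np.any(c_std == 0):
            raise ValueError("a cell became constant after gene-wise standardization")
        x = (x - x.mean(axis=0, keepdims=True)) / c_std
        row_dev = max(
            np.abs(x.mean(axis=1)).max(), np.abs(x.std(axis=1) - 1.0).max()
        )
        if row_dev < tol:
            break
    return x


def preprocess_counts(counts: CountMatrix, scale: str = "median") -> ProcessedMatrix:
    """Full chain: normalize_log -> filter_degenerate -> standardize."""
    norm = normalize_log(counts, scale=scale)
    filt, kept, dropped = filter_degenerate(norm, counts.gene_ids)
    x = standardize(filt)
    log.info("preprocessed %d genes x %d cells (c=%.4f)", x.shape[0], x.shape[1], x.shape[1] / x.shape[0])
    return ProcessedMatrix(
        x,
        kept,
        list(counts.cell_ids),
        normalized=True,
        logged=True,
        gene_standardized=True,
        cell_standardized=True,
        dropped_genes=dropped,
    )


def _gene_set_mean(normalized: np.ndarray, gene_ids: list[str], genes: list[str], name: str) -> np.ndarray | None:
    idx = [i for i, g in enumerate(gene_ids) if g in set(genes)]
    if not idx:
        warnings.warn(f"gene set {name!r} matches no genes; covariate skipped")
        return None
    return normalized[idx].mean(axis=0)


def build_covariates(
    counts: CountMatrix,
    normalized: np.ndarray,
    gene_sets: dict[str, list[str]] | None = None,
    extras: pd.DataFrame | None = None,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
    ribo_prefixes: tuple[str, ...] = DEFAULT_RIBO_PREFIXES,
) -> pd.DataFrame:
    """Assemble the per-cell nuisance covariates.

    Always includes ``log_total_counts`` = log(1 + raw per-cell total).
    ``mito_fraction`` / ``ribo_fraction`` are per-cell means of
    normalized expression over the prefix-matched gene sets;
    ``cycle_score`` / ``stress_score`` (and any other named set) are
    gene-set means z-scored across cells.  ``extras`` columns are passed
    through after an id check.
    """
    cov = pd.DataFrame(index=pd.Index(counts.cell_ids, name="cell_id"))
    cov["log_total_counts"] = np.log1p(counts.values.sum(axis=0).astype(float))

    mito = [g for g in counts.gene_ids if any(g.upper().startswith(p) for p in mito_prefixes)]
    ribo = [g for g in counts.gene_ids if any(g.upper().startswith(p) for p in ribo_prefixes)]
    for name, genes in (("mito_fraction", mito), ("ribo_fraction", ribo)):
        m = _gene_set_mean(normalized, counts.gene_ids, genes, name)
        if m is not None:
            cov[name] = m

    for name, genes in (gene_sets or {}).items():
        m = _gene_set_mean(normalized, counts.gene_ids, genes, name)
        if m is None:
            continue
        sd = m.std()
        cov[name] = (m - m.mean()) / sd if sd > 0 else 0.0

    if extras is not None:
        unknown = [c for c in extras.index if c not in set(counts.cell_ids)]
        if unknown:
            raise ValueError(f"extra covariates reference unknown cells: {unknown[:5]}")
        for col in extras.columns:
            cov[col] = extras[col].reindex(cov.index).to_numpy()

    usable = cov.std(axis=0) > 0
    for col in cov.columns[~usable]:
        warnings.warn(f"covariate {col!r} has zero variance; flagged unusable")
    return cov
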