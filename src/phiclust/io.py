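"""Readers and writers for the standard on-disk formats.

Counts are genes x cells throughout: MatrixMarket ``.mtx`` with
``genes.tsv`` / ``barcodes.tsv`` sidecars (rows = genes, columns =
cells, as written by CellRanger-style pipelines) or dense CSV/TSV with
gene ids in the first column and cell ids in the header row.  Results go
out as a JSON document plus a flat TSV summary; re-reading the JSON
reproduces every number bit-exactly (floats round-trip through repr).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "read_counts",
    "read_labels",
    "read_covariates",
    "read_gene_set",
    "write_results",
    "read_results",
    "write_counts",
]


@dataclass
class CountMatrix:
    """Raw genes x cells integer counts with identifiers.

    ``values`` has genes as rows and cells as columns; ``gene_ids`` and
    ``cell_ids`` are unique and match the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.values.size and self.values.min() < 0:
            i, j = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise ValueError(
                f"negative count at gene {self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids: list[str]) -> "CountMatrix":
        """Column subset in the given order."""
        idx = {c: k for k, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in idx]
        if missing:
            raise KeyError(f"cell ids not in matrix: {missing[:5]}")
        cols = [idx[c] for c in cell_ids]
        return CountMatrix(self.values[:, cols], list(self.gene_ids), list(cell_ids))


def _read_sidecar(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(path: str | Path, format: str | None = None, transpose: bool = False) -> CountMatrix:
    """Read a genes x cells count matrix.

    ``format`` is ``"mtx"``, ``"csv"`` or ``"tsv"``; ``None`` infers it
    from the suffix.  For ``mtx``, ``genes.tsv`` and ``barcodes.tsv``
    sidecars must sit in the same directory.  ``transpose`` flips a
    dense file whose rows are cells; it is never auto-detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        genes = _read_sidecar(path.parent / "genes.tsv")
        cells = _read_sidecar(path.parent / "barcodes.tsv")
        if transpose:
            mat = mat.T
        if mat.shape[0] != len(genes):
            raise ValueError(
                f"matrix has {mat.shape[0]} rows but genes.tsv lists {len(genes)} genes"
            )
        if mat.shape[1] != len(cells):
            raise ValueError(
                f"matrix has {mat.shape[1]} columns but barcodes.tsv lists {len(cells)} cells"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if transpose:
            df = df.T
        mat = df.to_numpy()
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")
    if not np.issubdtype(mat.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    return CountMatrix(mat, genes, cells)


def write_counts(counts: CountMatrix, out_dir: str | Path, format: str = "mtx") -> None:
    """Write counts as mtx + sidecars, or as a dense CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        scipy.io.mmwrite(out_dir / "matrix.mtx", scipy.sparse.coo_matrix(counts.values))
        pd.Series(counts.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(counts.cell_ids).to_csv(out_dir / "barcodes.tsv", sep="\t", header=False, index=False)
    elif format == "csv":
        pd.DataFrame(counts.values, index=counts.gene_ids, columns=counts.cell_ids).to_csv(
            out_dir / "counts.csv"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``cell_id<TAB>cluster`` into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label table needs cell_id and cluster columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="cluster")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate TSV (first column cell_id, one column per covariate)."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.astype(float)


def read_gene_set(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(results: list, out_dir: str | Path) -> None:
    """Write per-cluster results as JSON plus a TSV summary.

    The JSON carries everything (components included); the TSV holds
    one row per cluster with the headline numbers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"clusters": [_to_jsonable(r) for r in results]}
    with open(out_dir / "phiclust.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    rows = []
    for r in payload["clusters"]:
        rows.append(
            {
                "cluster_id": r["cluster_id"],
                "phiclust": r["phiclust"],
                "g_phiclust": r["g_phiclust"],
                "sigma_plus": r["sigma_plus"],
                "sigma_minus": r["sigma_minus"],
                "bulk_ks_p_adjusted": r["bulk_ks_p_adjusted"],
                "n_cells": r["n_cells"],
                "n_significant": len(r["components"]),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "phiclust.tsv", sep="\t", index=False)


def read_results(out_dir: str | Path) -> dict:
    """Read back the JSON written by :func:`write_results`."""
    with open(Path(out_dir) / "phiclust.json") as fh:
        return json.load(fh)
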