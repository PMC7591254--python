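"""Normalisation, covariate regression, variable-gene selection, and PCA.

The processing chain mirrors the standard single-cell workflow: depth
log-normalisation, per-gene ordinary-least-squares regression of total UMI
and mitochondrial content, selection of the 3,000 most variable genes by
trend-standardised variance, and PCA on the standardised variable-gene
submatrix (components 1-10 feed clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .simulate import CountMatrix


@dataclass
class NormalizedMatrix:
    """Genes x cells real matrix of log-normalised expression.

    ``values`` is sparse after :func:`log_normalize` and dense after
    :func:`regress_covariates` (residuals lose sparsity). Gene and cell
    identities are carried alongside so downstream tables stay labelled.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_total: int = 10_000
    covariates_regressed: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def gene_vector(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"gene {gene_id!r} not present")
        row = self.values[idx[0], :]
        return row.toarray().ravel() if sp.issparse(row) else np.asarray(row).ravel()


def log_normalize(matrix: CountMatrix, scale_total: int = 10_000) -> NormalizedMatrix:
    """value(g, c) = ln(1 + count(g, c) * scale_total / total(c))."""
    counts = matrix.counts.tocsc().astype(np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = matrix.cell_meta["cell_id"].iloc[zero[:5]].tolist()
        raise ValueError(f"cells with zero total counts: {names}")
    scaled = counts.multiply(sp.csr_matrix(scale_total / totals))
    values = scaled.log1p().tocsr()
    return NormalizedMatrix(
        values=values,
        gene_ids=matrix.gene_meta["gene_id"].to_numpy(),
        cell_ids=matrix.cell_meta["cell_id"].to_numpy(),
        scale_total=scale_total,
    )


def regress_covariates(
    norm: NormalizedMatrix, covariates: pd.DataFrame
) -> NormalizedMatrix:
    """Per-gene OLS of expression on the covariate columns; returns residuals.

    ``covariates`` rows align with cells; constant columns are dropped with
    a warning (they would alias the intercept). The residuals feed variable-
    gene selection, PCA, and clustering; detection-based statistics (the
    hurdle test, gating) read the log-normalised matrix, whose zero
    structure regression would destroy.
    """
    if len(covariates) != norm.n_cells:
        raise ValueError("covariate rows must match cell count")
    cols = []
    names = []
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped")
            continue
        cols.append((x - x.mean()) / x.std())
        names.append(name)
    Y = norm.dense()
    if not cols:
        return NormalizedMatrix(
            values=Y, gene_ids=norm.gene_ids, cell_ids=norm.cell_ids,
            scale_total=norm.scale_total, covariates_regressed=[],
        )
    X = np.column_stack([np.ones(norm.n_cells)] + cols)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    return NormalizedMatrix(
        values=resid.astype(np.float32),
        gene_ids=norm.gene_ids,
        cell_ids=norm.cell_ids,
        scale_total=norm.scale_total,
        covariates_regressed=names,
    )


def _row_mean_var(values) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(values):
        n = values.shape[1]
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=1)).ravel()
        var = (sq - mean**2) * n / max(n - 1, 1)
    else:
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1)
    return mean, np.maximum(var, 0.0)


def standardized_variance(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-gene variance standardised against a fitted mean-variance trend.

    The trend is a lowess fit of variance on mean over expressed genes;
    the ratio variance / trend(mean) ranks genes so that highly expressed
    genes do not dominate by magnitude alone.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mean, var = _row_mean_var(norm.values)
    expressed = mean > 0
    std_var = np.zeros_like(var)
    if expressed.sum() >= 10 and np.ptp(mean[expressed]) > 0:
        fit = lowess(var[expressed], mean[expressed], frac=0.3, return_sorted=True)
        trend = np.interp(mean, fit[:, 0], fit[:, 1])
        trend = np.maximum(trend, 1e-12)
        std_var = np.where(expressed, var / trend, 0.0)
    else:
        std_var = var  # too few genes for a trend; raw variance ranking
    return pd.DataFrame(
        {"gene_id": norm.gene_ids, "mean": mean, "variance": var,
         "standardized_variance": std_var}
    )


def select_hvgs(norm: NormalizedMatrix, n: int = 3000) -> list[str]:
    """The ``n`` genes of highest standardised variance, ties by gene order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    table = standardized_variance(norm)
    if n >= len(table):
        if n > len(table):
            warnings.warn("n exceeds gene count; returning all genes")
        return list(table["gene_id"])
    order = np.lexsort(
        (np.arange(len(table)), -table["standardized_variance"].to_numpy())
    )
    return list(table["gene_id"].to_numpy()[order[:n]])


def reduce_pca(
    norm: NormalizedMatrix, hvgs: list[str], n_pcs: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Cells x n_pcs principal-component scores of the standardised HVG matrix.

    Each variable gene is centred and unit-scaled before decomposition;
    component sign is fixed so the largest-magnitude gene loading is
    positive. Returns (scores, explained_variance).
    """
    if len(hvgs) == 0:
        raise ValueError("hvgs must be nonempty")
    idx = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = np.array([idx[g] for g in hvgs])
    sub = norm.values[rows, :]
    X = (sub.toarray() if sp.issparse(sub) else np.asarray(sub)).astype(np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    max_pcs = min(X.shape)
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(dims)={max_pcs}")
    pca = PCA(n_components=n_pcs, svd_solver="auto", random_state=seed)
    scores = pca.fit_transform(X.T)
    # Deterministic sign: largest-|loading| entry positive per component.
    for k in range(n_pcs):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            scores[:, k] *= -1
            pca.components_[k] *= -1
    return scores, pca.explained_variance_
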