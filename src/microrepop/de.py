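"""Two-part hurdle-model differential expression for single-cell data.

Each gene is tested with a hurdle model in the MAST family: a logistic
(binomial) component for detection (expression > 0) and an equal-variance
Gaussian component for the positive log-expression values, each with a
group term. Both components have closed-form maximum-likelihood estimates
for a two-group contrast, so the likelihood-ratio statistic is the sum of
two closed-form component LRTs referred to a chi-square whose degrees of
freedom count only the informative components (an all-zero or one-sided
component contributes zero df).

Fold changes use the log-normalised-data convention: the difference of
ln(mean(exp(x) - 1) + 1) between groups, so the 0.25 / 0.5 thresholds have
their usual meaning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

_SS_FLOOR = 1e-12


def _binomial_lrt(ka, na, kb, nb):
    """Closed-form LRT of equal detection probability; returns (stat, df)."""
    ka = np.asarray(ka, dtype=float)
    kb = np.asarray(kb, dtype=float)
    k = ka + kb
    n = float(na + nb)

    def ll(k_, n_):
        return xlogy(k_, k_ / n_) + xlogy(n_ - k_, 1 - k_ / n_)

    stat = 2.0 * (ll(ka, na) + ll(kb, nb) - ll(k, n))
    informative = (k > 0) & (k < n)
    stat = np.where(informative, np.maximum(stat, 0.0), 0.0)
    df = informative.astype(int)
    return stat, df


def _gaussian_lrt(na_pos, suma, ssqa, nb_pos, sumb, ssqb):
    """Closed-form equal-variance Gaussian LRT on positive values.

    Inputs are per-gene counts, sums, and sums of squares of the positive
    values in each group. Returns (stat, df).
    """
    na_pos = np.asarray(na_pos, dtype=float)
    nb_pos = np.asarray(nb_pos, dtype=float)
    n = na_pos + nb_pos
    informative = (na_pos > 0) & (nb_pos > 0) & (n >= 3)

    with np.errstate(divide="ignore", invalid="ignore"):
        ss_a = ssqa - np.where(na_pos > 0, suma**2 / na_pos, 0.0)
        ss_b = ssqb - np.where(nb_pos > 0, sumb**2 / nb_pos, 0.0)
        ss_full = np.maximum(ss_a + ss_b, 0.0)
        grand = (suma + sumb) / np.where(n > 0, n, 1.0)
        ss_null = np.maximum(ssqa + ssqb - n * grand**2, 0.0)
        ratio = np.where(
            ss_full > _SS_FLOOR,
            ss_null / np.maximum(ss_full, _SS_FLOOR),
            np.where(ss_null > _SS_FLOOR, np.inf, 1.0),
        )
        stat = n * np.log(ratio)
    stat = np.where(informative, np.maximum(stat, 0.0), 0.0)
    df = informative.astype(int)
    return stat, df


def hurdle_test(expr_a: np.ndarray, expr_b: np.ndarray) -> tuple[float, float]:
    """Hurdle LRT between two per-cell log-expression vectors.

    Returns (statistic, p_value). A gene with zero expression in both
    groups is untestable and returns (0.0, 1.0).
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    stat, df, p = _hurdle_matrix(a[None, :], b[None, :])
    return float(stat[0]), float(p[0])


def _hurdle_matrix(A: np.ndarray, B: np.ndarray):
    """Vectorised hurdle test over genes (rows)."""
    pos_a = A > 0
    pos_b = B > 0
    ka = pos_a.sum(axis=1)
    kb = pos_b.sum(axis=1)
    stat_d, df_d = _binomial_lrt(ka, A.shape[1], kb, B.shape[1])
    stat_c, df_c = _gaussian_lrt(
        ka, np.where(pos_a, A, 0.0).sum(axis=1), np.where(pos_a, A**2, 0.0).sum(axis=1),
        kb, np.where(pos_b, B, 0.0).sum(axis=1), np.where(pos_b, B**2, 0.0).sum(axis=1),
    )
    stat = stat_d + stat_c
    df = df_d + df_c
    p = np.ones_like(stat)
    testable = df > 0
    p[testable] = chi2.sf(stat[testable], df[testable])
    return stat, df, p


def _group_summaries(values, cols: np.ndarray):
    """(n, k_detected, sum, sumsq, sum_expm1) over a cell subset, per gene."""
    n = cols.size
    sub = values[:, cols]
    if sp.issparse(sub):
        sub = sub.tocsr()
        k = np.asarray((sub > 0).sum(axis=1)).ravel()
        s = np.asarray(sub.sum(axis=1)).ravel()
        ssq = np.asarray(sub.multiply(sub).sum(axis=1)).ravel()
        sexp = np.asarray(sub.expm1().sum(axis=1)).ravel()
    else:
        sub = np.asarray(sub, dtype=np.float64)
        pos = sub > 0
        k = pos.sum(axis=1)
        s = np.where(pos, sub, 0.0).sum(axis=1)
        ssq = np.where(pos, sub**2, 0.0).sum(axis=1)
        sexp = np.where(pos, np.expm1(sub), 0.0).sum(axis=1)
    return n, k, s, ssq, sexp


def log_fold_change(sexp_a, na, sexp_b, nb) -> np.ndarray:
    """ln(mean(expm1 x_a) + 1) - ln(mean(expm1 x_b) + 1)."""
    return np.log(sexp_a / na + 1.0) - np.log(sexp_b / nb + 1.0)


def _de_table(
    values, gene_ids, cells_a: np.ndarray, cells_b: np.ndarray,
    logfc_min: float, min_pct: float, adjust: str,
) -> pd.DataFrame:
    na, ka, sa, ssqa, sexpa = _group_summaries(values, cells_a)
    nb, kb, sb, ssqb, sexpb = _group_summaries(values, cells_b)
    pct_a = ka / na
    pct_b = kb / nb
    lfc = log_fold_change(sexpa, na, sexpb, nb)

    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(lfc) >= logfc_min)
    idx = np.flatnonzero(tested)
    stat = np.zeros(len(gene_ids))
    p = np.ones(len(gene_ids))
    if idx.size:
        stat_d, df_d = _binomial_lrt(ka[idx], na, kb[idx], nb)
        stat_c, df_c = _gaussian_lrt(
            ka[idx], sa[idx], ssqa[idx], kb[idx], sb[idx], ssqb[idx]
        )
        s = stat_d + stat_c
        df = df_d + df_c
        pv = np.ones(idx.size)
        ok = df > 0
        pv[ok] = chi2.sf(s[ok], df[ok])
        stat[idx] = s
        p[idx] = pv

    if adjust == "bonferroni":
        # Bonferroni over every gene in the matrix (the standard single-cell
        # convention), not just the fold-change-filtered ones: the filter
        # selects for extreme observed differences, so adjusting only over
        # survivors would be anti-conservative.
        p_adj_t = np.minimum(p[idx] * len(gene_ids), 1.0) if idx.size else np.array([])
    elif adjust == "bh":
        p_adj_t = multipletests(p[idx], method="fdr_bh")[1] if idx.size else np.array([])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    p_adj = np.ones(len(gene_ids))
    p_adj[idx] = p_adj_t

    table = pd.DataFrame(
        {
            "gene": np.asarray(gene_ids)[idx],
            "log_fc": lfc[idx],
            "p_value": p[idx],
            "p_adj": np.maximum(p_adj[idx], p[idx]),
            "pct_a": pct_a[idx],
            "pct_b": pct_b[idx],
        }
    )
    table["direction"] = np.where(table["log_fc"] >= 0, "up", "down")
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def find_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    group,
    logfc_min: float = 0.25,
    min_pct: float = 0.10,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Markers of one cluster versus all other cells.

    Genes are pre-filtered by fold change (|log FC| >= ``logfc_min``) and
    detection (>= ``min_pct`` of either group) before hurdle testing;
    adjusted p-values cover the tested genes.
    """
    labels = np.asarray(labels)
    cells_a = np.flatnonzero(labels == group)
    cells_b = np.flatnonzero(labels != group)
    if cells_a.size < 3:
        raise ValueError(f"group {group!r} has fewer than 3 cells")
    if cells_b.size == 0:
        raise ValueError("comparison group is empty")
    return _de_table(
        norm.values, norm.gene_ids, cells_a, cells_b, logfc_min, min_pct, adjust
    )


def contrast_de(
    norm: NormalizedMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    logfc_min: float = 0.5,
    min_pct: float = 0.10,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Hurdle DE between two arbitrary, disjoint cell sets."""
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.dtype == bool:
        cells_a = np.flatnonzero(cells_a)
    if cells_b.dtype == bool:
        cells_b = np.flatnonzero(cells_b)
    if np.intersect1d(cells_a, cells_b).size:
        raise ValueError("cell sets overlap")
    if cells_a.size < 3 or cells_b.size < 3:
        raise ValueError("each cell set needs at least 3 cells")
    return _de_table(
        norm.values, norm.gene_ids, cells_a, cells_b, logfc_min, min_pct, adjust
    )
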