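"""Differential cell abundance across conditions via a negative-binomial GLM.

Cells-per-cluster counts per sample are modelled as NB with a log link, the
log of each sample's total captured cells as offset (so frequencies, not raw
counts, are compared), and condition as the covariate. Coefficients are fit
by iteratively reweighted least squares. A common dispersion shared across
clusters is estimated by profile maximum likelihood (per-sample means from
the fitted models); each contrast is then tested with a quasi-likelihood
deviance F test — the deviance drop for the contrast divided by the
cluster's residual-deviance scale, referred to F(1, df_resid). With no
residual degrees of freedom the test falls back to a likelihood-ratio
chi-square with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2, f as f_dist
from statsmodels.stats.multitest import multipletests

_ETA_CAP = 30.0


@dataclass
class ClusterCounts:
    """Samples x clusters cell-count table with per-sample metadata."""

    counts: pd.DataFrame  # rows = samples, columns = clusters
    condition: pd.Series  # per sample
    total_cells: pd.Series  # per sample

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 samples")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        row_sums = self.counts.sum(axis=1)
        if (row_sums > self.total_cells.loc[self.counts.index]).any():
            raise ValueError("row sums exceed per-sample totals")


def tabulate_counts(
    cell_meta: pd.DataFrame,
    sample_col: str = "sample_id",
    cluster_col: str = "cluster",
    condition_col: str = "condition",
    totals: pd.Series | None = None,
) -> ClusterCounts:
    """Contingency table of cells per (sample, cluster) plus sample totals.

    ``totals`` defaults to the per-sample cell counts of ``cell_meta``; pass
    the pre-filtering totals to normalise against all captured cells.
    """
    table = (
        cell_meta.groupby([sample_col, cluster_col], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    condition = (
        cell_meta.drop_duplicates(sample_col)
        .set_index(sample_col)[condition_col]
        .loc[table.index]
    )
    if totals is None:
        totals = cell_meta.groupby(sample_col).size().loc[table.index]
    else:
        totals = totals.loc[table.index]
    return ClusterCounts(counts=table, condition=condition, total_cells=totals)


def _nb_loglik(y, mu, alpha) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if alpha < 1e-10:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - r * np.log1p(alpha * mu)
        )
    )


def _nb_deviance(y, mu, alpha) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
        if alpha < 1e-10:
            dev = term - (y - mu)
        else:
            r = 1.0 / alpha
            dev = term - (y + r) * np.log((1 + alpha * y) / (1 + alpha * mu))
    return float(2.0 * np.sum(dev))


def _irls(y, X, offset, alpha, max_iter=100, tol=1e-12):
    """NB (or Poisson at alpha=0) IRLS with log link and offset."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mu = np.maximum(y, 0.5)
    eta = np.log(mu)
    beta, *_ = np.linalg.lstsq(X, eta - offset, rcond=None)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            new, *_ = np.linalg.lstsq(WX, w * z, rcond=None)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = np.clip(X @ beta + offset, -_ETA_CAP, _ETA_CAP)
    return beta, np.exp(eta)


def _design(condition: np.ndarray, levels: list[str]) -> np.ndarray:
    """Treatment-coded design: intercept + one indicator per non-reference level."""
    cols = [np.ones(condition.shape[0])]
    for lv in levels[1:]:
        cols.append((condition == lv).astype(float))
    return np.column_stack(cols)


def fit_nb_glm(
    y, condition, offset, alpha: float | None = None
) -> tuple[pd.Series, float]:
    """Fit one cluster's NB GLM; returns (named coefficients, dispersion).

    ``condition`` is a factor; the first level in sorted-unique order (or a
    pandas Categorical's declared order) is the reference. ``offset`` is the
    per-sample log total. ``alpha`` (NB2 dispersion, variance =
    mu + alpha mu^2) is estimated by profile likelihood when not given.
    """
    y = np.asarray(y, dtype=float)
    condition = np.asarray(condition)
    offset = np.asarray(offset, dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero counts; nothing to fit")
    levels = list(pd.unique(condition))
    X = _design(condition, levels)
    if alpha is None:
        _, mu0 = _irls(y, X, offset, alpha=0.0)
        alpha = _profile_alpha([(y, mu0)])
        beta, mu = _irls(y, X, offset, alpha=alpha)
        alpha = _profile_alpha([(y, mu)])
    beta, _ = _irls(y, X, offset, alpha=alpha)
    names = ["intercept"] + [f"{lv}_vs_{levels[0]}" for lv in levels[1:]]
    return pd.Series(beta, index=names), float(alpha)


def _profile_alpha(pairs) -> float:
    """Common NB dispersion maximising the summed profile likelihood."""

    def neg(log_alpha):
        a = float(np.exp(log_alpha))
        return -sum(_nb_loglik(y, mu, a) for y, mu in pairs)

    ll_poisson = -sum(_nb_loglik(y, mu, 0.0) for y, mu in pairs)
    res = minimize_scalar(neg, bounds=(np.log(1e-6), np.log(50.0)), method="bounded")
    if not res.success or -res.fun < -ll_poisson:
        return 0.0
    alpha = float(np.exp(res.x))
    return 0.0 if alpha <= 2e-6 else alpha


def estimate_common_dispersion(counts: ClusterCounts) -> float:
    """Profile-ML common dispersion across all clusters.

    Means come from per-cluster Poisson fits, the shared alpha maximises the
    pooled NB likelihood at those means, and one NB refit of the means
    stabilises the estimate.
    """
    cond = counts.condition.to_numpy()
    levels = list(pd.unique(cond))
    X = _design(cond, levels)
    offset = np.log(counts.total_cells.to_numpy(dtype=float))
    ys = [
        counts.counts[c].to_numpy(dtype=float)
        for c in counts.counts.columns
        if counts.counts[c].sum() > 0
    ]
    if not ys:
        return 0.0
    pairs = [(y, _irls(y, X, offset, 0.0)[1]) for y in ys]
    alpha = _profile_alpha(pairs)
    pairs = [(y, _irls(y, X, offset, alpha)[1]) for y in ys]
    return _profile_alpha(pairs)


def test_abundance(
    counts: ClusterCounts,
    contrasts: list[tuple[str, str]] | None = None,
    alpha: float | None = None,
    adjust: str | None = None,
) -> pd.DataFrame:
    """QL deviance F test of each contrast for every cluster.

    ``contrasts`` are (level, reference) pairs, defaulting to each
    non-reference condition versus the first level (Ctrl first when
    present). Returns a tidy frame with log_fold_change (natural log of the
    frequency ratio), p_value, and the dispersion used. ``adjust='bh'``
    adds Benjamini-Hochberg-adjusted p-values across rows.
    """
    cond = counts.condition.to_numpy()
    levels = list(pd.unique(cond))
    if "Ctrl" in levels:
        levels = ["Ctrl"] + [l for l in levels if l != "Ctrl"]
    if contrasts is None:
        contrasts = [(lv, levels[0]) for lv in levels[1:]]
    for a, b in contrasts:
        if a not in levels or b not in levels:
            raise ValueError(f"contrast ({a}, {b}) references an absent level")

    offset = np.log(counts.total_cells.to_numpy(dtype=float))
    if alpha is None:
        alpha = estimate_common_dispersion(counts)

    X_full = _design(cond, levels)
    n, p = X_full.shape
    df_resid = n - p
    rows = []
    for cluster in counts.counts.columns:
        y = counts.counts[cluster].to_numpy(dtype=float)
        if y.sum() == 0:
            for lv, ref in contrasts:
                rows.append((cluster, f"{lv}_vs_{ref}", np.nan, np.nan, alpha, "all_zero"))
            continue
        beta, mu_full = _irls(y, X_full, offset, alpha)
        dev_full = _nb_deviance(y, mu_full, alpha)
        coef = dict(zip(["intercept"] + [f"{lv}" for lv in levels[1:]], beta))
        for lv, ref in contrasts:
            # Null model: the two contrasted levels share a mean.
            merged = np.where(cond == lv, ref, cond)
            null_levels = [l for l in levels if l != lv]
            X_null = _design(merged, null_levels)
            _, mu_null = _irls(y, X_null, offset, alpha)
            dev_null = _nb_deviance(y, mu_null, alpha)
            dev_drop = max(dev_null - dev_full, 0.0)
            lfc = coef.get(lv, 0.0) - coef.get(ref, 0.0)
            flag = ""
            if (y[cond == lv].sum() == 0) or (y[cond == ref].sum() == 0):
                flag = "separation"
            if df_resid > 0:
                scale = max(dev_full / df_resid, 1e-8)
                p_val = float(f_dist.sf(dev_drop / scale, 1, df_resid))
            else:
                warnings.warn(
                    "no residual degrees of freedom; likelihood-ratio chi-square used"
                )
                p_val = float(chi2.sf(dev_drop, 1))
            rows.append((cluster, f"{lv}_vs_{ref}", lfc, p_val, alpha, flag))
    out = pd.DataFrame(
        rows,
        columns=["cluster", "contrast", "log_fold_change", "p_value", "dispersion", "flag"],
    )
    if adjust == "bh":
        ok = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out
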