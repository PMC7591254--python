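"""Marker-threshold gating of MAC2+ (Lgals3-high) cells.

A cell is called positive when its log-normalised expression of the marker
exceeds the pooled mean plus ``k_sd`` sample standard deviations, computed
over all cells (zeros included) — the "one standard deviation above the
average log UMI counts" rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GateResult:
    threshold: float
    k_sd: float
    labels: np.ndarray  # per-cell boolean

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_total(self) -> int:
        return int(self.labels.size)


def gate_positive(expr: np.ndarray, k_sd: float = 1.0, ddof: int = 1) -> GateResult:
    """Threshold = mean + k_sd * sd over all cells; positive iff strictly above."""
    expr = np.asarray(expr, dtype=float)
    if expr.size == 0:
        raise ValueError("expression vector is empty")
    mean = expr.mean()
    sd = expr.std(ddof=ddof) if expr.size > ddof else 0.0
    if sd == 0:
        warnings.warn("zero variance; threshold equals mean, no positives")
    threshold = mean + k_sd * sd
    return GateResult(threshold=float(threshold), k_sd=k_sd, labels=expr > threshold)


def condition_frequencies(gate: GateResult, conditions) -> pd.DataFrame:
    """Per condition: positives, totals, and percentage to one decimal."""
    conditions = np.asarray(conditions)
    if conditions.size != gate.labels.size:
        raise ValueError("condition labels must cover all gated cells")
    rows = []
    for cond in pd.unique(conditions):
        mask = conditions == cond
        n_total = int(mask.sum())
        if n_total == 0:
            warnings.warn(f"condition {cond!r} has zero cells; omitted")
            continue
        n_pos = int(gate.labels[mask].sum())
        rows.append((cond, n_pos, n_total, round(100.0 * n_pos / n_total, 1)))
    return pd.DataFrame(rows, columns=["condition", "n_positive", "n_total", "pct"])


def frequencies_from_counts(pairs: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Condition frequencies from explicit (n_positive, n_total) pairs.

    Convenience for tabulating published count pairs; same rounding rule as
    :func:`condition_frequencies`.
    """
    rows = [
        (cond, pos, tot, round(100.0 * pos / tot, 1))
        for cond, (pos, tot) in pairs.items()
    ]
    return pd.DataFrame(rows, columns=["condition", "n_positive", "n_total", "pct"])


def cluster_composition(gate: GateResult, clusters) -> pd.DataFrame:
    """Counts of positive cells per cluster; counts sum to total positives."""
    clusters = np.asarray(clusters)
    if clusters.size != gate.labels.size:
        raise ValueError("cluster labels must cover all gated cells")
    pos = clusters[gate.labels]
    ids, counts = np.unique(pos, return_counts=True)
    total = counts.sum()
    return pd.DataFrame(
        {
            "cluster": ids,
            "n_positive": counts,
            "pct_of_positives": np.round(100.0 * counts / max(total, 1), 1),
        }
    )


def gate_metrics(gate: GateResult, truth) -> dict[str, float]:
    """Sensitivity/specificity of the gate against ground-truth labels."""
    truth = np.asarray(truth, dtype=bool)
    called = gate.labels
    tp = int((called & truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    fp = int((called & ~truth).sum())
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "n_true": int(truth.sum()),
        "n_called": int(called.sum()),
    }
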