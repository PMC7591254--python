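"""Hurdle-model DE: closed-form components vs oracles, planted effects."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

from microrepop.de import contrast_de, find_markers, hurdle_test
from microrepop.preprocess import NormalizedMatrix


def _norm(values):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(values.shape[0])]),
        cell_ids=np.array([f"c{i}" for i in range(values.shape[1])]),
    )


def _binomial_lrt_oracle(ka, na, kb, nb):
    """Brute-force maximised binomial log-likelihood ratio."""

    def ll(k, n, p):
        return xlogy(k, p) + xlogy(n - k, 1 - p)

    def max_ll(k, n):
        res = minimize_scalar(
            lambda p: -ll(k, n, p), bounds=(1e-9, 1 - 1e-9), method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    return 2 * (max_ll(ka, na) + max_ll(kb, nb) - max_ll(ka + kb, na + nb))


class TestHurdleTest:
    def test_identical_groups_give_null(self):
        x = np.array([0.0, 1.2, 0.0, 2.0, 0.7])
        stat, p = hurdle_test(x, x.copy())
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_gene_untestable(self):
        stat, p = hurdle_test(np.zeros(5), np.zeros(7))
        assert p == 1.0

    def test_detection_component_matches_brute_force_oracle(self):
        """5/5 vs 0/5 detection: statistic equals the maximised binomial LRT."""
        a = np.array([1.0, 1.0, 1.0, 1.0, 1.0])  # constant positives: no
        b = np.zeros(5)  # Gaussian contribution, detection only
        stat, _ = hurdle_test(a, b)
        assert stat == pytest.approx(_binomial_lrt_oracle(5, 5, 0, 5), abs=1e-6)

    def test_mixed_detection_matches_oracle(self):
        a = np.array([2.0, 0.0, 2.0, 2.0, 0.0, 2.0])  # 4/6, constant positives
        b = np.array([0.0, 0.0, 2.0, 0.0])  # 1/4, same positive value
        stat, _ = hurdle_test(a, b)
        assert stat == pytest.approx(_binomial_lrt_oracle(4, 6, 1, 4), abs=1e-6)

    def test_symmetry_under_group_swap(self, rng):
        a = np.maximum(rng.normal(1, 1, 40), 0)
        b = np.maximum(rng.normal(0.5, 1, 30), 0)
        sa, pa = hurdle_test(a, b)
        sb, pb = hurdle_test(b, a)
        assert sa == pytest.approx(sb, rel=1e-10)
        assert pa == pytest.approx(pb, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            hurdle_test(np.array([]), np.ones(3))


def _simulate_groups(rng, n_genes, n_a, n_b, logfc_rows=(), logfc=0.0, size=5.0):
    mu = rng.gamma(0.5, 4.0, size=n_genes) + 0.05
    mu_a = mu.copy()
    for r in logfc_rows:
        mu_a[r] *= np.exp(logfc)
    A = rng.poisson(rng.gamma(size, mu_a[:, None] / size, (n_genes, n_a)))
    B = rng.poisson(rng.gamma(size, mu[:, None] / size, (n_genes, n_b)))
    counts = np.hstack([A, B])
    totals = counts.sum(axis=0)
    values = np.log1p(counts * 1e4 / np.maximum(totals, 1))
    labels = np.array([1] * n_a + [0] * n_b)
    return _norm(values), labels


class TestFindMarkers:
    def test_planted_marker_recovered(self, rng):
        norm, labels = _simulate_groups(
            rng, 100, 500, 1500, logfc_rows=range(5), logfc=1.0
        )
        table = find_markers(norm, labels, group=1)
        hits = set(table.loc[table["p_adj"] < 0.01, "gene"])
        assert {"g0", "g1", "g2", "g3", "g4"} <= hits

    def test_null_split_yields_no_markers(self):
        zero_marker_reps = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            norm, labels = _simulate_groups(rng, 150, 150, 150)
            table = find_markers(norm, labels, group=1)
            if (table["p_adj"] < 0.05).sum() == 0:
                zero_marker_reps += 1
        assert zero_marker_reps >= reps - 1

    def test_infinite_logfc_threshold_empties_table(self, rng):
        norm, labels = _simulate_groups(rng, 50, 100, 100)
        table = find_markers(norm, labels, group=1, logfc_min=np.inf)
        assert len(table) == 0

    def test_small_group_rejected(self, rng):
        norm, _ = _simulate_groups(rng, 20, 50, 50)
        labels = np.zeros(100, dtype=int)
        labels[:2] = 1
        with pytest.raises(ValueError, match="fewer than 3"):
            find_markers(norm, labels, group=1)

    def test_p_adj_never_below_p(self, rng):
        norm, labels = _simulate_groups(rng, 80, 200, 200, logfc_rows=range(10),
                                        logfc=0.8)
        table = find_markers(norm, labels, group=1)
        assert (table["p_adj"] >= table["p_value"] - 1e-15).all()


class TestContrastDE:
    def test_overlapping_cell_sets_rejected(self, rng):
        norm, _ = _simulate_groups(rng, 20, 50, 50)
        with pytest.raises(ValueError, match="overlap"):
            contrast_de(norm, np.arange(10), np.arange(5, 15))

    def test_threshold_nesting(self, rng):
        norm, labels = _simulate_groups(rng, 150, 300, 300,
                                        logfc_rows=range(20), logfc=1.2)
        a = np.flatnonzero(labels == 1)
        b = np.flatnonzero(labels == 0)
        strict = set(contrast_de(norm, a, b, logfc_min=0.5)["gene"])
        loose = set(contrast_de(norm, a, b, logfc_min=0.25)["gene"])
        assert strict <= loose

    def test_logfc_monotone_in_planted_effect(self):
        lfcs = []
        for effect in (0.5, 1.0, 1.5):
            rng = np.random.default_rng(7)
            norm, labels = _simulate_groups(
                rng, 50, 400, 400, logfc_rows=[0], logfc=effect
            )
            table = contrast_de(
                norm, np.flatnonzero(labels == 1), np.flatnonzero(labels == 0),
                logfc_min=0.0,
            )
            lfcs.append(float(table.set_index("gene").loc["g0", "log_fc"]))
        assert lfcs[0] < lfcs[1] < lfcs[2]

    def test_program_gene_recovery_on_synthetic_object(
        self, clustered_pipeline
    ):
        """MAC2-program genes planted at logFC 1.5 surface among up-DEGs."""
        ctx = clustered_pipeline
        matrix, norm = ctx["matrix"], ctx["norm_raw"]
        meta = matrix.cell_meta
        mac2 = meta["true_mac2"].to_numpy()
        homeo = (meta["true_population"] == "homeostatic").to_numpy() & ~mac2
        table = contrast_de(
            norm, np.flatnonzero(mac2), np.flatnonzero(homeo), logfc_min=0.5
        )
        up = set(table.loc[(table["p_adj"] < 0.05) & (table["direction"] == "up"),
                           "gene"])
        planted = set(ctx["params"].panels["lgals3_program_up"])
        detectable = planted & set(norm.gene_ids)
        sensitivity = len(up & detectable) / len(detectable)
        assert sensitivity >= 0.8
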