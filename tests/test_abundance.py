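"""NB-GLM differential abundance: oracles, identities, planted effects."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from microrepop.abundance import ClusterCounts, fit_nb_glm, tabulate_counts
from microrepop.abundance import test_abundance as abundance_test


def _cluster_counts(counts_dict, cond, totals):
    idx = [f"s{i}" for i in range(len(cond))]
    return ClusterCounts(
        counts=pd.DataFrame(counts_dict, index=idx),
        condition=pd.Series(cond, index=idx),
        total_cells=pd.Series(totals, index=idx),
    )


class TestTabulateCounts:
    def test_hand_counted_table(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s1", "s2", "s2"],
                "condition": ["Ctrl", "Ctrl", "Ctrl", "D0", "D0"],
                "cluster": [0, 0, 1, 1, 1],
            }
        )
        cc = tabulate_counts(meta)
        assert cc.counts.loc["s1", 0] == 2
        assert cc.counts.loc["s1", 1] == 1
        assert cc.counts.loc["s2", 0] == 0
        assert cc.counts.loc["s2", 1] == 2
        assert cc.total_cells.tolist() == [3, 2]
        assert cc.condition.tolist() == ["Ctrl", "D0"]

    def test_single_cluster_column_equals_totals(self):
        meta = pd.DataFrame(
            {"sample_id": ["a"] * 4 + ["b"] * 6,
             "condition": ["Ctrl"] * 4 + ["D0"] * 6,
             "cluster": [0] * 10}
        )
        cc = tabulate_counts(meta)
        assert (cc.counts[0] == cc.total_cells).all()

    def test_cell_order_invariance(self, rng):
        meta = pd.DataFrame(
            {"sample_id": rng.choice(["a", "b", "c"], 200),
             "cluster": rng.integers(0, 4, 200)}
        )
        meta["condition"] = meta["sample_id"].map({"a": "Ctrl", "b": "D0", "c": "D2"})
        shuffled = meta.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            tabulate_counts(meta).counts, tabulate_counts(shuffled).counts
        )


class TestFitNbGlm:
    def test_counts_proportional_to_offsets_give_zero_condition_effect(self):
        totals = np.array([1000, 2000, 1500, 1200, 1800, 900])
        y = (0.1 * totals).astype(int)  # exactly proportional
        cond = np.array(["Ctrl"] * 3 + ["D0"] * 3)
        coef, _ = fit_nb_glm(y, cond, np.log(totals), alpha=0.0)
        assert abs(coef["D0_vs_Ctrl"]) < 1e-6

    def test_poisson_oracle_match(self, rng):
        """With dispersion 0 the IRLS fit equals a statsmodels Poisson GLM."""
        totals = rng.integers(3000, 7000, 8)
        cond = np.array(["Ctrl"] * 4 + ["D0"] * 4)
        y = rng.poisson(0.07 * totals)
        coef, _ = fit_nb_glm(y, cond, np.log(totals), alpha=0.0)
        X = np.column_stack([np.ones(8), (cond == "D0").astype(float)])
        oracle = sm.GLM(
            y, X, family=sm.families.Poisson(), offset=np.log(totals)
        ).fit()
        np.testing.assert_allclose(coef.to_numpy(), oracle.params, atol=1e-4)

    def test_nb_oracle_match_at_fixed_dispersion(self, rng):
        totals = rng.integers(3000, 7000, 8)
        cond = np.array(["Ctrl"] * 4 + ["D0"] * 4)
        y = rng.negative_binomial(5, 5 / (5 + 0.05 * totals))
        alpha = 0.2
        coef, _ = fit_nb_glm(y, cond, np.log(totals), alpha=alpha)
        X = np.column_stack([np.ones(8), (cond == "D0").astype(float)])
        oracle = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(totals),
        ).fit()
        np.testing.assert_allclose(coef.to_numpy(), oracle.params, atol=1e-4)

    def test_estimated_dispersion_shrinks_on_poisson_data(self, rng):
        totals = np.full(40, 5000)
        cond = np.array(["Ctrl"] * 20 + ["D0"] * 20)
        y = rng.poisson(0.1 * totals)
        _, alpha = fit_nb_glm(y, cond, np.log(totals))
        assert alpha < 0.01

    def test_doubling_offsets_shifts_intercept_by_log_two(self, rng):
        totals = rng.integers(2000, 4000, 6)
        cond = np.array(["Ctrl"] * 3 + ["D0"] * 3)
        y = rng.poisson(0.05 * totals)
        c1, _ = fit_nb_glm(y, cond, np.log(totals), alpha=0.0)
        c2, _ = fit_nb_glm(y, cond, np.log(2 * totals), alpha=0.0)
        assert c2["intercept"] == pytest.approx(c1["intercept"] - np.log(2), abs=1e-6)
        assert c2["D0_vs_Ctrl"] == pytest.approx(c1["D0_vs_Ctrl"], abs=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_nb_glm(np.zeros(6), np.array(["Ctrl"] * 3 + ["D0"] * 3),
                       np.zeros(6), alpha=0.0)


class TestTestAbundance:
    def test_identical_profiles_give_null_pvalues(self):
        cc = _cluster_counts(
            {"c0": [500] * 6, "c1": [100] * 6},
            ["Ctrl"] * 3 + ["D0"] * 3, [1000] * 6,
        )
        res = abundance_test(cc, alpha=0.0)
        assert (res["p_value"] > 0.9).all()

    def test_one_sample_per_level_falls_back_to_chi_square(self):
        cc = _cluster_counts({"c0": [50, 400]}, ["Ctrl", "D0"], [1000, 1000])
        with pytest.warns(UserWarning, match="chi-square"):
            res = abundance_test(cc, alpha=0.0)
        assert res["p_value"].iloc[0] < 0.05

    def test_absent_contrast_level_rejected(self):
        cc = _cluster_counts({"c0": [5, 6, 7, 8]}, ["Ctrl"] * 2 + ["D0"] * 2,
                             [100] * 4)
        with pytest.raises(ValueError, match="absent"):
            abundance_test(cc, contrasts=[("D2", "Ctrl")])

    def test_all_zero_cluster_flagged(self):
        cc = _cluster_counts(
            {"c0": [50] * 6, "c1": [0] * 6}, ["Ctrl"] * 3 + ["D0"] * 3, [500] * 6
        )
        res = abundance_test(cc, alpha=0.0)
        zero_rows = res[res["cluster"] == "c1"]
        assert (zero_rows["flag"] == "all_zero").all()
        assert zero_rows["p_value"].isna().all()

    def test_scale_invariance_of_pvalues(self, rng):
        counts = {f"c{j}": rng.poisson(300, 6) for j in range(3)}
        cond = ["Ctrl"] * 3 + ["D0"] * 3
        cc1 = _cluster_counts(counts, cond, [2000] * 6)
        cc2 = _cluster_counts({k: 10 * v for k, v in counts.items()}, cond,
                              [20_000] * 6)
        p1 = abundance_test(cc1, alpha=0.0)["p_value"].to_numpy()
        p2 = abundance_test(cc2, alpha=0.0)["p_value"].to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_power_monotone_in_fold_change(self):
        pvals = []
        for fold in (1.5, 3.0, 8.0):
            rng = np.random.default_rng(9)
            totals = np.full(6, 5000)
            base = 0.01
            frac = np.array([base] * 3 + [base * fold] * 3)
            y = rng.binomial(totals, frac)
            cc = _cluster_counts(
                {"c0": rng.binomial(totals, 0.4), "c1": y},
                ["Ctrl"] * 3 + ["D0"] * 3, totals,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = abundance_test(cc)
            pvals.append(float(res.set_index(["cluster", "contrast"])
                               .loc[("c1", "D0_vs_Ctrl"), "p_value"]))
        assert pvals[0] > pvals[1] > pvals[2]

    def test_synthetic_condition_shift_detected(self, clustered_pipeline):
        """Planted proliferative expansion (0.12% -> 10%) reaches significance."""
        meta = clustered_pipeline["matrix"].cell_meta.copy()
        meta["cluster"] = meta["true_population"]
        cc = tabulate_counts(meta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = abundance_test(cc)
        row = res.set_index(["cluster", "contrast"])
        assert row.loc[("proliferative", "D0_vs_Ctrl"), "p_value"] < 0.01
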